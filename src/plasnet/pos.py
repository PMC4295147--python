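"""Preferential Organismal Sharing (POS) assignment.

The POS of a gene is the organism contributing its best-ranked external
homolog from a strain *other than* the query's own — other strains of the
same species are eligible.  The toolkit ingests a ranked external-homology
table (as produced by an online search against a general protein database)
and applies the first-non-self rule; no additional identity or E-value
floor is imposed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_io import RepliconSet

__all__ = [
    "ExternalHit",
    "PosRecord",
    "normalize_organism",
    "assign_pos",
    "read_external_hits",
    "pos_summary",
    "write_pos_table",
]


@dataclass(frozen=True)
class ExternalHit:
    """One ranked hit from an external homology search."""

    rank: int
    subject_organism: str
    percent_identity: float
    e_value: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class PosRecord:
    """The first non-self-strain hit for one protein (or none)."""

    protein_id: str
    pos_organism: str | None
    percent_identity: float | None = None
    e_value: float | None = None


def normalize_organism(name: str) -> str:
    """Case-folded, whitespace-collapsed 'genus species strain' string."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def assign_pos(
    protein_id: str, hits: Sequence[ExternalHit], self_strain: str
) -> PosRecord:
    """First hit whose organism differs from the query's own strain.

    Hits must already be sorted by ascending rank; ranks must be unique.
    Returns a record with ``pos_organism=None`` when every hit is from the
    self strain (or the list is empty).
    """
    ranks = [h.rank for h in hits]
    if any(a >= b for a, b in zip(ranks, ranks[1:])):
        raise ValueError(f"protein {protein_id!r}: hit ranks not strictly ascending")
    self_norm = normalize_organism(self_strain)
    for h in hits:
        if normalize_organism(h.subject_organism) != self_norm:
            return PosRecord(protein_id, h.subject_organism,
                             h.percent_identity, h.e_value)
    return PosRecord(protein_id, None)


def read_external_hits(path: str | Path) -> dict[str, list[ExternalHit]]:
    """Read a ranked-hit TSV: protein_id, rank, subject_organism, pident, evalue."""
    table: dict[str, list[ExternalHit]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: expected header starting with 'protein_id'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            pid, rank, org, ident, ev = fields
            table.setdefault(pid, []).append(
                ExternalHit(int(rank), org, float(ident), float(ev))
            )
    for hits in table.values():
        hits.sort(key=lambda h: h.rank)
    return table


def pos_summary(
    records: Iterable[PosRecord], replicons: RepliconSet
) -> pd.DataFrame:
    """Per-replicon POS organism frequency table, sorted descending.

    Proteins with no POS are tallied under ``none``.  Counts per replicon
    sum to the number of records on that replicon.
    """
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        rid = replicons.replicon_of(rec.protein_id)
        org = rec.pos_organism if rec.pos_organism is not None else "none"
        counts[(rid, org)] = counts.get((rid, org), 0) + 1
    rows = [
        {"replicon_id": rid, "pos_organism": org, "count": n}
        for (rid, org), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["replicon_id", "pos_organism", "count"])
    if not df.empty:
        df = df.sort_values(
            ["replicon_id", "count", "pos_organism"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df


def write_pos_table(
    records: Iterable[PosRecord],
    connected: set[str],
    path: str | Path,
    functions: Mapping[str, str] | None = None,
) -> None:
    """Write the per-protein summary table.

    Columns: protein id, encoded function (if a function map is supplied),
    a has-homologs flag, POS organism, identity percent and E-value of the
    match.  Organism matching is exact on the normalized strain string.
    """
    functions = functions or {}
    with open(path, "w") as fh:
        fh.write("# organism matching: exact normalized 'genus species strain' string\n")
        fh.write("protein_id\tfunction\tconnected\tpos_organism\tpercent_identity\te_value\n")
        for rec in records:
            org = rec.pos_organism or ""
            ident = "" if rec.percent_identity is None else f"{rec.percent_identity:.1f}"
            ev = "" if rec.e_value is None else f"{rec.e_value:.3g}"
            fh.write(
                f"{rec.protein_id}\t{functions.get(rec.protein_id, '')}\t"
                f"{'yes' if rec.protein_id in connected else 'no'}\t{org}\t{ident}\t{ev}\n"
            )
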