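"""COG functional annotation from precomputed best-hit tables.

The database search itself happens outside the toolkit; this module ingests
a ranked best-hit table (protein_id, single-letter COG categories, E-value,
best hit first) and assigns each protein the categories of its best hit,
provided that hit's E-value is at or below 1e-20.  Profiles split the
assignments by connectivity status; a protein carrying k category letters
contributes to each of the k letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "COG_CATEGORIES",
    "AnnotationCriteria",
    "CogAssignment",
    "assign_cog",
    "read_cog_table",
    "functional_profile",
]

# standard single-letter COG functional category alphabet
COG_CATEGORIES = set("JAKLBDYVTMNZWUOCGEFHIPQRS")


@dataclass(frozen=True)
class AnnotationCriteria:
    """Significance threshold for accepting the best COG hit (inclusive)."""

    max_evalue: float = 1e-20

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass(frozen=True)
class CogAssignment:
    protein_id: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.categories) - COG_CATEGORIES
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: invalid COG letters {sorted(bad)}"
            )


def assign_cog(
    protein_id: str,
    ranked_hits: Sequence[tuple[str, float]],
    criteria: AnnotationCriteria | None = None,
) -> CogAssignment:
    """Categories of the single best hit, if significant.

    ``ranked_hits`` is a best-first list of (category letters, e_value)
    sorted ascending by E-value; hits after the first never matter.  An
    unsorted list is rejected rather than silently reordered.
    """
    criteria = criteria or AnnotationCriteria()
    evs = [ev for _, ev in ranked_hits]
    if any(a > b for a, b in zip(evs, evs[1:])):
        raise ValueError(f"protein {protein_id!r}: hits not sorted by e-value")
    if not ranked_hits:
        return CogAssignment(protein_id, frozenset())
    cats, ev = ranked_hits[0]
    if ev > criteria.max_evalue:
        return CogAssignment(protein_id, frozenset())
    return CogAssignment(protein_id, frozenset(cats))


def read_cog_table(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Read a ranked COG hit TSV: protein_id, categories, e_value.

    Rows for the same protein must be contiguous and best-first.
    """
    table: dict[str, list[tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: expected header starting with 'protein_id'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            pid, cats, ev = fields
            table.setdefault(pid, []).append((cats, float(ev)))
    return table


def functional_profile(
    assignments: Iterable[CogAssignment],
    connected: set[str],
) -> pd.DataFrame:
    """Per-category tallies split by connectivity status.

    Returns one row per category letter observed (plus an ``unassigned``
    row) with connected/unconnected counts and the descriptive enrichment
    ratio connected_fraction / unconnected_fraction (NaN when undefined).
    The assignment list defines the protein universe; a connected id
    outside it is an error.
    """
    assignments = list(assignments)
    universe = {a.protein_id for a in assignments}
    stray = connected - universe
    if stray:
        raise ValueError(f"connected proteins outside the universe: {sorted(stray)[:5]}")
    n_conn = len(connected)
    n_unconn = len(universe) - n_conn

    counts: dict[str, list[int]] = {}
    unassigned = [0, 0]
    for a in assignments:
        is_conn = a.protein_id in connected
        if not a.categories:
            unassigned[0 if is_conn else 1] += 1
            continue
        for cat in a.categories:
            c = counts.setdefault(cat, [0, 0])
            c[0 if is_conn else 1] += 1

    rows = []
    for cat in sorted(counts):
        c_conn, c_unconn = counts[cat]
        frac_c = c_conn / n_conn if n_conn else math.nan
        frac_u = c_unconn / n_unconn if n_unconn else math.nan
        ratio = frac_c / frac_u if frac_u and not math.isnan(frac_c) else math.nan
        rows.append({"category": cat, "connected": c_conn,
                     "unconnected": c_unconn, "ratio": ratio})
    rows.append({"category": "unassigned", "connected": unassigned[0],
                 "unconnected": unassigned[1], "ratio": math.nan})
    return pd.DataFrame(rows)
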