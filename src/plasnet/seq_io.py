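"""Replicon-aware protein/nucleotide FASTA I/O and basic composition.

A *replicon* is any independently replicating DNA molecule (chromosome or
plasmid).  The toolkit treats a strain's replicons as a registry: every
protein belongs to exactly one replicon, and downstream network levels
(intra-plasmid, plasmidome-wide, plasmid-vs-chromosome) are defined in terms
of that assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "Replicon",
    "RepliconSet",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_nucleotide_fasta",
    "gc_content",
    "load_replicon_set",
]

# residues kept verbatim; everything else in this set is masked to X
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_AMBIGUOUS_AA = set("BZJUO*")

ROLE_PLASMID = "plasmid"
ROLE_CHROMOSOME = "chromosome"
_VALID_ROLES = {ROLE_PLASMID, ROLE_CHROMOSOME}


@dataclass(frozen=True)
class ProteinRecord:
    """One translated gene with its replicon assignment.

    ``protein_id`` is the first whitespace-delimited token of the FASTA
    header (GI-style numeric ids are single tokens); the full header is
    retained as ``description``.
    """

    protein_id: str
    replicon_id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")


@dataclass
class Replicon:
    """A chromosome or plasmid with optional nucleotide-level attributes."""

    replicon_id: str
    role: str
    nt_sequence: str | None = None
    protein_count: int = 0

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ValueError(
                f"replicon {self.replicon_id!r}: unknown role {self.role!r} "
                f"(expected one of {sorted(_VALID_ROLES)})"
            )

    @property
    def nt_length(self) -> int | None:
        return len(self.nt_sequence) if self.nt_sequence is not None else None

    @property
    def gc_percent(self) -> float | None:
        if self.nt_sequence is None:
            return None
        return gc_content(self.nt_sequence)


@dataclass
class RepliconSet:
    """Ordered replicon registry plus the pooled protein list.

    Replicon ordering is preserved for track export; protein ids are unique
    across the whole set.
    """

    replicons: list[Replicon] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate protein ids across dataset: {sorted(dups)[:5]}")
        known = {r.replicon_id for r in self.replicons}
        for p in self.proteins:
            if p.replicon_id not in known:
                raise ValueError(
                    f"protein {p.protein_id!r} assigned to unregistered replicon "
                    f"{p.replicon_id!r}"
                )
        counts = self.protein_counts()
        for r in self.replicons:
            r.protein_count = counts.get(r.replicon_id, 0)

    # -- lookups -------------------------------------------------------
    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def replicon_of(self, protein_id: str) -> str:
        return self._replicon_index()[protein_id]

    def _replicon_index(self) -> dict[str, str]:
        idx = getattr(self, "_ridx", None)
        if idx is None or len(idx) != len(self.proteins):
            idx = {p.protein_id: p.replicon_id for p in self.proteins}
            object.__setattr__(self, "_ridx", idx)
        return idx

    def lengths(self) -> dict[str, int]:
        return {p.protein_id: p.length for p in self.proteins}

    def protein_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.proteins:
            counts[p.replicon_id] = counts.get(p.replicon_id, 0) + 1
        return counts

    def proteins_of(self, replicon_id: str) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.replicon_id == replicon_id]

    def plasmid_ids(self) -> list[str]:
        return [r.replicon_id for r in self.replicons if r.role == ROLE_PLASMID]

    def chromosome_ids(self) -> list[str]:
        return [r.replicon_id for r in self.replicons if r.role == ROLE_CHROMOSOME]


def _mask_ambiguous(seq: str, protein_id: str) -> str:
    """Map non-standard residues (B, Z, J, U, O, *) to X with a warning."""
    bad = set(seq) & _AMBIGUOUS_AA
    if bad:
        warnings.warn(
            f"protein {protein_id!r}: ambiguous residues {sorted(bad)} masked to X",
            stacklevel=3,
        )
        for ch in bad:
            seq = seq.replace(ch, "X")
    unknown = set(seq) - _STANDARD_AA
    if unknown:
        raise ValueError(
            f"protein {protein_id!r}: invalid residues {sorted(unknown)}"
        )
    return seq


def _check_fasta_shape(path: Path) -> None:
    """Reject text that is not FASTA, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            return


def read_protein_fasta(path: str | Path, replicon_id: str) -> list[ProteinRecord]:
    """Read a per-replicon protein multi-FASTA.

    The protein id is the first whitespace token of each header; sequences
    are uppercased and ambiguous residues masked to X.  Duplicate ids and
    empty sequences are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_shape(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = _mask_ambiguous(str(rec.seq).upper(), pid)
        if not seq:
            raise ValueError(f"{path}: protein {pid!r} has an empty sequence")
        records.append(
            ProteinRecord(
                protein_id=pid,
                replicon_id=replicon_id,
                sequence=seq,
                description=rec.description,
            )
        )
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records back to FASTA (round-trips with the reader)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id,
                  description=r.description if r.description != r.protein_id else "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> str:
    """Read a single-record (or concatenated multi-record) nucleotide FASTA."""
    path = Path(path)
    _check_fasta_shape(path)
    parts = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not parts:
        raise ValueError(f"{path}: no sequence records")
    return "".join(parts)


def gc_content(seq: str) -> float:
    """GC percentage of a nucleotide sequence, ignoring N bases entirely.

    N is excluded from both numerator and denominator so assembly gaps do
    not drag the estimate toward AT.
    """
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"gc_content: invalid bases {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return 100.0 * gc / (gc + at)


def load_replicon_set(manifest: str | Path | Mapping) -> RepliconSet:
    """Build a :class:`RepliconSet` from a manifest.

    The manifest maps replicon_id -> {role, proteins: <fasta path>,
    nucleotide: <optional fasta path>}; it may be a YAML file path or an
    already-parsed mapping.  Paths are resolved relative to the manifest
    file's directory.  At least one plasmid is required, and no protein
    FASTA may be shared between two replicons.
    """
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        base = mpath.parent
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping) or not manifest:
        raise ValueError("manifest must be a non-empty mapping of replicons")

    replicons: list[Replicon] = []
    proteins: list[ProteinRecord] = []
    seen_paths: dict[Path, str] = {}
    for rid, entry in manifest.items():
        role = entry.get("role")
        if role not in _VALID_ROLES:
            raise ValueError(f"replicon {rid!r}: unknown role {role!r}")
        ppath = (base / entry["proteins"]).resolve()
        if ppath in seen_paths:
            raise ValueError(
                f"protein file {ppath} shared between replicons "
                f"{seen_paths[ppath]!r} and {rid!r}"
            )
        seen_paths[ppath] = rid
        nt = None
        if entry.get("nucleotide"):
            nt = read_nucleotide_fasta(base / entry["nucleotide"])
        replicons.append(Replicon(replicon_id=str(rid), role=role, nt_sequence=nt))
        proteins.extend(read_protein_fasta(ppath, str(rid)))
    rset = RepliconSet(replicons=replicons, proteins=proteins)
    if not rset.plasmid_ids():
        raise ValueError("manifest must register at least one plasmid")
    return rset
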