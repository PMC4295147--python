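"""All-vs-all protein similarity: internal aligner, tabular ingestion,
triple-criterion filtering, and symmetrization into homology edges.

A protein pair is considered homologous when a directed hit simultaneously
passes three inclusive thresholds: percent identity >= 40.0, E-value <= 0.05,
and the alignment covering >= 70% of the query sequence; self-hits are
always removed.  Hits may come from the built-in Smith-Waterman aligner or
from an ingested 12-column blast-tabular file produced by an external
search engine.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import ProteinRecord

__all__ = [
    "SimilarityHit",
    "FilterCriteria",
    "AlignerParams",
    "HomologyEdge",
    "align_pair",
    "all_vs_all",
    "parse_tabular_hits",
    "filter_hits",
    "filter_hits_detailed",
    "symmetrize",
    "write_hits_tsv",
    "write_rejected_tsv",
]

RejectionReason = Literal["self_hit", "identity", "evalue", "coverage"]


@dataclass(frozen=True)
class SimilarityHit:
    """One directed pairwise comparison result.

    ``percent_identity`` follows the blast-tabular ``pident`` convention:
    identical aligned residue pairs over total alignment columns, gap
    columns included in the denominator.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1: {self.alignment_length}")
        if self.e_value < 0:
            raise ValueError(f"negative e_value: {self.e_value}")


@dataclass(frozen=True)
class FilterCriteria:
    """The three significance thresholds; every boundary is inclusive."""

    min_identity: float = 40.0
    max_evalue: float = 0.05
    min_query_coverage: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0.0 < self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")


@dataclass
class AlignerParams:
    """Parameters of the internal local aligner.

    E-values use a fixed Karlin-Altschul approximation
    ``E = K * m * n * exp(-lambda * S)`` with the gapped BLOSUM62 constants
    (lambda=0.267, K=0.041) and n = total residues in the searched dataset.
    This is an approximation declared in run metadata; ingesting real
    blast-tabular output is the fidelity path.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    search_space: int | None = None  # total residues in database; set by all_vs_all

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        try:
            matrix = substitution_matrices.load(self.substitution_matrix)
        except FileNotFoundError as exc:
            raise ValueError(
                f"unknown substitution matrix {self.substitution_matrix!r}"
            ) from exc
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class HomologyEdge:
    """One undirected, filtered, symmetrized homology link.

    ``edge_class`` is one of in_paralog (both endpoints on the same
    replicon), out_paralog (different plasmids), or plasmid_chromosome
    (exactly one endpoint on a chromosome); it is filled by the network
    module once replicon assignments are known.
    """

    u: str
    v: str
    identity: float
    e_value: float
    edge_class: str | None = None

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-edge on {self.u!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.u, self.v) if self.u <= self.v else (self.v, self.u)


def _alignment_stats(alignment) -> tuple[int, int]:
    """(identical pairs, alignment columns incl. internal gap columns)."""
    c = alignment.counts()
    # local alignments have no terminal gaps; internal insertion/deletion
    # residue counts equal the number of gap columns
    columns = c.identities + c.mismatches + c.internal_insertions + c.internal_deletions
    return c.identities, columns


def _evalue(raw_score: float, query_len: int, params: AlignerParams) -> float:
    n = params.search_space if params.search_space else query_len
    return params.karlin_k * query_len * n * math.exp(-params.karlin_lambda * raw_score)


def _bit_score(raw_score: float, params: AlignerParams) -> float:
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


def align_pair(
    a: ProteinRecord, b: ProteinRecord, params: AlignerParams | None = None
) -> SimilarityHit | None:
    """Locally align two proteins (Smith-Waterman, affine gaps).

    Returns a directed hit a->b, or None when the optimal local score is
    not positive.
    """
    params = params or AlignerParams()
    aligner = params.make_aligner()
    score = aligner.score(a.sequence, b.sequence)
    if score <= 0:
        return None
    identities, columns = _alignment_stats(aligner.align(a.sequence, b.sequence)[0])
    return SimilarityHit(
        query_id=a.protein_id,
        subject_id=b.protein_id,
        percent_identity=100.0 * identities / columns,
        alignment_length=columns,
        e_value=_evalue(score, a.length, params),
        bit_score=_bit_score(score, params),
    )


def all_vs_all(
    proteins: Sequence[ProteinRecord], params: AlignerParams | None = None
) -> list[SimilarityHit]:
    """Directed all-vs-all comparison of a protein set against itself.

    Emits self-hits and both directions of every aligning pair (the local
    alignment is computed once per unordered pair; only the E-value, which
    depends on the query length, differs between directions).  Deterministic
    given the input order.
    """
    if len(proteins) < 2:
        raise ValueError("all_vs_all requires at least 2 proteins")
    params = params or AlignerParams()
    if params.search_space is None:
        params.search_space = sum(p.length for p in proteins)
    aligner = params.make_aligner()

    hits: list[SimilarityHit] = []
    for p in proteins:  # self-hits: full-length, identity 100
        score = aligner.score(p.sequence, p.sequence)
        hits.append(
            SimilarityHit(
                p.protein_id, p.protein_id, 100.0, p.length,
                _evalue(score, p.length, params), _bit_score(score, params),
            )
        )
    for a, b in itertools.combinations(proteins, 2):
        score = aligner.score(a.sequence, b.sequence)
        if score <= 0:
            continue
        identities, columns = _alignment_stats(aligner.align(a.sequence, b.sequence)[0])
        pid = 100.0 * identities / columns
        bit = _bit_score(score, params)
        hits.append(SimilarityHit(a.protein_id, b.protein_id, pid, columns,
                                  _evalue(score, a.length, params), bit))
        hits.append(SimilarityHit(b.protein_id, a.protein_id, pid, columns,
                                  _evalue(score, b.length, params), bit))
    return hits


_TABULAR_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def parse_tabular_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column blast-tabular (outfmt-6 dialect) TSV.

    Columns 1, 2, 3, 4, 11, 12 map to query, subject, identity, alignment
    length, E-value and bit score; '#' comment lines are skipped.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_TABULAR_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field: {exc}") from exc
            hits.append(SimilarityHit(fields[0], fields[1], pident, length, evalue, bits))
    return hits


def _rejection_reason(
    hit: SimilarityHit, criteria: FilterCriteria, lengths: Mapping[str, int]
) -> RejectionReason | None:
    if hit.query_id not in lengths or hit.subject_id not in lengths:
        missing = hit.query_id if hit.query_id not in lengths else hit.subject_id
        raise KeyError(f"hit references unknown protein {missing!r}")
    if hit.query_id == hit.subject_id:
        return "self_hit"
    if hit.percent_identity < criteria.min_identity:
        return "identity"
    if hit.e_value > criteria.max_evalue:
        return "evalue"
    if hit.alignment_length / lengths[hit.query_id] < criteria.min_query_coverage:
        return "coverage"
    return None


def filter_hits_detailed(
    hits: Iterable[SimilarityHit],
    criteria: FilterCriteria,
    lengths: Mapping[str, int],
) -> tuple[list[SimilarityHit], list[tuple[SimilarityHit, RejectionReason]]]:
    """Apply the triple filter, also reporting why each rejected hit failed.

    A hit is retained iff it is not a self-hit AND passes identity, E-value
    and query-coverage thresholds simultaneously (all inclusive).  The
    rejection reason is the first failing criterion in the order
    self_hit, identity, evalue, coverage.  Input order is preserved.
    """
    retained: list[SimilarityHit] = []
    rejected: list[tuple[SimilarityHit, RejectionReason]] = []
    for hit in hits:
        reason = _rejection_reason(hit, criteria, lengths)
        if reason is None:
            retained.append(hit)
        else:
            rejected.append((hit, reason))
    return retained, rejected


def filter_hits(
    hits: Iterable[SimilarityHit],
    criteria: FilterCriteria,
    lengths: Mapping[str, int],
) -> list[SimilarityHit]:
    """Retained subset of :func:`filter_hits_detailed`."""
    return filter_hits_detailed(hits, criteria, lengths)[0]


def symmetrize(hits: Iterable[SimilarityHit]) -> list[HomologyEdge]:
    """Collapse filtered directed hits into undirected homology edges.

    One edge per unordered pair seen in at least one direction; edge
    identity is the maximum over available directions (best evidence) and
    edge E-value the minimum.  Output sorted lexicographically by pair so
    the result is invariant under permutation of the input.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for hit in hits:
        key = (min(hit.query_id, hit.subject_id), max(hit.query_id, hit.subject_id))
        if key[0] == key[1]:
            raise ValueError(f"symmetrize received an unfiltered self-hit on {key[0]!r}")
        prev = best.get(key)
        if prev is None:
            best[key] = (hit.percent_identity, hit.e_value)
        else:
            best[key] = (max(prev[0], hit.percent_identity), min(prev[1], hit.e_value))
    return [
        HomologyEdge(u, v, identity=ident, e_value=ev)
        for (u, v), (ident, ev) in sorted(best.items())
    ]


# -- TSV writers (blast-tabular dialect, Cytoscape/spreadsheet friendly) ----

def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the same 12-column dialect `parse_tabular_hits` reads.

    Positional columns not tracked internally (mismatch, gapopen, and the
    start/end coordinates) are written as 0.
    """
    with open(path, "w") as fh:
        fh.write("# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\t"
                 "qstart\tqend\tsstart\tsend\tevalue\tbitscore\n")
        for h in hits:
            bits = 0.0 if h.bit_score is None else h.bit_score
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t0\t0\t0\t0\t{h.e_value:.3g}\t{bits:.1f}\n"
            )


def write_rejected_tsv(
    rejected: Iterable[tuple[SimilarityHit, RejectionReason]], path: str | Path
) -> None:
    """Write rejected hits with the reason each one failed the filter."""
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tpident\tlength\tevalue\treason\n")
        for h, reason in rejected:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.e_value:.3g}\t{reason}\n"
            )
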