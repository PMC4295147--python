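import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasnet.seq_io import ProteinRecord
from plasnet.similarity import (
    AlignerParams,
    FilterCriteria,
    SimilarityHit,
    align_pair,
    all_vs_all,
    filter_hits,
    filter_hits_detailed,
    parse_tabular_hits,
    symmetrize,
)

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, open_pen=11.0, ext_pen=1.0) -> float:
    """Exhaustive Gotoh local-alignment DP, independent of the package.

    The first residue of a gap costs ``open_pen``, each further residue
    ``ext_pen`` (matching the aligner's open/extend convention).
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_pen, E[i][j - 1] - ext_pen)
            F[i][j] = max(H[i - 1][j] - open_pen, F[i - 1][j] - ext_pen)
            diag = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def prot(pid, seq, rep="r1"):
    return ProteinRecord(pid, rep, seq)


class TestAlignPair:
    def test_self_alignment_is_full_length_identity_100(self):
        p = prot("p", "MKVLYAAGGHHTTWWRRDDEE")
        hit = align_pair(p, p)
        assert hit.percent_identity == pytest.approx(100.0)
        assert hit.alignment_length == p.length

    def test_identical_short_peptides_score_sums_blosum62_diagonal(self):
        # M/M + K/K + V/V + L/L = 5 + 5 + 4 + 4 = 18 in BLOSUM62
        params = AlignerParams(search_space=8)
        aligner = params.make_aligner()
        assert aligner.score("MKVL", "MKVL") == pytest.approx(18.0)

    def test_disjoint_alphabet_pairs_never_pass_filter(self):
        rng = random.Random(7)
        a = prot("a", "".join(rng.choices("ACDEFGHIKL", k=100)))
        b = prot("b", "".join(rng.choices("MNPQRSTVWY", k=100)), "r2")
        params = AlignerParams(search_space=200)
        hit = align_pair(a, b, params)
        if hit is not None:
            kept = filter_hits([hit], FilterCriteria(), {"a": 100, "b": 100})
            assert kept == []

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            align_pair(prot("a", "MKVL"), prot("b", "MKVL"),
                       AlignerParams(substitution_matrix="NOSUCH"))

    @pytest.mark.parametrize("seed", range(30))
    def test_score_matches_dp_oracle_on_short_sequences(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choices("ACDE", k=rng.randint(1, 8)))
        b = "".join(rng.choices("ACDE", k=rng.randint(1, 8)))
        params = AlignerParams(search_space=len(a) + len(b))
        aligner = params.make_aligner()
        assert aligner.score(a, b) == pytest.approx(sw_affine_oracle(a, b))


class TestAllVsAll:
    def test_three_identical_proteins_give_six_directed_hits_at_100(self):
        ps = [prot(f"p{i}", "MKVLYAAGGHHTTWWRRDDEE") for i in range(3)]
        hits = all_vs_all(ps)
        non_self = [h for h in hits if h.query_id != h.subject_id]
        assert len(non_self) == 6
        assert all(h.percent_identity == pytest.approx(100.0) for h in non_self)
        assert sum(h.query_id == h.subject_id for h in hits) == 3

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all([prot("p", "MKVL")])

    def test_deterministic(self):
        rng = random.Random(3)
        ps = [prot(f"p{i}", "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=60)))
              for i in range(5)]
        assert all_vs_all(ps) == all_vs_all(ps)


class TestParseTabular:
    def test_direct_field_map(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("# BLASTP\np1\tp2\t85.5\t200\t29\t0\t1\t200\t1\t200\t1e-80\t300\n")
        (hit,) = parse_tabular_hits(p)
        assert hit == SimilarityHit("p1", "p2", 85.5, 200, 1e-80, 300.0)

    def test_wrong_column_count_errors_with_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("p1\tp2\t85.5\t200\t29\t0\t1\t200\t1\t200\t1e-80\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits(p)

    def test_non_numeric_field_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("p1\tp2\tabc\t200\t29\t0\t1\t200\t1\t200\t1e-80\t300\n")
        with pytest.raises(ValueError, match="non-numeric"):
            parse_tabular_hits(p)


LENGTHS = {"A": 100, "B": 100, "C": 100}


def hit(q="A", s="B", ident=50.0, length=80, ev=1e-10):
    return SimilarityHit(q, s, ident, length, ev)


class TestFilterHits:
    def test_all_boundaries_inclusive(self):
        boundary = hit(ident=40.0, ev=0.05, length=70)
        assert filter_hits([boundary], FilterCriteria(), LENGTHS) == [boundary]

    @pytest.mark.parametrize(
        "h,reason",
        [
            (hit(q="A", s="A"), "self_hit"),
            (hit(ident=39.9), "identity"),
            (hit(ev=0.051), "evalue"),
            (hit(length=69), "coverage"),
            (hit(q="A", s="A", ident=10.0, ev=9.0, length=1), "self_hit"),
        ],
    )
    def test_rejection_reasons(self, h, reason):
        retained, rejected = filter_hits_detailed([h], FilterCriteria(), LENGTHS)
        assert retained == []
        assert rejected == [(h, reason)]

    def test_unknown_protein_id_errors(self):
        with pytest.raises(KeyError):
            filter_hits([hit(q="Z")], FilterCriteria(), LENGTHS)

    def test_idempotent_and_order_preserving(self):
        hits = [hit(ident=95), hit(q="B", s="C", ident=45), hit(ident=39)]
        once = filter_hits(hits, FilterCriteria(), LENGTHS)
        assert filter_hits(once, FilterCriteria(), LENGTHS) == once
        assert once == [hits[0], hits[1]]

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.builds(
                hit,
                q=st.sampled_from("AB"),
                s=st.sampled_from("AB"),
                ident=st.floats(0, 100),
                length=st.integers(1, 100),
                ev=st.floats(0, 1),
            ),
            max_size=12,
        ),
        st.floats(40, 60),
        st.floats(0.7, 0.9),
    )
    def test_tightening_never_increases_retention(self, hits, ident2, cov2):
        base = FilterCriteria()
        tighter = FilterCriteria(
            min_identity=max(base.min_identity, ident2),
            max_evalue=base.max_evalue / 2,
            min_query_coverage=max(base.min_query_coverage, cov2),
        )
        assert len(filter_hits(hits, tighter, LENGTHS)) <= len(
            filter_hits(hits, base, LENGTHS)
        )


class TestSymmetrize:
    def test_max_identity_min_evalue_rule(self):
        edges = symmetrize(
            [hit("A", "B", 72.0, 80, 1e-10), hit("B", "A", 70.0, 80, 1e-12)]
        )
        assert len(edges) == 1
        assert edges[0].pair == ("A", "B")
        assert edges[0].identity == 72.0
        assert edges[0].e_value == 1e-12

    def test_single_direction_kept(self):
        (edge,) = symmetrize([hit("A", "B", 55.0)])
        assert edge.identity == 55.0

    def test_empty(self):
        assert symmetrize([]) == []

    def test_self_hit_rejected(self):
        with pytest.raises(ValueError):
            symmetrize([hit("A", "A")])

    @settings(derandomize=True, max_examples=40)
    @given(
        st.permutations(
            [
                hit("A", "B", 50), hit("B", "A", 60), hit("B", "C", 45),
                hit("A", "C", 99), hit("C", "A", 99.5),
            ]
        )
    )
    def test_invariant_under_input_permutation(self, hits):
        edges = symmetrize(hits)
        assert len(edges) <= len(hits)
        assert edges == symmetrize(list(reversed(hits)))
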