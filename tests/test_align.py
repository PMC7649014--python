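"""Pairwise alignment, guide trees, progressive MSA, consensus profiles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notchkit.align import (
    MultipleAlignment,
    consensus,
    conservation_profile,
    nj_guide_tree,
    pairwise_align,
    pairwise_distance,
    progressive_msa,
)
from notchkit.distmat import DistanceMatrix
from notchkit.records import SequenceRecord
from notchkit.simulate import evolve_clade, make_ancestor, canonical_roster

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rec(rid, seq):
    return SequenceRecord(id=rid, residues=seq)


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_identity_case(self):
        aln = pairwise_align("ACDE", "ACDE")
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_global_gap_placement_matches_exhaustive_dp(self):
        """ACDE vs ACE: exhaustive scoring of all 4 candidate gap placements."""
        from notchkit.matrices import gonnet_matrix, encode

        M = gonnet_matrix()

        def score(a, b):  # one gap, no extension beyond single column
            total = 0.0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    total -= 10.0
                else:
                    total += float(M[encode(x)[0], encode(y)[0]])
            return total

        candidates = [("ACDE", g[:i] + "-" + g[i:]) for g, i in
                      [("ACE", 0), ("ACE", 1), ("ACE", 2), ("ACE", 3)]]
        best = max(candidates, key=lambda ab: score(*ab))
        aln = pairwise_align("ACDE", "ACE")
        assert aln.aligned_b.count("-") == 1
        assert (aln.aligned_a, aln.aligned_b) == best
        assert aln.score == pytest.approx(score(*best))

    def test_local_on_exact_substring_scores_self_score(self):
        from notchkit.matrices import gonnet_matrix, encode

        M = gonnet_matrix()
        ref = "MKVLWAALLVTFLAGCQA"
        sub = ref[5:12]
        aln = pairwise_align(ref, sub, mode="local")
        self_score = float(np.diagonal(M)[encode(sub)].sum())
        assert aln.score == pytest.approx(self_score)
        assert aln.aligned_b == sub

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_align("", "ACDE")

    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_scores_match_biopython_oracle(self, mode):
        """Dual route: our DP vs Biopython's C PairwiseAligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("GONNET1992")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.mode = mode
        rng = np.random.default_rng(17)
        for _ in range(40):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 70)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 70)))
            ours = pairwise_align(a, b, mode=mode)
            assert ours.score == pytest.approx(aligner.score(a, b), abs=1e-4)

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(23)
        a = "".join(rng.choice(list(AA), size=33))
        b = "".join(rng.choice(list(AA), size=21))
        aln = pairwise_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACDE", "ACDE", 0.0), ("ACDE", "ACDF", 0.25), ("AAAA", "TTTT", 1.0)],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_distance(a, b) == pytest.approx(expected)

    def test_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=30))
            assert pairwise_distance(a, b) == pytest.approx(pairwise_distance(b, a))
        a = "".join(rng.choice(list(AA), size=40))
        assert pairwise_distance(a, a) == 0.0


# ---------------------------------------------------------------------------
# NJ guide tree
# ---------------------------------------------------------------------------

class TestGuideTree:
    def test_two_taxa_cherry(self):
        t = nj_guide_tree(DistanceMatrix(["A", "B"], np.array([[0, 3], [3, 0.0]])))
        assert sorted(t.leaf_names()) == ["A", "B"]
        assert t.n_leaves() == 2

    def test_identical_rows_join_first(self):
        m = np.array(
            [[0, 0.0, 5, 5], [0.0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0.0]]
        )
        t = nj_guide_tree(DistanceMatrix(list("ABCD"), m))
        sets = {n.leaf_set() for n in t.postorder() if not n.is_leaf}
        assert frozenset({"A", "B"}) in sets

    def test_additive_four_taxon_topology_recovery(self):
        """NJ recovers the generating split; oracle = least-squares fit over
        all three unrooted quartet topologies."""
        # additive tree: ((A:1,B:2):3,(C:1.5,D:2.5)) internal edge 3
        d = {
            ("A", "B"): 3, ("A", "C"): 5.5, ("A", "D"): 6.5,
            ("B", "C"): 6.5, ("B", "D"): 7.5, ("C", "D"): 4,
        }
        labels = list("ABCD")
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v

        def ls_residual(split):
            # design matrix over 5 edges: 4 pendant + 1 internal
            pairs = list(itertools.combinations(range(4), 2))
            X = np.zeros((6, 5))
            for r, (i, j) in enumerate(pairs):
                X[r, i] = X[r, j] = 1
                same = ({i, j} == set(split[0])) or ({i, j} == set(split[1]))
                if not same:
                    X[r, 4] = 1
            y = np.array([m[i, j] for i, j in pairs])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((X @ coef - y) ** 2))

        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        residuals = [ls_residual(s) for s in splits]
        assert residuals[0] == pytest.approx(0, abs=1e-18)  # AB|CD is additive
        assert min(residuals[1:]) > 0.1

        t = nj_guide_tree(DistanceMatrix(labels, m))
        sets = {n.leaf_set() for n in t.postorder() if not n.is_leaf}
        assert frozenset({"A", "B"}) in sets or frozenset({"C", "D"}) in sets

    def test_rejects_nan_and_negative(self):
        with pytest.raises(ValueError):
            nj_guide_tree(DistanceMatrix(["A", "B"], np.array([[0, -1], [-1, 0.0]])))
        with pytest.raises(ValueError):
            nj_guide_tree(
                DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))
            )


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _sp_score(rows, gap_open=10.0, gap_extend=0.5):
    """Sum-of-pairs score of an alignment (gap runs scored affinely)."""
    from notchkit.matrices import gonnet_matrix, encode

    M = gonnet_matrix()
    total = 0.0
    for a, b in itertools.combinations(rows, 2):
        gap_row = None  # which row the open gap run sits in
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                gap_row = None
                continue
            if x == "-" or y == "-":
                row = 0 if x == "-" else 1
                total -= gap_extend if gap_row == row else gap_open
                gap_row = row
            else:
                total += float(M[encode(x)[0], encode(y)[0]])
                gap_row = None
    return total


class TestProgressiveMSA:
    def test_two_records_equal_pairwise_global(self):
        a, b = _rec("a", "MKVLWAAL"), _rec("b", "MKVWAL")
        msa = progressive_msa([a, b])
        aln = pairwise_align(a, b)
        assert msa.rows == [aln.aligned_a, aln.aligned_b]

    def test_identical_copies_align_gap_free(self):
        recs = [_rec(f"r{i}", "MKVLWAALLVT") for i in range(3)]
        msa = progressive_msa(recs)
        assert msa.n_columns == 11
        assert all("-" not in row for row in msa.rows)

    def test_substitution_only_clade_aligns_gap_free(self):
        """Members derived from one ancestor by substitutions only keep the
        ancestor's coordinates: no gaps, column count = ancestor length."""
        spec = canonical_roster()[0]  # bacterial miniature, fast
        anc, _ = make_ancestor(spec, seed=3)
        members, _ = evolve_clade(anc, 5, sub_rate=0.05, indel_rate=0.0, seed=9)
        msa = progressive_msa(members)
        assert msa.n_columns == anc.length
        assert all("-" not in row for row in msa.rows)

    def test_degapped_rows_equal_inputs(self, small_benchmark):
        recs = [r for r in small_benchmark.records[:8]]
        msa = progressive_msa(recs)
        for r in recs:
            assert msa.degapped(r.id) == r.residues

    def test_row_order_is_input_order(self):
        recs = [_rec(c, "MKVLW" + c * 3) for c in "DGAC"]
        msa = progressive_msa(recs)
        assert msa.ids == ["D", "G", "A", "C"]

    def test_guide_tree_leaf_mismatch_errors(self):
        from notchkit.tree import TreeNode, leaf

        bad = TreeNode(children=[leaf("x"), leaf("y")], height=1.0)
        with pytest.raises(ValueError, match="guide tree"):
            progressive_msa([_rec("a", "ACDE"), _rec("b", "ACDE")], guide_tree=bad)

    def test_pairwise_projections_bounded_by_optimal_dp(self):
        """No pairwise projection of the MSA can beat the optimal pairwise
        alignment of the same two sequences (a theorem for any MSA)."""
        rng = np.random.default_rng(41)
        for trial in range(6):
            seqs = ["".join(rng.choice(list(AA), size=rng.integers(4, 9)))
                    for _ in range(4)]
            recs = [_rec(f"s{i}", s) for i, s in enumerate(seqs)]
            msa = progressive_msa(recs)
            for i, j in itertools.combinations(range(4), 2):
                a, b = msa.project_pair(f"s{i}", f"s{j}")
                proj = _sp_score([a, b])
                opt = pairwise_align(seqs[i], seqs[j]).score
                assert proj <= opt + 1e-6

    def test_sum_of_pairs_beats_star_alignment_on_homologous_sets(self):
        """For sequences sharing an ancestor, the guide-tree-ordered MSA
        scores at least as well (sum of pairs) as the naive star alignment
        to the first sequence."""
        rng = np.random.default_rng(43)
        for trial in range(8):
            anc = "".join(rng.choice(list(AA), size=8))
            seqs = []
            for _ in range(4):
                s = list(anc)
                for i in rng.choice(len(s), size=2, replace=False):
                    s[i] = rng.choice([a for a in AA if a != s[i]])
                seqs.append("".join(s))
            recs = [_rec(f"s{i}", s) for i, s in enumerate(seqs)]
            msa = progressive_msa(recs)
            star = _star_alignment(seqs)
            assert _sp_score(msa.rows) >= _sp_score(star) - 1e-6


def _star_alignment(seqs):
    """Merge pairwise alignments to seqs[0] by center-sequence coordinates."""
    center = seqs[0]
    alns = [pairwise_align(center, s) for s in seqs[1:]]

    def decompose(aln):
        """(residue per center position, insertion chunk after each position)."""
        res = {}
        chunks = {k: "" for k in range(-1, len(center))}
        pos = -1
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == "-":
                chunks[pos] += y
            else:
                pos += 1
                res[pos] = y
        return res, chunks

    decomposed = [decompose(a) for a in alns]
    ins = {
        k: max((len(chunks[k]) for _, chunks in decomposed), default=0)
        for k in range(-1, len(center))
    }
    rows = []
    # center row
    row = ["-"] * ins[-1]
    for k, c in enumerate(center):
        row.append(c)
        row.extend("-" * ins[k])
    rows.append("".join(row))
    for res, chunks in decomposed:
        row = list(chunks[-1].ljust(ins[-1], "-"))
        for k in range(len(center)):
            row.append(res.get(k, "-"))
            row.extend(chunks[k].ljust(ins[k], "-"))
        rows.append("".join(row))
    assert len({len(r) for r in rows}) == 1
    return rows


# ---------------------------------------------------------------------------
# consensus and conservation
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_majority_column(self):
        msa = MultipleAlignment(["a", "b", "c"], ["A", "A", "T"])
        assert consensus(msa) == "A"

    def test_tie_breaks_alphabetically(self):
        msa = MultipleAlignment(list("abcd"), ["A", "A", "T", "T"])
        assert consensus(msa) == "A"

    def test_gap_rule_omits_mostly_gapped_column(self):
        msa = MultipleAlignment(list("abcd"), ["A-", "A-", "A-", "AT"])
        assert consensus(msa) == "A"

    def test_single_row_identity(self):
        msa = MultipleAlignment(["a"], ["MKVLW"])
        assert consensus(msa) == "MKVLW"


class TestConservationProfile:
    def test_invariant_column(self):
        prof = conservation_profile(MultipleAlignment(["a", "b"], ["A", "A"]))
        assert prof[0].modal_freq == 1.0
        assert prof[0].modal_residue == "A"

    def test_two_state_column(self):
        prof = conservation_profile(
            MultipleAlignment(list("abcd"), ["F", "F", "Y", "Y"])
        )
        assert prof[0].modal_freq == 0.5
        assert prof[0].top2_residues == "FY"
        assert prof[0].top2_freq == 1.0

    def test_all_gap_column(self):
        prof = conservation_profile(MultipleAlignment(["a", "b"], ["-A", "-A"]))
        assert prof[0].modal_residue is None
        assert prof[0].gap_fraction == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet=AA, min_size=1, max_size=12), min_size=2, max_size=5))
def test_progressive_msa_degap_property(seqs):
    recs = [_rec(f"s{i}", s) for i, s in enumerate(seqs)]
    msa = progressive_msa(recs)
    for rec in recs:
        assert msa.degapped(rec.id) == rec.residues
    assert len({len(r) for r in msa.rows}) == 1
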