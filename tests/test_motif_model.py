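import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisclust import (
    Background0,
    CountMatrix,
    build_scoring_matrix,
    permute_matrix,
    pvalue,
    score_distribution,
    score_word,
)
from cisclust.motif_model import (
    read_count_matrices,
    write_count_matrix,
    write_distribution_tsv,
)

from conftest import enumerate_words, exact_pvalue, random_count_matrix


# ---------------------------------------------------------------------------
# build_scoring_matrix
# ---------------------------------------------------------------------------

class TestBuildScoringMatrix:
    def test_single_base_no_pseudocount(self, uniform_bg):
        cm = CountMatrix("m", [[1, 0, 0, 0]], pseudocount=0.0)
        with pytest.raises(ValueError, match="degenerate column"):
            build_scoring_matrix(cm, uniform_bg)

    def test_single_base_with_pseudocount_scores_consensus(self, uniform_bg):
        cm = CountMatrix("m", [[1, 0, 0, 0]], pseudocount=1e-12)
        sm = build_scoring_matrix(cm, uniform_bg)
        assert sm.scores[0, 0] == pytest.approx(2.0, abs=1e-9)  # log2(1/0.25)

    def test_flat_counts_give_zero_scores(self, uniform_bg):
        cm = CountMatrix("m", [[1, 1, 1, 1]], pseudocount=0.0)
        sm = build_scoring_matrix(cm, uniform_bg)
        assert np.allclose(sm.scores, 0.0)

    def test_width2_against_arithmetic_oracle(self, uniform_bg):
        # independent spreadsheet-style computation, cell by cell
        cm = CountMatrix("m", [[3, 1, 0, 0], [3, 1, 0, 0]], pseudocount=0.25)
        sm = build_scoring_matrix(cm, uniform_bg)
        adj = [3.25, 1.25, 0.25, 0.25]
        total = sum(adj)
        expected = [math.log2((a / total) / 0.25) for a in adj]
        for pos in range(2):
            assert sm.scores[pos].tolist() == pytest.approx(expected, abs=1e-12)

    def test_zero_total_count_column_errors(self, uniform_bg):
        cm = CountMatrix("m", [[0, 0, 0, 0]], pseudocount=0.1)
        sm = build_scoring_matrix(cm, uniform_bg)  # pseudocount saves it
        assert np.allclose(sm.scores, 0.0)
        with pytest.raises(ValueError):
            CountMatrix("m", [[0, 0, 0, 0]], pseudocount=0.0)


# ---------------------------------------------------------------------------
# score_word
# ---------------------------------------------------------------------------

class TestScoreWord:
    def test_zero_matrix_scores_zero(self):
        from cisclust import ScoringMatrix

        sm = ScoringMatrix("z", np.zeros((4, 4)))
        assert score_word(sm, "ACGT") == 0.0

    def test_argmax_word_attains_max(self, uniform_bg):
        rng = np.random.default_rng(7)
        sm = build_scoring_matrix(random_count_matrix(rng, 6), uniform_bg)
        assert score_word(sm, sm.consensus) == pytest.approx(sm.max_score)

    def test_width3_against_enumeration(self, uniform_bg):
        rng = np.random.default_rng(3)
        sm = build_scoring_matrix(random_count_matrix(rng, 3), uniform_bg)
        bases = "ACGT"
        for a in bases:
            for b in bases:
                for c in bases:
                    word = a + b + c
                    brute = sum(
                        sm.scores[i, bases.index(x)] for i, x in enumerate(word)
                    )
                    assert score_word(sm, word) == pytest.approx(brute)

    def test_masked_word_unscoreable(self, uniform_bg):
        rng = np.random.default_rng(3)
        sm = build_scoring_matrix(random_count_matrix(rng, 3), uniform_bg)
        with pytest.raises(ValueError, match="unscoreable window"):
            score_word(sm, "AcG")
        with pytest.raises(ValueError, match="unscoreable window"):
            score_word(sm, "ANG")


# ---------------------------------------------------------------------------
# score_distribution / pvalue
# ---------------------------------------------------------------------------

class TestScoreDistribution:
    def test_width1_two_point_distribution(self, uniform_bg):
        cm = CountMatrix("m", [[1, 0, 0, 0]], pseudocount=1e-12)
        sm = build_scoring_matrix(cm, uniform_bg)
        dist = score_distribution(sm, uniform_bg, bin_width=0.01)
        # support: score ~2 with p 0.25, score ~min with p 0.75
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist.pvalue(2.0) == pytest.approx(0.25)
        assert dist.pvalue(sm.min_score) == pytest.approx(1.0)

    def test_width2_matches_16_word_enumeration(self, uniform_bg):
        rng = np.random.default_rng(11)
        sm = build_scoring_matrix(random_count_matrix(rng, 2), uniform_bg)
        dist = score_distribution(sm, uniform_bg, bin_width=0.01)
        scores, probs = enumerate_words(sm, uniform_bg)
        for s in np.unique(scores):
            exact = exact_pvalue(scores, probs, s)
            rep = dist.pvalue(s)
            assert rep >= exact - 1e-12
            # within one bin: words within 2*bin_width below s may be included
            slack = exact_pvalue(scores, probs, s - 2 * 0.01) - exact
            assert rep <= exact + slack + 1e-12

    def test_probabilities_sum_to_one(self, uniform_bg):
        rng = np.random.default_rng(5)
        for w in (1, 3, 8):
            sm = build_scoring_matrix(random_count_matrix(rng, w), uniform_bg)
            dist = score_distribution(sm, uniform_bg)
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pvalue_of_min_score_is_one(self, uniform_bg):
        rng = np.random.default_rng(13)
        sm = build_scoring_matrix(random_count_matrix(rng, 5), uniform_bg)
        dist = score_distribution(sm, uniform_bg)
        assert dist.pvalue(sm.min_score) == pytest.approx(1.0)
        assert dist.pvalue(sm.min_score - 5.0) == pytest.approx(1.0)

    def test_pvalue_above_max_support_is_zero(self, uniform_bg):
        rng = np.random.default_rng(13)
        sm = build_scoring_matrix(random_count_matrix(rng, 4), uniform_bg)
        dist = score_distribution(sm, uniform_bg)
        assert dist.pvalue(sm.max_score + 1.0) == 0.0

    def test_consensus_pvalue_equals_bg_product(self, uniform_bg):
        # width-4 consensus-like matrix: p(max) = product of bg probs of the
        # consensus letters, checked by enumeration over 256 words
        from cisclust import consensus_pwm

        bg = Background0((0.2, 0.3, 0.3, 0.2))
        sm = build_scoring_matrix(consensus_pwm("ACGT", 97), bg)
        dist = score_distribution(sm, bg, bin_width=0.001)
        scores, probs = enumerate_words(sm, bg)
        expected = exact_pvalue(scores, probs, sm.max_score)
        assert dist.pvalue(sm.max_score) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.2 * 0.3 * 0.3 * 0.2)

    def test_nonuniform_background(self):
        bg = Background0((0.4, 0.1, 0.1, 0.4))
        rng = np.random.default_rng(17)
        sm = build_scoring_matrix(random_count_matrix(rng, 4), bg)
        dist = score_distribution(sm, bg, bin_width=0.01)
        scores, probs = enumerate_words(sm, bg)
        for q in (0.5, 0.05, 0.001):
            s = np.quantile(scores, 1 - q)
            assert dist.pvalue(s) >= exact_pvalue(scores, probs, s) - 1e-12

    def test_bad_bin_width(self, uniform_bg, anchor_cm):
        sm = build_scoring_matrix(anchor_cm, uniform_bg)
        with pytest.raises(ValueError):
            score_distribution(sm, uniform_bg, bin_width=0.0)

    def test_huge_bin_width_warns(self, uniform_bg):
        rng = np.random.default_rng(19)
        sm = build_scoring_matrix(random_count_matrix(rng, 3), uniform_bg)
        with pytest.warns(UserWarning, match="collapses"):
            score_distribution(sm, uniform_bg, bin_width=100.0)

    @settings(max_examples=25, deadline=None)
    @given(
        w=st.integers(1, 5),
        seed=st.integers(0, 10_000),
        a=st.floats(0.05, 0.9),
    )
    def test_property_conservative_vs_enumeration(self, w, seed, a):
        bg = Background0.uniform()
        rng = np.random.default_rng(seed)
        sm = build_scoring_matrix(random_count_matrix(rng, w), bg)
        dist = score_distribution(sm, bg, bin_width=0.01)
        scores, probs = enumerate_words(sm, bg)
        s = float(np.quantile(scores, a))
        exact = exact_pvalue(scores, probs, s)
        rep = dist.pvalue(s)
        assert rep >= exact - 1e-12
        assert rep <= exact_pvalue(scores, probs, s - w * 0.01 - 1e-12) + 1e-12

    @settings(max_examples=20, deadline=None)
    @given(w=st.integers(1, 6), seed=st.integers(0, 10_000))
    def test_property_pvalue_monotone(self, w, seed):
        bg = Background0.uniform()
        rng = np.random.default_rng(seed)
        sm = build_scoring_matrix(random_count_matrix(rng, w), bg)
        dist = score_distribution(sm, bg)
        grid = np.linspace(sm.min_score - 1, sm.max_score + 1, 200)
        pv = dist.pvalues(grid)
        assert np.all(np.diff(pv) <= 1e-15)
        assert pv[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# permute_matrix
# ---------------------------------------------------------------------------

class TestPermuteMatrix:
    def test_width1_identity(self, uniform_bg):
        cm = CountMatrix("m", [[5, 2, 1, 9]])
        pm = permute_matrix(cm, seed=0)
        assert np.array_equal(pm.counts, cm.counts)

    def test_distribution_invariant(self, uniform_bg):
        rng = np.random.default_rng(23)
        cm = random_count_matrix(rng, 8)
        sm = build_scoring_matrix(cm, uniform_bg)
        dist = score_distribution(sm, uniform_bg)
        for seed in range(10):
            psm = build_scoring_matrix(permute_matrix(cm, seed=seed), uniform_bg)
            pdist = score_distribution(psm, uniform_bg)
            assert np.array_equal(pdist.bins, dist.bins)
            assert np.allclose(pdist.probs, dist.probs, atol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(29)
        cm = random_count_matrix(rng, 8)
        a = permute_matrix(cm, seed=42)
        b = permute_matrix(cm, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_counts_are_a_column_permutation(self):
        rng = np.random.default_rng(31)
        cm = random_count_matrix(rng, 6)
        pm = permute_matrix(cm, seed=1)
        orig = {tuple(row) for row in cm.counts}
        perm = {tuple(row) for row in pm.counts}
        assert orig == perm

    def test_unknown_mode_rejected(self, anchor_cm):
        with pytest.raises(ValueError):
            permute_matrix(anchor_cm, mode="cells", seed=0)


# ---------------------------------------------------------------------------
# matrix and distribution I/O
# ---------------------------------------------------------------------------

class TestMatrixIO:
    def test_round_trip(self, tmp_path, anchor_cm):
        path = tmp_path / "m.counts"
        with open(path, "w") as fh:
            write_count_matrix(anchor_cm, fh)
        (cm,) = read_count_matrices(path)
        assert cm.motif_id == anchor_cm.motif_id
        assert np.array_equal(cm.counts, anchor_cm.counts)

    def test_multiple_matrices_per_file(self, tmp_path, anchor_cm, meis_cm):
        path = tmp_path / "m.counts"
        with open(path, "w") as fh:
            write_count_matrix(anchor_cm, fh)
            write_count_matrix(meis_cm, fh)
        mats = read_count_matrices(path)
        assert [m.motif_id for m in mats] == ["anchor", "meis"]

    def test_missing_row_errors(self, tmp_path):
        path = tmp_path / "bad.counts"
        path.write_text(">x\nA 1 2\nC 1 2\nG 1 2\n")
        with pytest.raises(ValueError, match="missing rows"):
            read_count_matrices(path)

    def test_distribution_tsv(self, tmp_path, uniform_bg, anchor_cm):
        sm = build_scoring_matrix(anchor_cm, uniform_bg)
        dist = score_distribution(sm, uniform_bg)
        out = tmp_path / "d.tsv"
        write_distribution_tsv(dist, out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "score_bin\tp_ge"
        assert len(lines) == len(dist.bins) + 1
        # first data row has p >= 1 - epsilon (cumulative upper at min bin)
        assert float(lines[1].split("\t")[1]) == pytest.approx(1.0, abs=1e-9)


class TestBackground:
    def test_uniform(self):
        assert Background0.uniform().as_array().tolist() == [0.25] * 4

    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Background0((0.3, 0.3, 0.3, 0.3))

    def test_must_be_positive(self):
        with pytest.raises(ValueError):
            Background0((0.5, 0.5, 0.0, 0.0))

    def test_from_sequences_skips_masked(self):
        from cisclust import MaskedSequence

        # only the 4 uppercase As count; +1 pseudocount per base
        seqs = [MaskedSequence("x", "AAAAccccNNNN")]
        bg = Background0.from_sequences(seqs, pseudocount=1.0)
        assert bg.probs == pytest.approx((5 / 8, 1 / 8, 1 / 8, 1 / 8))
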