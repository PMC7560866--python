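import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

import priorcut as pc
from priorcut.correlation import CorrelationResult
from priorcut.network import PriorNetwork
from priorcut.overlap import (NO_CUTOFF, OverlapTable, scores_for_grid,
                              significant_edge_count)


def enumerated_fisher(tp, fp, fn, tn, rtol=1e-7):
    """Independent oracle: exhaustive enumeration of all tables with the
    observed margins, exact integer PMF comparison."""
    total = tp + fp + fn + tn
    k_edges, n_pred = tp + fn, tp + fp
    if total == 0 or k_edges in (0, total) or n_pred in (0, total):
        return 1.0
    denom = math.comb(total, n_pred)
    nums = {k: math.comb(k_edges, k) * math.comb(total - k_edges, n_pred - k)
            for k in range(max(0, n_pred - (total - k_edges)), min(k_edges, n_pred) + 1)}
    obs = nums[tp]
    scale = 10 ** 12
    acc = sum(v for v in nums.values() if v * scale <= obs * int(scale * (1 + rtol)))
    return acc / denom


def _corr_from_matrix(coef, ids):
    coef = np.asarray(coef, dtype=float)
    p = np.ones_like(coef)
    return CorrelationResult(coef, p, "pearson", 10, coef.shape[0], ids)


def _four_var_setup():
    ids = list("abcd")
    coef = np.eye(4)
    # |coef| >= 0.5 exactly for pairs (a,b) and (a,c)
    coef[0, 1] = coef[1, 0] = 0.9
    coef[0, 2] = coef[2, 0] = -0.6
    coef[0, 3] = coef[3, 0] = 0.1
    coef[1, 2] = coef[2, 1] = 0.2
    coef[1, 3] = coef[3, 1] = 0.05
    coef[2, 3] = coef[3, 2] = 0.3
    prior = PriorNetwork.from_edges([("a", "b"), ("c", "d")], ids)
    return _corr_from_matrix(coef, ids), prior


class TestContingency:
    def test_cutoff_zero_predicts_everything(self):
        corr, prior = _four_var_setup()
        t = pc.contingency(corr, 0.0, prior)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 4, 0, 0)

    def test_cutoff_above_max(self):
        corr, prior = _four_var_setup()
        t = pc.contingency(corr, 0.95, prior)
        assert (t.tp, t.fp) == (0, 0)
        assert t.fn == prior.edge_count

    def test_hand_enumerated_example(self):
        corr, prior = _four_var_setup()
        t = pc.contingency(corr, 0.5, prior)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 3)

    def test_counts_sum_to_pairs_and_margin_fixed(self):
        corr, prior = _four_var_setup()
        for cutoff in np.linspace(0, 1, 11):
            t = pc.contingency(corr, cutoff, prior)
            assert t.total == 6
            assert t.tp + t.fn == prior.edge_count

    def test_eval_mask_restricts_pairs(self):
        corr, prior = _four_var_setup()
        t = pc.contingency(corr, 0.5, prior, eval_mask=["a", "b", "c"])
        assert t.total == 3

    def test_no_common_variables_rejected(self):
        corr, _ = _four_var_setup()
        other = PriorNetwork.from_edges([("x", "y")])
        with pytest.raises(ValueError, match="shared"):
            pc.contingency(corr, 0.5, other)

    def test_cutoff_out_of_range_rejected(self):
        corr, prior = _four_var_setup()
        with pytest.raises(ValueError, match="outside"):
            pc.contingency(corr, 1.5, prior)


class TestFisher:
    def test_degenerate_margin_is_one(self):
        assert pc.fisher_two_sided(OverlapTable(0, 0, 5, 5)) == 1.0
        assert pc.fisher_two_sided(OverlapTable(0, 5, 0, 5)) == 1.0

    def test_diagonal_table_closed_form(self):
        assert pc.fisher_two_sided(OverlapTable(5, 0, 0, 5)) == \
            pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_matches_enumeration_oracle_small(self):
        for total in range(21):
            for tp in range(total + 1):
                for fp in range(total - tp + 1):
                    for fn in range(total - tp - fp + 1):
                        tn = total - tp - fp - fn
                        p = pc.fisher_two_sided(OverlapTable(tp, fp, fn, tn))
                        assert p == pytest.approx(
                            enumerated_fisher(tp, fp, fn, tn), abs=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 40, size=4)
            ours = pc.fisher_two_sided(OverlapTable(tp, fp, fn, tn))
            ref = fisher_exact([[tp, fp], [fn, tn]])[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_transposition_symmetry(self, t):
        tp, fp, fn, tn = t
        a = pc.fisher_two_sided(OverlapTable(tp, fp, fn, tn))
        b = pc.fisher_two_sided(OverlapTable(fn, tn, tp, fp))
        assert a == pytest.approx(b, rel=1e-9)

    def test_large_counts_do_not_overflow(self):
        p = pc.fisher_two_sided(OverlapTable(5000, 10**6, 2000, 10**8))
        assert 0 <= p <= 1

    def test_overlap_score(self):
        assert pc.overlap_score(OverlapTable(0, 0, 5, 5)) == 0.0
        t = OverlapTable(8, 2, 1, 9)
        assert pc.overlap_score(t) == pytest.approx(-math.log10(pc.fisher_two_sided(t)))

    def test_scores_for_grid_matches_per_cutoff(self):
        corr, prior = _four_var_setup()
        from priorcut.overlap import pair_arrays
        absr, edge = pair_arrays(corr, prior)
        grid = np.linspace(0, 1, 21)
        fast = scores_for_grid(absr, edge, grid)
        slow = [pc.overlap_score(pc.contingency(corr, c, prior)) for c in grid]
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestAdjust:
    def test_single_pvalue_unchanged(self):
        for method in ("BH", "bonferroni"):
            np.testing.assert_allclose(pc.adjust_pvalues([0.03], method), [0.03])

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            pc.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH"),
            [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_example(self):
        np.testing.assert_allclose(
            pc.adjust_pvalues([0.001, 0.5], "bonferroni"), [0.002, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pc.adjust_pvalues([0.5, 1.5], "BH")

    def test_bonferroni_threshold(self):
        assert pc.bonferroni_threshold(0.01, 311) == pytest.approx(0.01 / 311)


def _random_corr(rng, k=20, n=40):
    from priorcut.data import OmicsMatrix
    x = OmicsMatrix(rng.normal(size=(n, k)),
                    [f"s{i}" for i in range(n)], [f"v{j}" for j in range(k)])
    return pc.pearson(x)


class TestStatisticalCutoff:
    def test_all_significant_returns_min_abs(self):
        coef = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, -0.7], [0.6, -0.7, 1.0]])
        p = np.full((3, 3), 1e-6)
        np.fill_diagonal(p, 1.0)
        corr = CorrelationResult(coef, p, "pearson", 50, 3, list("abc"))
        assert pc.statistical_cutoff(corr, 0.01, "BH") == pytest.approx(0.6)

    def test_none_significant_returns_sentinel(self):
        coef = np.eye(3)
        p = np.ones((3, 3))
        corr = CorrelationResult(coef, p, "pearson", 50, 3, list("abc"))
        cut = pc.statistical_cutoff(corr, 0.01, "BH")
        assert cut > 1 and cut == NO_CUTOFF

    def test_matches_hand_composed_oracle(self, rng):
        corr = _random_corr(rng)
        r, p = corr.offdiag_upper()
        # hand-composed: BH adjust, then min |r| among significant
        m = p.size
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        adj_full = np.empty(m)
        adj_full[order] = np.clip(adj, 0, 1)
        sig = adj_full <= 0.25
        expected = np.abs(r[sig]).min() if sig.any() else NO_CUTOFF
        assert pc.statistical_cutoff(corr, 0.25, "BH") == pytest.approx(expected)

    def test_edge_count_consistency_when_distinct(self, rng):
        corr = _random_corr(rng, k=15)
        r, _ = corr.offdiag_upper()
        assert len(np.unique(np.abs(r))) == r.size  # distinct |r| precondition
        cut = pc.statistical_cutoff(corr, 0.3, "BH")
        n_sig = significant_edge_count(corr, 0.3, "BH")
        if np.isfinite(cut):
            assert (np.abs(r) >= cut).sum() == n_sig
        else:
            assert n_sig == 0
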