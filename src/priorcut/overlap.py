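"""Overlap between a thresholded correlation network and a prior network.

Every unordered pair of evaluated variables is classified as TP/FP/FN/TN by
crossing (|r| >= cutoff) with (edge in the prior). Agreement is scored by
the two-sided Fisher's exact test: the hypergeometric point probability of
the observed table is the kernel, and the two-sided p-value sums the point
probabilities of all tables with the same margins that are at most as
probable (with a small relative tolerance on the comparison). Lower p means
better overlap; the score reported on optimization curves is -log10 p.

All hypergeometric terms are computed in log space so that transcriptome-
scale pair counts (~1e8) do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationResult
from .network import PriorNetwork

#: Sentinel returned by :func:`statistical_cutoff` when no pair is
#: significant: strictly above 1, so the implied network is empty.
NO_CUTOFF = float("inf")

#: Relative tolerance on the "PMF at most as probable" comparison.
PMF_RTOL = 1e-7

_LN10 = math.log(10.0)


@dataclass
class OverlapTable:
    """2x2 contingency table of network-vs-prior edge classification."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def odds_ratio(self) -> float:
        """(TP*TN)/(FP*FN); inf when the denominator is 0. Diagnostic for
        telling enrichment-driven from depletion-driven optima apart."""
        denom = self.fp * self.fn
        if denom == 0:
            return float("inf") if self.tp * self.tn > 0 else float("nan")
        return self.tp * self.tn / denom

    @property
    def f1(self) -> float:
        """Diagnostic only; never used as the selection criterion."""
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def evaluated_variables(
    corr: CorrelationResult,
    prior: PriorNetwork,
    eval_mask=None,
) -> list[str]:
    """Variables entering overlap evaluation: present in both the correlation
    result and the prior node set, and in ``eval_mask`` when given.
    Order follows the correlation result."""
    prior_nodes = set(prior.node_ids)
    keep = [v for v in corr.variable_ids if v in prior_nodes]
    if eval_mask is not None:
        mask = {str(m) for m in eval_mask}
        keep = [v for v in keep if v in mask]
    return keep


def pair_arrays(
    corr: CorrelationResult,
    prior: PriorNetwork,
    eval_mask=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(|r|, prior-edge flag) per unordered evaluated pair.

    This is the vectorized core shared by :func:`contingency` and the grid
    scan in :mod:`priorcut.optimization`.
    """
    keep = evaluated_variables(corr, prior, eval_mask)
    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 variables shared between correlation result and prior"
        )
    ci = {v: i for i, v in enumerate(corr.variable_ids)}
    pi = {v: i for i, v in enumerate(prior.node_ids)}
    c_idx = np.array([ci[v] for v in keep])
    p_idx = np.array([pi[v] for v in keep])
    sub_r = np.abs(corr.coef[np.ix_(c_idx, c_idx)])
    sub_a = prior.adjacency[np.ix_(p_idx, p_idx)]
    iu = np.triu_indices(len(keep), 1)
    return sub_r[iu], sub_a[iu]


def contingency(
    corr: CorrelationResult,
    cutoff: float,
    prior: PriorNetwork,
    eval_mask=None,
) -> OverlapTable:
    """Classify evaluated pairs at ``cutoff`` (edge rule: |r| >= cutoff)."""
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    absr, edge = pair_arrays(corr, prior, eval_mask)
    pred = absr >= cutoff
    return OverlapTable(
        tp=int((pred & edge).sum()),
        fp=int((pred & ~edge).sum()),
        fn=int((~pred & edge).sum()),
        tn=int((~pred & ~edge).sum()),
    )


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided_logp(tp: int, fp: int, fn: int, tn: int) -> float:
    """Natural-log two-sided Fisher p for one table; exactly 0 (p=1) when
    any margin is zero."""
    total = tp + fp + fn + tn
    k_edges = tp + fn       # prior edges (one margin)
    n_pred = tp + fp        # predicted edges (other margin)
    if total == 0 or k_edges in (0, total) or n_pred in (0, total):
        return 0.0
    kmin = max(0, n_pred - (total - k_edges))
    kmax = min(k_edges, n_pred)
    ks = np.arange(kmin, kmax + 1)
    lp = (_log_comb(k_edges, ks)
          + _log_comb(total - k_edges, n_pred - ks)
          - _log_comb(total, n_pred))
    obs = lp[tp - kmin]
    keep = lp <= obs + math.log1p(PMF_RTOL)
    return min(0.0, float(logsumexp(lp[keep])))


def fisher_two_sided(table: OverlapTable) -> float:
    """Two-sided Fisher's exact test p-value for an overlap table."""
    return math.exp(fisher_two_sided_logp(*table.as_tuple()))


def overlap_score(table: OverlapTable) -> float:
    """-log10 of the two-sided Fisher p; 0 when p = 1."""
    return -fisher_two_sided_logp(*table.as_tuple()) / _LN10


def scores_for_grid(
    absr: np.ndarray,
    edge: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """-log10 Fisher p at every cutoff of ``grid`` for fixed pair arrays.

    Sorting the |r| values once makes each cutoff an O(log P) count query;
    the Fisher sum itself is O(min(margin)) per cutoff.
    """
    v_edge = np.sort(absr[edge])
    v_non = np.sort(absr[~edge])
    n_edge, n_non = v_edge.size, v_non.size
    total = n_edge + n_non
    out = np.empty(len(grid))
    for i, c in enumerate(grid):
        tp = n_edge - int(np.searchsorted(v_edge, c, side="left"))
        fp = n_non - int(np.searchsorted(v_non, c, side="left"))
        out[i] = -fisher_two_sided_logp(tp, fp, n_edge - tp, total - n_edge - fp) / _LN10
    return out


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: 'BH' (step-up FDR) or 'bonferroni'."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values outside [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p.ravel(), method=key)[1].reshape(p.shape)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests (e.g. the
    conservative screen threshold used across many parallel pathway tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def statistical_cutoff(
    corr: CorrelationResult,
    alpha: float = 0.01,
    method: str = "BH",
) -> float:
    """Smallest still-significant |r| after multiple-testing adjustment.

    Uses the full off-diagonal matrix. Returns :data:`NO_CUTOFF` (> 1,
    empty network) when nothing is significant.
    """
    r, p = corr.offdiag_upper()
    if r.size == 0:
        raise ValueError("correlation result has no off-diagonal coefficients")
    adj = adjust_pvalues(p, method)
    sig = adj <= alpha
    if not sig.any():
        return NO_CUTOFF
    return float(np.abs(r[sig]).min())


def significant_edge_count(
    corr: CorrelationResult,
    alpha: float = 0.01,
    method: str = "BH",
) -> int:
    """Number of pairs significant at ``alpha`` after adjustment."""
    _, p = corr.offdiag_upper()
    return int((adjust_pvalues(p, method) <= alpha).sum())
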