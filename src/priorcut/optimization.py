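"""Prior-guided cutoff optimization.

The central object is :class:`CutoffOptimization`, a statsmodels-style
model: it is constructed from a data matrix and a biological reference
network, and :meth:`CutoffOptimization.fit` bootstraps the data, scores a
grid of correlation-magnitude cutoffs by the two-sided Fisher overlap test
against the reference, and returns a results object carrying the
optimization curve, the selected optimal cutoff with bootstrap confidence
bands, the statistical (p-value based) cutoffs for comparison, and a
summary table. The module-level functions (:func:`scan`,
:func:`select_optimal`, :func:`evaluate_at_cutoff`,
:func:`samplesize_profile`) expose the individual steps.

Randomness policy: one master seed; bootstrap/subsample replicate ``b``
uses ``master_seed + b``, so external reimplementations can match runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import overlap as ov
from .correlation import CorrelationResult, estimate
from .data import OmicsMatrix
from .network import PriorNetwork

__all__ = [
    "OptimizationCurve",
    "CutoffSelection",
    "default_grid",
    "scan",
    "select_optimal",
    "evaluate_at_cutoff",
    "samplesize_profile",
    "CutoffOptimization",
    "CutoffOptimizationResults",
]


def default_grid(step: float = 0.01) -> np.ndarray:
    """Cutoff grid 0.00 .. 1.00 (inclusive) at ``step`` resolution."""
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


@dataclass
class OptimizationCurve:
    """Per-cutoff mean overlap score with bootstrap percentile bands."""

    cutoffs: np.ndarray
    mean_score: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int
    estimator: str
    per_boot_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        for name in ("mean_score", "ci_low", "ci_high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.cutoffs.shape:
                raise ValueError(f"{name} length does not match cutoff grid")
            setattr(self, name, arr)
        if np.any(self.ci_low > self.ci_high + 1e-12):
            raise ValueError("ci_low exceeds ci_high")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "mean_score": self.mean_score,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


@dataclass
class CutoffSelection:
    optimal_cutoff: float
    optimal_score: float
    statistical_cutoffs: dict = field(default_factory=dict)


def _validate_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cutoff grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("cutoff grid must be strictly ascending")
    if grid[0] < 0 or grid[-1] > 1:
        raise ValueError("cutoff grid must lie within [0, 1]")
    return grid


def _bootstrap_values(x: OmicsMatrix, rng: np.random.Generator) -> OmicsMatrix:
    idx = rng.integers(0, x.n_samples, x.n_samples)
    return OmicsMatrix(x.values[idx], [f"b{i}" for i in range(x.n_samples)],
                       list(x.variable_ids))


def scan(
    x: OmicsMatrix,
    prior: PriorNetwork,
    estimator: str = "shrinkage",
    grid=None,
    n_boot: int = 100,
    seed: int = 0,
    eval_mask=None,
) -> OptimizationCurve:
    """Bootstrap the sample rows, re-estimate the correlation matrix once
    per replicate, and score every grid cutoff against the prior.

    Returns the mean -log10 Fisher p per cutoff with 2.5/97.5 percentile
    bands across replicates.
    """
    grid = _validate_grid(default_grid() if grid is None else grid)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scores = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        rng = np.random.default_rng(seed + b)
        corr = estimate(_bootstrap_values(x, rng), estimator)
        absr, edge = ov.pair_arrays(corr, prior, eval_mask)
        scores[b] = ov.scores_for_grid(absr, edge, grid)
    return OptimizationCurve(
        cutoffs=grid,
        mean_score=scores.mean(axis=0),
        ci_low=np.percentile(scores, 2.5, axis=0),
        ci_high=np.percentile(scores, 97.5, axis=0),
        n_boot=n_boot,
        seed=seed,
        estimator=estimator,
        per_boot_scores=scores,
    )


def select_optimal(curve: OptimizationCurve, statistical_cutoffs=None) -> CutoffSelection:
    """Grid element maximizing the mean score; ties break toward the
    LARGEST cutoff (sparser network). Warns when the best score is 0, i.e.
    no cutoff beats the empty network."""
    if curve.cutoffs.size == 0:
        raise ValueError("empty optimization curve")
    best = curve.mean_score.max()
    idx = int(np.flatnonzero(curve.mean_score >= best - 1e-12)[-1])
    if best <= 0:
        warnings.warn("maximum overlap score is 0; no cutoff beats the empty network",
                      stacklevel=2)
    return CutoffSelection(
        optimal_cutoff=float(curve.cutoffs[idx]),
        optimal_score=float(best),
        statistical_cutoffs=dict(statistical_cutoffs or {}),
    )


def evaluate_at_cutoff(
    x: OmicsMatrix,
    prior: PriorNetwork,
    estimator: str = "shrinkage",
    cutoff: float = 0.0,
    eval_mask=None,
) -> tuple[ov.OverlapTable, float]:
    """Fisher overlap of the ORIGINAL (un-resampled) data network at a fixed
    cutoff — used to report the bootstrapped optimum on the original data and
    to validate it against a second, disjoint reference."""
    corr = estimate(x, estimator)
    table = ov.contingency(corr, cutoff, prior, eval_mask)
    return table, ov.fisher_two_sided(table)


def samplesize_profile(
    x: OmicsMatrix,
    sizes,
    n_rep: int = 100,
    alpha: float = 0.01,
    adjust: str = "BH",
    estimators=("pearson", "parcor", "shrinkage"),
    seed: int = 0,
) -> pd.DataFrame:
    """Statistical cutoff and edge count versus sample size.

    For each size, the rows are subsampled WITHOUT replacement ``n_rep``
    times (replicate b seeded with seed + b); per estimator the adjusted-p
    statistical cutoff and significant-edge count are aggregated to mean and
    95% percentile interval. Exact-partial rows for sizes <= k are emitted
    as missing (the covariance is not invertible there).
    """
    sizes = list(sizes)
    if any(s > x.n_samples for s in sizes):
        raise ValueError("every size must be <= the number of samples")
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    records = {(s, e): {"cutoff": [], "edges": []} for s in sizes for e in estimators}
    for b in range(n_rep):
        rng = np.random.default_rng(seed + b)
        for size in sizes:
            idx = rng.choice(x.n_samples, size=size, replace=False)
            sub = OmicsMatrix(x.values[idx],
                              [x.sample_ids[i] for i in idx],
                              list(x.variable_ids))
            for est in estimators:
                rec = records[(size, est)]
                if est == "parcor" and size <= x.n_variables:
                    rec["cutoff"].append(np.nan)
                    rec["edges"].append(np.nan)
                    continue
                corr = estimate(sub, est)
                cut = ov.statistical_cutoff(corr, alpha, adjust)
                rec["cutoff"].append(cut if np.isfinite(cut) else np.nan)
                rec["edges"].append(ov.significant_edge_count(corr, alpha, adjust))
    rows = []
    for (size, est), rec in records.items():
        cuts = np.asarray(rec["cutoff"], dtype=float)
        edges = np.asarray(rec["edges"], dtype=float)
        valid = np.isfinite(cuts)
        def _stats(a, v):
            if not v.any():
                return (np.nan, np.nan, np.nan)
            return (float(np.nanmean(a[v])),
                    float(np.nanpercentile(a[v], 2.5)),
                    float(np.nanpercentile(a[v], 97.5)))
        c_mean, c_lo, c_hi = _stats(cuts, valid)
        e_mean, e_lo, e_hi = _stats(edges, np.isfinite(edges))
        rows.append({
            "size": size, "estimator": est, "n_valid": int(valid.sum()),
            "mean_cutoff": c_mean, "cutoff_ci_low": c_lo, "cutoff_ci_high": c_hi,
            "mean_edges": e_mean, "edges_ci_low": e_lo, "edges_ci_high": e_hi,
        })
    return pd.DataFrame(rows).sort_values(["estimator", "size"]).reset_index(drop=True)


class CutoffOptimization:
    """Prior-guided correlation cutoff selection model.

    Parameters
    ----------
    data : OmicsMatrix
        Preprocessed (complete, covariate-corrected) samples x variables
        matrix.
    prior : PriorNetwork
        Biological reference network. Variables absent from the prior are
        kept for correlation estimation but excluded from overlap scoring.
    estimator : {'pearson', 'parcor', 'shrinkage'}
    grid : array-like, optional
        Ascending cutoffs in [0, 1]; defaults to 0.00..1.00 step 0.01.
    eval_mask : iterable of str, optional
        If given, overlap scoring is additionally restricted to these
        variables (e.g. identified metabolites only).
    """

    def __init__(self, data: OmicsMatrix, prior: PriorNetwork,
                 estimator: str = "shrinkage", grid=None, eval_mask=None):
        self.data = data
        self.prior = prior
        self.estimator = estimator
        self.grid = _validate_grid(default_grid() if grid is None else grid)
        self.eval_mask = list(eval_mask) if eval_mask is not None else None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, prior: PriorNetwork, **kwargs):
        return cls(OmicsMatrix.from_frame(frame), prior, **kwargs)

    def fit(self, n_boot: int = 100, seed: int = 0) -> "CutoffOptimizationResults":
        curve = scan(self.data, self.prior, self.estimator, self.grid,
                     n_boot=n_boot, seed=seed, eval_mask=self.eval_mask)
        full = estimate(self.data, self.estimator)
        stat = {
            (method, alpha): ov.statistical_cutoff(full, alpha, method)
            for method in ("BH", "bonferroni") for alpha in (0.01, 0.05)
        }
        selection = select_optimal(curve, statistical_cutoffs=stat)
        table = ov.contingency(full, selection.optimal_cutoff, self.prior,
                               self.eval_mask)
        pval = ov.fisher_two_sided(table)
        return CutoffOptimizationResults(self, curve, selection, full, table, pval)


class CutoffOptimizationResults:
    """Fit results: optimization curve, selected cutoff, diagnostics."""

    def __init__(self, model: CutoffOptimization, curve: OptimizationCurve,
                 selection: CutoffSelection, full_result: CorrelationResult,
                 overlap_at_optimum: ov.OverlapTable, pvalue_at_optimum: float):
        self.model = model
        self.curve = curve
        self.selection = selection
        self.full_result = full_result
        self.overlap_at_optimum = overlap_at_optimum
        self.pvalue_at_optimum = pvalue_at_optimum

    @property
    def optimal_cutoff(self) -> float:
        return self.selection.optimal_cutoff

    @property
    def optimal_score(self) -> float:
        return self.selection.optimal_score

    @property
    def odds_ratio(self) -> float:
        return self.overlap_at_optimum.odds_ratio

    def optimal_edges(self) -> list[tuple[str, str]]:
        """Edge list of the original-data network at the optimal cutoff."""
        r = self.full_result
        ids = r.variable_ids
        i, j = np.nonzero(np.triu(np.abs(r.coef) >= self.optimal_cutoff, 1))
        return sorted(tuple(sorted((ids[a], ids[b]))) for a, b in zip(i, j))

    def evaluate(self, prior: PriorNetwork | None = None,
                 cutoff: float | None = None) -> tuple[ov.OverlapTable, float]:
        """Overlap of the original-data network with a (possibly different,
        e.g. disjoint validation) prior at a (possibly different) cutoff."""
        prior = prior if prior is not None else self.model.prior
        cutoff = cutoff if cutoff is not None else self.optimal_cutoff
        table = ov.contingency(self.full_result, cutoff, prior, self.model.eval_mask)
        return table, ov.fisher_two_sided(table)

    def curve_frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    def summary(self) -> str:
        m, c = self.model, self.curve
        t = self.overlap_at_optimum
        lines = [
            "Prior-guided correlation cutoff selection",
            "=" * 57,
            f"estimator:            {m.estimator}",
            f"samples x variables:  {m.data.n_samples} x {m.data.n_variables}",
            f"prior edges (eval):   {t.tp + t.fn} over {t.total} pairs",
            f"bootstrap replicates: {c.n_boot} (seed {c.seed})",
            f"grid:                 [{c.cutoffs[0]:.2f}, {c.cutoffs[-1]:.2f}] "
            f"in {c.cutoffs.size} steps",
            "-" * 57,
            f"optimal cutoff:       {self.optimal_cutoff:.2f}",
            f"mean -log10 p:        {self.optimal_score:.3f}",
            f"p (original data):    {self.pvalue_at_optimum:.3e}",
            f"TP/FP/FN/TN:          {t.tp}/{t.fp}/{t.fn}/{t.tn}",
            f"odds ratio:           {self.odds_ratio:.3g}",
            "-" * 57,
        ]
        for (method, alpha), cut in sorted(self.selection.statistical_cutoffs.items()):
            shown = f"{cut:.3f}" if np.isfinite(cut) else "none (empty network)"
            lines.append(f"statistical cutoff {method:>10} @ {alpha:g}: {shown}")
        fit = self.full_result.fit
        if fit is not None:
            lines.append(
                f"shrinkage fit:        lambda={fit.lambda_shrink:.3f} "
                f"kappa={fit.kappa:.1f} eta0={fit.eta0:.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Optimization curve with bootstrap band, optimum and statistical
        cutoffs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.fill_between(c.cutoffs, c.ci_low, c.ci_high, alpha=0.25, label="95% band")
        ax.plot(c.cutoffs, c.mean_score, color="black", label="mean -log10 p")
        ax.axvline(self.optimal_cutoff, color="red", ls="-",
                   label=f"optimum {self.optimal_cutoff:.2f}")
        for (method, alpha), cut in sorted(self.selection.statistical_cutoffs.items()):
            if np.isfinite(cut):
                ax.axvline(cut, ls="--", alpha=0.6, label=f"{method} {alpha:g}")
        ax.set_xlabel("correlation cutoff")
        ax.set_ylabel("-log10 Fisher p")
        ax.legend(fontsize="small")
        return ax
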