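"""Correlation estimators with per-pair p-values.

Three estimators are provided:

* ``pearson`` — pairwise Pearson correlation, p-values from the classical
  t-statistic ``t = r * sqrt((N-2) / (1-r^2))`` on N-2 degrees of freedom.
* ``parcor`` — exact partial correlation from the inverted covariance
  matrix; requires more samples than variables. The t-statistic loses one
  degree of freedom per conditioned variable (df = N - k).
* ``shrinkage`` — partial correlation from a Schaefer–Strimmer-regularized
  correlation matrix ``R* = (1-lambda) R + lambda I`` with the analytic
  shrinkage intensity; p-values come from an empirically fitted null
  density ``f0(r; kappa) ~ (1 - r^2)^((kappa-3)/2)``, which makes the
  statistical cutoff largely sample-size independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data import OmicsMatrix

__all__ = [
    "CorrelationResult",
    "ShrinkageFit",
    "pearson",
    "partial_exact",
    "partial_shrinkage",
    "fit_null",
    "null_pvalues",
    "partial_from_covariance",
    "shrinkage_intensity",
    "ESTIMATORS",
    "estimate",
]


@dataclass
class ShrinkageFit:
    """Parameters of the shrinkage estimator's empirical null.

    lambda_shrink : shrinkage intensity in [0, 1] applied to the sample
        correlation matrix (0 = none, 1 = identity).
    kappa : degrees of freedom of the null density of partial correlation
        coefficients, > 1.
    eta0 : estimated proportion of null coefficients in [0, 1].
    """

    lambda_shrink: float
    kappa: float
    eta0: float

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_shrink <= 1:
            raise ValueError(f"lambda_shrink {self.lambda_shrink} outside [0, 1]")
        if not self.kappa > 1:
            raise ValueError(f"kappa must exceed 1, got {self.kappa}")
        if not 0 <= self.eta0 <= 1:
            raise ValueError(f"eta0 {self.eta0} outside [0, 1]")


@dataclass
class CorrelationResult:
    """Symmetric coefficient and p-value matrices plus estimator metadata."""

    coef: np.ndarray
    pvalues: np.ndarray
    estimator: str
    n_samples: int
    n_variables: int
    variable_ids: list[str]
    fit: ShrinkageFit | None = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        k = self.n_variables
        if self.coef.shape != (k, k) or self.pvalues.shape != (k, k):
            raise ValueError("coef/pvalues must be square matrices of size n_variables")
        if np.abs(self.coef - self.coef.T).max(initial=0.0) > 1e-12:
            raise ValueError("coefficient matrix not symmetric to 1e-12")
        if np.abs(self.pvalues - self.pvalues.T).max(initial=0.0) > 1e-12:
            raise ValueError("p-value matrix not symmetric to 1e-12")
        if np.abs(self.coef).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlation coefficients outside [-1, 1]")
        if self.pvalues.min(initial=1.0) < 0 or self.pvalues.max(initial=0.0) > 1:
            raise ValueError("p-values outside [0, 1]")

    def offdiag_upper(self):
        """(|i<j| coefficient, p-value) vectors over the upper triangle."""
        iu = np.triu_indices(self.n_variables, 1)
        return self.coef[iu], self.pvalues[iu]


def _check_complete(x: OmicsMatrix, min_n: int = 3) -> None:
    if np.isnan(x.values).any():
        raise ValueError("correlation estimators require a complete matrix; impute first")
    if x.n_samples < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.n_samples}")


def _check_variance(x: OmicsMatrix) -> None:
    sd = x.values.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        raise ValueError(f"variable {x.variable_ids[j]!r} has zero variance")


def _symmetrize(m: np.ndarray) -> np.ndarray:
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return np.clip(m, -1.0, 1.0)


def _t_pvalues(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from the t-statistic r * sqrt(df / (1 - r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 1.0)
    return np.clip(p, 0.0, 1.0)


def pearson(x: OmicsMatrix) -> CorrelationResult:
    """Pairwise Pearson correlation with classical t-test p-values."""
    _check_complete(x)
    _check_variance(x)
    r = _symmetrize(np.corrcoef(x.values, rowvar=False))
    p = _t_pvalues(r, x.n_samples - 2)
    return CorrelationResult(r, p, "pearson", x.n_samples, x.n_variables,
                             list(x.variable_ids))


def partial_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Partial correlations from a covariance (or correlation) matrix:
    invert, then ``pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)``."""
    cov = np.asarray(cov, dtype=float)
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance matrix is singular; use the shrinkage estimator"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    return _symmetrize(pcor)


def partial_exact(x: OmicsMatrix) -> CorrelationResult:
    """Exact partial correlation ('parcor') via covariance inversion."""
    _check_complete(x)
    _check_variance(x)
    if x.n_samples <= x.n_variables:
        raise ValueError(
            "exact partial correlation coefficients can only be estimated for a "
            f"sample size greater than the number of variables "
            f"(N={x.n_samples}, k={x.n_variables}); use the shrinkage estimator"
        )
    cov = np.cov(x.values, rowvar=False)
    pcor = partial_from_covariance(cov)
    # conditioning on the remaining k-2 variables costs k-2 degrees of freedom
    df = x.n_samples - 2 - (x.n_variables - 2)
    p = _t_pvalues(pcor, df)
    return CorrelationResult(pcor, p, "parcor", x.n_samples, x.n_variables,
                             list(x.variable_ids))


def shrinkage_intensity(values: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    ``lambda* = sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2`` clamped to [0, 1],
    with Var(r_ij) from the standard unbiased w-statistics formula.
    """
    n, k = values.shape
    sd = values.std(axis=0, ddof=1)
    xs = (values - values.mean(axis=0)) / sd
    s1 = xs.T @ xs                      # sum_k w_kij
    s2 = (xs ** 2).T @ (xs ** 2)        # sum_k w_kij^2
    var_r = n / (n - 1.0) ** 3 * (s2 - s1 ** 2 / n)
    r = s1 / (n - 1.0)
    iu = np.triu_indices(k, 1)
    denom = float((r[iu] ** 2).sum())
    if denom == 0:
        return 1.0
    return float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0))


def null_pvalues(r: np.ndarray, kappa: float) -> np.ndarray:
    """Two-sided p-values under the null density f0(r; kappa):
    ``p(r) = 1 - I_{r^2}(1/2, (kappa-1)/2)`` via the mirrored incomplete
    beta for numerical accuracy at large |r|."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    if np.isinf(kappa):
        return np.where(np.abs(r) < 1e-12, 1.0, 0.0)
    return special.betainc((kappa - 1.0) / 2.0, 0.5, 1.0 - r * r)


def fit_null(pcors: np.ndarray, truncation_quantile: float = 0.9) -> ShrinkageFit:
    """Fit the null degrees of freedom kappa to observed partial correlations.

    Only coefficients with |r| at or below the ``truncation_quantile`` of the
    observed |r| distribution (an approximately-null subset) enter the fit;
    the likelihood is that of the null density truncated to that window, so
    the estimate is consistent when the coefficients are genuinely null.
    eta0 is the (clamped) fraction of coefficients with p > 0.5, doubled.
    The shrinkage intensity is not estimated here and is set to 0.
    """
    r = np.asarray(pcors, dtype=float).ravel()
    if r.size < 10:
        raise ValueError(f"need at least 10 coefficients to fit the null, got {r.size}")
    if np.abs(r).max() >= 1:
        raise ValueError("coefficients must lie strictly inside (-1, 1)")
    c = float(np.quantile(np.abs(r), truncation_quantile))
    sub = r[np.abs(r) <= c]
    if c < 1e-12:
        raise ValueError("coefficients are degenerate (all ~0); cannot fit kappa")
    log1mr2 = np.log1p(-sub * sub)

    def nll(log_km1: float) -> float:
        kappa = 1.0 + np.exp(log_km1)
        b = (kappa - 1.0) / 2.0
        log_norm = special.betaln(0.5, b)
        # probability mass of the null inside the truncation window
        log_mass = np.log(np.clip(special.betainc(0.5, b, c * c), 1e-300, 1.0))
        ll = ((kappa - 3.0) / 2.0) * log1mr2.sum() \
            - sub.size * (log_norm + np.log(2.0) + log_mass)
        # density is over r in (-1,1): f(r) = (1-r^2)^((k-3)/2) / (2 B(1/2,(k-1)/2))
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-4), np.log(1e7)),
                                   method="bounded")
    if not res.success:
        raise ValueError("kappa optimization failed; more data may be needed")
    kappa = 1.0 + float(np.exp(res.x))
    if kappa <= 1.0001:
        raise ValueError(f"fitted kappa {kappa:.4f} at boundary (<= 1); more data needed")
    p = null_pvalues(r, kappa)
    eta0 = float(np.clip(2.0 * np.mean(p > 0.5), 0.0, 1.0))
    return ShrinkageFit(0.0, kappa, eta0)


def partial_shrinkage(
    x: OmicsMatrix,
    shrinkage: float | None = None,
) -> CorrelationResult:
    """Shrinkage partial correlation with empirically fitted null p-values.

    ``shrinkage`` overrides the analytic intensity (mainly for testing the
    limiting cases lambda=0 and lambda=1).
    """
    _check_complete(x)
    _check_variance(x)
    r = _symmetrize(np.corrcoef(x.values, rowvar=False))
    lam = shrinkage_intensity(x.values) if shrinkage is None else float(shrinkage)
    if not 0 <= lam <= 1:
        raise ValueError(f"shrinkage intensity {lam} outside [0, 1]")
    r_star = (1.0 - lam) * r + lam * np.eye(x.n_variables)
    pcor = partial_from_covariance(r_star)
    iu = np.triu_indices(x.n_variables, 1)
    if np.abs(pcor[iu]).max(initial=0.0) < 1e-12:
        # fully shrunk (or empty) matrix: every coefficient is exactly null
        fit = ShrinkageFit(lam, float("inf"), 1.0)
        p = np.ones_like(pcor)
    else:
        try:
            base = fit_null(pcor[iu])
        except ValueError as exc:
            warnings.warn(f"null fit failed ({exc}); p-values set to 1", stacklevel=2)
            fit = ShrinkageFit(lam, float("inf"), 1.0)
            p = np.ones_like(pcor)
        else:
            fit = ShrinkageFit(lam, base.kappa, base.eta0)
            p = null_pvalues(pcor, base.kappa)
            np.fill_diagonal(p, 1.0)
    return CorrelationResult(pcor, p, "shrinkage", x.n_samples, x.n_variables,
                             list(x.variable_ids), fit=fit)


ESTIMATORS = {
    "pearson": pearson,
    "parcor": partial_exact,
    "shrinkage": partial_shrinkage,
}


def estimate(x: OmicsMatrix, estimator: str) -> CorrelationResult:
    """Dispatch to a named estimator ('pearson', 'parcor', 'shrinkage')."""
    try:
        fn = ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(
            f"unknown estimator {estimator!r}; choose from {sorted(ESTIMATORS)}"
        ) from None
    return fn(x)
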