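"""Preprocessing chain for abundance matrices.

Order of application used by the pipeline: probabilistic quotient
normalization (raw scale), log transform, missingness filtering
(variables first, then samples), KNN imputation, covariate residualization.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.linalg

from .data import CovariateTable, OmicsMatrix

logger = logging.getLogger(__name__)


def _require_positive(values: np.ndarray, what: str) -> None:
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"{what} requires strictly positive values; "
                         f"found {values[r, c]!r} at row {r}, column {c}")


def pqn_normalize(x: OmicsMatrix, reference: np.ndarray | None = None) -> OmicsMatrix:
    """Probabilistic quotient normalization.

    The reference spectrum defaults to the per-variable median across all
    samples; a precomputed reference (e.g. from a training cohort) can be
    supplied instead. Each sample is divided by the median of its quotients
    against the reference (its dilution factor). Missing values are ignored
    inside medians and stay missing.

    For a fixed reference the dilution factor cancels any per-sample scale
    factor exactly; with the self-derived reference, rescaling samples also
    moves the per-variable medians, so invariance is only approximate.
    """
    v = x.values
    _require_positive(v, "PQN")
    if reference is None:
        reference = np.nanmedian(v, axis=0)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (x.n_variables,):
            raise ValueError(f"reference length {reference.shape} != {x.n_variables} variables")
        if np.any(reference <= 0) or np.any(~np.isfinite(reference)):
            raise ValueError("reference spectrum must be strictly positive and finite")
    quotients = v / reference
    with np.errstate(invalid="ignore"):
        dilution = np.nanmedian(quotients, axis=1)
    for i, d in enumerate(dilution):
        if not np.isfinite(d) or d == 0:
            raise ValueError(f"undefined dilution factor for sample {x.sample_ids[i]!r}")
    return OmicsMatrix(v / dilution[:, None], x.sample_ids, x.variable_ids)


def log_transform(x: OmicsMatrix, base: float | str = "e") -> OmicsMatrix:
    """Elementwise logarithm; ``base`` is ``'e'``, 2 or 10."""
    _require_positive(x.values, "log transform")
    if base == "e":
        out = np.log(x.values)
    elif float(base) in (2.0, 10.0):
        out = np.log(x.values) / math.log(float(base))
    else:
        raise ValueError(f"unsupported log base {base!r}")
    return OmicsMatrix(out, x.sample_ids, x.variable_ids)


def filter_missing(
    x: OmicsMatrix,
    max_var_missing: float = 0.2,
    max_sample_missing: float = 0.1,
) -> OmicsMatrix:
    """Drop variables with more than ``max_var_missing`` missing fraction,
    then samples with more than ``max_sample_missing`` — strictly-greater
    thresholds, in that fixed order."""
    for f in (max_var_missing, max_sample_missing):
        if not 0 <= f <= 1:
            raise ValueError(f"missingness threshold {f} outside [0, 1]")
    miss = np.isnan(x.values)
    keep_var = miss.mean(axis=0) <= max_var_missing
    values = x.values[:, keep_var]
    if values.shape[1] == 0:
        raise ValueError("missingness filtering removed all rows or columns")
    keep_smp = np.isnan(values).mean(axis=1) <= max_sample_missing
    values = values[keep_smp]
    if values.size == 0:
        raise ValueError("missingness filtering removed all rows or columns")
    return OmicsMatrix(
        values,
        [s for s, k in zip(x.sample_ids, keep_smp) if k],
        [v for v, k in zip(x.variable_ids, keep_var) if k],
    )


def _pairwise_correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation on pairwise-complete observations (NaN-tolerant)."""
    return pd.DataFrame(values).corr(min_periods=3).to_numpy()


def knn_impute(x: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing cells from the k most-correlated variables.

    For a missing cell (sample s, variable v) the k variables with the largest
    absolute pairwise-complete Pearson correlation to v that are observed in
    sample s each contribute a univariate regression prediction
    ``mean_v + r * (sd_v / sd_u) * (u_s - mean_u)`` (moments over the samples
    where both u and v are observed); predictions are averaged with weights
    |r|. A perfectly correlated neighbour therefore reproduces its value
    exactly.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= x.n_variables:
        raise ValueError(f"k={k} must be smaller than the number of variables ({x.n_variables})")
    v = x.values.copy()
    if not np.isnan(v).any():
        return x.copy()
    corr = _pairwise_correlation(x.values)
    np.fill_diagonal(corr, np.nan)
    obs = ~np.isnan(x.values)
    for j in range(x.n_variables):
        rows = np.flatnonzero(~obs[:, j])
        if rows.size == 0:
            continue
        cj = corr[:, j]
        if np.all(np.isnan(cj)):
            raise ValueError(
                f"variable {x.variable_ids[j]!r} has no complete pairings for imputation"
            )
        order = np.argsort(-np.abs(np.where(np.isnan(cj), -np.inf, cj)))
        for s in rows:
            preds, weights = [], []
            for u in order:
                if len(preds) >= k:
                    break
                r = cj[u]
                if np.isnan(r) or not obs[s, u]:
                    continue
                both = obs[:, j] & obs[:, u]
                xv, xu = x.values[both, j], x.values[both, u]
                sd_u = xu.std(ddof=1)
                if both.sum() < 3 or sd_u == 0:
                    continue
                pred = xv.mean() + r * (xv.std(ddof=1) / sd_u) * (x.values[s, u] - xu.mean())
                preds.append(pred)
                weights.append(abs(r))
            if not preds or sum(weights) == 0:
                # fall back to the variable mean when no usable neighbour exists
                v[s, j] = np.nanmean(x.values[:, j])
            else:
                v[s, j] = np.average(preds, weights=weights)
    return OmicsMatrix(v, x.sample_ids, x.variable_ids)


def residualize(x: OmicsMatrix, covariates: CovariateTable) -> OmicsMatrix:
    """Replace each variable by its OLS residuals on intercept + covariates.

    Samples are aligned by ID (inner join); dropped samples are logged.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    if np.isnan(x.values).any():
        raise ValueError("residualize requires a complete matrix; impute first")
    design = covariates.design_matrix()
    common = [s for s in x.sample_ids if s in set(design.index)]
    dropped = [s for s in x.sample_ids if s not in set(design.index)]
    if dropped:
        logger.info("residualize: dropping %d samples without covariates: %s",
                    len(dropped), dropped[:10])
    if not common:
        raise ValueError("no samples shared between data matrix and covariate table")
    frame = x.to_frame().loc[common]
    d = design.loc[common].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("covariate table contains missing values for joined samples")
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        r_mat, piv = scipy.linalg.qr(d, mode="r", pivoting=True)
        diag = np.abs(np.diag(r_mat))
        tol = diag.max() * max(d.shape) * np.finfo(float).eps
        collinear = [str(design.columns[p]) for p in piv[diag < tol]] or \
            [str(design.columns[p]) for p in piv[rank:]]
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {d.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    y = frame.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ beta
    return OmicsMatrix(resid, common, x.variable_ids)
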