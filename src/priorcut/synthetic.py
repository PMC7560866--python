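"""Synthetic Gaussian graphical model data with a known pathway graph.

The generator builds a sparse precision matrix whose off-diagonal support
is exactly a chosen pathway graph, so the true partial correlation network
is known. Sampled data emulate preprocessed (normalized, log-scale,
covariate-affected) omics matrices: multivariate normal draws plus optional
linear covariate effects and completely-at-random missingness. It does not
model raw-scale artefacts (counts, batch structure, detection limits).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import partial_from_covariance
from .data import CovariateTable, OmicsMatrix
from .network import PriorNetwork

__all__ = ["SyntheticModel", "random_pathway", "ggm_from_graph", "sample_data"]


@dataclass
class SyntheticModel:
    """Ground-truth GGM: pathway graph, precision/covariance, achieved edge
    partial correlations (recorded because positive-definiteness repair can
    shrink them below the nominal strength)."""

    graph: PriorNetwork
    precision: np.ndarray
    covariance: np.ndarray
    pcor_strength: float
    achieved_pcors: dict
    seed: int

    def true_partial_correlations(self) -> np.ndarray:
        return partial_from_covariance(self.covariance)


def random_pathway(
    n_nodes: int,
    n_edges: int,
    topology: str = "chain_lattice",
    seed: int = 0,
) -> PriorNetwork:
    """Seeded random graph with exactly ``n_edges`` edges.

    ``chain_lattice`` is a sparse low-degree synthesis-pathway-like grid: a
    backbone path plus rungs between second neighbours. ``erdos_renyi``
    draws edges uniformly; ``scale_free`` grows a preferential-attachment
    graph adjusted to the exact edge count.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_nodes < 2 or not 0 <= n_edges <= max_edges:
        raise ValueError(f"cannot place {n_edges} edges on {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"V{i:03d}" for i in range(n_nodes)]
    if topology == "chain_lattice":
        if n_edges < n_nodes - 1:
            raise ValueError("chain_lattice needs at least n_nodes - 1 edges (backbone path)")
        edges = [(i, i + 1) for i in range(n_nodes - 1)]
        rungs = [(i, i + 2) for i in range(n_nodes - 2)]
        extra = n_edges - len(edges)
        if extra > len(rungs):
            raise ValueError("chain_lattice topology cannot host that many edges")
        pick = rng.choice(len(rungs), size=extra, replace=False)
        edges += [rungs[i] for i in sorted(pick)]
    elif topology == "erdos_renyi":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        edges = list(g.edges)
    elif topology == "scale_free":
        m = max(1, round(n_edges / n_nodes))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
        edges = list(g.edges)
        while len(edges) > n_edges:
            edges.pop(int(rng.integers(len(edges))))
        existing = {tuple(sorted(e)) for e in edges}
        while len(edges) < n_edges:
            a, b = rng.choice(n_nodes, size=2, replace=False)
            key = (min(a, b), max(a, b))
            if key not in existing:
                existing.add(key)
                edges.append(key)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return PriorNetwork.from_edges(
        [(nodes[a], nodes[b]) for a, b in edges], nodes
    )


def ggm_from_graph(
    graph: PriorNetwork,
    pcor_strength: float = 0.25,
    seed: int = 0,
) -> SyntheticModel:
    """Build a GGM whose edges carry |partial correlation| ~ pcor_strength.

    The precision matrix gets -strength (random sign) at each edge and a
    unit diagonal; if that is not positive definite the diagonal is
    inflated by |lambda_min| + 0.05 and the matrix re-normalized to unit
    partial variances, which shrinks the achieved strengths (recorded in
    ``achieved_pcors``). Non-edge partial correlations are exactly zero.
    """
    if not 0 < pcor_strength <= 0.5:
        raise ValueError(f"pcor_strength {pcor_strength} outside (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = graph.n_nodes
    prec = np.eye(m)
    iu = np.triu_indices(m, 1)
    signs = rng.choice([-1.0, 1.0], size=m * (m - 1) // 2)
    vals = np.where(graph.adjacency[iu], -pcor_strength * signs, 0.0)
    prec[iu] = vals
    prec = prec + prec.T - np.eye(m)
    lam_min = float(np.linalg.eigvalsh(prec)[0])
    if lam_min <= 0:
        prec += (abs(lam_min) + 0.05) * np.eye(m)
    # re-normalize to unit partial variances (unit diagonal precision)
    d = np.sqrt(np.diag(prec))
    prec = prec / np.outer(d, d)
    cov = np.linalg.inv(prec)
    pcor = -prec.copy()
    np.fill_diagonal(pcor, 1.0)
    achieved = {
        (graph.node_ids[a], graph.node_ids[b]): float(pcor[a, b])
        for a, b in zip(*np.nonzero(np.triu(graph.adjacency, 1)))
    }
    return SyntheticModel(graph, prec, cov, pcor_strength, achieved, seed)


def sample_data(
    model: SyntheticModel,
    n: int,
    seed: int = 0,
    covariate_effects: np.ndarray | None = None,
    missing_rate: float = 0.0,
) -> tuple[OmicsMatrix, CovariateTable]:
    """Draw ``n`` samples from the model's covariance.

    ``covariate_effects`` is an optional (2, k) coefficient matrix for two
    emulated covariates — an age-like continuous covariate (standardized)
    and a gender-like binary one — added linearly to the Gaussian draws.
    ``missing_rate`` punches missing cells completely at random.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate {missing_rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    k = model.graph.n_nodes
    chol = np.linalg.cholesky(model.covariance)
    values = rng.standard_normal((n, k)) @ chol.T
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    if covariate_effects is not None:
        eff = np.asarray(covariate_effects, dtype=float)
        if eff.shape != (2, k):
            raise ValueError(f"covariate_effects must be (2, {k}), got {eff.shape}")
        z_age = (age - age.mean()) / age.std()
        values = values + np.outer(z_age, eff[0]) + np.outer(sex, eff[1])
    if missing_rate > 0:
        holes = rng.random((n, k)) < missing_rate
        values = np.where(holes, np.nan, values)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    cov_table = CovariateTable(
        pd.DataFrame({"age": age, "sex": sex}, index=sample_ids)
    )
    return OmicsMatrix(values, sample_ids, list(model.graph.node_ids)), cov_table
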