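"""Construction and controlled degradation of biological reference networks.

These operations emulate the partial-knowledge scenarios a user faces in
practice: an incomplete reference (random edge subsets), a partially wrong
reference (degree-preserving edge swaps up to full randomization), and a
coarse reference (block adjacency from class annotations). Set operations
support building disjoint optimization/validation reference pairs.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .network import PriorNetwork

__all__ = [
    "subsample_prior",
    "rewire_prior",
    "randomize_prior",
    "block_prior",
    "intersect_priors",
    "prior_difference",
    "read_class_annotation",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subsample_prior(prior: PriorNetwork, keep_fraction: float, rng_seed: int) -> PriorNetwork:
    """Keep a uniform random subset of round(keep_fraction * E) edges;
    the node set is unchanged (removed edges may leave nodes isolated)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction {keep_fraction} outside (0, 1]")
    edges = prior.edges()
    n_keep = _round_half_away(keep_fraction * len(edges))
    if n_keep == 0:
        raise ValueError("keep_fraction leaves zero edges")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(edges), size=n_keep, replace=False)
    return PriorNetwork.from_edges([edges[i] for i in sorted(idx)], prior.node_ids)


def rewire_prior(
    prior: PriorNetwork,
    n_swaps: int,
    rng_seed: int,
    swap_mode: str = "double_edge",
    max_tries_factor: int = 1000,
) -> PriorNetwork:
    """Apply ``n_swaps`` accepted edge swaps.

    ``double_edge`` (default) exchanges endpoints of two edges
    ((a,b),(c,d) -> (a,d),(c,b)), preserving every node degree; swaps that
    would create self-loops or duplicate edges are rejected without
    consuming the swap budget. ``uniform`` deletes a random edge and adds a
    uniformly random non-edge instead (degree NOT preserved), as a
    sensitivity alternative.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    if n_swaps == 0:
        return PriorNetwork(prior.adjacency.copy(), list(prior.node_ids))
    if prior.edge_count < 2:
        raise ValueError("rewiring requires at least 2 edges")
    if swap_mode == "double_edge":
        g = prior.to_networkx()
        try:
            nx.double_edge_swap(g, nswap=n_swaps,
                                max_tries=max_tries_factor * n_swaps,
                                seed=int(rng_seed))
        except nx.NetworkXAlgorithmError as exc:
            raise ValueError(f"no valid swap found within the attempt budget: {exc}") from exc
        return PriorNetwork.from_networkx(g)
    if swap_mode == "uniform":
        rng = np.random.default_rng(rng_seed)
        edge_set = set(prior.edges())
        nodes = list(prior.node_ids)
        for _ in range(n_swaps):
            edges = sorted(edge_set)
            drop = edges[rng.integers(len(edges))]
            edge_set.discard(drop)
            for _ in range(max_tries_factor):
                a, b = (nodes[i] for i in rng.choice(len(nodes), size=2, replace=False))
                cand = tuple(sorted((a, b)))
                if cand not in edge_set:
                    edge_set.add(cand)
                    break
            else:
                raise ValueError("no valid replacement edge found within the attempt budget")
        return PriorNetwork.from_edges(sorted(edge_set), nodes)
    raise ValueError(f"unknown swap_mode {swap_mode!r}")


def randomize_prior(prior: PriorNetwork, rng_seed: int) -> PriorNetwork:
    """Uniform random graph on the same node set with the same edge count."""
    m = prior.n_nodes
    n_edges = prior.edge_count
    if n_edges == 0:
        return PriorNetwork(prior.adjacency.copy(), list(prior.node_ids))
    rng = np.random.default_rng(rng_seed)
    iu = np.triu_indices(m, 1)
    pick = rng.choice(iu[0].size, size=n_edges, replace=False)
    adj = np.zeros((m, m), dtype=bool)
    adj[iu[0][pick], iu[1][pick]] = True
    return PriorNetwork(adj | adj.T, list(prior.node_ids))


def block_prior(classes: dict, node_ids=None) -> PriorNetwork:
    """Coarse reference: connect every pair of variables sharing a class
    label. ``classes`` maps variable ID -> class label (one label each)."""
    classes = {str(k): str(v) for k, v in classes.items()}
    if node_ids is None:
        node_ids = sorted(classes)
    node_ids = [str(n) for n in node_ids]
    index = {n: i for i, n in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=bool)
    by_class: dict[str, list[str]] = {}
    for var, lab in classes.items():
        by_class.setdefault(lab, []).append(var)
    for members in by_class.values():
        idx = [index[v] for v in members if v in index]
        for ii, a in enumerate(idx):
            for b in idx[ii + 1:]:
                adj[a, b] = adj[b, a] = True
    return PriorNetwork(adj, node_ids)


def _union_nodes(a: PriorNetwork, b: PriorNetwork) -> list[str]:
    extra = [n for n in b.node_ids if n not in set(a.node_ids)]
    return list(a.node_ids) + extra


def intersect_priors(a: PriorNetwork, b: PriorNetwork) -> PriorNetwork:
    """Edges present in both priors; node set is the union (nodes missing
    from one prior are treated as isolated there)."""
    nodes = _union_nodes(a, b)
    return PriorNetwork.from_edges(sorted(a.edge_set() & b.edge_set()), nodes)


def prior_difference(a: PriorNetwork, b: PriorNetwork) -> PriorNetwork:
    """Edges of ``a`` not in ``b`` (e.g. making an optimization reference
    disjoint from a validation reference); node set is the union."""
    nodes = _union_nodes(a, b)
    return PriorNetwork.from_edges(sorted(a.edge_set() - b.edge_set()), nodes)


def read_class_annotation(path) -> dict:
    """Read variable -> class labels from a two-column TSV or a GMT file
    (class, description, members...). Each variable must map to exactly one
    class per file."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        if first.count("\t") >= 2:  # GMT: class <tab> description <tab> members...
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                label = parts[0]
                for var in parts[2:]:
                    if var and var in out:
                        raise ValueError(f"variable {var!r} annotated with multiple classes")
                    if var:
                        out[var] = label
        else:
            df = pd.read_csv(path, sep="\t", header=None, dtype=str)
            for var, label in df.itertuples(index=False):
                if var in out:
                    raise ValueError(f"variable {var!r} annotated with multiple classes")
                out[var] = label
    return out
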