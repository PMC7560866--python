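"""Biological reference (prior knowledge) networks.

A :class:`PriorNetwork` is an undirected, unweighted graph over named
variables, stored as a boolean symmetric adjacency matrix with zero
diagonal. It is the reference against which thresholded correlation
networks are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class PriorNetwork:
    adjacency: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.node_ids = [str(n) for n in self.node_ids]
        m = len(self.node_ids)
        if self.adjacency.shape != (m, m):
            raise ValueError(f"adjacency shape {self.adjacency.shape} != ({m}, {m})")
        if len(set(self.node_ids)) != m:
            raise ValueError("node IDs must be unique")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal (no self-edges)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        """Unordered edges as sorted-name tuples, deterministic order."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        out = [tuple(sorted((self.node_ids[a], self.node_ids[b]))) for a, b in zip(i, j)]
        return sorted(out)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())

    def degree_sequence(self) -> list[int]:
        return sorted(int(d) for d in self.adjacency.sum(axis=0))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(cls, edges, node_ids=None) -> "PriorNetwork":
        edges = [(str(a), str(b)) for a, b in edges]
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} rejected")
        if node_ids is None:
            node_ids = sorted({n for e in edges for n in e})
        node_ids = [str(n) for n in node_ids]
        index = {n: i for i, n in enumerate(node_ids)}
        adj = np.zeros((len(node_ids), len(node_ids)), dtype=bool)
        for a, b in edges:
            if a not in index or b not in index:
                raise ValueError(f"edge ({a!r}, {b!r}) references a node outside node_ids")
            adj[index[a], index[b]] = adj[index[b], index[a]] = True
        return cls(adj, node_ids)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PriorNetwork":
        nodes = [str(n) for n in g.nodes]
        return cls.from_edges([(str(a), str(b)) for a, b in g.edges], nodes)

    @classmethod
    def empty(cls, node_ids) -> "PriorNetwork":
        m = len(list(node_ids))
        return cls(np.zeros((m, m), dtype=bool), list(node_ids))


def read_prior(path, node_ids=None) -> PriorNetwork:
    """Read a prior network from TSV.

    Accepts either a two-column edge list (no header) or a square 0/1
    adjacency matrix with matching header and row names. Duplicate edges and
    self-loops in an edge list are rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] == 2:
        edges = [(a, b) for a, b in df.itertuples(index=False)]
        seen = set()
        for a, b in edges:
            key = tuple(sorted((a, b)))
            if a == b:
                raise ValueError(f"self-loop on node {a!r} rejected")
            if key in seen:
                raise ValueError(f"duplicate edge ({a!r}, {b!r}) rejected")
            seen.add(key)
        return PriorNetwork.from_edges(edges, node_ids)
    adj = pd.read_csv(path, sep="\t", index_col=0)
    if list(adj.index.astype(str)) != [str(c) for c in adj.columns]:
        raise ValueError("adjacency TSV must have identical row and column names")
    values = adj.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("adjacency TSV must contain only 0/1 entries")
    return PriorNetwork(values.astype(bool), [str(c) for c in adj.columns])


def write_prior(prior: PriorNetwork, path) -> None:
    """Write the prior as a two-column edge-list TSV (no header)."""
    pd.DataFrame(prior.edges()).to_csv(path, sep="\t", header=False, index=False)
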