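"""Two-level map-equation partitioning of the bipartite genome-protein graph.

The map equation scores a partition M of an undirected graph by the expected
description length of a random walk,

    L(M) = q H(Q) + sum_i p_i H(P_i),

with node visit rates proportional to degree, module exit rates q_i from
inter-module edge weight, and Shannon entropies over the exit and within-
module visit distributions. Minimizing L groups genomes that share protein
clusters. The optimizer is greedy agglomerative (local node moves plus module
merges) with seeded deterministic tie-breaking; on small graphs it is checked
against exhaustive set-partition enumeration.
"""

from __future__ import annotations

import logging
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)


def _xlog2x(x: float) -> float:
    return 0.0 if x <= 0.0 else x * np.log2(x)


def map_equation(G: nx.Graph, partition: Mapping[Hashable, int]) -> float:
    """Codelength L(M) in bits of a partition (node -> module id).

    Uniform edge weights unless a 'weight' attribute is present. Isolated
    nodes carry zero visit rate and do not contribute.
    """
    W = G.size(weight="weight")
    if W <= 0:
        return 0.0
    two_w = 2.0 * W
    modules = set(partition[v] for v in G.nodes)
    p_node = {v: G.degree(v, weight="weight") / two_w for v in G.nodes}
    q = {m: 0.0 for m in modules}
    for u, v, w in G.edges(data="weight", default=1.0):
        if partition[u] != partition[v]:
            q[partition[u]] += w / two_w
            q[partition[v]] += w / two_w
    q_tot = sum(q.values())
    # index codebook
    L = _xlog2x(q_tot) - sum(_xlog2x(qi) for qi in q.values())
    # module codebooks
    p_mod = {m: q[m] for m in modules}
    for v in G.nodes:
        p_mod[partition[v]] += p_node[v]
    for m in modules:
        L += _xlog2x(p_mod[m]) - _xlog2x(q[m])
    L -= sum(_xlog2x(p) for p in p_node.values())
    return float(L)


def exhaustive_partition(G: nx.Graph) -> tuple[dict, float]:
    """Globally optimal partition by complete set-partition enumeration
    (independent check for the greedy optimizer; feasible to ~10 nodes)."""
    nodes = sorted(G.nodes, key=str)
    if len(nodes) > 12:
        raise ValueError("exhaustive enumeration is limited to 12 nodes")
    best, best_L = None, np.inf
    for assignment in _set_partitions(len(nodes)):
        part = {v: assignment[i] for i, v in enumerate(nodes)}
        L = map_equation(G, part)
        if L < best_L - 1e-12:
            best, best_L = part, L
    return best, best_L


def _set_partitions(n: int):
    """Restricted-growth strings enumerating all set partitions of n items."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i]) (0 for i == 0)
    while True:
        yield tuple(a)
        for i in range(n - 1, 0, -1):
            if a[i] <= b[i]:
                a[i] += 1
                bi = max(b[i], a[i])
                for k in range(i + 1, n):
                    a[k] = 0
                    b[k] = bi
                break
        else:
            return


class MapEquationPartitioner:
    """Greedy map-equation community detection (sklearn-style estimator).

    Parameters
    ----------
    seed : int
        Seeds the node-visit order; results are deterministic for a fixed
        seed and input graph.
    max_passes : int
        Upper bound on local-move/merge sweeps.

    Attributes
    ----------
    labels_ : dict node -> module index (0-based, densely renumbered)
    codelength_ : float, the achieved L(M) in bits
    """

    def __init__(self, seed: int = 42, max_passes: int = 50):
        self.seed = seed
        self.max_passes = max_passes

    def get_params(self, deep: bool = True) -> dict:
        return {"seed": self.seed, "max_passes": self.max_passes}

    def set_params(self, **params) -> "MapEquationPartitioner":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, G: nx.Graph) -> "MapEquationPartitioner":
        if G.number_of_nodes() == 0:
            raise ValueError("empty graph")
        rng = np.random.default_rng(self.seed)
        nodes = sorted(G.nodes, key=str)
        part = {v: i for i, v in enumerate(nodes)}
        L = map_equation(G, part)
        for _ in range(self.max_passes):
            part, L, moved = self._local_moves(G, part, L, nodes, rng)
            part, L, merged = self._merge_pass(G, part, L)
            if not moved and not merged:
                break
        self.labels_ = self._renumber(part, nodes)
        self.codelength_ = L
        return self

    def fit_predict(self, G: nx.Graph) -> dict:
        return self.fit(G).labels_

    @staticmethod
    def _renumber(part: Mapping, nodes: Iterable) -> dict:
        remap: dict[int, int] = {}
        out = {}
        for v in nodes:
            m = part[v]
            if m not in remap:
                remap[m] = len(remap)
            out[v] = remap[m]
        return out

    def _local_moves(self, G, part, L, nodes, rng):
        moved_any = False
        for _ in range(self.max_passes):
            order = list(nodes)
            rng.shuffle(order)
            improved = False
            for v in order:
                current = part[v]
                candidates = sorted(
                    {part[u] for u in G.neighbors(v) if part[u] != current}
                )
                best_m, best_L = current, L
                for m in candidates:
                    part[v] = m
                    cand_L = map_equation(G, part)
                    if cand_L < best_L - 1e-12:
                        best_m, best_L = m, cand_L
                part[v] = best_m
                if best_m != current:
                    L = best_L
                    improved = True
                    moved_any = True
            if not improved:
                break
        return part, L, moved_any

    def _merge_pass(self, G, part, L):
        merged_any = False
        while True:
            adjacent = set()
            for u, v in G.edges:
                if part[u] != part[v]:
                    adjacent.add(tuple(sorted((part[u], part[v]))))
            best_pair, best_L = None, L
            for a, b in sorted(adjacent):
                trial = {v: (a if m == b else m) for v, m in part.items()}
                cand_L = map_equation(G, trial)
                if cand_L < best_L - 1e-12:
                    best_pair, best_L = (a, b), cand_L
            if best_pair is None:
                return part, L, merged_any
            a, b = best_pair
            part = {v: (a if m == b else m) for v, m in part.items()}
            L = best_L
            merged_any = True


def partition_genomes(
    G: nx.Graph,
    genome_nodes: Iterable[Hashable],
    seed: int = 42,
) -> dict:
    """Partition the bipartite flow graph and restrict module membership to
    the genome nodes. Genomes isolated from the graph each get their own
    module."""
    genome_nodes = list(genome_nodes)
    H = G.copy()
    for v in genome_nodes:
        if v not in H:
            H.add_node(v)
    labels = MapEquationPartitioner(seed=seed).fit(H).labels_
    out = {}
    next_solo = max(labels.values(), default=-1) + 1
    for v in sorted(genome_nodes, key=str):
        if H.degree(v) == 0:
            out[v] = next_solo
            next_solo += 1
        else:
            out[v] = labels[v]
    return out
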