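"""Median-joining haplotype networks.

Builds the ε-relaxed minimum spanning network (MSN) over observed haplotypes
and iteratively adds inferred median haplotypes (quasi-medians) that shorten
the total connection cost, in the style of the median-joining algorithm used
for haplotype genealogy figures. For biallelic allele strings the
quasi-median of three sequences is simply the position-wise majority string.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .haplotypes import Haplotype


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length allele strings differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class NetworkNode:
    name: str
    alleles: str
    n_members: int = 0
    inferred: bool = False


@dataclass
class HaploNetwork:
    """Graph of observed + inferred haplotypes with Hamming-weighted edges."""

    nodes: list[NetworkNode]
    edges: list[tuple[str, str, int]]  # (name_a, name_b, weight), name_a < name_b
    epsilon: int = 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.name, alleles=n.alleles, n_members=n.n_members,
                       inferred=n.inferred)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def total_cost(self) -> int:
        """Total weight of a minimum spanning tree of the network's own edges."""
        g = self.to_networkx()
        if g.number_of_nodes() <= 1:
            return 0
        return int(sum(d["weight"] for _, _, d in
                       nx.minimum_spanning_edges(g, data=True)))


def _distance_matrix(strings: Sequence[str]) -> np.ndarray:
    arr = np.array([[c == "A" for c in s] for s in strings], dtype=bool)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)


def _mst_parents(dist: np.ndarray) -> list[tuple[int, int]]:
    """Prim's algorithm; returns MST edges for a dense symmetric matrix."""
    n = dist.shape[0]
    if n <= 1:
        return []
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].astype(float).copy()
    best[0] = np.inf
    parent = np.zeros(n, dtype=int)
    edges = []
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        edges.append((int(parent[j]), j))
        in_tree[j] = True
        upd = dist[j] < best
        parent[upd] = j
        best = np.minimum(best, dist[j])
        best[in_tree] = np.inf
    return edges


def _bottleneck_matrix(dist: np.ndarray) -> np.ndarray:
    """Minimax path weight between every pair (max edge on the MST path)."""
    n = dist.shape[0]
    mst_edges = _mst_parents(dist)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for a, b in mst_edges:
        w = int(dist[a, b])
        adj[a].append((b, w))
        adj[b].append((a, w))
    out = np.zeros((n, n), dtype=int)
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            u, mx = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    out[src, v] = max(mx, w)
                    stack.append((v, max(mx, w)))
    return out


def _msn_edges(dist: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """ε-relaxed minimum spanning network over a dense distance matrix.

    An edge (u, v) is included iff d(u, v) ≤ bottleneck(u, v) + ε, where the
    bottleneck is the minimum feasible connection weight (minimax path). At
    ε = 0 this is exactly the union of all minimum spanning trees.
    """
    n = dist.shape[0]
    bottleneck = _bottleneck_matrix(dist)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if dist[i, j] <= bottleneck[i, j] + epsilon]


def _check_uniform_lengths(strings: Sequence[str]) -> None:
    lengths = {len(s) for s in strings}
    if len(lengths) > 1:
        raise ValueError(f"haplotype strings have non-uniform lengths: {sorted(lengths)}")


def _to_network(strings: Sequence[str], meta: dict[str, Haplotype],
                median_names: dict[str, str], epsilon: int) -> HaploNetwork:
    dist = _distance_matrix(strings)
    nodes = []
    names = []
    for s in strings:
        if s in meta:
            h = meta[s]
            nodes.append(NetworkNode(h.name, s, h.n_members, inferred=False))
            names.append(h.name)
        else:
            nodes.append(NetworkNode(median_names[s], s, 0, inferred=True))
            names.append(median_names[s])
    edges = [(min(names[i], names[j]), max(names[i], names[j]), int(dist[i, j]))
             for i, j in _msn_edges(dist, epsilon)]
    return HaploNetwork(nodes=nodes, edges=sorted(edges), epsilon=epsilon)


def build_msn(haplotypes: Sequence[Haplotype], epsilon: int = 0) -> HaploNetwork:
    """ε-relaxed minimum spanning network over observed haplotypes only."""
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    strings = [h.alleles for h in haplotypes]
    _check_uniform_lengths(strings)
    meta = {h.alleles: h for h in haplotypes}
    return _to_network(strings, meta, {}, epsilon)


def _majority(a: str, b: str, c: str) -> str:
    return "".join(x if x == y or x == z else y for x, y, z in zip(a, b, c))


def _mst_cost(strings: Sequence[str]) -> int:
    if len(strings) <= 1:
        return 0
    dist = _distance_matrix(strings)
    return int(sum(dist[a, b] for a, b in _mst_parents(dist)))


def build_mj_network(haplotypes: Sequence[Haplotype],
                     epsilon: int = 0) -> HaploNetwork:
    """Median-joining network: MSN plus inferred median haplotypes.

    Iterates: build the ε-relaxed MSN over the current node set; propose the
    position-wise majority string of every connected triple (two MSN edges
    sharing a node); greedily add the median that most reduces the total
    connection cost; stop at a fixpoint. Inferred nodes that end up with MSN
    degree ≤ 2 are pruned (by the triangle inequality they cannot reduce
    cost). Observed haplotypes are never pruned. Terminates because each
    accepted median strictly reduces the integer connection cost.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    strings = [h.alleles for h in haplotypes]
    _check_uniform_lengths(strings)
    meta = {h.alleles: h for h in haplotypes}
    observed = set(strings)
    nodes = list(dict.fromkeys(strings))

    while True:
        cost = _mst_cost(nodes)
        dist = _distance_matrix(nodes)
        edges = _msn_edges(dist, epsilon)
        neighbours: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for a, b in edges:
            neighbours[a].add(b)
            neighbours[b].add(a)
        candidates: set[str] = set()
        for u, nbrs in neighbours.items():
            for v, w in itertools.combinations(sorted(nbrs), 2):
                m = _majority(nodes[u], nodes[v], nodes[w])
                if m not in nodes:
                    candidates.add(m)
        best_m, best_cost = None, cost
        for m in sorted(candidates):
            c = _mst_cost(nodes + [m])
            if c < best_cost or (c == best_cost and best_m is not None and m < best_m):
                best_m, best_cost = m, c
        if best_m is None:
            break
        nodes.append(best_m)

    # prune inferred nodes that are not branch points
    while True:
        dist = _distance_matrix(nodes)
        degree = {i: 0 for i in range(len(nodes))}
        for a, b in _msn_edges(dist, epsilon):
            degree[a] += 1
            degree[b] += 1
        removable = [i for i in range(len(nodes))
                     if nodes[i] not in observed and degree[i] <= 2]
        if not removable:
            break
        nodes = [s for i, s in enumerate(nodes) if i != removable[0]]

    median_names = {}
    k = 0
    for s in nodes:
        if s not in meta:
            k += 1
            median_names[s] = f"mv{k}"
    return _to_network(nodes, meta, median_names, epsilon)


def edge_table(network: HaploNetwork) -> list[dict]:
    """Rows for the edge-list TSV."""
    kind = {n.name: ("median" if n.inferred else "observed") for n in network.nodes}
    return [{"node_a": a, "node_b": b, "weight": w,
             "type_a": kind[a], "type_b": kind[b]}
            for a, b, w in network.edges]


def node_table(network: HaploNetwork) -> list[dict]:
    return [{"node": n.name, "alleles": n.alleles, "n_members": n.n_members,
             "inferred": int(n.inferred)} for n in network.nodes]
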