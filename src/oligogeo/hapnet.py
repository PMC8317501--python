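"""Median-joining haplotype networks over oligotype sequences.

Nodes are sampled oligotypes plus inferred median (Steiner) vectors; edges
are labelled with the Hamming distance between their endpoint sequences.
Node weights follow the frequency-sum convention: per-site relative
frequencies of each oligotype are summed across sites, so the weights over
all oligotypes sum to the number of sites regardless of unequal sequencing
depths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .sequences import decode, encode

__all__ = ["node_weights", "median_joining", "msn_edges", "mst_cost"]


def node_weights(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Frequency-sum node weights and the per-site composition matrix.

    Each site's counts are normalised to relative frequencies; an oligotype's
    weight is the sum of its frequencies across sites.  Returns the weight
    series and the oligotype x site frequency matrix (for pie rendering).
    """
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        zero = list(sums.index[sums == 0])
        raise ValueError(f"zero-sum site column(s): {zero}")
    freq = counts / sums
    return freq.sum(axis=1), freq


def _dist_matrix(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i] = (codes[i] != codes).sum(axis=1)
    return d


def mst_cost(D: np.ndarray) -> float:
    """Total weight of a minimum spanning tree of the distance matrix."""
    return float(minimum_spanning_tree(D).sum())


def msn_edges(D: np.ndarray, epsilon: float = 0.0) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    Kruskal over ascending distance classes: every edge of a class that joins
    two components *as they stood before the class was processed* is admitted
    (the union of all MSTs when epsilon = 0); with epsilon > 0 a class also
    admits edges up to epsilon heavier.
    """
    n = D.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = [(D[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    weights = sorted({w for w, _, _ in pairs})
    edges: set[tuple[int, int]] = set()
    for w in weights:
        batch = [
            (i, j)
            for d, i, j in pairs
            if w <= d <= w + epsilon and find(i) != find(j)
        ]
        if not batch:
            continue
        for i, j in batch:
            edges.add((min(i, j), max(i, j)))
        for i, j in batch:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return edges


def _triplet_median(codes: np.ndarray, seqs: list[str], tri: tuple[int, int, int]):
    """Position-wise majority median; 3-way ties keep the state of the
    lexicographically first sequence of the triplet."""
    order = sorted(tri, key=lambda i: seqs[i])
    a, b, c = (codes[i] for i in tri)
    med = codes[order[0]].copy()
    maj_ab = a == b
    maj_ac = a == c
    maj_bc = b == c
    med[maj_ab] = a[maj_ab]
    med[maj_ac] = a[maj_ac]
    med[maj_bc] = b[maj_bc]
    return med


def median_joining(
    seqs: list[str],
    weights: pd.Series | dict | None = None,
    epsilon: float = 0.0,
    composition: pd.DataFrame | None = None,
) -> nx.Graph:
    """Median-joining network of unique haplotype sequences.

    Iterates: (1) build the epsilon-relaxed minimum spanning network over the
    current node set; (2) for every connected triplet compute the majority
    median and add the single median giving the largest strict reduction in
    total connection cost (MST weight), ties broken by lexicographically
    smallest sequence; (3) repeat to a fixed point; (4) iteratively prune
    unsampled medians of degree <= 2.  Deterministic given the input.

    Returns a :class:`networkx.Graph` whose nodes carry ``sequence``,
    ``sampled``, ``weight`` (0 for medians) and optional ``composition``
    attributes, and whose edges carry ``mutations``.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate sequences: deduplicate into oligotypes first")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must share one length")

    node_seqs = list(seqs)
    sampled = {s: True for s in seqs}
    codes = encode(node_seqs)

    while True:
        D = _dist_matrix(codes)
        edges = msn_edges(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(node_seqs))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        cost_now = mst_cost(D)

        # candidate medians from connected triplets (a path u-v-w suffices)
        candidates: set[str] = set()
        for v in range(len(node_seqs)):
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                med = _triplet_median(codes, node_seqs, (u, v, w))
                med_s = decode(med[None, :])[0]
                if med_s not in sampled and med_s not in candidates:
                    candidates.add(med_s)

        best = None
        for med_s in sorted(candidates):
            ext = np.vstack([codes, encode([med_s])])
            reduction = cost_now - mst_cost(_dist_matrix(ext))
            if reduction > 1e-9 and (best is None or reduction > best[0] + 1e-9):
                best = (reduction, med_s)
        if best is None:
            break
        node_seqs.append(best[1])
        sampled[best[1]] = False
        codes = encode(node_seqs)

    # prune unsampled medians of degree <= 2, rebuilding the network each time
    while True:
        D = _dist_matrix(codes)
        edges = msn_edges(D, epsilon)
        degree = np.zeros(len(node_seqs), dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        prunable = [
            i
            for i in range(len(node_seqs))
            if not sampled[node_seqs[i]] and degree[i] <= 2
        ]
        if not prunable:
            break
        drop = min(prunable, key=lambda i: node_seqs[i])
        del node_seqs[drop]
        codes = encode(node_seqs)

    D = _dist_matrix(codes)
    edges = msn_edges(D, epsilon)

    g = nx.Graph()
    if weights is None:
        seq_weight = {s: 1.0 for s in seqs}
    else:
        vals = list(weights.values) if hasattr(weights, "values") else list(weights)
        if len(vals) != len(seqs):
            raise ValueError("weights must align with seqs")
        seq_weight = {s: float(w) for s, w in zip(seqs, vals)}

    for i, s in enumerate(node_seqs):
        g.add_node(
            i,
            sequence=s,
            sampled=sampled[s],
            weight=seq_weight.get(s, 0.0) if sampled[s] else 0.0,
        )
        if composition is not None and sampled[s]:
            pos = seqs.index(s)
            g.nodes[i]["composition"] = composition.iloc[pos].to_dict()
    for i, j in sorted(edges):
        g.add_edge(i, j, mutations=int(D[i, j]))
    return g
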