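"""Independent brute-force oracles used by the test suite.

These expand oligotype count matrices into individual sequences and evaluate
the statistics from their definitions, deliberately sharing no code with the
frequency-weighted implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def expand(counts: np.ndarray) -> list[tuple[int, int]]:
    """List of (oligotype index, site index) individuals."""
    out = []
    k, s = counts.shape
    for i in range(k):
        for j in range(s):
            out.extend([(i, j)] * int(counts[i, j]))
    return out


def hamming_bf(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b) if x != "N" and y != "N")


def diversity_bf(col: np.ndarray, D: np.ndarray):
    """H and Pi for one site, evaluated pair by pair over individuals.

    H is the fraction of unordered individual pairs belonging to different
    oligotypes; Pi is the mean pairwise distance — both identical to the
    small-sample-corrected frequency formulas.
    """
    inds = [i for i, c in enumerate(col) for _ in range(int(c))]
    n = len(inds)
    if n < 2:
        return np.nan, np.nan
    pairs = list(itertools.combinations(range(n), 2))
    H = sum(1 for a, b in pairs if inds[a] != inds[b]) / len(pairs)
    Pi = sum(D[inds[a], inds[b]] for a, b in pairs) / len(pairs)
    return H, Pi


def amova_bf(c1: np.ndarray, c2: np.ndarray, D: np.ndarray, mode: str) -> float:
    """Two-level AMOVA statistic from fully expanded individuals."""
    inds = [(i, 0) for i, c in enumerate(c1) for _ in range(int(c))]
    inds += [(i, 1) for i, c in enumerate(c2) for _ in range(int(c))]
    N = len(inds)
    n1 = int(c1.sum())
    n2 = int(c2.sum())

    def d2(a, b):
        d = D[a, b]
        if mode == "fst":
            return 1.0 if d > 0 else 0.0
        return float(d) ** 2

    ssd_total = sum(d2(a[0], b[0]) for a, b in itertools.product(inds, inds)) / (2 * N)
    g1 = [a for a in inds if a[1] == 0]
    g2 = [a for a in inds if a[1] == 1]
    ssd_within = sum(d2(a[0], b[0]) for a, b in itertools.product(g1, g1)) / (2 * n1)
    ssd_within += sum(d2(a[0], b[0]) for a, b in itertools.product(g2, g2)) / (2 * n2)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - 2)
    n_prime = N - (n1**2 + n2**2) / N
    sigma_a = max((ssd_among - sigma_w) / n_prime, 0.0)
    if sigma_a + sigma_w <= 0:
        return 0.0
    return min(max(sigma_a / (sigma_a + sigma_w), 0.0), 1.0)


def snn_bf(counts: np.ndarray, D: np.ndarray) -> float:
    """Hudson's Snn from expanded individuals; nearest-neighbour ties shared."""
    inds = expand(counts)
    N = len(inds)
    total = 0.0
    for a in range(N):
        oa, sa = inds[a]
        dists = [D[oa, inds[b][0]] for b in range(N) if b != a]
        others = [b for b in range(N) if b != a]
        dmin = min(dists)
        nn = [b for b, d in zip(others, dists) if d == dmin]
        same = sum(1 for b in nn if inds[b][1] == sa)
        total += same / len(nn)
    return total / N


def mj_steiner_bf(seqs: list[str], alphabet: str = "AC") -> float:
    """Minimal MST cost over seqs plus any subset of possible median points.

    Exhaustive Steiner search over all sequences of the given alphabet and
    length — only feasible for tiny instances.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    L = len(seqs[0])
    universe = ["".join(p) for p in itertools.product(alphabet, repeat=L)]
    extra = [u for u in universe if u not in seqs]

    def cost(nodes):
        n = len(nodes)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = hamming_bf(nodes[i], nodes[j])
        return float(minimum_spanning_tree(D).sum())

    best = cost(seqs)
    for r in range(1, len(extra) + 1):
        for combo in itertools.combinations(extra, r):
            best = min(best, cost(seqs + list(combo)))
    return best
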