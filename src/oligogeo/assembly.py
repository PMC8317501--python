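"""Ecological-process partitioning of oligotype turnover.

Pairwise phylogenetic turnover (abundance-weighted beta-mean-nearest-taxon
distance, betaMNTD) is compared to a null built by shuffling oligotype labels
across the tips of a fixed tree, giving the beta-nearest-taxon index (betaNTI
z-score).  Taxonomic turnover is judged against an abundance-weighted
Raup-Crick null of Bray-Curtis dissimilarity (RC_Bray).  Pairs are then
classified into five assembly processes:

* betaNTI < -2           -> homogeneous selection
* betaNTI > +2           -> variable selection
* else, RC < -0.95       -> homogenizing dispersal
* else, RC > +0.95       -> dispersal limitation (plus drift)
* otherwise              -> ecological drift

The tree is a neighbour-joining tree on inter-oligotype Hamming distances
(negative branch lengths clamped to zero), a desk-scale substitute for a
maximum-likelihood phylogeny.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "nj_tree",
    "patristic_matrix",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "rc_bray",
    "partition_processes",
    "ProcessPartition",
    "PROCESSES",
]

PROCESSES = (
    "homogeneous_selection",
    "homogenizing_dispersal",
    "ecological_drift",
    "dispersal_limitation",
    "variable_selection",
)


def nj_tree(dists: pd.DataFrame) -> TreeNode:
    """Neighbour-joining tree from a symmetric distance matrix.

    Negative branch lengths (an NJ artefact) are clamped to zero.  With fewer
    than three taxa a trivial star tree is returned with a warning.
    """
    ids = [str(i) for i in dists.index]
    D = np.asarray(dists, dtype=float)
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if len(ids) < 3:
        warnings.warn("fewer than 3 taxa: returning trivial star tree")
        root = TreeNode(name=None)
        for i, name in enumerate(ids):
            length = float(D[0, 1]) / 2.0 if len(ids) == 2 else 0.0
            root.append(TreeNode(name=name, length=length))
        return root
    tree = nj(DistanceMatrix(D, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def patristic_matrix(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Tip-to-tip path distances ordered by ``taxa``."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in map(str, taxa)]
    return dm.data[np.ix_(idx, idx)]


def _bmntd_pair(f1: np.ndarray, f2: np.ndarray, D: np.ndarray) -> float:
    """Abundance-weighted betaMNTD for two relative-abundance vectors."""
    in1 = f1 > 0
    in2 = f2 > 0
    if not in1.any() or not in2.any():
        raise ValueError("empty sample in betaMNTD")
    d12 = D[np.ix_(in1, in2)]
    term1 = float(f1[in1] @ d12.min(axis=1))
    term2 = float(f2[in2] @ d12.min(axis=0))
    return 0.5 * (term1 + term2)


def beta_mntd(
    comm: pd.DataFrame, tree: TreeNode, pair: tuple[str, str]
) -> float:
    """betaMNTD between two samples of a samples x oligotypes matrix."""
    D = patristic_matrix(tree, list(comm.columns))
    a = comm.loc[pair[0]].to_numpy(dtype=float)
    b = comm.loc[pair[1]].to_numpy(dtype=float)
    fa = a / a.sum() if a.sum() else a
    fb = b / b.sum() if b.sum() else b
    return _bmntd_pair(fa, fb, D)


def beta_mntd_matrix(comm: pd.DataFrame, tree: TreeNode) -> pd.DataFrame:
    """All-pairs betaMNTD matrix."""
    D = patristic_matrix(tree, list(comm.columns))
    F = comm.to_numpy(dtype=float)
    F = F / F.sum(axis=1, keepdims=True)
    n = len(comm.index)
    out = pd.DataFrame(0.0, index=comm.index, columns=comm.index)
    for i, j in itertools.combinations(range(n), 2):
        v = _bmntd_pair(F[i], F[j], D)
        out.iloc[i, j] = out.iloc[j, i] = v
    return out


def beta_nti(
    comm: pd.DataFrame,
    tree: TreeNode,
    reps: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """betaNTI z-scores against a tip-label shuffle null.

    The null shuffles oligotype labels across tree tips (equivalently,
    jointly permutes rows/columns of the patristic matrix) and recomputes
    betaMNTD.  A null with zero standard deviation yields betaNTI = 0 with a
    warning.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = rng or np.random.default_rng()
    taxa = list(comm.columns)
    D = patristic_matrix(tree, taxa)
    F = comm.to_numpy(dtype=float)
    F = F / F.sum(axis=1, keepdims=True)
    n = len(comm.index)
    pairs = list(itertools.combinations(range(n), 2))

    obs = np.array([_bmntd_pair(F[i], F[j], D) for i, j in pairs])
    null = np.empty((reps, len(pairs)))
    for r in range(reps):
        perm = rng.permutation(len(taxa))
        Dp = D[np.ix_(perm, perm)]
        null[r] = [_bmntd_pair(F[i], F[j], Dp) for i, j in pairs]
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.zeros(len(pairs))
    nonzero = sd > 0
    z[nonzero] = (obs[nonzero] - mean[nonzero]) / sd[nonzero]
    if (~nonzero).any():
        warnings.warn("null betaMNTD sd is 0 for some pair(s); betaNTI set to 0")
    out = pd.DataFrame(0.0, index=comm.index, columns=comm.index)
    for (i, j), v in zip(pairs, z):
        out.iloc[i, j] = out.iloc[j, i] = v
    return out


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    s = (x + y).sum()
    return float(np.abs(x - y).sum() / s) if s else 0.0


def rc_bray(
    comm: pd.DataFrame,
    reps: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Abundance-weighted Raup-Crick deviation of Bray-Curtis, in [-1, 1].

    For each pair, null communities preserve each sample's observed richness
    (taxa drawn without replacement with probability proportional to
    occupancy across samples) and total abundance (distributed multinomially
    proportional to metacommunity relative abundances over the drawn taxa);
    ``RC = 2 ((#null < obs) + 0.5 (#null = obs)) / reps - 1``.  A
    metacommunity with a single oligotype yields RC = 0 by convention.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = rng or np.random.default_rng()
    X = comm.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample in community matrix")
    n, t = X.shape
    occupancy = (X > 0).sum(axis=0).astype(float)
    meta = X.sum(axis=0)
    meta_p = meta / meta.sum()
    present = occupancy > 0

    out = pd.DataFrame(0.0, index=comm.index, columns=comm.index)
    if present.sum() < 2:
        return out  # single-oligotype metacommunity: RC = 0 everywhere

    occ_p = occupancy[present] / occupancy[present].sum()
    active = np.flatnonzero(present)
    richness = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)

    def null_sample(i: int) -> np.ndarray:
        k = min(int(richness[i]), len(active))
        drawn = rng.choice(active, size=k, replace=False, p=occ_p)
        p = meta_p[drawn]
        p = p / p.sum()
        vec = np.zeros(t)
        vec[drawn] = rng.multinomial(int(round(totals[i])), p)
        return vec

    for i, j in itertools.combinations(range(n), 2):
        obs = _bray_curtis(X[i], X[j])
        less = equal = 0
        for _ in range(reps):
            bc = _bray_curtis(null_sample(i), null_sample(j))
            if bc < obs - 1e-12:
                less += 1
            elif abs(bc - obs) <= 1e-12:
                equal += 1
        rc = 2.0 * (less + 0.5 * equal) / reps - 1.0
        out.iloc[i, j] = out.iloc[j, i] = rc
    return out


@dataclass
class ProcessPartition:
    """Fractions and pair counts of the five assembly processes."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_pairs: int
    n_excluded: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series({p: self.fractions[p] for p in PROCESSES})


def partition_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> ProcessPartition:
    """Classify sample pairs into the five assembly processes.

    betaNTI beyond +/-2 signals selection; otherwise RC_Bray beyond +/-0.95
    separates dispersal processes from drift.  Pairs with a missing value in
    either matrix are excluded with a warning.
    """
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise ValueError("betaNTI and RC matrices must cover identical pairs")
    counts = {p: 0 for p in PROCESSES}
    n_excluded = 0
    idx = list(bnti.index)
    for i, j in itertools.combinations(range(len(idx)), 2):
        b = bnti.iloc[i, j]
        r = rc.iloc[i, j]
        if np.isnan(b) or np.isnan(r):
            n_excluded += 1
            continue
        if b < -2:
            counts["homogeneous_selection"] += 1
        elif b > 2:
            counts["variable_selection"] += 1
        elif r < -0.95:
            counts["homogenizing_dispersal"] += 1
        elif r > 0.95:
            counts["dispersal_limitation"] += 1
        else:
            counts["ecological_drift"] += 1
    if n_excluded:
        warnings.warn(f"{n_excluded} pair(s) excluded for missing values")
    n_pairs = sum(counts.values())
    if n_pairs == 0:
        raise ValueError("no classifiable pairs")
    fractions = {p: counts[p] / n_pairs for p in PROCESSES}
    return ProcessPartition(fractions, counts, n_pairs, n_excluded)
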