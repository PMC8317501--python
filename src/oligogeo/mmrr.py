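"""Isolation by distance vs isolation by environment via matrix regression.

Distance matrices compared:

* geographic: great-circle (haversine) distances between site coordinates,
  optionally Hellinger-transformed row-wise (the convention replicated here
  from the source workflow, unusual as the transform was designed for
  community tables; disable with ``hellinger=False``);
* environmental: per-site scores of the first principal component of the
  standardized environmental table, turned into 1-D Euclidean distances;
* response: Bray-Curtis dissimilarity of oligotype composition.

Inference is multiple matrix regression with randomization (MMRR): ordinary
least squares on the vectorized lower triangles, with significance from
jointly permuting rows and columns of the response matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "great_circle_km",
    "hellinger_rows",
    "env_pc1_distance",
    "bray_curtis",
    "mmrr",
    "MMRRFit",
    "expand_site_matrix",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(geo: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distances (km) between sites.

    ``geo`` must have columns ``latitude`` and ``longitude`` in decimal
    degrees, indexed by unique site id.
    """
    if geo.index.duplicated().any():
        raise ValueError("duplicate site ids")
    lat = np.radians(geo["latitude"].to_numpy(dtype=float))
    lon = np.radians(geo["longitude"].to_numpy(dtype=float))
    if (np.abs(geo["latitude"]) > 90).any() or (np.abs(geo["longitude"]) > 180).any():
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(
        dlon / 2
    ) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=geo.index, columns=geo.index)


def hellinger_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform each row: ``x -> sqrt(x / row sum)``."""
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("entries must be non-negative")
    sums = X.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("zero row sum")
    out = np.sqrt(X / sums[:, None])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def env_pc1_distance(env: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """PC1 scores of the standardized environment table as 1-D distances.

    Columns are standardized ((x - mean)/sd); constant columns are dropped
    with a warning.  Returns the site x site |PC1_i - PC1_j| matrix and the
    fraction of variance explained by PC1.
    """
    if env.shape[0] < 2:
        raise ValueError("need at least two sites")
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(env.columns[~keep])
        warnings.warn(f"constant variable(s) dropped: {dropped}")
    if not keep.any():
        raise ValueError("all variables constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    d = np.abs(scores[:, None] - scores[None, :])
    return pd.DataFrame(d, index=env.index, columns=env.index), var_explained


def bray_curtis(comm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa matrix."""
    X = comm.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    for i, j in itertools.combinations(range(len(X)), 2):
        if X[i].sum() == 0 and X[j].sum() == 0:
            raise ValueError(f"both-zero sample pair ({i}, {j})")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=comm.index, columns=comm.index)


def expand_site_matrix(site_dm: pd.DataFrame, sample_site: dict[str, str]) -> pd.DataFrame:
    """Expand a site-level distance matrix to sample pairs.

    Between-site sample pairs take the site distance; within-site pairs 0.
    """
    samples = list(sample_site)
    n = len(samples)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        si, sj = sample_site[samples[i]], sample_site[samples[j]]
        out[i, j] = out[j, i] = 0.0 if si == sj else float(site_dm.loc[si, sj])
    return pd.DataFrame(out, index=samples, columns=samples)


@dataclass
class MMRRFit:
    """OLS coefficients with permutation inference, Table-style report."""

    coefficients: dict[str, float]
    t_statistics: dict[str, float]
    t_pvalues: dict[str, float]
    f_statistic: float
    f_pvalue: float
    r_squared: float
    intercept: float
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.coefficients:
            rows.append(
                {
                    "predictor": name,
                    "coefficient": self.coefficients[name],
                    "t_statistic": self.t_statistics[name],
                    "t_p_value": self.t_pvalues[name],
                }
            )
        df = pd.DataFrame(rows).set_index("predictor")
        df["f_statistic"] = [self.f_statistic] + [np.nan] * (len(df) - 1)
        df["f_p_value"] = [self.f_pvalue] + [np.nan] * (len(df) - 1)
        df["r_squared"] = [self.r_squared] + [np.nan] * (len(df) - 1)
        return df


def _lower(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], -1)
    return mat[i, j]


def mmrr(
    Y: pd.DataFrame,
    X: dict[str, pd.DataFrame] | list[pd.DataFrame],
    perms: int = 9999,
    rng: np.random.Generator | None = None,
    standardize: bool = False,
) -> MMRRFit:
    """Multiple matrix regression with randomization.

    Vectorizes lower triangles, fits OLS of the response distances on the
    predictor distances (with intercept), and builds the null by jointly
    permuting rows and columns of the response matrix; ``p`` values use the
    ``(count + 1)/(perms + 1)`` estimator on ``|t|`` and ``F``.
    Predictors are used on their supplied scale unless ``standardize``.
    """
    if perms < 1:
        raise ValueError("perms must be >= 1")
    rng = rng or np.random.default_rng()
    if isinstance(X, list):
        X = {f"X{i + 1}": m for i, m in enumerate(X)}
    names = list(X)
    n = Y.shape[0]
    for name, m in X.items():
        if m.shape != (n, n):
            raise ValueError(f"predictor {name} has mismatched shape")

    Ymat = Y.to_numpy(dtype=float)
    y = _lower(Ymat)
    cols = [_lower(m.to_numpy(dtype=float)) for m in X.values()]
    if standardize:
        cols = [(c - c.mean()) / c.std(ddof=1) for c in cols]
        y = (y - y.mean()) / y.std(ddof=1)

    # collinearity guard
    for (i, a), (j, b) in itertools.combinations(enumerate(cols), 2):
        if a.std() == 0 or b.std() == 0:
            continue
        r = np.corrcoef(a, b)[0, 1]
        if abs(r) > 0.99999:
            raise ValueError(
                f"collinear predictors: {names[i]} and {names[j]} (|r|={abs(r):.6f})"
            )

    design = np.column_stack([np.ones_like(y)] + cols)
    k = len(cols)
    n_obs = len(y)
    if n_obs <= k + 1:
        raise ValueError("too few sample pairs for the number of predictors")
    XtX = design.T @ design
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular design: predictors are collinear")
    XtX_inv = np.linalg.inv(XtX)
    hat = XtX_inv @ design.T

    def fit(yvec: np.ndarray):
        beta = hat @ yvec
        resid = yvec - design @ beta
        rss = float(resid @ resid)
        tss = float(((yvec - yvec.mean()) ** 2).sum())
        sigma2 = rss / (n_obs - k - 1)
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
        t = beta / se
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        if r2 >= 1.0 - 1e-15:
            F = math.inf
        else:
            F = (r2 / k) / ((1.0 - r2) / (n_obs - k - 1))
        return beta, t, F, r2

    beta, t_obs, F_obs, r2 = fit(y)

    ge_t = np.zeros(k)
    ge_f = 0
    for _ in range(perms):
        perm = rng.permutation(n)
        yp = _lower(Ymat[np.ix_(perm, perm)])
        if standardize:
            yp = (yp - yp.mean()) / yp.std(ddof=1)
        _, t_p, F_p, _ = fit(yp)
        ge_t += np.abs(t_p[1:]) >= np.abs(t_obs[1:])
        if F_p >= F_obs:
            ge_f += 1

    t_pvals = (ge_t + 1) / (perms + 1)
    f_pval = (ge_f + 1) / (perms + 1)
    return MMRRFit(
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        t_statistics={nm: float(v) for nm, v in zip(names, t_obs[1:])},
        t_pvalues={nm: float(v) for nm, v in zip(names, t_pvals)},
        f_statistic=float(F_obs),
        f_pvalue=float(f_pval),
        r_squared=float(r2),
        intercept=float(beta[0]),
        n_permutations=perms,
    )
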