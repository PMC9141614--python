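"""Bivariate global and local Moran's I with permutation inference.

Implements the spatial cross-correlation between one variable at a
location (here: rental price, P) and a second variable at its
neighbours (here: green-space exposure, A):

    global:  I_PA = N * sum_i sum_{j != i} w_ij z_i^P z_j^A
                    / ((N - 1) * sum_i sum_j w_ij)

    local:   I_i  = z_i^P * sum_j w_ij z_j^A

with z-scores computed using the sample (n-1) standard deviation, so the
(N - 1) normaliser of the global statistic is consistent with the
standardisation.  The local statistics satisfy the exact identity

    N * sum_i I_i / ((N - 1) * S0) = I_PA.

Significance is assessed by permutation: the global test permutes the
neighbour variable A across all units; the local (conditional) test holds
the focal unit's value fixed and draws its neighbours' values from the
remaining units.  Pseudo p-values are (1 + #extreme) / (1 + n_perm),
two-sided on the absolute statistic.

Spatial weights are queen contiguity over the community polygons by
default (row-standardised), with k-nearest-neighbour weights available
for sensitivity analysis.  Islands (units without neighbours) are kept in
the data structure with zero rows, excluded from the statistics, and
counted in a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

QUADRANT_LABELS = ("High-High", "High-Low", "Low-Low", "Low-High")


@dataclass
class SpatialWeights:
    """Sparse neighbour structure w_ij >= 0 with no self-neighbours."""

    sparse: sp.csr_matrix
    row_standardized: bool = False

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.sparse)
        if w.shape[0] != w.shape[1]:
            raise ValueError("weights matrix must be square")
        if w.diagonal().any():
            raise ValueError("self-neighbours (w_ii != 0) are not allowed")
        if (w.data < 0).any():
            raise ValueError("weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("weights matrix has no non-zero entries (S0 = 0)")
        self.sparse = w

    @property
    def n(self) -> int:
        return self.sparse.shape[0]

    @property
    def s0(self) -> float:
        return float(self.sparse.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.sparse.sum(axis=1)).ravel()

    @property
    def islands(self) -> np.ndarray:
        """Indices of units with no neighbours."""
        return np.flatnonzero(self.row_sums == 0)

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour indices and weights of unit i."""
        row = self.sparse.getrow(i)
        return row.indices, row.data


def queen_weights(polygons: list[BaseGeometry], snap_tol: float = 1e-6) -> SpatialWeights:
    """Binary queen-contiguity weights: shared boundary point => neighbours.

    Two polygons are neighbours if they come within ``snap_tol`` metres of
    each other (covers shared edges and shared single vertices, tolerant of
    floating-point coordinates).  Symmetric; islands allowed and logged.
    """
    n = len(polygons)
    if n < 2:
        raise ValueError("queen weights require at least 2 polygons")
    tree = STRtree(polygons)
    rows: list[int] = []
    cols: list[int] = []
    for i, poly in enumerate(polygons):
        for j in tree.query(poly.buffer(snap_tol)):
            j = int(j)
            if j != i and polygons[j].distance(poly) <= snap_tol:
                rows.append(i)
                cols.append(j)
    w = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    w = w.maximum(w.T)  # enforce symmetry
    weights = SpatialWeights(sparse=w, row_standardized=False)
    n_islands = len(weights.islands)
    if n_islands:
        logger.warning("queen_weights: %d island polygon(s) without neighbours", n_islands)
    return weights


def knn_weights(centroids: np.ndarray, k: int) -> SpatialWeights:
    """Binary k-nearest-neighbour weights; distance ties broken by lower id.

    Generally asymmetric; never produces islands.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k >= n:
        raise ValueError(f"k must be smaller than the number of units ({n})")
    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    ids = np.broadcast_to(np.arange(n), (n, n))
    # lexsort: primary key distance, secondary key id (lower id wins ties)
    order = np.lexsort((ids, dist), axis=1)
    neigh = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    w = sp.csr_matrix((np.ones(n * k), (rows, neigh.ravel())), shape=(n, n))
    return SpatialWeights(sparse=w, row_standardized=False)


def row_standardize(weights: SpatialWeights) -> SpatialWeights:
    """Divide each non-island row by its sum; island rows stay all-zero."""
    w = weights.sparse.copy().astype(float)
    sums = np.asarray(w.sum(axis=1)).ravel()
    n_islands = int((sums == 0).sum())
    if n_islands:
        logger.warning("row_standardize: %d island row(s) left at zero", n_islands)
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    w = sp.diags(inv) @ w
    return SpatialWeights(sparse=sp.csr_matrix(w), row_standardized=True)


@dataclass(frozen=True)
class StandardizedVector:
    """z-scores with their source mean and sample (n-1) standard deviation."""

    z: np.ndarray
    mean: float
    sd: float


def standardize(values: np.ndarray) -> StandardizedVector:
    """z_i = (x_i - mean) / sd with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("standardize requires a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("constant variable; Moran's I undefined")
    return StandardizedVector(z=(x - mean) / sd, mean=mean, sd=sd)


def spatial_lag(weights: SpatialWeights, z: np.ndarray) -> np.ndarray:
    """lag_i = sum_j w_ij z_j (zero for islands)."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != weights.n:
        raise ValueError("dimension mismatch between weights and vector")
    return weights.sparse @ z


def _effective_n(weights: SpatialWeights) -> int:
    """Unit count entering the global statistic: islands are excluded."""
    return weights.n - len(weights.islands)


def global_bivariate_moran(
    zP: np.ndarray, zA: np.ndarray, weights: SpatialWeights
) -> float:
    """I = N * sum_ij w_ij z_i^P z_j^A / ((N-1) * S0).

    N counts units with at least one neighbour; islands contribute nothing
    to either sum and are excluded from N.
    """
    zP = np.asarray(zP, dtype=float)
    zA = np.asarray(zA, dtype=float)
    if zP.shape[0] != weights.n or zA.shape[0] != weights.n:
        raise ValueError("dimension mismatch between weights and z-vectors")
    n_eff = _effective_n(weights)
    if n_eff < 2:
        raise ValueError("all units are islands; Moran's I undefined")
    num = float(zP @ (weights.sparse @ zA))
    return n_eff * num / ((n_eff - 1) * weights.s0)


def local_bivariate_moran(
    zP: np.ndarray, zA: np.ndarray, weights: SpatialWeights
) -> np.ndarray:
    """local_I_i = z_i^P * sum_j w_ij z_j^A (zero for islands)."""
    zP = np.asarray(zP, dtype=float)
    return zP * spatial_lag(weights, zA)


def classify_quadrant(zP: np.ndarray, lag: np.ndarray) -> np.ndarray:
    """LISA quadrant from the signs of (z_i^P, lag_i); zero counts as High.

    (+,+) High-High: high price surrounded by high greenness;
    (+,-) High-Low; (-,-) Low-Low; (-,+) Low-High.
    """
    zP = np.asarray(zP, dtype=float)
    lag = np.asarray(lag, dtype=float)
    p_high = zP >= 0
    a_high = lag >= 0
    out = np.empty(zP.shape[0], dtype=object)
    out[p_high & a_high] = "High-High"
    out[p_high & ~a_high] = "High-Low"
    out[~p_high & ~a_high] = "Low-Low"
    out[~p_high & a_high] = "Low-High"
    return out


@dataclass(frozen=True)
class MoranGlobalResult:
    """Global bivariate Moran's I with its permutation pseudo p-value."""

    I: float
    pseudo_p: float
    n_perm: int
    seed: int
    n: int
    s0: float


def permutation_test_global(
    P: np.ndarray,
    A: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranGlobalResult:
    """Two-sided permutation test of the global bivariate Moran's I.

    The neighbour variable A is randomly permuted across units ``n_perm``
    times with P and W held fixed; pseudo_p = (1 + #{|I_perm| >= |I_obs|})
    / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    zP = standardize(np.asarray(P, dtype=float)).z
    zA = standardize(np.asarray(A, dtype=float)).z
    i_obs = global_bivariate_moran(zP, zA, weights)
    n_eff = _effective_n(weights)
    scale = n_eff / ((n_eff - 1) * weights.s0)
    rng = np.random.default_rng(seed)
    # permute zA across units in a (n_perm, n) block, then one sparse matmul
    perm = np.argsort(rng.random((n_perm, weights.n)), axis=1)
    za_perm = zA[perm]  # (n_perm, n)
    lags = weights.sparse @ za_perm.T  # (n, n_perm)
    i_perm = scale * (zP @ lags)
    n_extreme = int(np.sum(np.abs(i_perm) >= abs(i_obs)))
    pseudo_p = (1 + n_extreme) / (1 + n_perm)
    return MoranGlobalResult(
        I=i_obs, pseudo_p=pseudo_p, n_perm=n_perm, seed=seed,
        n=n_eff, s0=weights.s0,
    )


def conditional_permutation_local(
    P: np.ndarray,
    A: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """LISA table: local bivariate Moran's I with conditional permutations.

    For each unit i the focal value z_i^P is held fixed while its
    neighbours' greenness values are drawn from the other n-1 units; the
    two-sided pseudo p compares |permuted local I| with the observed one.
    Quadrants are assigned to every unit from (sign z_i^P, sign lag_i); the
    significance flag subsets them at ``alpha`` (optionally BH-FDR
    adjusted; the raw-alpha cut is the mapping convention).

    Returns a DataFrame with columns: local_I, lag, quadrant, pseudo_p,
    significant, island.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    zP = standardize(np.asarray(P, dtype=float)).z
    zA = standardize(np.asarray(A, dtype=float)).z
    n = weights.n
    lag = spatial_lag(weights, zA)
    local_obs = zP * lag
    islands = set(weights.islands.tolist())

    rng = np.random.default_rng(seed)
    row_card = np.diff(weights.sparse.indptr)
    kmax = int(row_card.max())
    # one pool of index draws shared across units: each permutation row is a
    # sample without replacement from the n-1 "other" positions
    draw = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :kmax]

    pseudo_p = np.full(n, np.nan)
    for i in range(n):
        if i in islands:
            continue
        idx, w_i = weights.neighbors(i)
        k = len(idx)
        others = np.delete(zA, i)
        neigh_vals = others[draw[:, :k]]  # (n_perm, k)
        lag_perm = neigh_vals @ w_i
        local_perm = zP[i] * lag_perm
        n_extreme = int(np.sum(np.abs(local_perm) >= abs(local_obs[i])))
        pseudo_p[i] = (1 + n_extreme) / (1 + n_perm)

    quadrant = classify_quadrant(zP, lag)
    significant = np.zeros(n, dtype=bool)
    scored = ~np.isnan(pseudo_p)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        rej = multipletests(pseudo_p[scored], alpha=alpha, method="fdr_bh")[0]
        significant[np.flatnonzero(scored)] = rej
    else:
        significant[scored] = pseudo_p[scored] <= alpha
    return pd.DataFrame(
        {
            "local_I": local_obs,
            "lag": lag,
            "quadrant": quadrant,
            "pseudo_p": pseudo_p,
            "significant": significant,
            "island": [i in islands for i in range(n)],
        }
    )
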