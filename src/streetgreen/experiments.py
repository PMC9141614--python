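"""Simulation studies: permutation-test calibration and planted-effect recovery.

Two reusable study designs over the synthetic city:

* :func:`type_i_error_study` — size calibration of the global bivariate
  Moran permutation test under the null (independent price and greenness
  on a lattice), reporting the empirical rejection rate at a given alpha.

* :func:`recovery_study` — power/recovery of the planted negative
  greenness-price association at the reference study scale.  Community
  geometry, sample-point buffer membership and spatial weights are held
  fixed across replicates (they are deterministic study conditions);
  the stochastic layers — the smoothed greenery noise field and the
  price noise — are redrawn each replicate.  Point greenness enters as
  the planted surface value directly; the imaging round-trip
  (render -> classify -> pool) reproduces that value exactly up to pixel
  quantisation and is verified separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely

from .pipeline import RunConfig, stage_seed
from .exposure import buffer_radius
from .spatial_stats import (
    SpatialWeights,
    permutation_test_global,
    queen_weights,
    row_standardize,
)
from .synthetic_city import (
    PriceModel,
    generate_communities,
    generate_prices,
    generate_street_grid,
    plant_green_field,
    sample_points,
)


def lattice_weights(side: int) -> SpatialWeights:
    """Row-standardised queen weights on a side x side square lattice."""
    from shapely.geometry import box

    polys = [
        box(i, j, i + 1, j + 1) for j in range(side) for i in range(side)
    ]
    return row_standardize(queen_weights(polys))


def type_i_error_study(
    n_units_side: int = 10,
    n_reps: int = 500,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the global permutation test under the null.

    Price and greenness are drawn independently (standard normal) on a
    queen-contiguity lattice of ``n_units_side**2`` units; each replicate
    runs the full two-sided permutation test.  Returns the rejection rate
    at ``alpha`` plus the replicate p-values.
    """
    w = lattice_weights(n_units_side)
    rng = np.random.default_rng(seed)
    n = w.n
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        P = rng.standard_normal(n)
        A = rng.standard_normal(n)
        res = permutation_test_global(
            P, A, w, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[r] = res.pseudo_p
    return {
        "n_units": n,
        "n_reps": n_reps,
        "n_perm": n_perm,
        "alpha": alpha,
        "rejection_rate": float((pvals <= alpha).mean()),
        "pvalues": pvals,
    }


@dataclass
class _FixedGeometry:
    """Deterministic study conditions shared across recovery replicates."""

    xs: np.ndarray
    ys: np.ndarray
    membership: sp.csr_matrix  # (n_communities, n_points), row-normalised
    weights: SpatialWeights
    centroid_dist: np.ndarray  # community centroid distance to city centre
    config: RunConfig


def _build_geometry(config: RunConfig, buffer_minutes: float) -> _FixedGeometry:
    network = generate_street_grid(
        config.extent, config.street_spacing_m, config.street_jitter,
        seed=stage_seed(config.seed, "streets"),
    )
    locs = sample_points(network, config.sample_interval_m)
    xs = np.array([p[0] for p in locs])
    ys = np.array([p[1] for p in locs])
    geoms = shapely.points(xs, ys)
    tree = shapely.STRtree(geoms)

    polys = generate_communities(
        config.extent, config.n_communities, seed=stage_seed(config.seed, "communities")
    )
    radius = buffer_radius(buffer_minutes, config.walking_speed)
    rows, cols, vals = [], [], []
    for i, poly in enumerate(polys):
        buf = poly.buffer(radius)
        cand = tree.query(buf)
        inside = cand[shapely.covers(buf, geoms[cand])]
        if len(inside) == 0:
            raise RuntimeError(f"community {i} has no sample point in buffer")
        rows.extend([i] * len(inside))
        cols.extend(inside.tolist())
        vals.extend([1.0 / len(inside)] * len(inside))
    membership = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(polys), len(xs))
    )
    weights = row_standardize(queen_weights(polys))
    xmin, ymin, xmax, ymax = config.extent
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    dist = np.hypot(cents[:, 0] - cx, cents[:, 1] - cy)
    return _FixedGeometry(xs, ys, membership, weights, dist, config)


def recovery_study(
    n_reps: int = 200,
    config: RunConfig | None = None,
    buffer_minutes: float = 15.0,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery of the planted greenness-price association.

    Each replicate redraws the greenery noise field and the price noise
    under ``config`` (default: the reference city with beta < 0), computes
    community exposure at ``buffer_minutes``, and runs the global
    bivariate Moran permutation test.  Returns one row per replicate with
    the observed I and pseudo p.
    """
    config = config or RunConfig()
    geom = _build_geometry(config, buffer_minutes)
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_reps):
        field = plant_green_field(
            config.field_spec(), config.extent, seed=int(rng.integers(2**31))
        )
        point_gvi = field(geom.xs, geom.ys)
        comm_gvi = geom.membership @ point_gvi
        model = PriceModel(
            alpha=config.price_alpha, beta=config.price_beta,
            sigma=config.price_sigma, floor=config.price_floor,
            seed=int(rng.integers(2**31)),
        )
        prices = generate_prices(comm_gvi, geom.weights, model)
        res = permutation_test_global(
            prices, comm_gvi, geom.weights, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rows.append({"replicate": r, "I": res.I, "pseudo_p": res.pseudo_p})
    return pd.DataFrame(rows)
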