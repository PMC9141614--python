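"""Synthetic study region with known ground truth.

Generates every input the exposure-inequity pipeline needs — a street
network, sample points, per-point view label images, community polygons
and rental prices — in planar metric coordinates, so that each downstream
stage can be tested against planted values without any external data.

The greenery surface is a deterministic spatial trend (linear gradient
and/or a radial centre–periphery component emulating the concentric
structure of an old city core) plus kernel-smoothed white noise, clipped
to [0, 1].  Prices are generated with a planted association to the
spatial lag of neighbourhood greenness:

    price_i = alpha + beta * (W @ gvi)_i + eps_i,   eps_i ~ N(0, sigma^2)

so beta < 0 plants a negative greenness–price association, beta > 0 the
opposite and beta = 0 the null.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon, box

from .greenness import DEFAULT_GREEN_NAMES, LabelImage

#: palette used for synthetic label rasters; ids 3-5 are the green classes
SYNTHETIC_PALETTE: dict[int, str] = {
    0: "sky",
    1: "building",
    2: "road",
    3: "tree",
    4: "grass",
    5: "shrub",
}

Extent = tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)


@dataclass(frozen=True)
class StreetNetwork:
    """Street geometry: polylines in projected planar metres."""

    segments: list[LineString]
    extent: Extent

    def total_length(self) -> float:
        return float(sum(seg.length for seg in self.segments))


def generate_street_grid(
    extent_m: Extent,
    spacing_m: float,
    jitter: float = 0.0,
    seed: int = 0,
) -> StreetNetwork:
    """Regular grid of horizontal and vertical streets, optionally jittered.

    Lines are placed every ``spacing_m`` starting at the extent edges, with
    vertices at each grid crossing.  ``jitter`` displaces every vertex by a
    uniform offset in ``[-jitter*spacing_m, +jitter*spacing_m]`` per axis
    (clipped to the extent), which breaks the exact coincidence of crossings
    and makes the network look organically irregular.
    """
    if spacing_m <= 0:
        raise ValueError(f"spacing_m must be positive, got {spacing_m}")
    xmin, ymin, xmax, ymax = extent_m
    if spacing_m >= min(xmax - xmin, ymax - ymin):
        raise ValueError("spacing_m must be smaller than the extent sides")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    xs = np.arange(xmin, xmax + spacing_m / 2, spacing_m)
    ys = np.arange(ymin, ymax + spacing_m / 2, spacing_m)
    # vertex grid shared by horizontal and vertical lines so streets still
    # meet at common vertices after jittering
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    if jitter > 0:
        amp = jitter * spacing_m
        gx = gx + rng.uniform(-amp, amp, gx.shape)
        gy = gy + rng.uniform(-amp, amp, gy.shape)
        gx = np.clip(gx, xmin, xmax)
        gy = np.clip(gy, ymin, ymax)
    segments: list[LineString] = []
    for j in range(len(ys)):  # horizontal lines: vary x at fixed row j
        coords = [(gx[i, j], gy[i, j]) for i in range(len(xs))]
        segments.append(LineString(coords))
    for i in range(len(xs)):  # vertical lines
        coords = [(gx[i, j], gy[i, j]) for j in range(len(ys))]
        segments.append(LineString(coords))
    return StreetNetwork(segments=segments, extent=extent_m)


def sample_points(network: StreetNetwork, interval_m: float) -> list[tuple[float, float]]:
    """Place points along each polyline at arc-length multiples of the interval.

    Both endpoints of every polyline are always included.  Points that
    coincide exactly (after rounding to 1e-6 m, e.g. at street crossings of
    an unjittered grid) are emitted once.
    """
    if interval_m <= 0:
        raise ValueError(f"interval_m must be positive, got {interval_m}")
    seen: set[tuple[float, float]] = set()
    out: list[tuple[float, float]] = []
    for seg in network.segments:
        length = seg.length
        distances = list(np.arange(0.0, length, interval_m)) + [length]
        for d in distances:
            p: Point = seg.interpolate(d)
            key = (round(p.x, 6), round(p.y, 6))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


@dataclass
class GreenFieldSpec:
    """Parameters of the planted greenery surface.

    intercept, gradient
        Deterministic trend: ``intercept + gx*x + gy*y`` (per metre).
    radial_amplitude, radial_scale, center
        Optional centre–periphery component
        ``amp * exp(-d^2 / (2*scale^2))`` with d the distance to ``center``;
        emulates an old-city core that is greener than the periphery.
    noise_sd, length_scale
        Kernel-smoothed white-noise layer: white noise on a grid, smoothed
        with a Gaussian kernel of the given length scale (metres), rescaled
        to the requested pointwise standard deviation.
    """

    intercept: float = 0.25
    gradient: tuple[float, float] = (0.0, 0.0)
    radial_amplitude: float = 0.0
    radial_scale: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    length_scale: float = 500.0
    grid_resolution_m: float = 100.0


class GreenField:
    """Greenery fraction surface g(x, y) in [0, 1], deterministic per seed."""

    def __init__(self, spec: GreenFieldSpec, extent: Extent, seed: int = 0):
        params = [
            spec.intercept, *spec.gradient, spec.radial_amplitude,
            spec.radial_scale, *spec.center, spec.noise_sd, spec.length_scale,
        ]
        if not np.all(np.isfinite(params)):
            raise ValueError("green field parameters must be finite")
        self.spec = spec
        self.extent = extent
        self.seed = seed
        self._noise = None
        if spec.noise_sd > 0:
            xmin, ymin, xmax, ymax = extent
            res = spec.grid_resolution_m
            # pad so smoothing has support beyond the extent edges
            pad = 3 * spec.length_scale
            xs = np.arange(xmin - pad, xmax + pad + res, res)
            ys = np.arange(ymin - pad, ymax + pad + res, res)
            rng = np.random.default_rng(seed)
            raw = rng.standard_normal((len(xs), len(ys)))
            smooth = gaussian_filter(raw, sigma=spec.length_scale / res, mode="nearest")
            sd = smooth.std()
            if sd > 0:
                smooth = smooth * (spec.noise_sd / sd)
            self._noise = RegularGridInterpolator(
                (xs, ys), smooth, bounds_error=False, fill_value=0.0
            )

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        s = self.spec
        g = s.intercept + s.gradient[0] * x + s.gradient[1] * y
        if s.radial_amplitude != 0.0:
            d2 = (x - s.center[0]) ** 2 + (y - s.center[1]) ** 2
            g = g + s.radial_amplitude * np.exp(-d2 / (2.0 * s.radial_scale**2))
        if self._noise is not None:
            pts = np.stack([x, y], axis=-1)
            g = g + self._noise(pts)
        return np.clip(g, 0.0, 1.0)


def plant_green_field(
    spec: GreenFieldSpec, extent: Extent, seed: int = 0
) -> GreenField:
    """Construct the planted greenery surface for an extent."""
    return GreenField(spec, extent, seed)


def render_views(
    target_fraction: float,
    image_shape: tuple[int, int] = (40, 40),
    n_views: int = 4,
    seed: int = 0,
) -> list[LabelImage]:
    """Render label images whose pooled green fraction hits the target exactly.

    Across the ``n_views`` rasters the pooled number of green-class pixels is
    ``round(target_fraction * n_views * H * W)``; green pixels are scattered
    pseudo-randomly and assigned one of the green classes (tree/grass/shrub),
    the rest one of the non-green classes.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in [0, 1], got {target_fraction}")
    h, w = image_shape
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be >= 1")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_views * h * w
    n_green = int(round(target_fraction * total))
    flat_classes = rng.integers(0, 3, size=total)  # sky/building/road
    green_positions = rng.choice(total, size=n_green, replace=False)
    flat_classes[green_positions] = rng.integers(3, 6, size=n_green)  # tree/grass/shrub
    rasters = flat_classes.reshape(n_views, h, w)
    return [
        LabelImage(classes=rasters[i], palette=SYNTHETIC_PALETTE,
                   green_names=DEFAULT_GREEN_NAMES)
        for i in range(n_views)
    ]


def generate_communities(extent_m: Extent, n: int, seed: int = 0) -> list[Polygon]:
    """Tessellate the extent into ``n`` interior-disjoint community polygons.

    Voronoi cells of ``n`` random seed points, clipped to the extent.  The
    tessellation is bounded by mirroring the seed points across the four
    extent edges before triangulating, so every cell of an original point is
    finite; clipping to the extent box then gives an exact partition.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    xmin, ymin, xmax, ymax = extent_m
    rng = np.random.default_rng(seed)
    pts = np.column_stack([
        rng.uniform(xmin, xmax, n),
        rng.uniform(ymin, ymax, n),
    ])
    if n == 1:
        return [box(xmin, ymin, xmax, ymax)]
    mirrored = np.vstack([
        pts,
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ])
    vor = Voronoi(mirrored)
    clip = box(xmin, ymin, xmax, ymax)
    polys: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError(f"unbounded Voronoi cell for seed point {i}")
        cell = Polygon(vor.vertices[region]).intersection(clip)
        if cell.is_empty or cell.area <= 0:
            raise RuntimeError(
                f"degenerate community polygon for seed point {i}; "
                f"n={n} may be too large for this extent"
            )
        polys.append(cell)
    return polys


@dataclass(frozen=True)
class PriceModel:
    """Rental-price generator with a planted greenness association.

    alpha is the baseline price (currency/m^2), beta the slope on the
    spatial lag of community GVI (currency/m^2 per unit GVI), sigma the
    noise standard deviation, floor the positive minimum applied after
    noise (location entropy divides by price).
    """

    alpha: float = 30.0
    beta: float = -40.0
    sigma: float = 3.0
    floor: float = 1.0
    seed: int = 0


def generate_prices(
    gvi_values: np.ndarray,
    weights,  # SpatialWeights (row-standardized)
    model: PriceModel,
    communities: list[Polygon] | None = None,
) -> np.ndarray:
    """price_i = alpha + beta * (W @ gvi)_i + N(0, sigma^2), floored."""
    gvi = np.asarray(gvi_values, dtype=float)
    if not np.all(np.isfinite(gvi)):
        raise ValueError("gvi_values must be finite")
    if communities is not None and len(communities) != gvi.shape[0]:
        raise ValueError(
            f"dimension mismatch: {len(communities)} communities, "
            f"{gvi.shape[0]} gvi values"
        )
    if weights.n != gvi.shape[0]:
        raise ValueError(
            f"dimension mismatch: weights n={weights.n}, gvi n={gvi.shape[0]}"
        )
    if not weights.row_standardized:
        raise ValueError("price model expects row-standardized weights")
    if model.floor <= 0:
        raise ValueError("price floor must be positive")
    rng = np.random.default_rng(model.seed)
    lag = weights.sparse @ gvi
    noise = rng.normal(0.0, model.sigma, size=gvi.shape[0]) if model.sigma > 0 else 0.0
    prices = model.alpha + model.beta * lag + noise
    return np.maximum(prices, model.floor)
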