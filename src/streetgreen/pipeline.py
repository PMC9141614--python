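"""End-to-end reproducible run: simulate -> GVI -> exposure -> LQ -> Moran.

A single master seed drives every stochastic stage; per-stage seeds are
derived deterministically from the master seed and the stage name, so two
runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as exposure_mod
from . import inequity, spatial_stats, synthetic_city
from .exposure import Community, exposure_table
from .greenness import SamplePoint, apply_qc
from .io import write_communities_geojson, write_points_csv
from .spatial_stats import (
    conditional_permutation_local,
    permutation_test_global,
    queen_weights,
    knn_weights,
    row_standardize,
)
from .synthetic_city import (
    GreenFieldSpec,
    PriceModel,
    generate_communities,
    generate_street_grid,
    plant_green_field,
    render_views,
    sample_points,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to JSON.

    Defaults describe the reference synthetic city: a 12 x 12 km downtown
    with a 200 m street grid sampled every 200 m (~7.4k sample points),
    499 communities, a centre-high greenery surface and rental prices
    planted with a negative association to neighbourhood greenness.
    """

    # geometry / sampling
    extent: tuple[float, float, float, float] = (0.0, 0.0, 12000.0, 12000.0)
    street_spacing_m: float = 200.0
    street_jitter: float = 0.15
    sample_interval_m: float = 200.0
    n_communities: int = 499
    # imagery
    image_shape: tuple[int, int] = (40, 40)
    n_views: int = 4
    min_views: int = 4
    exclusion_list: tuple[str, ...] = ()
    # greenery surface: old-city core greener than the periphery
    field_intercept: float = 0.10
    field_gradient: tuple[float, float] = (0.0, 0.0)
    field_radial_amplitude: float = 0.25
    field_radial_scale_m: float = 4000.0
    field_noise_sd: float = 0.05
    field_length_scale_m: float = 800.0
    # rental prices (currency / m^2)
    price_alpha: float = 30.0
    price_beta: float = -40.0
    price_sigma: float = 3.0
    price_floor: float = 1.0
    price_buffer_minutes: float = 15.0
    # analysis
    buffer_minutes: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0)
    walking_speed: float = 72.0
    weights: str = "queen"  # or "knn"
    knn_k: int = 6
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0

    def field_spec(self) -> GreenFieldSpec:
        xmin, ymin, xmax, ymax = self.extent
        return GreenFieldSpec(
            intercept=self.field_intercept,
            gradient=self.field_gradient,
            radial_amplitude=self.field_radial_amplitude,
            radial_scale=self.field_radial_scale_m,
            center=((xmin + xmax) / 2.0, (ymin + ymax) / 2.0),
            noise_sd=self.field_noise_sd,
            length_scale=self.field_length_scale_m,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class RunResult:
    """In-memory bundle of every pipeline stage output."""

    config: RunConfig
    points: list[SamplePoint]
    communities: list[Community]
    weights: spatial_stats.SpatialWeights
    exposure: pd.DataFrame
    lq: pd.DataFrame
    lq_summaries: dict[float, pd.DataFrame]
    moran_global: pd.DataFrame
    lisa: dict[float, pd.DataFrame]
    manifest: dict


def simulate_points(config: RunConfig) -> tuple[list[SamplePoint], np.ndarray]:
    """Street grid -> sample points -> planted per-point green fractions
    -> rendered views.  Returns the points and their planted fractions."""
    network = generate_street_grid(
        config.extent, config.street_spacing_m, config.street_jitter,
        seed=stage_seed(config.seed, "streets"),
    )
    locations = sample_points(network, config.sample_interval_m)
    gfield = plant_green_field(
        config.field_spec(), config.extent, seed=stage_seed(config.seed, "field")
    )
    xs = np.array([p[0] for p in locations])
    ys = np.array([p[1] for p in locations])
    fractions = gfield(xs, ys)
    view_seed = stage_seed(config.seed, "views")
    points = []
    for i, (x, y) in enumerate(locations):
        views = render_views(
            float(fractions[i]), config.image_shape, config.n_views,
            seed=(view_seed + i) % (2**31),
        )
        points.append(
            SamplePoint(
                id=f"pt{i:05d}", x=x, y=y,
                views={d * 90: v for d, v in enumerate(views)},
            )
        )
    return points, fractions


def build_weights(config: RunConfig, communities: list[Community]) -> spatial_stats.SpatialWeights:
    polys = [c.boundary for c in communities]
    if config.weights == "queen":
        w = queen_weights(polys)
    elif config.weights == "knn":
        cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
        w = knn_weights(cents, config.knn_k)
    else:
        raise ValueError(f"unknown weights spec: {config.weights}")
    return row_standardize(w)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full analysis; optionally write every artefact to disk."""
    # --- simulate + GVI
    points, fractions = simulate_points(config)
    points = apply_qc(points, config.exclusion_list, config.min_views)
    kept = [p for p in points if p.qc_status == "kept"]
    logger.info("simulated %d points (%d kept)", len(points), len(kept))

    # --- communities, weights
    communities_polys = generate_communities(
        config.extent, config.n_communities, seed=stage_seed(config.seed, "communities")
    )
    communities = [
        Community(id=f"c{i:04d}", boundary=poly, price=np.nan)
        for i, poly in enumerate(communities_polys)
    ]
    weights = build_weights(config, communities)

    # --- exposure
    exp = exposure_table(
        communities, points, config.buffer_minutes, config.walking_speed
    )

    # --- prices planted on the reference-buffer greenness lag
    ref_gvi = np.array([c.gvi_by_buffer[config.price_buffer_minutes] for c in communities])
    if np.isnan(ref_gvi).any():
        bad = int(np.flatnonzero(np.isnan(ref_gvi))[0])
        raise RuntimeError(
            f"stage prices: community {communities[bad].id} has no greenness "
            f"value at the {config.price_buffer_minutes:g}-min reference buffer"
        )
    model = PriceModel(
        alpha=config.price_alpha, beta=config.price_beta,
        sigma=config.price_sigma, floor=config.price_floor,
        seed=stage_seed(config.seed, "prices"),
    )
    prices = synthetic_city.generate_prices(ref_gvi, weights, model, communities_polys)
    for c, price in zip(communities, prices):
        c.price = float(price)

    # --- location entropy per buffer
    lq_rows = []
    lq_summaries: dict[float, pd.DataFrame] = {}
    for minutes in config.buffer_minutes:
        sub = exp[exp["minutes"] == minutes].set_index("community_id")
        scored = sub["gvi"].notna()
        n_missing = int((~scored).sum())
        if n_missing:
            logger.warning("LQ %g min: %d community(ies) without GVI dropped", minutes, n_missing)
        ids = sub.index[scored]
        gvi = sub.loc[scored, "gvi"].to_numpy()
        price = np.array([c.price for c in communities if c.id in set(ids)])
        lq = inequity.location_entropy(gvi, price)
        lq_summaries[minutes] = inequity.lq_summary(lq)
        for cid, v in zip(ids, lq):
            lq_rows.append(
                {"community_id": cid, "minutes": minutes, "lq": v, "bin": inequity.bin_lq(v)}
            )
    lq_df = pd.DataFrame(lq_rows)

    # --- bivariate Moran per buffer
    moran_rows = []
    lisa: dict[float, pd.DataFrame] = {}
    moran_seed = stage_seed(config.seed, "moran")
    for minutes in config.buffer_minutes:
        sub = exp[exp["minutes"] == minutes].set_index("community_id")
        scored_mask = sub["gvi"].notna().to_numpy()
        if not scored_mask.all():
            raise RuntimeError(
                f"stage moran: missing greenness at {minutes:g} min for community "
                f"{sub.index[~scored_mask][0]}; listwise subsetting of the weights "
                "matrix is not supported in the pipeline"
            )
        gvi = sub["gvi"].to_numpy()
        price = np.array([c.price for c in communities])
        res = permutation_test_global(
            price, gvi, weights, n_perm=config.n_perm,
            seed=(moran_seed + int(minutes)) % (2**31),
        )
        moran_rows.append(
            {
                "minutes": minutes,
                "radius_m": exposure_mod.buffer_radius(minutes, config.walking_speed),
                "I": res.I, "pseudo_p": res.pseudo_p,
                "n_perm": res.n_perm, "seed": res.seed, "n": res.n,
            }
        )
        tbl = conditional_permutation_local(
            price, gvi, weights, n_perm=config.n_perm,
            seed=(moran_seed + int(minutes) + 1_000_000) % (2**31),
            alpha=config.alpha,
        )
        tbl.insert(0, "community_id", [c.id for c in communities])
        lisa[minutes] = tbl
    moran_df = pd.DataFrame(moran_rows)

    manifest = {
        "seed": config.seed,
        "n_points_generated": len(points),
        "n_points_kept": len(kept),
        "n_points_excluded": len(points) - len(kept),
        "n_communities": len(communities),
        "n_islands": int(len(weights.islands)),
        "exposure_rows": int(len(exp)),
        "lq_rows": int(len(lq_df)),
        "buffers_minutes": list(config.buffer_minutes),
    }
    result = RunResult(
        config=config, points=points, communities=communities, weights=weights,
        exposure=exp, lq=lq_df, lq_summaries=lq_summaries,
        moran_global=moran_df, lisa=lisa, manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: RunResult, out_dir: Path) -> None:
    """Write every stage artefact plus the verbatim config and manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(result.config.to_json())
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    write_points_csv(out_dir / "points.csv", result.points)
    write_communities_geojson(out_dir / "communities.geojson", result.communities)
    result.exposure.to_csv(out_dir / "exposure.csv", index=False)
    result.lq.to_csv(out_dir / "lq.csv", index=False)
    summary_rows = []
    for minutes, summ in result.lq_summaries.items():
        for bin_label, row in summ.iterrows():
            summary_rows.append(
                {
                    "minutes": minutes, "bin": bin_label,
                    "count": int(row["count"]), "percentage": row["percentage"],
                }
            )
    pd.DataFrame(summary_rows).to_csv(out_dir / "lq_summary.csv", index=False)
    result.moran_global.to_csv(out_dir / "moran_global.csv", index=False)
    for minutes, tbl in result.lisa.items():
        tbl.to_csv(out_dir / f"lisa_{minutes:g}min.csv", index=False)
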