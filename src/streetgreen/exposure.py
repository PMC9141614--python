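"""Community green-space exposure within walking-time buffers.

Each community polygon is buffered outward by ``minutes * walking_speed``
metres (default speed 72 m/min, the 15-minute-city convention, so the
standard 5/10/15/30-minute buffers are 360/720/1080/2160 m).  A
community's exposure at a buffer distance is the unweighted mean GVI of
all kept sample points inside or on that buffer; communities whose buffer
contains no point get a missing value (never zero) and are excluded
listwise downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .greenness import SamplePoint

logger = logging.getLogger(__name__)

DEFAULT_WALKING_SPEED = 72.0  # metres per minute
DEFAULT_BUFFER_MINUTES = (5, 10, 15, 30)


def buffer_radius(minutes: float, walking_speed: float = DEFAULT_WALKING_SPEED) -> float:
    """Walking-buffer radius in metres: minutes x speed, exactly."""
    if minutes <= 0:
        raise ValueError(f"minutes must be positive, got {minutes}")
    if walking_speed <= 0:
        raise ValueError(f"walking_speed must be positive, got {walking_speed}")
    return minutes * walking_speed


@dataclass(frozen=True)
class BufferSpec:
    """A walking-time buffer: minutes, speed and the derived radius."""

    minutes: float
    walking_speed: float = DEFAULT_WALKING_SPEED

    @property
    def radius_m(self) -> float:
        return buffer_radius(self.minutes, self.walking_speed)


@dataclass
class Community:
    """A residential community: polygon, rental price and per-buffer GVI."""

    id: str
    boundary: Polygon
    price: float
    gvi_by_buffer: dict[float, float] = field(default_factory=dict)
    n_points_by_buffer: dict[float, int] = field(default_factory=dict)


def buffered_boundary(boundary: BaseGeometry, radius_m: float) -> BaseGeometry:
    """Euclidean outward buffer of the community polygon (interior included)."""
    if radius_m < 0:
        raise ValueError(f"radius must be >= 0, got {radius_m}")
    if not boundary.is_valid:
        raise ValueError("invalid community geometry")
    if radius_m == 0:
        return boundary
    return boundary.buffer(radius_m)


def community_gvi(
    buffer_polygon: BaseGeometry, points: list[SamplePoint]
) -> tuple[float | None, int]:
    """Unweighted mean GVI of kept points inside or on the buffer boundary.

    Returns ``(mean_gvi, n_points)``; ``(None, 0)`` when the buffer holds
    no point (missing, not zero).
    """
    kept = [p for p in points if p.qc_status == "kept" and p.gvi is not None]
    if not kept:
        return None, 0
    xs = np.array([p.x for p in kept])
    ys = np.array([p.y for p in kept])
    geoms = shapely.points(xs, ys)
    inside = shapely.covers(buffer_polygon, geoms)  # boundary-inclusive
    n = int(inside.sum())
    if n == 0:
        return None, 0
    gvi = np.array([p.gvi for p in kept])
    return float(gvi[inside].mean()), n


def exposure_table(
    communities: list[Community],
    points: list[SamplePoint],
    buffer_minutes: tuple[float, ...] = DEFAULT_BUFFER_MINUTES,
    walking_speed: float = DEFAULT_WALKING_SPEED,
) -> pd.DataFrame:
    """Fill every community x buffer cell; long-format table.

    Columns: community_id, minutes, radius_m, n_points, gvi.  Missing cells
    (no point in buffer) carry NaN gvi and are logged.  The same
    ``gvi_by_buffer`` / ``n_points_by_buffer`` values are written back onto
    the Community records.
    """
    if not communities:
        raise ValueError("exposure_table requires at least one community")
    kept = [p for p in points if p.qc_status == "kept" and p.gvi is not None]
    xs = np.array([p.x for p in kept])
    ys = np.array([p.y for p in kept])
    gvis = np.array([p.gvi for p in kept])
    geoms = shapely.points(xs, ys) if kept else np.array([], dtype=object)
    tree = shapely.STRtree(geoms) if kept else None

    rows = []
    n_missing = 0
    for comm in communities:
        for minutes in buffer_minutes:
            radius = buffer_radius(minutes, walking_speed)
            buf = buffered_boundary(comm.boundary, radius)
            if tree is not None:
                cand = tree.query(buf)
                inside = cand[shapely.covers(buf, geoms[cand])]
            else:
                inside = np.array([], dtype=int)
            n = len(inside)
            value = float(gvis[inside].mean()) if n > 0 else np.nan
            if n == 0:
                n_missing += 1
            comm.gvi_by_buffer[minutes] = value
            comm.n_points_by_buffer[minutes] = n
            rows.append(
                {
                    "community_id": comm.id,
                    "minutes": minutes,
                    "radius_m": radius,
                    "n_points": n,
                    "gvi": value,
                }
            )
    if n_missing:
        logger.warning("exposure_table: %d community x buffer cell(s) without points", n_missing)
    return pd.DataFrame(rows)
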