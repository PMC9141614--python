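"""Read/write adapters: GeoJSON feature collections, CSV tables and
PNG label rasters with JSON palette sidecars.

All geometry is in projected planar metres; the CRS note is recorded in
the FeatureCollection metadata so readers do not mistake the coordinates
for longitude/latitude.  Round trips are lossless for every record type.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .exposure import Community
from .greenness import DEFAULT_GREEN_NAMES, LabelImage, SamplePoint

logger = logging.getLogger(__name__)

CRS_NOTE = "projected planar metres (local engineering CRS)"


class SchemaError(ValueError):
    """Raised when a file does not match the expected schema."""


# ---------------------------------------------------------------- GeoJSON

def write_communities_geojson(path: str | Path, communities: list[Community]) -> None:
    features = []
    for c in communities:
        props: dict = {"id": c.id, "price": c.price}
        for minutes, gvi in sorted(c.gvi_by_buffer.items()):
            props[f"gvi_{minutes:g}min"] = None if np.isnan(gvi) else gvi
        features.append(
            {"type": "Feature", "geometry": mapping(c.boundary), "properties": props}
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": CRS_NOTE,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_communities_geojson(path: str | Path) -> list[Community]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    communities = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom: BaseGeometry = shape(feat["geometry"])
            props = feat["properties"]
            comm = Community(
                id=str(props["id"]), boundary=geom, price=float(props["price"])
            )
        except (KeyError, TypeError, ValueError, AttributeError) as exc:
            raise SchemaError(f"{path}: malformed feature at index {i}: {exc}") from exc
        for key, val in props.items():
            if key.startswith("gvi_") and key.endswith("min"):
                minutes = float(key[4:-3])
                comm.gvi_by_buffer[minutes] = np.nan if val is None else float(val)
        communities.append(comm)
    return communities


# ------------------------------------------------------------------- CSV

POINTS_CSV_COLUMNS = ["id", "x", "y", "green_count", "total_count", "gvi", "qc_status"]


def write_points_csv(path: str | Path, points: list[SamplePoint]) -> None:
    """Per-point table; missing GVI is an empty field, never a sentinel."""
    from .greenness import green_fraction

    rows = []
    for p in points:
        green = total = 0
        for img in p.views.values():
            g, t = green_fraction(img)
            green += g
            total += t
        rows.append(
            {
                "id": p.id,
                "x": p.x,
                "y": p.y,
                "green_count": green,
                "total_count": total,
                "gvi": p.gvi,
                "qc_status": p.qc_status,
            }
        )
    pd.DataFrame(rows, columns=POINTS_CSV_COLUMNS).to_csv(path, index=False)


def read_points_csv(path: str | Path) -> list[SamplePoint]:
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    extra = set(df.columns) - set(POINTS_CSV_COLUMNS)
    if extra:
        logger.warning("%s: extra column(s) %s preserved but unused", path, sorted(extra))
    points = []
    for _, row in df.iterrows():
        gvi = row.get("gvi", np.nan)
        points.append(
            SamplePoint(
                id=str(row["id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                gvi=None if pd.isna(gvi) else float(gvi),
                qc_status=str(row.get("qc_status", "kept")),
            )
        )
    return points


# ----------------------------------------------------------- PNG rasters

def write_label_image(path: str | Path, img: LabelImage) -> None:
    """Single-channel PNG of class indices + JSON palette sidecar."""
    path = Path(path)
    arr = img.classes.astype(np.uint8)
    if img.classes.max(initial=0) > 255:
        raise ValueError("class ids above 255 cannot be stored as 8-bit PNG")
    Image.fromarray(arr, mode="L").save(path)
    sidecar = {
        "palette": {str(k): v for k, v in img.palette.items()},
        "green_names": sorted(img.green_names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_label_image(path: str | Path, palette_path: str | Path | None = None) -> LabelImage:
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=np.int64)
    sidecar_path = Path(palette_path) if palette_path else path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text())
    palette = {int(k): v for k, v in sidecar["palette"].items()}
    green = frozenset(sidecar.get("green_names", DEFAULT_GREEN_NAMES))
    return LabelImage(classes=arr, palette=palette, green_names=green)
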