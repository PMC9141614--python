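"""Green View Index (GVI) computation from street-level label images.

The GVI of a street sample point is the fraction of vegetation pixels
pooled over its (up to four) cardinal-direction views:

    GVI = sum_n green_pixels_n / sum_n total_pixels_n

i.e. a ratio of sums over views, not a mean of per-view ratios.  The two
coincide when all views have equal pixel counts; the ratio of sums is the
canonical definition here and the one implemented.

Label images are integer class rasters with a palette mapping class id to
a semantic name.  Classes whose names are in the configured green set
(by default grass, tree and shrub, case-insensitively) count as vegetation.
A rule-based HSV colour classifier is provided to turn plain RGB imagery
into binary green/non-green rasters for self-contained runs; any external
semantic segmenter's class rasters can be ingested instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from matplotlib.colors import rgb_to_hsv

#: class names counted as vegetation unless overridden (case-insensitive)
DEFAULT_GREEN_NAMES = frozenset({"grass", "tree", "shrub"})


class ImageFormatError(ValueError):
    """Raised when an input image does not match the expected layout."""


@dataclass(frozen=True)
class LabelImage:
    """A pixel-class raster for one view direction.

    Parameters
    ----------
    classes
        2-D integer array of class ids, shape ``(height, width)``.
    palette
        Mapping from class id to semantic class name.  Every id occurring
        in ``classes`` must be present.
    green_names
        Class names (case-insensitive) counted as vegetation.
    """

    classes: np.ndarray
    palette: Mapping[int, str]
    green_names: frozenset[str] = DEFAULT_GREEN_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if arr.ndim != 2 or arr.size == 0:
            raise ImageFormatError(
                f"class raster must be 2-D and non-empty, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            raise ImageFormatError("class raster must be an integer array")
        present = set(np.unique(arr).tolist())
        missing = present - set(self.palette)
        if missing:
            raise ImageFormatError(f"class ids {sorted(missing)} missing from palette")
        object.__setattr__(self, "classes", arr)
        object.__setattr__(
            self, "green_names", frozenset(n.lower() for n in self.green_names)
        )

    @property
    def height(self) -> int:
        return self.classes.shape[0]

    @property
    def width(self) -> int:
        return self.classes.shape[1]

    @property
    def green_class_ids(self) -> frozenset[int]:
        return frozenset(
            cid for cid, name in self.palette.items() if name.lower() in self.green_names
        )


@dataclass
class SamplePoint:
    """A street location with up to four views and a pooled GVI.

    ``views`` is keyed by compass heading in degrees (0, 90, 180, 270).
    ``gvi`` is populated only for points whose ``qc_status`` is "kept".
    """

    id: str
    x: float
    y: float
    views: dict[int, LabelImage] = field(default_factory=dict)
    gvi: float | None = None
    qc_status: str = "kept"


@dataclass(frozen=True)
class HsvThresholds:
    """Green band in HSV space for the rule-based classifier.

    Hue is on the [0, 1) circle (pure green = 1/3).  Defaults select
    saturated, non-dark pixels whose hue lies between yellow-green and
    cyan-green, which captures foliage in synthetic and natural imagery
    while rejecting gray pavement and sky.
    """

    hue_min: float = 0.17
    hue_max: float = 0.45
    sat_min: float = 0.20
    val_min: float = 0.10


def classify_green(
    rgb_image: np.ndarray, thresholds: HsvThresholds | None = None
) -> LabelImage:
    """Classify an RGB image into a binary green / non-green label raster.

    Parameters
    ----------
    rgb_image
        ``(H, W, 3)`` array, either uint8 in [0, 255] or float in [0, 1].
    thresholds
        HSV green-band specification; defaults to :class:`HsvThresholds`.

    Returns
    -------
    LabelImage with palette ``{0: "non_green", 1: "green"}`` where class 1
    is counted as vegetation.
    """
    thresholds = thresholds or HsvThresholds()
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"expected a 3-channel RGB image, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    hsv = rgb_to_hsv(np.clip(arr, 0.0, 1.0))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    green = (
        (h >= thresholds.hue_min)
        & (h <= thresholds.hue_max)
        & (s >= thresholds.sat_min)
        & (v >= thresholds.val_min)
    )
    return LabelImage(
        classes=green.astype(np.int64),
        palette={0: "non_green", 1: "green"},
        green_names=frozenset({"green"}),
    )


def green_fraction(img: LabelImage) -> tuple[int, int]:
    """Return ``(green_count, total_count)`` for one label image."""
    ids = img.green_class_ids
    if not ids:
        return 0, img.classes.size
    green = int(np.isin(img.classes, sorted(ids)).sum())
    return green, img.classes.size


def point_gvi(views: Sequence[LabelImage]) -> float:
    """Pooled GVI over a point's views: ratio of summed counts.

    Raises
    ------
    ValueError
        If no views are given or the pooled pixel count is zero.
    """
    if not views:
        raise ValueError("point_gvi requires at least one view")
    green = 0
    total = 0
    for img in views:
        g, t = green_fraction(img)
        green += g
        total += t
    if total == 0:
        raise ValueError("zero total pixels across views")
    return green / total


def apply_qc(
    points: Iterable[SamplePoint],
    exclusion_list: Iterable[str] = (),
    min_views: int = 4,
) -> list[SamplePoint]:
    """Set qc_status on each point and compute GVI for the kept ones.

    A point is excluded iff its id is on ``exclusion_list`` or it has fewer
    than ``min_views`` views (the mechanised form of the manual screening of
    off-season imagery).  Excluded points carry no GVI.
    """
    excluded_ids = set(exclusion_list)
    out: list[SamplePoint] = []
    for p in points:
        if p.id in excluded_ids or len(p.views) < min_views:
            p.qc_status = "excluded"
            p.gvi = None
        else:
            p.qc_status = "kept"
            p.gvi = point_gvi(list(p.views.values()))
        out.append(p)
    return out
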