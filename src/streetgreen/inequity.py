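"""Location-entropy (location quotient) inequity statistic.

The location quotient of community i compares its green-space service per
unit of rent against the study-area-wide rate:

    LQ_i = (GVI_i / price_i) / (sum_j GVI_j / sum_j price_j)

LQ > 1 means the community enjoys more greenery per unit of rental price
than the area average; LQ < 1 means less.  An exact algebraic consequence
is that the price-weighted mean of LQ is one:

    sum_i LQ_i * price_i / sum_i price_i = 1

which is asserted on every computation as a numerical self-check.

Scores are summarised into the seven conventional levels <0.2, 0.2-0.5,
0.5-1.0, 1.0-1.5, 1.5-2.0, 2.0-5.0 and >5.0 (half-open, lower edge
inclusive), with counts and half-up-rounded percentages, plus the
aggregate shares of very-low (LQ < 0.5) and high (LQ > 2) communities.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

LQ_BIN_EDGES = (0.0, 0.2, 0.5, 1.0, 1.5, 2.0, 5.0, np.inf)
LQ_BIN_LABELS = ("<0.2", "0.2–0.5", "0.5–1.0", "1.0–1.5", "1.5–2.0", "2.0–5.0", ">5.0")


def location_entropy(gvi: np.ndarray, price: np.ndarray) -> np.ndarray:
    """LQ_i = (gvi_i / price_i) / (sum gvi / sum price).

    Raises on non-positive prices (naming the offending community index),
    zero total greenery, or mismatched lengths.
    """
    gvi = np.asarray(gvi, dtype=float)
    price = np.asarray(price, dtype=float)
    if gvi.shape != price.shape or gvi.ndim != 1:
        raise ValueError("gvi and price must be 1-D vectors of equal length")
    if gvi.shape[0] < 2:
        raise ValueError("location entropy requires at least 2 communities")
    bad = np.flatnonzero(~(price > 0))
    if bad.size:
        raise ValueError(f"non-positive price for community index {bad[0]}")
    if not np.all(np.isfinite(gvi)) or not np.all(gvi >= 0):
        raise ValueError("gvi values must be finite and non-negative")
    total_gvi = gvi.sum()
    if total_gvi == 0:
        raise ValueError("total GVI is zero; location entropy undefined")
    base_rate = total_gvi / price.sum()
    lq = (gvi / price) / base_rate
    # conservation identity: price-weighted mean of LQ is exactly 1
    check = float(lq @ price / price.sum())
    assert abs(check - 1.0) < 1e-12, f"LQ conservation violated: {check}"
    return lq


def bin_lq(lq: float) -> str:
    """Bin label for one LQ value; bins are half-open, lower-inclusive."""
    if lq < 0 or not np.isfinite(lq):
        raise ValueError(f"LQ must be finite and >= 0, got {lq}")
    idx = int(np.searchsorted(LQ_BIN_EDGES[1:-1], lq, side="right"))
    return LQ_BIN_LABELS[idx]


def _pct_half_up(count: int, total: int) -> float:
    """Percentage 100*count/total rounded half-up to 2 decimal places."""
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def lq_summary(lq: np.ndarray) -> pd.DataFrame:
    """Per-bin counts and percentages over a vector of LQ scores.

    Returns a DataFrame indexed by bin label with columns ``count`` and
    ``percentage`` (half-up, 2 dp), carrying the total and the aggregate
    very-low (LQ < 0.5) and high (LQ > 2) shares in ``attrs``.
    """
    lq = np.asarray(lq, dtype=float)
    if lq.size == 0:
        raise ValueError("lq_summary requires a non-empty vector")
    total = int(lq.size)
    labels = [bin_lq(v) for v in lq]
    counts = {label: labels.count(label) for label in LQ_BIN_LABELS}
    df = pd.DataFrame(
        {
            "count": [counts[label] for label in LQ_BIN_LABELS],
            "percentage": [_pct_half_up(counts[label], total) for label in LQ_BIN_LABELS],
        },
        index=pd.Index(LQ_BIN_LABELS, name="bin"),
    )
    n_very_low = int((lq < 0.5).sum())
    n_high = int((lq > 2.0).sum())
    df.attrs["total"] = total
    df.attrs["n_very_low"] = n_very_low
    df.attrs["pct_very_low"] = _pct_half_up(n_very_low, total)
    df.attrs["n_high"] = n_high
    df.attrs["pct_high"] = _pct_half_up(n_high, total)
    return df
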