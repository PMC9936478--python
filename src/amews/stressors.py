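"""Climate and market stressors as multiplicative effectiveness factors.

Stressor intensity is conceptualized as a monthly deviation from a
long-term ward-level average: an NDVI z-score for the climate channel and
a relative price deviation from a 10-year staple (maize) baseline for the
market channel.  Deviations map to per-dimension effectiveness factors in
(0, 1] — below-average greenness depresses own food production, above-
baseline prices depress buying/bartering — with a floor guarding against
total annihilation of a dimension by data artifacts.  The local-network
dimension carries no exogenous stressor by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import DIMENSIONS

logger = logging.getLogger(__name__)

#: Which stressor drives which strategy dimension.
DEFAULT_MAPPING: Mapping[str, str] = {"climate": "own_production", "market": "buy_barter"}

STRESSOR_COLUMNS = (
    "ward_id",
    "month",
    "ndvi",
    "ndvi_lt_mean",
    "ndvi_lt_sd",
    "price",
    "price_baseline",
)


@dataclass(frozen=True)
class StressorState:
    """Per-ward, per-month effectiveness factors aligned with strategy dimensions."""

    x: tuple[float, float, float]

    def __post_init__(self):
        if len(self.x) != 3 or any(not 0.0 < v <= 1.0 for v in self.x):
            raise ValueError(f"effectiveness factors must lie in (0, 1], got {self.x}")


def climate_factor(ndvi, mean, sd, beta_c: float = 0.25, floor: float = 0.1):
    """Effectiveness factor from an NDVI deviation.

    z = (ndvi − mean)/sd; factor = clip(1 + beta_c·min(z, 0), floor, 1).
    Above-average greenness never pushes the factor beyond 1.  Accepts
    scalars or arrays.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if not np.all(np.isfinite(ndvi)) or not np.all(np.isfinite(mean)) or not np.all(np.isfinite(sd)):
        raise ValueError("NDVI inputs must be finite")
    if np.any(sd <= 0):
        raise ValueError("long-term NDVI sd must be positive")
    if beta_c < 0:
        raise ValueError("beta_c must be non-negative")
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must be in (0, 1)")
    z = (ndvi - mean) / sd
    out = np.clip(1.0 + beta_c * np.minimum(z, 0.0), floor, 1.0)
    return float(out) if out.ndim == 0 else out


def market_factor(price, baseline, beta_m: float = 0.5, floor: float = 0.1):
    """Effectiveness factor from a staple-price deviation.

    r = (price − baseline)/baseline; factor = clip(1 − beta_m·max(r, 0),
    floor, 1).  Prices below baseline never raise the factor beyond 1.
    """
    price = np.asarray(price, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(price < 0):
        raise ValueError("price must be non-negative")
    if np.any(baseline <= 0):
        raise ValueError("price baseline must be positive")
    if beta_m < 0:
        raise ValueError("beta_m must be non-negative")
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must be in (0, 1)")
    r = (price - baseline) / baseline
    out = np.clip(1.0 - beta_m * np.maximum(r, 0.0), floor, 1.0)
    return float(out) if out.ndim == 0 else out


def apply_shock(x, dimension, factor: float) -> tuple[float, float, float]:
    """Multiply one dimension's effectiveness by ``factor``, leaving the others untouched.

    ``dimension`` is a name from :data:`amews.core.DIMENSIONS` (or an
    index).  A factor of 0.2 reduces the dimension's effectiveness by 80%.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"shock factor must be in (0, 1], got {factor}")
    if isinstance(dimension, str):
        try:
            d = DIMENSIONS.index(dimension)
        except ValueError:
            raise ValueError(
                f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}"
            ) from None
    else:
        d = int(dimension)
        if not 0 <= d < 3:
            raise ValueError(f"dimension index out of range: {d}")
    xv = tuple(float(v) for v in x)
    if len(xv) != 3:
        raise ValueError("x must be a 3-vector")
    return tuple(v * factor if i == d else v for i, v in enumerate(xv))


def effectiveness_factors(
    stressor_table: pd.DataFrame,
    beta_c: float = 0.25,
    beta_m: float = 0.5,
    climate_floor: float = 0.1,
    market_floor: float = 0.1,
    mapping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Convert a raw stressor table into per-ward-month factors for the engine.

    Input columns: ``ward_id, month, ndvi, ndvi_lt_mean, ndvi_lt_sd,
    price, price_baseline``.  Output columns: ``ward_id, month, x_own,
    x_net, x_buy``.  The stressor→dimension mapping is configurable and
    logged; by default climate drives own production and market drives
    buy/barter, while local networks stay unstressed.
    """
    missing = [c for c in STRESSOR_COLUMNS if c not in stressor_table.columns]
    if missing:
        raise ValueError(f"stressor table missing columns: {missing}")
    if mapping is None:
        mapping = DEFAULT_MAPPING
    for channel, dim in mapping.items():
        if channel not in ("climate", "market"):
            raise ValueError(f"unknown stressor channel {channel!r}")
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dim!r}")
    logger.info("stressor mapping: %s", dict(mapping))

    dup = stressor_table.duplicated(subset=["ward_id", "month"])
    if dup.any():
        raise ValueError(
            f"duplicate (ward_id, month) rows in stressor table at positions {list(stressor_table.index[dup])}"
        )

    cf = climate_factor(
        stressor_table["ndvi"].to_numpy(),
        stressor_table["ndvi_lt_mean"].to_numpy(),
        stressor_table["ndvi_lt_sd"].to_numpy(),
        beta_c=beta_c,
        floor=climate_floor,
    )
    mf = market_factor(
        stressor_table["price"].to_numpy(),
        stressor_table["price_baseline"].to_numpy(),
        beta_m=beta_m,
        floor=market_floor,
    )
    cols = {d: np.ones(len(stressor_table)) for d in DIMENSIONS}
    if "climate" in mapping:
        cols[mapping["climate"]] = cols[mapping["climate"]] * cf
    if "market" in mapping:
        cols[mapping["market"]] = cols[mapping["market"]] * mf
    return pd.DataFrame(
        {
            "ward_id": stressor_table["ward_id"].to_numpy(),
            "month": stressor_table["month"].to_numpy(),
            "x_own": cols["own_production"],
            "x_net": cols["local_networks"],
            "x_buy": cols["buy_barter"],
        }
    )
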