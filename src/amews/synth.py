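"""Synthetic sentinel-survey inputs with known ground truth.

Emulates the structure of NDMA-style household surveillance in Kenya's
arid and semi-arid lands: a fixed panel of 30 households per sentinel
site observed monthly, child-level (MUAC-based) malnutrition aggregated
to ward-month prevalence, ward-level NDVI and maize-price stressor
series expressed against long-term baselines, and livelihood-zone
heterogeneity (pastoral / agro-pastoral / mixed) in household capability
profiles.  The ground-truth generator runs the packaged engine at known
parameters and emits its prevalence as "observed" data, which is what
makes parameter-recovery, split-sample and leading-edge experiments
possible without any restricted microdata.

It deliberately does not emulate MUAC measurement error, survey
non-response, or geographic realism beyond ward labels and planar
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import stressors as stress_mod
from .core import SimulationParams, simulate

ZONES = ("pastoral", "agro_pastoral", "mixed")

#: Mean capability (own production, local networks, buy/barter) per livelihood zone.
#: Deliberately peaked: in narrow ASAL livelihood contexts the channel a
#: household is equipped for dominates, so holding a mismatched strategy is
#: genuinely costly and adaptive capacity matters.
ARCHETYPES = {
    "pastoral": (0.90, 0.45, 0.15),
    "agro_pastoral": (0.70, 0.55, 0.35),
    "mixed": (0.40, 0.50, 0.85),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic fixture.

    Defaults follow the sentinel design (30 households per site, monthly
    observation) and place one site per ward across five wards for two
    years.  Child counts are truncated Poisson(2) on {1..6}; assets h_a
    come from a rich/poor Beta mixture (Beta(5,2) with weight 0.4 vs
    Beta(2,5) with weight 0.6); health h_p is Beta(9,1).  The shock
    schedule is a 3-month drought anomaly of −2.5 NDVI z-units in the
    second year followed by a 3-month 50% maize-price spike — sized so
    the default pipeline produces multi-phase IPC variation.  ``benign``
    switches to fully capable single-child households with no shocks (the
    zero-prevalence limit).
    """

    n_wards: int = 5
    sites_per_ward: int = 1
    households_per_site: int = 30
    months: int = 24
    start_month: str = "2017-01"
    child_mean: float = 2.0
    child_max: int = 6
    rich_weight: float = 0.4
    rich_beta: tuple = (5.0, 2.0)
    poor_beta: tuple = (2.0, 5.0)
    h_p_beta: tuple = (9.0, 1.0)
    capability_concentration: float = 30.0
    ndvi_mean: float = 0.45
    ndvi_sd: float = 0.15
    ndvi_season_amp: float = 0.03
    ndvi_noise_sd: float = 0.005
    price_baseline: float = 4.0
    price_drift: float = 0.002
    price_noise_sd: float = 0.005
    drought_start: int = 12
    drought_duration: int = 3
    drought_z: float = -2.5
    spike_start: int = 16
    spike_duration: int = 3
    spike_size: float = 0.5
    benign: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_wards", "sites_per_ward", "households_per_site", "months"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.child_max <= 6:
            raise ValueError("child_max must lie in {1..6}")
        if not 0.0 <= self.rich_weight <= 1.0:
            raise ValueError("mixture weights must sum to 1 (rich_weight in [0,1])")
        if self.ndvi_sd <= 0 or self.price_baseline <= 0:
            raise ValueError("long-term baselines must be positive")

    def month_labels(self) -> list[str]:
        start = pd.Period(self.start_month, freq="M")
        return [(start + i).strftime("%Y-%m") for i in range(self.months)]

    def ward_ids(self) -> list[str]:
        return [f"w{i + 1}" for i in range(self.n_wards)]

    def ward_zone(self, ward_index: int) -> str:
        return ZONES[ward_index % len(ZONES)]


def default_true_params(seed: int = 0) -> SimulationParams:
    """The fixture's ground-truth engine parameters.

    λ sits at the center of the calibration box; the spawn rate is at the
    bottom of its box because inventing a genuinely novel livelihood
    strategy is rare relative to imitating a neighbor.  Households start
    with a singleton strategy repertoire (narrow ASAL livelihood
    contexts), so broadening it through imitation is the dominant coping
    margin.  n_0 is 0.04 on the normalized per-child food scale: with
    food divided by the number of children and h_p, h_a acting
    multiplicatively, the capable median household clears the threshold
    in normal months while poor, large, or strategy-mismatched households
    slip under, yielding endemic prevalence in the high tens of percent
    with drought-driven spikes — crisis-level conditions typical of ASAL
    sentinel data in drought years.
    """
    return SimulationParams(
        learning_rate=0.05,
        spawn_rate=0.01,
        sufficiency_threshold=0.04,
        init_set_size=1,
        seed=seed,
    )


def _truncated_poisson(rng: np.random.Generator, mean: float, lo: int, hi: int, size: int):
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = rng.poisson(mean, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _beta_capability(rng: np.random.Generator, mean: float, concentration: float, size: int):
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


def generate_households(config: GeneratorConfig) -> pd.DataFrame:
    """Household table: capabilities per zone archetype, mixed assets, panel of 30 per site."""
    rng = np.random.default_rng(config.seed)
    rows = []
    hid = 0
    for wi, ward in enumerate(config.ward_ids()):
        zone = config.ward_zone(wi)
        means = ARCHETYPES[zone]
        for site in range(config.sites_per_ward):
            n = config.households_per_site
            cx, cy = wi + 0.5, site + 0.5  # site center inside the ward's unit cell
            xs = np.clip(cx + rng.normal(0, 0.15, n), wi, wi + 1)
            ys = np.clip(cy + rng.normal(0, 0.15, n), site, site + 1)
            if config.benign:
                caps = np.ones((n, 3))
                h_p = np.ones(n)
                h_a = np.ones(n)
                children = np.ones(n, dtype=int)
            else:
                caps = np.column_stack(
                    [
                        _beta_capability(rng, m, config.capability_concentration, n)
                        for m in means
                    ]
                )
                h_p = rng.beta(*config.h_p_beta, size=n)
                rich = rng.random(n) < config.rich_weight
                h_a = np.where(
                    rich,
                    rng.beta(*config.rich_beta, size=n),
                    rng.beta(*config.poor_beta, size=n),
                )
                children = _truncated_poisson(rng, config.child_mean, 1, config.child_max, n)
            for k in range(n):
                hid += 1
                rows.append(
                    {
                        "id": f"h{hid:05d}",
                        "ward_id": ward,
                        "x": float(xs[k]),
                        "y": float(ys[k]),
                        "cap_own": float(caps[k, 0]),
                        "cap_network": float(caps[k, 1]),
                        "cap_market": float(caps[k, 2]),
                        "h_p": float(h_p[k]),
                        "h_a": float(h_a[k]),
                        "n_children": int(children[k]),
                    }
                )
    if not rows:
        raise ValueError("configuration generates zero households")
    return pd.DataFrame(rows)


def generate_stressors(config: GeneratorConfig) -> pd.DataFrame:
    """Monthly NDVI and maize-price series per ward, with consistent long-term baselines.

    NDVI is a small seasonal sinusoid plus noise around the long-term
    mean, with scheduled drought months pulled down by ``drought_z``
    standard deviations.  Price follows the ward baseline with a slow
    drift, noise, and scheduled spike months.
    """
    if config.months < 12:
        raise ValueError("stressor series need at least 12 months")
    rng = np.random.default_rng(config.seed + 1)
    months = config.month_labels()
    drought = set(range(config.drought_start, config.drought_start + config.drought_duration))
    spike = set(range(config.spike_start, config.spike_start + config.spike_duration))
    if config.benign:
        drought = set()
        spike = set()
    rows = []
    for wi, ward in enumerate(config.ward_ids()):
        baseline = config.price_baseline * (1.0 + 0.1 * (rng.random() - 0.5))
        for m, label in enumerate(months):
            ndvi = (
                config.ndvi_mean
                + config.ndvi_season_amp * math.sin(2 * math.pi * (m % 12) / 12.0)
                + rng.normal(0, config.ndvi_noise_sd)
            )
            if m in drought:
                ndvi += config.drought_z * config.ndvi_sd
            price = baseline * (
                1.0
                + config.price_drift * m
                + rng.normal(0, config.price_noise_sd)
            )
            if m in spike:
                price *= 1.0 + config.spike_size
            rows.append(
                {
                    "ward_id": ward,
                    "month": label,
                    "ndvi": float(ndvi),
                    "ndvi_lt_mean": config.ndvi_mean,
                    "ndvi_lt_sd": config.ndvi_sd,
                    "price": float(max(price, 0.0)),
                    "price_baseline": float(baseline),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    households: pd.DataFrame
    stressors: pd.DataFrame
    factors: pd.DataFrame
    observed: pd.DataFrame
    params: SimulationParams
    config: GeneratorConfig

    def truth_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "config": asdict(self.config),
        }


def generate_ground_truth(
    config: GeneratorConfig,
    true_params: SimulationParams | None = None,
) -> GroundTruth:
    """Run the engine at known parameters and emit its prevalence as 'observed' data."""
    if true_params is None:
        true_params = default_true_params(seed=config.seed)
    households = generate_households(config)
    stressor_table = generate_stressors(config)
    factors = stress_mod.effectiveness_factors(stressor_table)
    observed = simulate(households, factors, true_params)
    return GroundTruth(
        households=households,
        stressors=stressor_table,
        factors=factors,
        observed=observed,
        params=true_params,
        config=config,
    )
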