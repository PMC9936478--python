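"""Agent-based engine for household food-security dynamics.

Households are the actors. Each holds a set of livelihood strategies —
3-vectors of reliance weights over (own food production, local networks,
buying/bartering) — and repeats, once per monthly round, the cycle
*strategy selection → action → adaption*:

1.  A strategy is drawn from the household's set with probability
    proportional to its remembered performance (an exponential moving
    average of realized nutritional sufficiency), plus a small selection
    floor so unproven strategies keep a chance of being explored.
2.  The strategy ``s``, the household's capability profile ``h_s`` and the
    ward's effectiveness factors ``x`` (climate / market stressors)
    determine food availability per child; health ``h_p`` and assets
    ``h_a`` act as multiplicative constraints on the resulting
    nutritional sufficiency ``n_s``.  A household is nutritionally
    insufficient when ``n_s`` falls below the global threshold ``n_0``,
    and acutely malnourished (``w``) after ``K`` consecutive
    insufficient rounds.
3.  Households that failed sufficiency adapt by hill climbing: with
    probability ``λ`` they copy the strategy of the best-performing
    geographic neighbor (regardless of their own capability profile), and
    with an independent spawn probability they add a mutated variant of
    their active strategy to the set.

Ward-month acute-malnutrition prevalence is the child-weighted share of
malnourished households, which keeps the simulated statistic aligned with
child-level MUAC prevalence from sentinel surveillance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Order of the three livelihood dimensions used throughout the package.
DIMENSIONS = ("own_production", "local_networks", "buy_barter")

#: Calibration box for the learning and spawn rates.
RATE_BOX = (0.01, 0.1)

_TOL = 1e-9


def _as_weights(value) -> tuple[float, float, float]:
    if isinstance(value, Strategy):
        return value.weights
    w = tuple(float(v) for v in value)
    if len(w) != 3:
        raise ValueError(f"expected a 3-vector of weights, got length {len(w)}")
    return w


class Strategy:
    """A livelihood mix: non-negative weights over the three dimensions, summing to 1."""

    __slots__ = ("weights",)

    def __init__(self, weights: Sequence[float]):
        w = _as_weights(weights)
        if any(v < -_TOL for v in w):
            raise ValueError(f"strategy weights must be non-negative, got {w}")
        if abs(sum(w) - 1.0) > _TOL:
            raise ValueError(f"strategy weights must sum to 1, got {w} (sum {sum(w)})")
        self.weights = tuple(min(max(v, 0.0), 1.0) for v in w)

    def __repr__(self) -> str:
        return f"Strategy({self.weights})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Strategy) and self.weights == other.weights

    def __hash__(self) -> int:
        return hash(self.weights)


def strategies_close(a, b, tol: float = 1e-9) -> bool:
    """Component-wise equality within ``tol`` (the set's duplicate criterion)."""
    wa, wb = _as_weights(a), _as_weights(b)
    return max(abs(x - y) for x, y in zip(wa, wb)) <= tol


def simplex_catalog(step: float = 0.25) -> list[Strategy]:
    """All strategies on a simplex grid with the given step (0.25 -> 15 strategies)."""
    n = round(1.0 / step)
    if n < 1 or abs(n * step - 1.0) > _TOL:
        raise ValueError(f"step must divide 1 evenly, got {step}")
    return [
        Strategy((i / n, j / n, (n - i - j) / n))
        for i in range(n + 1)
        for j in range(n - i + 1)
    ]


def filter_catalog(
    catalog: Sequence[Strategy],
    bounds: Mapping[str, tuple[float, float]],
) -> list[Strategy]:
    """Restrict a catalog to strategies whose weights fall inside per-dimension bounds.

    ``bounds`` maps dimension names (see :data:`DIMENSIONS`) to (lo, hi)
    intervals; e.g. pastoral zones may cap ``own_production`` agriculture
    entries.  Raises if the mask empties the catalog.
    """
    idx = {name: i for i, name in enumerate(DIMENSIONS)}
    for name in bounds:
        if name not in idx:
            raise ValueError(f"unknown dimension {name!r}; expected one of {DIMENSIONS}")
    kept = [
        s
        for s in catalog
        if all(lo - _TOL <= s.weights[idx[d]] <= hi + _TOL for d, (lo, hi) in bounds.items())
    ]
    if not kept:
        raise ValueError("zone mask removed every strategy from the catalog")
    return kept


class StrategySet:
    """An ordered strategy collection with a performance memory per strategy.

    The memory is an exponential moving average of realized sufficiency
    ``n_s`` and drives success-weighted selection.  Duplicates (within
    component-wise 1e-9) are rejected.  ``max_size`` caps growth through
    adoption/spawning; an initial set larger than the cap is tolerated and
    only shrinks through eviction of the lowest-memory strategy.
    """

    __slots__ = ("strategies", "memory", "max_size")

    def __init__(
        self,
        strategies: Iterable,
        memory: Sequence[float] | None = None,
        max_size: int = 8,
    ):
        strat = [Strategy(s).weights for s in strategies]
        if not strat:
            raise ValueError("strategy set must be non-empty")
        for i in range(len(strat)):
            for j in range(i + 1, len(strat)):
                if strategies_close(strat[i], strat[j]):
                    raise ValueError(f"duplicate strategies at positions {i} and {j}")
        if int(max_size) < 1:
            raise ValueError("max_size must be a positive integer")
        if memory is None:
            memory = [1.0] * len(strat)
        memory = [float(m) for m in memory]
        if len(memory) != len(strat):
            raise ValueError("memory length must equal strategy count")
        if any(m < 0 for m in memory):
            raise ValueError("performance memory must be non-negative")
        self.strategies: list[tuple[float, float, float]] = strat
        self.memory: list[float] = memory
        self.max_size = int(max_size)

    def __len__(self) -> int:
        return len(self.strategies)

    def index_of(self, weights, tol: float = 1e-9) -> int | None:
        w = _as_weights(weights)
        for i, s in enumerate(self.strategies):
            if max(abs(a - b) for a, b in zip(s, w)) <= tol:
                return i
        return None


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the engine.

    ``learning_rate`` (λ) and ``spawn_rate`` live in the calibration box
    [0.01, 0.1]; values outside are accepted (scenario transforms scale λ
    by ±50%) but logged.  ``sufficiency_threshold`` is n_0 on the
    normalized per-child food scale, ``persistence_window`` the number K of
    consecutive insufficient rounds defining acute malnutrition, and
    ``init_set_size`` the number of catalog strategies each household
    starts with (its repertoire can then grow by imitation and spawning up
    to ``max_set_size``).
    """

    learning_rate: float = 0.05
    spawn_rate: float = 0.05
    learning_mode: str = "hill_climbing"
    sufficiency_threshold: float = 0.5
    persistence_window: int = 2
    neighborhood_k: int = 8
    selection_floor: float = 0.05
    ema_alpha: float = 0.3
    init_set_size: int = 3
    max_set_size: int = 8
    spawn_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_mode != "hill_climbing":
            raise ValueError(f"unsupported learning mode {self.learning_mode!r}")
        for name in ("learning_rate", "spawn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            if not RATE_BOX[0] <= v <= RATE_BOX[1]:
                logger.info("%s=%g lies outside the calibration box %s", name, v, RATE_BOX)
        if self.sufficiency_threshold <= 0:
            raise ValueError("sufficiency_threshold must be positive")
        if self.persistence_window < 1:
            raise ValueError("persistence_window must be >= 1")
        if self.neighborhood_k < 0:
            raise ValueError("neighborhood_k must be >= 0")
        if not 0.0 <= self.selection_floor < 1.0:
            raise ValueError("selection_floor must be in [0, 1)")
        if not 0.0 < self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must be in (0, 1]")
        if self.init_set_size < 1:
            raise ValueError("init_set_size must be >= 1")
        if self.max_set_size < 1:
            raise ValueError("max_set_size must be >= 1")
        if self.spawn_scale <= 0:
            raise ValueError("spawn_scale must be positive")


class Household:
    """A single surveyed household: capabilities, constraints, and its strategy set."""

    __slots__ = (
        "id",
        "ward_id",
        "coords",
        "capabilities",
        "h_p",
        "h_a",
        "n_children",
        "strategy_set",
        "active_strategy",
        "sufficiency_history",
        "malnourished",
        "last_ns",
        "insufficiency_run",
        "neighbors",
    )

    def __init__(
        self,
        id,
        ward_id,
        coords,
        capabilities,
        h_p: float,
        h_a: float,
        n_children: int,
        strategy_set: StrategySet,
        active_strategy: int = 0,
    ):
        caps = tuple(float(c) for c in capabilities)
        if len(caps) != 3 or any(not 0.0 <= c <= 1.0 for c in caps):
            raise ValueError(f"capabilities must be a 3-vector in [0,1], got {caps}")
        if not 0.0 <= h_p <= 1.0:
            raise ValueError(f"h_p must be in [0,1], got {h_p}")
        if not 0.0 <= h_a <= 1.0:
            raise ValueError(f"h_a must be in [0,1], got {h_a}")
        if int(n_children) < 1:
            raise ValueError(f"n_children must be >= 1, got {n_children}")
        if not 0 <= int(active_strategy) < len(strategy_set):
            raise ValueError(f"active_strategy {active_strategy} out of range")
        self.id = id
        self.ward_id = ward_id
        self.coords = (float(coords[0]), float(coords[1]))
        self.capabilities = caps
        self.h_p = float(h_p)
        self.h_a = float(h_a)
        self.n_children = int(n_children)
        self.strategy_set = strategy_set
        self.active_strategy = int(active_strategy)
        self.sufficiency_history: list[bool] = []
        self.malnourished = False
        self.last_ns = 0.0
        self.insufficiency_run = 0
        self.neighbors: tuple[int, ...] = ()

    def active_weights(self) -> tuple[float, float, float]:
        return self.strategy_set.strategies[self.active_strategy]

    def _evict_for_growth(self) -> None:
        ss = self.strategy_set
        if len(ss) < ss.max_size:
            return
        # evict the lowest-memory strategy, never the active one
        candidates = [i for i in range(len(ss)) if i != self.active_strategy]
        ev = min(candidates, key=lambda i: (ss.memory[i], i))
        del ss.strategies[ev]
        del ss.memory[ev]
        if self.active_strategy > ev:
            self.active_strategy -= 1

    def adopt_strategy(self, weights, memory_value: float) -> None:
        """Adopt a neighbor's strategy: add it (or find it) and make it active."""
        ss = self.strategy_set
        idx = ss.index_of(weights)
        if idx is None:
            self._evict_for_growth()
            ss.strategies.append(_as_weights(weights))
            ss.memory.append(max(float(memory_value), 0.0))
            idx = len(ss) - 1
        else:
            ss.memory[idx] = max(ss.memory[idx], float(memory_value))
        self.active_strategy = idx

    def spawn_strategy(self, rng: np.random.Generator, scale: float) -> None:
        """Append a renormalized perturbation of the active strategy (common-prior memory)."""
        ss = self.strategy_set
        base = ss.strategies[self.active_strategy]
        noise = rng.normal(0.0, scale, 3)
        pert = [max(b + g, 0.0) for b, g in zip(base, noise)]
        total = sum(pert)
        if total <= 0.0:
            weights = (1 / 3, 1 / 3, 1 / 3)
        else:
            weights = tuple(p / total for p in pert)
        if ss.index_of(weights) is not None:
            return  # would duplicate an existing strategy; no-op
        prior = sum(ss.memory) / len(ss.memory)
        self._evict_for_growth()
        ss.strategies.append(weights)
        ss.memory.append(prior)


@dataclass
class ModelState:
    """Full simulation state; identical (inputs, params, seed) give identical trajectories."""

    t: int
    households: list[Household]
    params: SimulationParams
    rng: np.random.Generator
    wards: list
    ward_households: dict


# ---------------------------------------------------------------------------
# elementary operations


def compute_food_availability(strategy, h_s, x, n_children: int) -> float:
    """Per-child food availability: (Σ_d s_d · h_s,d · x_d) / n_children.

    Normalized so a fully capable, unshocked, single-child household on any
    pure strategy attains exactly 1.0.
    """
    s = _as_weights(strategy)
    c = _as_weights(h_s)
    xv = _as_weights(x)
    if int(n_children) < 1:
        raise ValueError("n_children must be >= 1")
    if any(v < 0 for v in s + c + xv):
        raise ValueError("strategy, capabilities and effectiveness factors must be non-negative")
    return (s[0] * c[0] * xv[0] + s[1] * c[1] * xv[1] + s[2] * c[2] * xv[2]) / int(n_children)


def evaluate_sufficiency(food_per_child: float, h_p: float, h_a: float, n_0: float):
    """Nutritional sufficiency n_s = food · h_p · h_a, compared against threshold n_0."""
    if not 0.0 <= h_p <= 1.0 or not 0.0 <= h_a <= 1.0:
        raise ValueError("h_p and h_a must be in [0, 1]")
    if n_0 <= 0:
        raise ValueError("n_0 must be positive")
    if food_per_child < 0:
        raise ValueError("food availability must be non-negative")
    n_s = food_per_child * h_p * h_a
    return n_s, n_s >= n_0


def update_malnutrition(sufficiency_history: Sequence[bool], K: int) -> bool:
    """True iff the most recent K rounds were all insufficient.

    When the history is shorter than K, the missing leading rounds are
    treated as sufficient, so a household cannot be malnourished before K
    observed rounds.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(sufficiency_history) == 0:
        raise ValueError("sufficiency history must be non-empty")
    if len(sufficiency_history) < K:
        return False
    return not any(sufficiency_history[-K:])


def select_strategy(
    strategy_set: StrategySet,
    rng: np.random.Generator,
    floor: float = 0.05,
    u: float | None = None,
) -> int:
    """Success-weighted random selection.

    Sampling weight for strategy j is ``memory_j + floor · mean(memory)``.
    With an all-zero memory and floor 0 the draw falls back to uniform.
    """
    m = len(strategy_set)
    if m == 1:
        return 0
    if u is None:
        u = float(rng.random())
    mem = strategy_set.memory
    mean_mem = sum(mem) / m
    base = floor * mean_mem
    total = sum(mem) + base * m
    if total <= 0.0:
        return min(int(u * m), m - 1)
    r = u * total
    acc = 0.0
    for j in range(m - 1):
        acc += mem[j] + base
        if r <= acc:
            return j
    return m - 1


def adapt(
    household: Household,
    neighbors: Sequence[Household],
    params: SimulationParams,
    rng: np.random.Generator,
    u_learn: float | None = None,
    u_spawn: float | None = None,
) -> Household:
    """Post-failure adaption: hill-climbing imitation plus strategy spawning.

    With probability λ the household copies the strategy of the neighbor
    with the highest most-recent realized n_s, provided it strictly exceeds
    the household's own most-recent n_s (ties broken uniformly at random);
    independently, with the spawn probability, it appends a mutated variant
    of its active strategy.  Both happen regardless of the household's own
    capability profile.  Called only for households that failed sufficiency
    this round.
    """
    if u_learn is None:
        u_learn = float(rng.random())
    if u_spawn is None:
        u_spawn = float(rng.random())
    if neighbors and u_learn < params.learning_rate:
        best = -1.0
        tied: list[Household] = []
        for nb in neighbors:
            v = nb.last_ns
            if v > best:
                best = v
                tied = [nb]
            elif v == best:
                tied.append(nb)
        if best > household.last_ns:
            nb = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
            household.adopt_strategy(
                nb.strategy_set.strategies[nb.active_strategy], nb.last_ns
            )
    if u_spawn < params.spawn_rate:
        household.spawn_strategy(rng, params.spawn_scale)
    return household


# ---------------------------------------------------------------------------
# model assembly and stepping


_REQUIRED_COLUMNS = (
    "id",
    "ward_id",
    "cap_own",
    "cap_network",
    "cap_market",
    "h_p",
    "h_a",
    "n_children",
)


def initialize_model(
    households_table: pd.DataFrame,
    params: SimulationParams,
    strategy_catalog: Sequence[Strategy],
    zone_masks: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    ward_zones: Mapping[str, str] | None = None,
) -> ModelState:
    """Seed the model from a household table.

    Every household draws ``init_set_size`` distinct strategies uniformly
    from the catalog (restricted by its ward's livelihood-zone mask when
    provided) with a common performance prior, and a uniform-random active
    strategy — so a household may start with a narrow strategy repertoire
    and only broadens it through imitation and spawning.  Households
    without coordinates are placed at density-weighted random positions
    within their ward's unit cell.  Neighborhoods are the k nearest
    households within the same ward (skipped entirely when k = 0).
    """
    if len(households_table) == 0:
        raise ValueError("household table is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in households_table.columns]
    if missing:
        raise ValueError(f"household table missing columns: {missing}")
    catalog = [Strategy(s) for s in strategy_catalog]
    if not catalog:
        raise ValueError("strategy catalog must be non-empty")
    if zone_masks and ward_zones:
        for ward, zone in ward_zones.items():
            if zone not in zone_masks and zone is not None:
                raise ValueError(f"ward {ward!r} references unknown zone {zone!r}")

    rng = np.random.default_rng(params.seed)
    wards = list(dict.fromkeys(households_table["ward_id"]))
    ward_pos = {w: i for i, w in enumerate(wards)}
    has_coords = "x" in households_table.columns and "y" in households_table.columns

    per_ward_catalog: dict = {}
    for w in wards:
        cat = catalog
        if zone_masks and ward_zones and ward_zones.get(w) in zone_masks:
            cat = filter_catalog(catalog, zone_masks[ward_zones[w]])
        per_ward_catalog[w] = [s.weights for s in cat]

    households: list[Household] = []
    ward_households: dict = {w: [] for w in wards}
    for row in households_table.itertuples(index=False):
        w = row.ward_id
        cat = per_ward_catalog[w]
        if has_coords:
            coords = (float(row.x), float(row.y))
        else:
            coords = (ward_pos[w] + float(rng.random()), float(rng.random()))
        k = min(params.init_set_size, len(cat))
        chosen = rng.choice(len(cat), size=k, replace=False)
        subset = [cat[int(i)] for i in chosen]
        max_size = max(params.max_set_size, len(subset))
        ss = StrategySet(subset, memory=[1.0] * len(subset), max_size=max_size)
        active = int(rng.integers(len(subset)))
        hh = Household(
            id=row.id,
            ward_id=w,
            coords=coords,
            capabilities=(row.cap_own, row.cap_network, row.cap_market),
            h_p=row.h_p,
            h_a=row.h_a,
            n_children=row.n_children,
            strategy_set=ss,
            active_strategy=active,
        )
        ward_households[w].append(len(households))
        households.append(hh)

    if params.neighborhood_k > 0:
        for w, idxs in ward_households.items():
            if len(idxs) < 2:
                continue
            pts = np.array([households[i].coords for i in idxs])
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            kk = min(params.neighborhood_k, len(idxs) - 1)
            order = np.argsort(d2, axis=1, kind="stable")[:, :kk]
            for local_i, i in enumerate(idxs):
                households[i].neighbors = tuple(idxs[j] for j in order[local_i])

    return ModelState(
        t=0,
        households=households,
        params=params,
        rng=rng,
        wards=wards,
        ward_households=ward_households,
    )


def step(state: ModelState, stressors_t: Mapping) -> ModelState:
    """Advance the model by one round under the given per-ward effectiveness factors.

    Households are processed exactly once each, in a freshly shuffled
    order: select → act (availability, sufficiency, malnutrition state,
    memory update) → adapt when insufficient.
    """
    p = state.params
    hhs = state.households
    missing = [w for w in state.wards if w not in stressors_t]
    if missing:
        raise KeyError(f"missing stressor factors for wards: {missing}")
    xcache = {w: _as_weights(stressors_t[w]) for w in state.wards}
    for w, xv in xcache.items():
        if any(v < 0 for v in xv):
            raise ValueError(f"negative effectiveness factor for ward {w!r}: {xv}")

    rng = state.rng
    n = len(hhs)
    order = rng.permutation(n).tolist()
    u_sel = rng.random(n).tolist()
    u_learn = rng.random(n).tolist()
    u_spawn = rng.random(n).tolist()

    n0 = p.sufficiency_threshold
    K = p.persistence_window
    alpha = p.ema_alpha
    floor = p.selection_floor

    for pos, i in enumerate(order):
        hh = hhs[i]
        x = xcache[hh.ward_id]
        j = select_strategy(hh.strategy_set, rng, floor, u=u_sel[pos])
        hh.active_strategy = j
        s = hh.strategy_set.strategies[j]
        c = hh.capabilities
        food = (s[0] * c[0] * x[0] + s[1] * c[1] * x[1] + s[2] * c[2] * x[2]) / hh.n_children
        ns = food * hh.h_p * hh.h_a
        sufficient = ns >= n0
        hh.last_ns = ns
        hh.sufficiency_history.append(sufficient)
        hh.insufficiency_run = 0 if sufficient else hh.insufficiency_run + 1
        hh.malnourished = hh.insufficiency_run >= K
        mem = hh.strategy_set.memory
        mem[j] = (1.0 - alpha) * mem[j] + alpha * ns
        if not sufficient:
            neighbors = [hhs[k] for k in hh.neighbors]
            adapt(hh, neighbors, p, rng, u_learn=u_learn[pos], u_spawn=u_spawn[pos])
    state.t += 1
    return state


def aggregate_prevalence(state: ModelState, ward_id) -> float:
    """Ward acute-malnutrition prevalence in percent, weighting households by children.

    Child weighting keeps the household-level statistic aligned with the
    child-level MUAC rates that sentinel surveillance reports.
    """
    idxs = state.ward_households.get(ward_id)
    if not idxs:
        raise KeyError(f"unknown or empty ward {ward_id!r}")
    total = 0
    mal = 0
    for i in idxs:
        hh = state.households[i]
        total += hh.n_children
        if hh.malnourished:
            mal += hh.n_children
    return 100.0 * mal / total


def simulate(
    households_table: pd.DataFrame,
    factors: pd.DataFrame,
    params: SimulationParams,
    catalog: Sequence[Strategy] | None = None,
    zone_masks=None,
    ward_zones=None,
    months: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the engine over a monthly factor table.

    ``factors`` must carry columns ``ward_id, month, x_own, x_net, x_buy``
    (see :mod:`amews.stressors`).  Returns a tidy frame with columns
    ``ward_id, month, prevalence_pct``, one row per ward-month.
    """
    if catalog is None:
        catalog = simplex_catalog()
    state = initialize_model(households_table, params, catalog, zone_masks, ward_zones)

    by_month: dict = {}
    for row in factors.itertuples(index=False):
        by_month.setdefault(row.month, {})[row.ward_id] = (row.x_own, row.x_net, row.x_buy)
    if months is None:
        months = sorted(by_month)
    records = []
    for month in months:
        if month not in by_month:
            raise KeyError(f"no stressor factors for month {month!r}")
        step(state, by_month[month])
        for w in state.wards:
            records.append((w, month, aggregate_prevalence(state, w)))
    return pd.DataFrame(records, columns=["ward_id", "month", "prevalence_pct"])


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and an integer key path."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
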