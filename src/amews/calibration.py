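"""Calibration and forecast evaluation against observed ward-month prevalence.

The learning rate λ (and optionally the spawn rate and sufficiency
threshold n_0) is empirically unobservable, so it is estimated by grid
search: every grid cell runs R replicate simulations and is scored by the
RMSD between the replicate-mean simulated trajectory and observed
prevalence (proportion scale), with macro-F1 as tie-break.  Scoring the
replicate mean averages Monte-Carlo variance out of the objective so it
estimates systematic bias, which is what the RMSD criterion is about; the
mean of per-replicate RMSDs is also reported in the grid table.  Grid
search is preferred over gradient methods because the simulator is
stochastic and the parameter ranges are boxes.

Two out-of-sample protocols are provided: a temporal split (calibrate on
the early span, simulate through the later span with frozen parameters)
and rolling leading-edge forecasting (re-calibrate before each
consecutive fixed-horizon window, pooling per-window forecast errors).
The first months of every scored span are discarded as burn-in, since the
malnutrition state needs history to be meaningful.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .core import SimulationParams, derive_seed, simulate
from .metrics import IpcThresholds, ValidationReport, macro_f1, prevalence_to_ipc

logger = logging.getLogger(__name__)

_OBS_COLUMNS = ("ward_id", "month", "prevalence_pct")


@dataclass(frozen=True)
class CalibrationGrid:
    """Search box for the unobservable behavioral parameters."""

    lambdas: tuple = tuple(round(0.01 * i, 2) for i in range(1, 11))
    spawns: tuple = (0.05,)
    n0s: tuple | None = None
    replicates: int = 20

    def __post_init__(self):
        if len(self.lambdas) == 0 or len(self.spawns) == 0:
            raise ValueError("grid axes must be non-empty")
        if self.n0s is not None and len(self.n0s) == 0:
            raise ValueError("n0 axis, when given, must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self, base_n0: float):
        n0s = self.n0s if self.n0s is not None else (base_n0,)
        return list(itertools.product(self.lambdas, self.spawns, n0s))


@dataclass
class CalibrationResult:
    best_params: SimulationParams
    report: ValidationReport
    table: pd.DataFrame


@dataclass
class SplitResult:
    train_report: ValidationReport
    test_report: ValidationReport
    best_params: SimulationParams


@dataclass
class WindowReport:
    train_months: list
    test_months: list
    report: ValidationReport
    best_params: SimulationParams


@dataclass
class LeadingEdgeResult:
    windows: list
    errors: pd.DataFrame


def _check_observed(observed: pd.DataFrame) -> None:
    missing = [c for c in _OBS_COLUMNS if c not in observed.columns]
    if missing:
        raise ValueError(f"observed table missing columns: {missing}")
    if len(observed) == 0:
        raise ValueError("observed prevalence table is empty")
    if observed["ward_id"].nunique() < 2:
        warnings.warn("observed data covers a single ward; validation metrics will be degenerate")
    if observed["month"].nunique() < 6:
        warnings.warn("observed data covers fewer than 6 months; calibration may be unreliable")


def _scored_rows(observed: pd.DataFrame, sim_months: Sequence[str], burn_in: int):
    scorable = set(sim_months[burn_in:])
    scored = observed[observed["month"].isin(scorable)].sort_values(["month", "ward_id"])
    if len(scored) == 0:
        raise ValueError(
            f"no observed rows left to score after a burn-in of {burn_in} months"
        )
    return scored


def _mean_prediction(
    households: pd.DataFrame,
    factors: pd.DataFrame,
    params: SimulationParams,
    sim_months: Sequence[str],
    scored: pd.DataFrame,
    replicates: int,
    seed: int,
    cell_index: int,
    catalog,
    zone_masks,
    ward_zones,
):
    """Run R replicates; return (per-replicate predictions, key positions)."""
    keys = list(zip(scored["ward_id"], scored["month"]))
    positions = None
    preds = np.empty((replicates, len(keys)))
    for rep in range(replicates):
        p = replace(params, seed=derive_seed(seed, cell_index, rep))
        sim = simulate(
            households,
            factors,
            p,
            catalog=catalog,
            zone_masks=zone_masks,
            ward_zones=ward_zones,
            months=list(sim_months),
        )
        if positions is None:
            lookup = {
                (w, m): i
                for i, (w, m) in enumerate(zip(sim["ward_id"], sim["month"]))
            }
            try:
                positions = [lookup[k] for k in keys]
            except KeyError as exc:
                raise ValueError(f"simulation produced no prevalence for {exc}") from exc
        preds[rep] = sim["prevalence_pct"].to_numpy()[positions]
    return preds


def calibrate(
    observed: pd.DataFrame,
    households: pd.DataFrame,
    factors: pd.DataFrame,
    grid: CalibrationGrid | None = None,
    base_params: SimulationParams | None = None,
    seed: int = 0,
    burn_in: int = 6,
    catalog=None,
    zone_masks=None,
    ward_zones=None,
    thresholds: IpcThresholds | None = None,
) -> CalibrationResult:
    """Grid-search λ (and optionally spawn rate / n_0) against observed prevalence.

    For each cell, R replicate simulations are run with deterministic
    per-cell, per-replicate seeds derived from ``seed``; the objective is
    the RMSD of the replicate-mean trajectory (minimized) with its
    macro-F1 as tie-break (maximized).  Only observed
    rows from months after the burn-in are scored, and only months up to
    the last observed month are simulated, so later data cannot leak in.
    """
    _check_observed(observed)
    if grid is None:
        grid = CalibrationGrid()
    if base_params is None:
        base_params = SimulationParams()

    factor_months = sorted(set(factors["month"]))
    last_obs = max(observed["month"])
    sim_months = [m for m in factor_months if m <= last_obs]
    if not sim_months:
        raise ValueError("stressor factors do not cover the observed months")
    scored = _scored_rows(observed, sim_months, burn_in)
    obs_pct = scored["prevalence_pct"].to_numpy(dtype=float)
    obs_phase = prevalence_to_ipc(obs_pct, thresholds)

    rows = []
    best = None
    for ci, (lam, spawn, n0) in enumerate(grid.cells(base_params.sufficiency_threshold)):
        params = replace(
            base_params, learning_rate=lam, spawn_rate=spawn, sufficiency_threshold=n0
        )
        preds = _mean_prediction(
            households, factors, params, sim_months, scored,
            grid.replicates, seed, ci, catalog, zone_masks, ward_zones,
        )
        rep_rmsd = np.sqrt(np.mean((preds / 100.0 - obs_pct / 100.0) ** 2, axis=1))
        mean_pred = preds.mean(axis=0)
        rmsd_of_mean = float(np.sqrt(np.mean((mean_pred / 100.0 - obs_pct / 100.0) ** 2)))
        f1 = macro_f1(obs_phase, prevalence_to_ipc(mean_pred, thresholds))
        rows.append(
            {
                "learning_rate": lam,
                "spawn_rate": spawn,
                "n_0": n0,
                "rmsd": rmsd_of_mean,
                "replicate_rmsd_mean": float(rep_rmsd.mean()),
                "f1_macro": f1,
            }
        )
        key = (rmsd_of_mean, -f1, ci)
        if best is None or key < best[0]:
            best = (key, params, mean_pred)

    table = pd.DataFrame(rows)
    _, best_params, best_mean_pred = best
    report = ValidationReport.from_prevalence(obs_pct, best_mean_pred, thresholds)
    logger.info(
        "calibrated λ=%g spawn=%g n0=%g (RMSD %.4f, F1 %.3f)",
        best_params.learning_rate,
        best_params.spawn_rate,
        best_params.sufficiency_threshold,
        report.rmsd,
        report.f1_macro,
    )
    return CalibrationResult(best_params=best_params, report=report, table=table)


def _frozen_report(
    observed_rows: pd.DataFrame,
    households,
    factors,
    params: SimulationParams,
    sim_months,
    replicates: int,
    seed: int,
    catalog,
    zone_masks,
    ward_zones,
    thresholds,
) -> ValidationReport:
    preds = _mean_prediction(
        households, factors, params, sim_months, observed_rows,
        replicates, seed, 0, catalog, zone_masks, ward_zones,
    )
    mean_pred = preds.mean(axis=0)
    return ValidationReport.from_prevalence(
        observed_rows["prevalence_pct"].to_numpy(dtype=float), mean_pred, thresholds
    )


def temporal_split_eval(
    observed: pd.DataFrame,
    households: pd.DataFrame,
    factors: pd.DataFrame,
    split_month: str,
    grid: CalibrationGrid | None = None,
    base_params: SimulationParams | None = None,
    seed: int = 0,
    burn_in: int = 6,
    catalog=None,
    zone_masks=None,
    ward_zones=None,
    thresholds: IpcThresholds | None = None,
) -> SplitResult:
    """Calibrate on months before ``split_month``; evaluate both sides with frozen parameters."""
    train = observed[observed["month"] < split_month]
    test = observed[observed["month"] >= split_month]
    if len(train) == 0 or len(test) == 0:
        raise ValueError(
            f"split month {split_month!r} leaves an empty train or test side"
        )
    grid = grid or CalibrationGrid()
    cal = calibrate(
        train, households, factors, grid, base_params, seed, burn_in,
        catalog, zone_masks, ward_zones, thresholds,
    )
    factor_months = sorted(set(factors["month"]))
    last = max(observed["month"])
    sim_months = [m for m in factor_months if m <= last]
    train_scored = _scored_rows(train, sim_months, burn_in)
    test_scored = test.sort_values(["month", "ward_id"])
    eval_seed = derive_seed(seed, 2**20)  # distinct stream from calibration cells
    train_report = _frozen_report(
        train_scored, households, factors, cal.best_params, sim_months,
        grid.replicates, eval_seed, catalog, zone_masks, ward_zones, thresholds,
    )
    test_report = _frozen_report(
        test_scored, households, factors, cal.best_params, sim_months,
        grid.replicates, eval_seed, catalog, zone_masks, ward_zones, thresholds,
    )
    return SplitResult(
        train_report=train_report, test_report=test_report, best_params=cal.best_params
    )


def leading_edge(
    observed: pd.DataFrame,
    households: pd.DataFrame,
    factors: pd.DataFrame,
    horizon: int = 4,
    grid: CalibrationGrid | None = None,
    base_params: SimulationParams | None = None,
    seed: int = 0,
    initial_train_months: int = 12,
    burn_in: int = 6,
    catalog=None,
    zone_masks=None,
    ward_zones=None,
    thresholds: IpcThresholds | None = None,
    allow_any_horizon: bool = False,
) -> LeadingEdgeResult:
    """Rolling fixed-horizon forecasting with re-estimation before each window.

    The months after the initial training span are cut into consecutive
    non-overlapping windows of ``horizon`` months (12 test months at
    horizon 4 give three windows; at horizon 2, six).  Before each window
    the model is re-calibrated on everything observed so far, then run
    through the window with frozen parameters.  Returns per-window
    validation reports plus the pooled ward-month forecast errors.
    """
    if horizon not in (2, 4) and not allow_any_horizon:
        raise ValueError("horizon must be 2 or 4 (pass allow_any_horizon=True to override)")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    _check_observed(observed)
    grid = grid or CalibrationGrid()
    if base_params is None:
        base_params = SimulationParams()

    months = sorted(set(observed["month"]))
    if len(months) < initial_train_months + horizon:
        raise ValueError(
            f"need at least {initial_train_months + horizon} observed months, got {len(months)}"
        )
    test_months = months[initial_train_months:]
    n_windows = len(test_months) // horizon

    factor_months = sorted(set(factors["month"]))
    windows: list[WindowReport] = []
    err_rows = []
    for w in range(n_windows):
        win = test_months[w * horizon : (w + 1) * horizon]
        train = observed[observed["month"] < win[0]]
        cal = calibrate(
            train, households, factors, grid, base_params,
            derive_seed(seed, w), burn_in, catalog, zone_masks, ward_zones, thresholds,
        )
        sim_months = [m for m in factor_months if m <= win[-1]]
        win_rows = observed[observed["month"].isin(win)].sort_values(["month", "ward_id"])
        preds = _mean_prediction(
            households, factors, cal.best_params, sim_months, win_rows,
            grid.replicates, derive_seed(seed, w, 2**20), 0,
            catalog, zone_masks, ward_zones,
        )
        mean_pred = preds.mean(axis=0)
        obs_pct = win_rows["prevalence_pct"].to_numpy(dtype=float)
        report = ValidationReport.from_prevalence(obs_pct, mean_pred, thresholds)
        windows.append(
            WindowReport(
                train_months=sorted(set(train["month"])),
                test_months=list(win),
                report=report,
                best_params=cal.best_params,
            )
        )
        for (ward, month), o, p in zip(
            zip(win_rows["ward_id"], win_rows["month"]), obs_pct, mean_pred
        ):
            err_rows.append(
                {
                    "window": w,
                    "ward_id": ward,
                    "month": month,
                    "observed_pct": o,
                    "predicted_pct": p,
                    "error": (p - o) / 100.0,
                }
            )
    return LeadingEdgeResult(windows=windows, errors=pd.DataFrame(err_rows))
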