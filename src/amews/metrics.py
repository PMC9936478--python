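"""IPC acute-malnutrition phase mapping and multi-class validation metrics.

Continuous ward-month prevalence (%) is banded into the 5-point IPC
acute-malnutrition scale; simulated and observed phase vectors are then
compared with macro-F1 (predictive accuracy), Hamming loss (fraction of
misclassified units), and RMSD on the proportion scale (systematic bias).
A prediction is jointly valid when F1 > 0.5 and RMSD < 0.2 — a random
multi-class baseline on imbalanced phase data lands around F1 0.3–0.4, so
0.5 marks genuine skill, and 0.2 caps tolerable bias on proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Default GAM prevalence breakpoints (%) between IPC AMN phases 1..5.
DEFAULT_IPC_BREAKPOINTS = (5.0, 10.0, 15.0, 30.0)


@dataclass(frozen=True)
class IpcThresholds:
    """Ascending prevalence breakpoints (%) separating phases 1–5."""

    breakpoints: tuple[float, float, float, float] = DEFAULT_IPC_BREAKPOINTS

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if len(bp) != 4:
            raise ValueError("exactly 4 breakpoints are required for 5 phases")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints must be strictly increasing, got {bp}")
        object.__setattr__(self, "breakpoints", bp)


def prevalence_to_ipc(W, thresholds: IpcThresholds | None = None):
    """Map prevalence (%) to IPC phase 1–5: phase = 1 + #breakpoints ≤ W.

    Accepts a scalar or an array; monotone non-decreasing in W.
    """
    if thresholds is None:
        thresholds = IpcThresholds()
    w = np.asarray(W, dtype=float)
    if np.any(w < 0) or np.any(w > 100):
        raise ValueError("prevalence must lie in [0, 100] percent")
    bp = np.asarray(thresholds.breakpoints)
    phase = 1 + (w[..., None] >= bp).sum(axis=-1)
    return int(phase) if phase.ndim == 0 else phase


def _check_pair(observed, predicted):
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.ndim != 1 or pred.ndim != 1:
        raise ValueError("phase vectors must be one-dimensional")
    if len(obs) != len(pred):
        raise ValueError(f"length mismatch: {len(obs)} observed vs {len(pred)} predicted")
    if len(obs) == 0:
        raise ValueError("phase vectors must be non-empty")
    return obs, pred


def hamming_loss(observed_phases, predicted_phases) -> float:
    """Fraction of units whose predicted phase differs from the observed phase."""
    obs, pred = _check_pair(observed_phases, predicted_phases)
    return float(np.mean(obs != pred))


def macro_f1(observed_phases, predicted_phases) -> float:
    """Unweighted mean of per-class F1 over classes present in observed ∪ predicted.

    Per-class F1 is 0 when precision + recall is 0 (no predictions and no
    true positives for that class); classes absent from both vectors are
    excluded from the average.
    """
    obs, pred = _check_pair(observed_phases, predicted_phases)
    classes = sorted(set(obs.tolist()) | set(pred.tolist()))
    scores = []
    for c in classes:
        tp = int(np.sum((obs == c) & (pred == c)))
        fp = int(np.sum((obs != c) & (pred == c)))
        fn = int(np.sum((obs == c) & (pred != c)))
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        scores.append(f1)
    return float(np.mean(scores))


def rmsd(observed, predicted) -> float:
    """Root-mean-square deviation; prevalence inputs belong on the proportion scale [0, 1]."""
    obs, pred = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((obs.astype(float) - pred.astype(float)) ** 2)))


def joint_validity(f1: float, rmsd_value: float) -> bool:
    """Joint criterion: F1 strictly above 0.5 and RMSD strictly below 0.2."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("F1 must lie in [0, 1]")
    if rmsd_value < 0:
        raise ValueError("RMSD must be non-negative")
    return f1 > 0.5 and rmsd_value < 0.2


@dataclass(frozen=True)
class ValidationReport:
    """Bundle of the three validation metrics plus the joint validity verdict."""

    f1_macro: float
    hamming: float
    rmsd: float
    valid: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "valid", joint_validity(self.f1_macro, self.rmsd))

    @classmethod
    def from_prevalence(
        cls,
        observed_pct,
        predicted_pct,
        thresholds: IpcThresholds | None = None,
    ) -> "ValidationReport":
        """Score predicted against observed prevalence (%), banding into IPC phases.

        RMSD is computed on proportions (prevalence / 100).
        """
        obs = np.asarray(observed_pct, dtype=float)
        pred = np.asarray(predicted_pct, dtype=float)
        obs_phase = prevalence_to_ipc(obs, thresholds)
        pred_phase = prevalence_to_ipc(pred, thresholds)
        return cls(
            f1_macro=macro_f1(obs_phase, pred_phase),
            hamming=hamming_loss(obs_phase, pred_phase),
            rmsd=rmsd(obs / 100.0, pred / 100.0),
        )

    def to_dict(self) -> dict:
        return {
            "f1_macro": self.f1_macro,
            "hamming": self.hamming,
            "rmsd": self.rmsd,
            "valid": self.valid,
        }

    def text_block(self, label: str = "Validation") -> str:
        """A compact, table-style summary block."""
        mark = "*" if self.valid else " "
        return "\n".join(
            [
                f"{label}",
                f"  F1 (macro)    {self.f1_macro:6.2f}{mark}   [0-1, higher is better]",
                f"  Hamming loss  {self.hamming:6.2f}    [1-0, lower is better]",
                f"  RMSD          {self.rmsd:6.2f}{mark}   [>0, lower is better]",
                f"  jointly valid: {'yes' if self.valid else 'no'} (F1 > 0.5 and RMSD < 0.2)",
            ]
        )
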