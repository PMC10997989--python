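"""Cost-of-detection scoring for one detector output on one trial.

A trial is scored by three components — false positive rate over the
post-baseline rest window, false negative rate over the move phase, and a
latency penalty — combined as their maximum (infinity norm):

    C = max(rFP, rFN, f(dt))                      C in [0, 1]

    f(dt) = 0 (dt < 0); dt/250 (0 <= dt < 250 ms); 1 (dt >= 250 ms or none)

The false positive rate is estimated on the 5 s of rest following the 3 s
threshold-baseline segment (and normalized by that window's length); the
false negative rate and the latency are estimated on the 5 s move phase.
A detector is "acceptable" on a trial when C <= 0.2, i.e. exactly when
rFP <= 0.2, rFN <= 0.2 and dt <= 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import DetectorOutput
from .signal_models import SimulatedTrial

__all__ = [
    "CostComponents",
    "false_positive_rate",
    "false_negative_rate",
    "detection_latency",
    "latency_penalty",
    "cost",
    "evaluate",
    "acceptance_rate",
]

#: baseline (threshold-estimation) duration in seconds
BASELINE_S = 3.0
#: latency saturation in ms
LATENCY_SATURATION_MS = 250.0
#: acceptable-cost bound
C_ACCEPT = 0.2


@dataclass(frozen=True)
class CostComponents:
    """(rFP, rFN, latency, latency penalty, cost) for one trial."""

    r_fp: float
    r_fn: float
    dt_ms: float | None
    f_dt: float
    cost: float


def false_positive_rate(y: np.ndarray, n_rest: int, fs: float) -> float:
    """Fraction of 1s in the post-baseline rest window."""
    start = int(round(BASELINE_S * fs))
    if not start < n_rest:
        raise ValueError("rest phase does not extend past the baseline segment")
    window = np.asarray(y[start:n_rest])
    return float(np.count_nonzero(window)) / window.size


def false_negative_rate(y: np.ndarray, n_rest: int) -> float:
    """Fraction of 0s in the move phase."""
    window = np.asarray(y[n_rest:])
    if window.size == 0:
        raise ValueError("empty move phase")
    return float(window.size - np.count_nonzero(window)) / window.size


def detection_latency(y: np.ndarray, n_rest: int, fs: float) -> float | None:
    """Delay (ms) from move-phase start to the first detection, or None."""
    move = np.asarray(y[n_rest:])
    hits = np.flatnonzero(move)
    if hits.size == 0:
        return None
    return float(hits[0]) * 1000.0 / fs


def latency_penalty(dt_ms: float | None) -> float:
    """Piecewise-linear latency cost, saturating at 250 ms; None maps to 1."""
    if dt_ms is None:
        return 1.0
    if dt_ms < 0.0:
        return 0.0
    if dt_ms >= LATENCY_SATURATION_MS:
        return 1.0
    return dt_ms / LATENCY_SATURATION_MS


def cost(r_fp: float, r_fn: float, f_dt: float) -> float:
    """Infinity norm of the cost vector."""
    return max(r_fp, r_fn, f_dt)


def evaluate(trial: SimulatedTrial, output: DetectorOutput) -> CostComponents:
    """Score a detector output against the trial's known phase boundary."""
    y = output.y
    if y.shape != trial.samples.shape:
        raise ValueError("detector output length does not match the trial")
    r_fp = false_positive_rate(y, trial.n_rest, trial.fs)
    r_fn = false_negative_rate(y, trial.n_rest)
    dt = detection_latency(y, trial.n_rest, trial.fs)
    f_dt = latency_penalty(dt)
    return CostComponents(r_fp=r_fp, r_fn=r_fn, dt_ms=dt, f_dt=f_dt, cost=cost(r_fp, r_fn, f_dt))


def acceptance_rate(costs, c_accept: float = C_ACCEPT) -> float:
    """Fraction of trials with cost <= c_accept (non-strict)."""
    costs = np.asarray(list(costs), dtype=float)
    if costs.size == 0:
        raise ValueError("empty cost list")
    return float(np.count_nonzero(costs <= c_accept)) / costs.size
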