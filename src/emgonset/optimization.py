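"""Brute-force grid search for detector parameters.

For every parameter combination the detector is run on each training trial
and the trial costs are reduced to a score

    P = sqrt(median(C)^2 + IQR(C)^2)

favouring combinations that are both good (low median) and consistent (low
spread).  The optimum is the arg-min of P, ties broken by enumeration
order over the sorted parameter grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detectors import PARAM_SCHEMAS, DetectorParams, detect
from .evaluation import evaluate

__all__ = ["GridSearch", "GridSearchResult", "combo_score", "default_grid", "grid_search"]

logger = logging.getLogger(__name__)


def combo_score(costs) -> tuple[float, float, float]:
    """(median, IQR, P) of a cost list; IQR uses linear-interpolation quartiles."""
    costs = np.asarray(list(costs), dtype=float)
    med = float(np.median(costs))
    q1, q3 = np.percentile(costs, [25.0, 75.0], method="linear")
    iqr = float(q3 - q1)
    return med, iqr, float(np.hypot(med, iqr))


DEFAULT_GRIDS: dict[str, dict[str, list[float]]] = {
    "Modified Hodges": {
        "alpha": [1, 2, 3, 4, 5],
        "fc": [3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5],
    },
    "Hodges": {
        "alpha": [1, 2, 3, 4, 5],
        "fc": [3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5],
        "W": [50, 100, 150, 200],
    },
    "Modified Lidierth": {
        "alpha": [1, 2, 3, 4, 5],
        "fc": [3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5],
        "m": [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55],
        "T1": [30, 60],
    },
    "Lidierth": {
        "alpha": [1, 2, 3, 4, 5],
        "W": [50, 100, 150, 200],
        "m": [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55],
        "T1": [30, 60],
    },
    # window/shift/persistence held at their published operating point
    "RMS": {"alpha": [1, 2, 3, 4, 5], "W": [120], "p": [40], "m": [40]},
    "TKEO": {
        "alpha": [1, 2, 3, 4, 5],
        "fc": [5, 10, 15, 20, 25, 30],
        "W": [50, 100, 150, 200],
        "T1": [30, 60],
    },
    "Bonato": {
        "alpha": [1, 2, 3, 4, 5],
        "m": [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55],
        "T1": [30, 60],
    },
    "AGLR-G": {"alpha": [1, 2, 3, 4, 5], "W": [50, 100, 150, 200]},
    "AGLR-L": {"alpha": [1, 2, 3, 4, 5], "W": [50, 100, 150, 200]},
    "Sample Entropy": {
        "alpha": [1, 2, 3, 4, 5],
        "W": [50, 60, 70, 80, 90, 100],
        "rho": [0.5, 1.0, 1.5],
    },
    "Fuzzy Entropy": {
        "alpha": [1, 2, 3, 4, 5],
        "W": [50, 60, 70, 80, 90, 100],
    },
    "CWT": {
        "alpha": [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 2.0, 3.0],
        "a": [4, 8, 16, 32, 64],
    },
    "SSA": {"W": [50, 52, 60, 80, 100, 150, 200]},
}


def default_grid(detector_type: str) -> dict[str, list[float]]:
    """Documented default parameter grid for a detector type."""
    if detector_type not in DEFAULT_GRIDS:
        raise ValueError(f"no default grid for detector {detector_type!r}")
    return {k: list(v) for k, v in DEFAULT_GRIDS[detector_type].items()}


@dataclass
class GridSearchResult:
    """Scores for every combination plus the arg-min combination."""

    detector_type: str
    combos: list[DetectorParams]
    costs: list[np.ndarray]
    table: pd.DataFrame = field(repr=False)
    best_index: int = 0

    @property
    def best_params(self) -> DetectorParams:
        return self.combos[self.best_index]

    @property
    def best_score(self) -> float:
        return float(self.table.loc[self.best_index, "P"])

    def summary(self) -> str:
        """Human-readable account of the search, best combination first."""
        ordered = self.table.sort_values("P")
        lines = [
            f"Grid search: {self.detector_type}"
            f" ({len(self.combos)} combinations, {self.costs[0].size} training trials)",
            f"best: {self.best_params.values}  "
            f"(median={self.table.loc[self.best_index, 'c_med']:.3f}, "
            f"IQR={self.table.loc[self.best_index, 'c_iqr']:.3f}, "
            f"P={self.best_score:.3f})",
            "",
            ordered.to_string(index=False),
        ]
        return "\n".join(lines)


def grid_search(
    detector_type: str,
    grid: dict[str, list[float]],
    training_trials,
) -> GridSearchResult:
    """Evaluate every combination on the training trials and pick the arg-min.

    A detector failure on a trial contributes the worst-case cost of 1 for
    that trial (and is logged) instead of aborting the search.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    if set(grid) != set(PARAM_SCHEMAS[detector_type]):
        raise ValueError(
            f"grid keys {sorted(grid)} do not match the {detector_type} schema "
            f"{sorted(PARAM_SCHEMAS[detector_type])}"
        )
    trials = list(training_trials)
    if len(trials) < 2:
        raise ValueError("grid search needs at least two training trials")

    names = sorted(grid)
    combos: list[DetectorParams] = []
    rows = []
    all_costs: list[np.ndarray] = []
    for values in itertools.product(*(grid[k] for k in names)):
        params = DetectorParams(detector_type, dict(zip(names, values)))
        costs = np.empty(len(trials))
        for t, trial in enumerate(trials):
            try:
                costs[t] = evaluate(trial, detect(trial, params)).cost
            except Exception:
                logger.exception(
                    "%s failed on trial %d with %s; assigning worst-case cost",
                    detector_type,
                    t,
                    params.values,
                )
                costs[t] = 1.0
        med, iqr, score = combo_score(costs)
        combos.append(params)
        all_costs.append(costs)
        rows.append({**params.values, "c_med": med, "c_iqr": iqr, "P": score})

    table = pd.DataFrame(rows)
    best = int(np.argmin(table["P"].to_numpy()))  # argmin keeps enumeration-order ties
    return GridSearchResult(
        detector_type=detector_type,
        combos=combos,
        costs=all_costs,
        table=table,
        best_index=best,
    )


class GridSearch:
    """Model-style front end: configure, ``fit`` on trials, inspect results."""

    def __init__(self, detector_type: str, grid: dict[str, list[float]] | None = None):
        self.detector_type = detector_type
        self.grid = grid if grid is not None else default_grid(detector_type)

    def fit(self, training_trials) -> GridSearchResult:
        return grid_search(self.detector_type, self.grid, training_trials)
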