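"""Deterministic sensitivity analysis: sweeps, thresholds, two-way maps.

Overriding a resection probability shifts mass to the strategy's residual
branch (NAT: no surgery, with exploratory surgery held at its baseline; SF:
exploratory-only surgery), which is how the baseline complements are defined.
Indifference thresholds are found by bisection on the between-strategy QALM
difference, so the result does not depend on any sweep grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import PathwayParams

__all__ = [
    "ThresholdResult",
    "SuperiorityMap",
    "apply_override",
    "one_way_sweep",
    "find_threshold",
    "two_way_map",
]


def apply_override(params: PathwayParams, param_id: str, value: float) -> PathwayParams:
    """Return params with one probability replaced; residual mass re-checked."""
    return params.with_value(param_id, value)


@dataclass(frozen=True)
class ThresholdResult:
    """An indifference threshold for one parameter."""

    param_id: str
    threshold: Optional[float]
    below: Optional[str]  # superior strategy below the threshold
    above: Optional[str]
    objective: str = "qalm"

    @property
    def found(self) -> bool:
        return self.threshold is not None


@dataclass(frozen=True)
class SuperiorityMap:
    """Winner per cell of a two-parameter grid (by QALM)."""

    id_a: str
    id_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    winner: np.ndarray  # (len(grid_a), len(grid_b)) of {"SF","NAT","tie"}
    best_qalm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.grid_a):
            for j, b in enumerate(self.grid_b):
                rows.append(
                    {
                        self.id_a: a,
                        self.id_b: b,
                        "winner": self.winner[i, j],
                        "best_qalm": self.best_qalm[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _objective_diff(model, params: PathwayParams, objective: str) -> float:
    out = model.evaluate_at(params)
    if objective == "qalm":
        return out.sf.qalms - out.nat.qalms
    if objective == "lm":
        return out.sf.life_months - out.nat.life_months
    raise ValueError(f"unknown objective {objective!r}")


def one_way_sweep(model, param_id: str, lo: float, hi: float, steps: int = 21) -> pd.DataFrame:
    """Evaluate both strategies along a grid of one parameter."""
    if not lo < hi:
        raise ValueError("lo must be below hi")
    grid = np.linspace(lo, hi, steps)
    rows = []
    for value in grid:
        out = model.evaluate_at(apply_override(model.params, param_id, float(value)))
        rows.append(
            {
                "value": value,
                "sf_lm": out.sf.life_months,
                "sf_qalm": out.sf.qalms,
                "nat_lm": out.nat.life_months,
                "nat_qalm": out.nat.qalms,
            }
        )
    return pd.DataFrame(rows)


def find_threshold(
    model,
    param_id: str,
    lo: float,
    hi: float,
    tol: float = 1e-4,
    objective: str = "qalm",
) -> ThresholdResult:
    """Bisect the SF-minus-NAT difference to locate the indifference point.

    Returns a no-threshold result when the difference does not change sign on
    ``[lo, hi]`` (including the degenerate case of a parameter with no effect).
    """
    f_lo = _objective_diff(model, apply_override(model.params, param_id, lo), objective)
    f_hi = _objective_diff(model, apply_override(model.params, param_id, hi), objective)
    if f_lo == 0.0 and f_hi == 0.0:
        return ThresholdResult(param_id, None, None, None, objective)
    if f_lo * f_hi > 0:
        winner = "SF" if f_lo > 0 else "NAT"
        return ThresholdResult(param_id, None, winner, winner, objective)
    a, b, f_a = lo, hi, f_lo
    while b - a > tol:
        mid = 0.5 * (a + b)
        f_mid = _objective_diff(model, apply_override(model.params, param_id, mid), objective)
        if f_a * f_mid <= 0:
            b = mid
        else:
            a, f_a = mid, f_mid
    threshold = 0.5 * (a + b)
    below = "SF" if f_lo > 0 else "NAT"
    above = "NAT" if below == "SF" else "SF"
    return ThresholdResult(param_id, threshold, below, above, objective)


def two_way_map(
    model,
    id_a: str,
    id_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    tie_tol: float = 0.01,
) -> SuperiorityMap:
    """QALM winner over a two-parameter grid; |difference| < tie_tol is a tie."""
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if np.any(np.diff(grid_a) <= 0) or np.any(np.diff(grid_b) <= 0):
        raise ValueError("grids must be strictly increasing")
    winner = np.empty((grid_a.size, grid_b.size), dtype=object)
    best = np.empty((grid_a.size, grid_b.size))
    for i, a in enumerate(grid_a):
        pa = apply_override(model.params, id_a, float(a))
        for j, b in enumerate(grid_b):
            out = model.evaluate_at(apply_override(pa, id_b, float(b)))
            diff = out.sf.qalms - out.nat.qalms
            if abs(diff) < tie_tol:
                winner[i, j] = "tie"
                best[i, j] = max(out.sf.qalms, out.nat.qalms)
            elif diff > 0:
                winner[i, j] = "SF"
                best[i, j] = out.sf.qalms
            else:
                winner[i, j] = "NAT"
                best[i, j] = out.nat.qalms
    return SuperiorityMap(id_a, id_b, grid_a, grid_b, winner, best)
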