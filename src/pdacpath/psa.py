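"""Probabilistic sensitivity analysis: seeded Monte Carlo over the model.

Each iteration draws all twelve transition probabilities, re-balances the
branch complements, re-evaluates both strategies' rollups, and records the
expected life-months and QALMs. Three sampling rules are available per
parameter (``sampling=``):

``range`` (default)
    Uniform over the parameter's reported lowest-to-highest study range —
    the reading that every probability is "sampled from the entire range" of
    its data distribution.
``beta``
    A beta distribution moment-matched to the parameter's point estimate and
    standard deviation, truncated to the reported range by inverse-CDF
    restriction. If the printed moments are infeasible for a beta law the
    sampler falls back to uniform over the range, with a warning.
``fitted``
    The literal fitted parametric distribution attached to the parameter,
    clamped to [0, 1]. The fitted parameters sit on a scale far below the
    baseline probabilities, so this mode exists for comparison, not as a
    recommended default.

All randomness flows from one seeded generator; parameters are drawn in their
declared order so the sample stream is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
from scipy import stats

from . import distributions as dist
from .parameters import PARAM_ORDER, PathwayParams, ProportionEstimate

logger = logging.getLogger(__name__)

__all__ = ["PSAResult", "run_psa", "indifference_rate", "build_samplers"]

_SAMPLING_MODES = ("range", "beta", "fitted")


def _constant(value: float):
    return lambda u: np.full_like(u, value)


def _uniform_range(est: ProportionEstimate):
    lo, hi = est.range_low, est.range_high
    if hi <= lo:
        return _constant(lo)
    return lambda u: lo + u * (hi - lo)


def _beta_truncated(param_id: str, est: ProportionEstimate):
    m, s = est.point, est.sd
    if s == 0.0 or m <= 0.0 or m >= 1.0:
        return _constant(m)
    nu = m * (1.0 - m) / (s * s) - 1.0
    if nu <= 0.0:
        logger.warning(
            "%s: sd %.4g infeasible for a beta with mean %.3g; falling back to "
            "uniform over the reported range",
            param_id, s, m,
        )
        return _uniform_range(est)
    d = stats.beta(m * nu, (1.0 - m) * nu)
    f_lo, f_hi = d.cdf(est.range_low), d.cdf(est.range_high)
    if f_hi - f_lo < 1e-12:
        return _constant(min(max(m, est.range_low), est.range_high))
    return lambda u: d.ppf(f_lo + u * (f_hi - f_lo))


def _fitted(param_id: str, est: ProportionEstimate):
    if est.distribution is None:
        raise ValueError(f"{param_id}: no fitted distribution attached")
    frozen = dist.frozen(est.distribution)
    return lambda u: np.asarray(frozen.ppf(u), dtype=float)


def build_samplers(params: PathwayParams, sampling: str) -> Dict[str, object]:
    """One quantile-style sampler (uniform -> value) per parameter id."""
    if sampling not in _SAMPLING_MODES:
        raise ValueError(f"unknown sampling mode {sampling!r}; choose from {_SAMPLING_MODES}")
    samplers = {}
    for pid in PARAM_ORDER:
        est = params.get(pid)
        if sampling == "range":
            samplers[pid] = _uniform_range(est)
        elif sampling == "beta":
            samplers[pid] = _beta_truncated(pid, est)
        else:
            samplers[pid] = _fitted(pid, est)
    return samplers


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration strategy expectations and their aggregates."""

    sf_lm: np.ndarray
    nat_lm: np.ndarray
    sf_qalm: np.ndarray
    nat_qalm: np.ndarray
    seed: Optional[int]
    sampling: str

    @property
    def n_iter(self) -> int:
        return self.sf_lm.size

    def stats(self, strategy: str, measure: str = "lm") -> Dict[str, float]:
        x = getattr(self, f"{strategy.lower()}_{measure}")
        sd = float(np.std(x))
        return {
            "mean": float(np.mean(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "sd": sd,
            "variance": sd**2,
            "n_iter": self.n_iter,
        }

    def summary_frame(self):
        import pandas as pd

        rows = []
        for strategy in ("sf", "nat"):
            for measure in ("lm", "qalm"):
                rows.append(
                    {"strategy": strategy.upper(), "measure": measure.upper(),
                     **self.stats(strategy, measure)}
                )
        return pd.DataFrame(rows)

    def iteration_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "sf_lm": self.sf_lm,
                "nat_lm": self.nat_lm,
                "sf_qalm": self.sf_qalm,
                "nat_qalm": self.nat_qalm,
            }
        )

    def indifference(self, msd: float = 3.65, measure: str = "lm") -> Dict[str, float]:
        return indifference_rate(self, msd=msd, measure=measure)


def indifference_rate(result: PSAResult, msd: float = 3.65, measure: str = "lm") -> Dict[str, float]:
    """Fraction of iterations where neither strategy wins by >= ``msd``.

    Returns the indifference rate together with the per-strategy win
    frequencies at that minimum significant difference.
    """
    diff = getattr(result, f"sf_{measure}") - getattr(result, f"nat_{measure}")
    return {
        "msd": msd,
        "indifference": float(np.mean(np.abs(diff) < msd)),
        "sf_wins": float(np.mean(diff >= msd)),
        "nat_wins": float(np.mean(diff <= -msd)),
    }


def run_psa(
    model,
    n_iter: int = 10000,
    seed: "int | np.random.SeedSequence | None" = None,
    sampling: str = "range",
) -> PSAResult:
    """Monte Carlo over the decision model; reproducible given ``seed``."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    samplers = build_samplers(model.params, sampling)
    draws: Dict[str, np.ndarray] = {}
    for pid in PARAM_ORDER:  # fixed draw order keeps the stream stable
        x = np.asarray(samplers[pid](rng.random(n_iter)), dtype=float)
        clamped = int(np.sum((x < 0.0) | (x > 1.0)))
        if clamped:
            x = np.clip(x, 0.0, 1.0)
            if clamped > 0.01 * n_iter:
                logger.warning("%s: clamped %d/%d draws to [0, 1]", pid, clamped, n_iter)
        draws[pid] = x

    # residual-branch rebalancing: exploratory surgery yields to resection
    over = draws["nat.resect"] + draws["nat.explore"] > 1.0
    if np.any(over):
        if over.sum() > 0.01 * n_iter:
            logger.warning(
                "nat residual rebalanced in %d/%d iterations", int(over.sum()), n_iter
            )
        draws["nat.explore"] = np.where(
            over, 1.0 - draws["nat.resect"], draws["nat.explore"]
        )

    sf_lm = np.empty(n_iter)
    nat_lm = np.empty(n_iter)
    sf_qalm = np.empty(n_iter)
    nat_qalm = np.empty(n_iter)
    base = model.params
    for i in range(n_iter):
        nat = {
            name: replace(
                base.nat[name],
                point=(v := float(draws[f"nat.{name}"][i])),
                ci_low=min(base.nat[name].ci_low, v),
                ci_high=max(base.nat[name].ci_high, v),
            )
            for name in base.nat
        }
        sf = {
            name: replace(
                base.sf[name],
                point=(v := float(draws[f"sf.{name}"][i])),
                ci_low=min(base.sf[name].ci_low, v),
                ci_high=max(base.sf[name].ci_high, v),
            )
            for name in base.sf
        }
        out = model.evaluate_at(PathwayParams(nat=nat, sf=sf))
        sf_lm[i], sf_qalm[i] = out.sf.life_months, out.sf.qalms
        nat_lm[i], nat_qalm[i] = out.nat.life_months, out.nat.qalms

    return PSAResult(
        sf_lm=sf_lm,
        nat_lm=nat_lm,
        sf_qalm=sf_qalm,
        nat_qalm=nat_qalm,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        sampling=sampling,
    )
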