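"""Synthetic literature pools with known ground truth.

Emulates the kind of trial pool the model's parameters are pooled from: per
study a sample size drawn from the observed size spread, binomial outcome
counts around true proportions with between-study heterogeneity injected on
the arcsine-square-root scale (the scale the pooling model works on), and a
median overall survival drawn from the sampling distribution of a sample
median of exponential lifetimes. Everything is reproducible from a seed,
which makes parameter-recovery experiments for the pooling estimators cheap.

What this generator does NOT emulate: publication bias, outcome-reporting
differences between trials, non-exponential survival shapes, or correlation
between outcomes within a study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .parameters import Pathway, StudyDesign, StudyRecord
from .pooling import ft_transform, pool_random_effects, pooled_median

__all__ = ["SyntheticPoolConfig", "generate_study_pool", "recovery_experiment"]


@dataclass(frozen=True)
class SyntheticPoolConfig:
    """Ground truth and pool geometry for one synthetic literature pool.

    Defaults mirror the real pool feeding the model: 50 trials with 11 to 121
    patients each, outcome proportions at the baseline transition
    probabilities, moderate between-study heterogeneity (tau = 0.05 on the
    arcsine scale), and a true median overall survival of 17 months.
    """

    k_studies: int = 50
    n_range: Tuple[int, int] = (11, 121)
    true_proportions: Dict[str, float] = field(
        default_factory=lambda: {"resect": 0.41, "tox3": 0.35, "explore": 0.10}
    )
    tau: float = 0.05
    true_median_os: float = 17.0
    pathway: Pathway = Pathway.NAT
    design: StudyDesign = StudyDesign.PHASE2
    exact_medians: bool = False  # order-statistic simulation instead of the
    # asymptotic normal approximation

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not (1 <= self.n_range[0] <= self.n_range[1]):
            raise ValueError(f"invalid n_range {self.n_range}")
        for name, p in self.true_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"true proportion {name}={p} outside [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.true_median_os <= 0:
            raise ValueError("true median must be positive")


def _study_proportion(p_true: float, tau: float, rng: np.random.Generator) -> float:
    """Study-level proportion: heterogeneity on the arcsine-sqrt scale."""
    theta = math.asin(math.sqrt(p_true)) + rng.normal(0.0, tau)
    return math.sin(min(max(theta, 0.0), math.pi / 2)) ** 2


def _study_median(m_true: float, n: int, cfg: SyntheticPoolConfig, rng) -> float:
    lam = math.log(2.0) / m_true
    if cfg.exact_medians:
        return float(np.median(rng.exponential(1.0 / lam, size=n)))
    # asymptotic: sd of the sample median of n exponential lifetimes is
    # 1 / (2 sqrt(n) f(m)) with density f(m) = lam / 2 at the median
    sd = 1.0 / (lam * math.sqrt(n))
    draw = rng.normal(m_true, sd)
    return max(draw, 0.05 * m_true)  # keep medians positive


def generate_study_pool(
    cfg: SyntheticPoolConfig, seed: "int | np.random.Generator | None" = None
) -> List[StudyRecord]:
    """Draw one synthetic pool of trial arms; identical pools for equal seeds."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for i in range(cfg.k_studies):
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        events = {
            outcome: int(rng.binomial(n, _study_proportion(p, cfg.tau, rng)))
            for outcome, p in cfg.true_proportions.items()
        }
        records.append(
            StudyRecord(
                study_id=f"synth_{i:03d}",
                pathway=cfg.pathway,
                design=cfg.design,
                n=n,
                events=events,
                median_os=_study_median(cfg.true_median_os, n, cfg, rng),
            )
        )
    return records


def recovery_experiment(
    cfg: SyntheticPoolConfig,
    replicates: int = 200,
    seed: "int | None" = None,
) -> pd.DataFrame:
    """Bias and CI coverage of the pooling estimators on synthetic pools.

    Per replicate: generate a pool, pool every outcome with the
    random-effects estimator and the medians with the exponential-hazard
    estimator, and compare against the configured truth. Returns one row per
    parameter with the mean estimate, bias, and 95% CI coverage (coverage is
    NaN for the median, whose pooling carries no interval).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    est: Dict[str, List[float]] = {o: [] for o in cfg.true_proportions}
    cover: Dict[str, List[bool]] = {o: [] for o in cfg.true_proportions}
    med_est: List[float] = []
    for _ in range(replicates):
        pool = generate_study_pool(cfg, rng)
        for outcome, p_true in cfg.true_proportions.items():
            pooled = pool_random_effects(
                [ft_transform(r.events[outcome], r.n) for r in pool]
            )
            est[outcome].append(pooled.point)
            cover[outcome].append(pooled.ci_low <= p_true <= pooled.ci_high)
        med_est.append(
            pooled_median([(r.median_os, r.n) for r in pool if r.median_os]).m_p
        )
    rows = []
    for outcome, p_true in cfg.true_proportions.items():
        mean_est = float(np.mean(est[outcome]))
        rows.append(
            {
                "parameter": outcome,
                "truth": p_true,
                "mean_estimate": mean_est,
                "bias": mean_est - p_true,
                "coverage": float(np.mean(cover[outcome])),
            }
        )
    mean_med = float(np.mean(med_est))
    rows.append(
        {
            "parameter": "median_os",
            "truth": cfg.true_median_os,
            "mean_estimate": mean_med,
            "bias": mean_med - cfg.true_median_os,
            "coverage": float("nan"),
        }
    )
    return pd.DataFrame(rows)
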