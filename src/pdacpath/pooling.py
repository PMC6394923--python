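"""Meta-analytic synthesis of model inputs from a literature pool.

Two estimators:

* Pooled event proportions via the Freeman-Tukey double-arcsine transform
  under a DerSimonian-Laird random-effects model. The transform
  ``t = (asin(sqrt(r/(n+1))) + asin(sqrt((r+1)/(n+1)))) / 2`` stabilises the
  binomial variance at ``1/(4n+2)`` so that inverse-variance weighting is
  well behaved even at r = 0 or r = n; the pooled value is mapped back to the
  probability scale with Miller's inverse using the harmonic mean sample size.

* Pooled median overall survival under an exponential survival model: each
  study's median ``m_i`` implies a constant hazard ``lambda_i = ln 2 / m_i``;
  hazards are averaged with size weights ``w_i = n_i / sum(n)`` and the pooled
  median recovered as ``ln 2 / lambda_p`` — a weighted harmonic mean of the
  study medians. Averaging the medians themselves is biased, which is why the
  hazard-scale route is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .parameters import ProportionEstimate, StudyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TransformedStudy",
    "PooledMedian",
    "ft_transform",
    "ft_inverse",
    "pool_random_effects",
    "pooled_median",
    "pool_outcome",
    "pool_study_records",
]


@dataclass(frozen=True)
class TransformedStudy:
    """One study's double-arcsine transformed proportion."""

    t: float
    var_t: float
    n: int
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= math.pi / 2 + 1e-12):
            raise ValueError(f"transformed value {self.t} outside [0, pi/2]")
        if self.var_t <= 0:
            raise ValueError("var_t must be positive")


@dataclass(frozen=True)
class PooledMedian:
    """Size-weighted exponential-hazard pooling of study medians."""

    m_p: float
    weights: np.ndarray
    hazards: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def ft_transform(r: int, n: int) -> TransformedStudy:
    """Freeman-Tukey double-arcsine transform of ``r`` events in ``n`` patients."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not (0 <= r <= n):
        raise ValueError(f"event count {r} outside [0, n={n}]")
    t = 0.5 * (math.asin(math.sqrt(r / (n + 1.0))) + math.asin(math.sqrt((r + 1.0) / (n + 1.0))))
    return TransformedStudy(t=t, var_t=1.0 / (4.0 * n + 2.0), n=n)


def ft_inverse(t_pooled: float, n_inv_mean: float) -> float:
    """Miller's back-transform of a pooled double-arcsine value.

    ``n_inv_mean`` is the mean of 1/n over studies, i.e. the reciprocal of the
    harmonic mean sample size. Values of ``t_pooled`` at or beyond the
    transform's boundaries clamp to 0 or 1.
    """
    if t_pooled <= 0.0:
        return 0.0
    if t_pooled >= math.pi / 2:
        return 1.0
    s = math.sin(2.0 * t_pooled)
    c = math.cos(2.0 * t_pooled)
    inner = s + (s - 1.0 / s) * n_inv_mean
    radicand = max(0.0, 1.0 - inner * inner)
    p = 0.5 * (1.0 - math.copysign(1.0, c) * math.sqrt(radicand))
    return min(1.0, max(0.0, p))


def pool_random_effects(studies: Sequence[TransformedStudy]) -> ProportionEstimate:
    """DerSimonian-Laird random-effects pooling on the double-arcsine scale.

    Returns the back-transformed pooled proportion with a 95% CI. The
    between-study variance tau^2 is the moment estimator from Cochran's Q,
    floored at zero; with a single study the study's own estimate is returned
    with a warning.
    """
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    t = np.array([s.t for s in studies])
    v = np.array([s.var_t for s in studies])
    n = np.array([s.n for s in studies], dtype=float)
    n_inv_mean = float(np.mean(1.0 / n))

    if len(studies) == 1:
        logger.warning("pooling a single study: returning its own estimate")
        tau2 = 0.0
        w_star = 1.0 / v
    else:
        w = 1.0 / v
        t_fixed = float(np.sum(w * t) / np.sum(w))
        q = float(np.sum(w * (t - t_fixed) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (len(studies) - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (v + tau2)

    t_pooled = float(np.sum(w_star * t) / np.sum(w_star))
    se = math.sqrt(1.0 / float(np.sum(w_star)))
    z = 1.959963984540054
    lo_t, hi_t = t_pooled - z * se, t_pooled + z * se

    point = ft_inverse(t_pooled, n_inv_mean)
    ci_low = ft_inverse(lo_t, n_inv_mean)
    ci_high = ft_inverse(hi_t, n_inv_mean)
    # delta-method sd on the probability scale: dp/dt ~ sin(2t)
    sd_p = se * abs(math.sin(2.0 * t_pooled))

    props = np.array([ft_inverse(s.t, 1.0 / s.n) for s in studies])
    return ProportionEstimate(
        point=point,
        ci_low=min(ci_low, point),
        ci_high=max(ci_high, point),
        range_low=float(props.min()),
        range_high=float(props.max()),
        sd=sd_p,
    )


def pooled_median(studies: Iterable[Tuple[float, int]]) -> PooledMedian:
    """Pool study medians ``(m_i, n_i)`` via exponential hazards.

    ``m_p = (sum_i w_i / m_i)^-1`` with ``w_i = n_i / sum(n)``: the weighted
    harmonic mean of the medians, equivalently ``ln 2`` over the size-weighted
    mean hazard.
    """
    pairs = list(studies)
    if not pairs:
        raise ValueError("at least one study is required")
    m = np.array([p[0] for p in pairs], dtype=float)
    n = np.array([p[1] for p in pairs], dtype=float)
    if np.any(m <= 0):
        raise ValueError("all medians must be positive")
    if np.any(n < 1):
        raise ValueError("all sample sizes must be >= 1")
    w = n / n.sum()
    hazards = math.log(2.0) / m
    lambda_p = float(np.sum(w * hazards))
    return PooledMedian(m_p=math.log(2.0) / lambda_p, weights=w, hazards=hazards)


def pool_outcome(records: Sequence[StudyRecord], outcome: str) -> ProportionEstimate:
    """Pool one named event outcome across all records reporting it."""
    transformed = [ft_transform(r.events[outcome], r.n) for r in records if outcome in r.events]
    if not transformed:
        raise ValueError(f"no study reports outcome {outcome!r}")
    return pool_random_effects(transformed)


def pool_study_records(records: Sequence[StudyRecord]) -> "Dict[str, dict]":
    """Pool every reported outcome and the median OS, per pathway.

    Returns ``{pathway: {"proportions": {outcome: ProportionEstimate},
    "median_os": PooledMedian | None, "k_studies": int}}`` — the shape the
    ``pool`` CLI subcommand serialises.
    """
    out: Dict[str, dict] = {}
    for pathway in sorted({r.pathway for r in records}, key=lambda p: p.value):
        sub = [r for r in records if r.pathway == pathway]
        outcomes = sorted({o for r in sub for o in r.events})
        props = {o: pool_outcome(sub, o) for o in outcomes}
        med_pairs = [(r.median_os, r.n) for r in sub if r.median_os is not None]
        out[pathway.value] = {
            "proportions": props,
            "median_os": pooled_median(med_pairs) if med_pairs else None,
            "k_studies": len(sub),
        }
    return out
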