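"""Parametric families for probabilistic sensitivity analysis.

Each family is registered with the parameter names used in decision-analysis
tooling (shape ``k``, scale ``sigma``, location ``mu`` for the extreme-value
families; ``gamma``/``delta``/``lambda``/``xi`` for Johnson SB; and so on) and
is backed by the corresponding scipy.stats distribution where one exists.
Log-Pearson 3 — the logarithm following a Pearson type III law, possibly with
negative scale — is assembled from scipy's gamma because scipy has no such
family.

The module provides quantile/CDF evaluation, maximum-likelihood fitting with
explicit convergence flagging, the Anderson-Darling goodness-of-fit statistic
``A^2 = -n - (1/n) * sum_i (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))]``, and
best-fit selection by minimal A^2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .parameters import DistributionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "FitResult",
    "FitError",
    "frozen",
    "quantile",
    "cdf",
    "sample",
    "fit_mle",
    "anderson_darling",
    "select_best_fit",
]


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted or every candidate fails."""


class _LogPearson3:
    """ln X ~ Pearson III: ln x = gamma + beta * G with G ~ Gamma(alpha).

    ``beta`` may be negative, giving support (0, exp(gamma)); positive beta
    gives support (exp(gamma), inf).
    """

    def __init__(self, alpha: float, beta: float, gamma: float):
        if alpha <= 0:
            raise ValueError("LogPearson3 alpha must be positive")
        if beta == 0:
            raise ValueError("LogPearson3 beta must be nonzero")
        self.alpha, self.beta, self.gamma = alpha, beta, gamma
        self._g = stats.gamma(a=alpha)

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if self.beta > 0:
            g = self._g.ppf(u)
        else:
            g = self._g.ppf(1.0 - u)
        return np.exp(self.gamma + self.beta * g)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        z = (np.log(np.where(pos, x, 1.0)) - self.gamma) / self.beta
        inner = self._g.cdf(z)
        out[pos] = inner[pos] if self.beta > 0 else 1.0 - inner[pos]
        out[~pos] = 0.0 if self.beta > 0 else (x[~pos] * 0.0)
        if self.beta < 0:
            out[~pos] = 0.0
        return out

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.log(x) - self.gamma) / self.beta
            lp = self._g.logpdf(z) - math.log(abs(self.beta)) - np.log(x)
        return np.where((x > 0) & np.isfinite(lp), lp, -np.inf)


@dataclass(frozen=True)
class Family:
    name: str
    param_names: tuple
    make: Callable[[Dict[str, float]], object]
    fit: Callable[[np.ndarray], Dict[str, float]]


def _require_positive(params: Dict[str, float], *names: str) -> None:
    for n in names:
        if params[n] <= 0:
            raise ValueError(f"parameter {n!r} must be strictly positive, got {params[n]}")


def _gev_make(p):
    _require_positive(p, "sigma")
    return stats.genextreme(c=-p["k"], loc=p["mu"], scale=p["sigma"])


def _gev_fit(x):
    c, loc, scale = stats.genextreme.fit(x)
    return {"k": -c, "sigma": scale, "mu": loc}


def _gpd_make(p):
    _require_positive(p, "sigma")
    return stats.genpareto(c=p["k"], loc=p["mu"], scale=p["sigma"])


def _gpd_fit(x):
    c, loc, scale = stats.genpareto.fit(x)
    return {"k": c, "sigma": scale, "mu": loc}


def _jsb_make(p):
    _require_positive(p, "delta", "lambda")
    return stats.johnsonsb(a=p["gamma"], b=p["delta"], loc=p["xi"], scale=p["lambda"])


def _jsb_fit(x):
    a, b, loc, scale = stats.johnsonsb.fit(x)
    return {"gamma": a, "delta": b, "lambda": scale, "xi": loc}


def _burr_make(p):
    _require_positive(p, "k", "alpha", "beta")
    return stats.burr12(c=p["alpha"], d=p["k"], scale=p["beta"])


def _burr_fit(x):
    c, d, _loc, scale = stats.burr12.fit(x, floc=0)
    return {"k": d, "alpha": c, "beta": scale}


def _p5_make(p):
    _require_positive(p, "alpha", "beta")
    return stats.invgamma(a=p["alpha"], scale=p["beta"])


def _p5_fit(x):
    a, _loc, scale = stats.invgamma.fit(x, floc=0)
    return {"alpha": a, "beta": scale}


def _lp3_make(p):
    return _LogPearson3(p["alpha"], p["beta"], p["gamma"])


def _lp3_fit(x):
    if np.any(x <= 0):
        raise FitError("LogPearson3 requires strictly positive data")
    skew, loc, scale = stats.pearson3.fit(np.log(x))
    if abs(skew) < 1e-6:
        raise FitError("LogPearson3 fit degenerated to zero skew (lognormal limit)")
    alpha = 4.0 / skew**2
    beta = math.copysign(scale / math.sqrt(alpha), skew)
    gamma = loc - alpha * beta
    return {"alpha": alpha, "beta": beta, "gamma": gamma}


def _cauchy_make(p):
    _require_positive(p, "sigma")
    return stats.cauchy(loc=p["mu"], scale=p["sigma"])


def _cauchy_fit(x):
    loc, scale = stats.cauchy.fit(x)
    return {"mu": loc, "sigma": scale}


def _pareto2_make(p):
    _require_positive(p, "alpha", "beta")
    return stats.lomax(c=p["alpha"], scale=p["beta"])


def _pareto2_fit(x):
    c, _loc, scale = stats.lomax.fit(x, floc=0)
    return {"alpha": c, "beta": scale}


def _norm_make(p):
    _require_positive(p, "sigma")
    return stats.norm(loc=p["mu"], scale=p["sigma"])


def _lognorm_make(p):
    _require_positive(p, "sigma")
    return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))


def _beta_make(p):
    _require_positive(p, "alpha", "beta")
    return stats.beta(a=p["alpha"], b=p["beta"])


def _gamma_make(p):
    _require_positive(p, "alpha", "beta")
    return stats.gamma(a=p["alpha"], scale=p["beta"])


def _weibull_make(p):
    _require_positive(p, "alpha", "beta")
    return stats.weibull_min(c=p["alpha"], scale=p["beta"])


def _expon_make(p):
    _require_positive(p, "lambda")
    return stats.expon(scale=1.0 / p["lambda"])


def _lognorm_fit(x):
    s, _loc, scale = stats.lognorm.fit(x, floc=0)
    return {"sigma": s, "mu": math.log(scale)}


def _gamma_fit(x):
    a, _loc, scale = stats.gamma.fit(x, floc=0)
    return {"alpha": a, "beta": scale}


def _weibull_fit(x):
    c, _loc, scale = stats.weibull_min.fit(x, floc=0)
    return {"alpha": c, "beta": scale}


FAMILIES: Dict[str, Family] = {
    f.name: f
    for f in [
        Family("GeneralizedExtremeValue", ("k", "sigma", "mu"), _gev_make, _gev_fit),
        Family("GeneralizedPareto", ("k", "sigma", "mu"), _gpd_make, _gpd_fit),
        Family("JohnsonSB", ("gamma", "delta", "lambda", "xi"), _jsb_make, _jsb_fit),
        Family("Burr", ("k", "alpha", "beta"), _burr_make, _burr_fit),
        Family("Pearson5", ("alpha", "beta"), _p5_make, _p5_fit),
        Family("LogPearson3", ("alpha", "beta", "gamma"), _lp3_make, _lp3_fit),
        Family("Cauchy", ("sigma", "mu"), _cauchy_make, _cauchy_fit),
        Family("Pareto2", ("alpha", "beta"), _pareto2_make, _pareto2_fit),
        Family(
            "Normal", ("mu", "sigma"), _norm_make,
            lambda x: dict(zip(("mu", "sigma"), stats.norm.fit(x))),
        ),
        Family("LogNormal", ("mu", "sigma"), _lognorm_make, _lognorm_fit),
        Family(
            "Beta", ("alpha", "beta"), _beta_make,
            lambda x: dict(zip(("alpha", "beta"), stats.beta.fit(x, floc=0, fscale=1)[:2])),
        ),
        Family("Gamma", ("alpha", "beta"), _gamma_make, _gamma_fit),
        Family("Weibull", ("alpha", "beta"), _weibull_make, _weibull_fit),
        Family(
            "Exponential", ("lambda",), _expon_make,
            lambda x: {"lambda": 1.0 / stats.expon.fit(x, floc=0)[1]},
        ),
    ]
}


def frozen(spec: DistributionSpec):
    """The frozen distribution object (ppf/cdf/logpdf) behind a spec."""
    try:
        family = FAMILIES[spec.family]
    except KeyError:
        raise ValueError(f"unknown distribution family {spec.family!r}") from None
    missing = [n for n in family.param_names if n not in spec.params]
    if missing:
        raise ValueError(f"{spec.family}: missing parameters {missing}")
    return family.make(spec.params)


def quantile(spec: DistributionSpec, u) -> "float | np.ndarray":
    """Inverse CDF of the spec at uniform variate(s) ``u`` in (0, 1)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr <= 0.0) | (u_arr >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = frozen(spec).ppf(u_arr)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def cdf(spec: DistributionSpec, x) -> "float | np.ndarray":
    out = frozen(spec).cdf(np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) else out


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling (keeps the uniform stream the only RNG source)."""
    return np.asarray(frozen(spec).ppf(rng.random(n)), dtype=float)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit, converged or not."""

    spec: DistributionSpec
    converged: bool
    loglike: float
    message: str = ""


def fit_mle(data: Sequence[float], family: str) -> FitResult:
    """Fit one family by maximum likelihood; failures are flagged, not hidden."""
    x = np.asarray(data, dtype=float)
    if x.size < 5:
        raise FitError(f"need at least 5 observations, got {x.size}")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate (constant) sample cannot be fitted")
    fam = FAMILIES[family]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = fam.fit(x)
            if not all(np.isfinite(list(params.values()))):
                raise FitError("non-finite parameter estimate")
            dist = fam.make(params)
            ll = float(np.sum(dist.logpdf(x)))
        spec = DistributionSpec(family=family, params=params)
        if not np.isfinite(ll):
            return FitResult(spec, False, ll, "non-finite log-likelihood at optimum")
        return FitResult(spec, True, ll)
    except FitError:
        raise
    except Exception as exc:  # scipy optimizers raise a zoo of exceptions
        return FitResult(
            DistributionSpec(family=family, params={}), False, -np.inf, f"fit failed: {exc}"
        )


def anderson_darling(data: Sequence[float], spec: DistributionSpec) -> float:
    """Anderson-Darling A^2 of ``data`` against the spec's CDF.

    CDF values exactly 0 or 1 at a data point are clamped away from the
    boundary (with a warning) so the statistic stays finite.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one observation")
    f = np.asarray(frozen(spec).cdf(x), dtype=float)
    eps = 1e-12
    if np.any((f <= 0.0) | (f >= 1.0)):
        logger.warning("CDF hit 0 or 1 at a data point; clamping for A^2")
        f = np.clip(f, eps, 1.0 - eps)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(f) + np.log(1.0 - f[::-1]))))


def select_best_fit(
    data: Sequence[float], families: Sequence[str], return_all: bool = False
):
    """Fit every candidate family and keep the converged fit with minimal A^2.

    Ties (identical A^2) resolve to the family declared first, with a log
    message; if every fit fails a :class:`FitError` is raised.
    """
    if len(families) < 1:
        raise ValueError("at least one candidate family is required")
    results: List[tuple] = []
    for family in families:
        try:
            res = fit_mle(data, family)
        except FitError as exc:
            logger.warning("%s: %s", family, exc)
            continue
        if not res.converged:
            logger.warning("%s: %s", family, res.message)
            continue
        a2 = anderson_darling(data, res.spec)
        results.append((a2, family, res))
    if not results:
        raise FitError("no candidate family produced a converged fit")
    best_a2 = min(a2 for a2, _, _ in results)
    winners = [r for r in results if r[0] == best_a2]
    if len(winners) > 1:
        logger.info("A^2 tie between %s; keeping first-declared", [w[1] for w in winners])
    a2, family, res = winners[0]
    spec = DistributionSpec(family=family, params=res.spec.params, ad_stat=a2)
    if return_all:
        return spec, {fam: (a, r) for a, fam, r in results}
    return spec
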