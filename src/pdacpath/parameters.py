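"""Domain data model for the two-pathway decision analysis.

Holds the transition-probability estimates, their uncertainty descriptions
(confidence interval, reported range, standard deviation, fitted parametric
distribution), the QALM utility weights, and the per-cohort Markov payoffs,
together with readers/writers for the YAML config and the study-record CSV.

All probabilities are validated on construction: points must lie in [0, 1],
confidence intervals must bracket their point estimate, and within a strategy
the branch probabilities that share a chance node may not exceed unit mass.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Pathway",
    "StudyDesign",
    "HealthPhase",
    "StudyRecord",
    "ProportionEstimate",
    "DistributionSpec",
    "UtilityTable",
    "PathwayParams",
    "CohortPayoff",
    "ModelInputs",
    "ConfigError",
    "load_config",
    "save_config",
    "load_study_records",
    "save_study_records",
    "baseline_config_path",
    "bundled_studies_path",
    "NAT_PARAM_NAMES",
    "SF_PARAM_NAMES",
    "PARAM_ORDER",
]


class ConfigError(ValueError):
    """Raised when a config or study-record file violates the schema."""


class Pathway(str, Enum):
    NAT = "NAT"
    SF = "SF"


class StudyDesign(str, Enum):
    RCT = "RCT"
    PHASE2 = "phase2"
    COHORT = "cohort"


class HealthPhase(str, Enum):
    """Quality-of-life phases carrying a utility weight (dead is implicitly 0)."""

    STABLE_DISEASE = "stable_disease"
    ON_CHEMORADIOTHERAPY = "on_chemoradiotherapy"
    CHEMO_TOXICITY = "chemo_toxicity"
    SURGICAL_RECOVERY = "surgical_recovery"
    SURGICAL_COMPLICATION = "surgical_complication"
    UNRESECTABLE = "unresectable"


#: parameter names per strategy, in the declared (and sampling) order
NAT_PARAM_NAMES = ("tox3", "resect", "explore", "r0", "poc34", "poc5")
SF_PARAM_NAMES = ("resect", "r0", "poc34", "poc5", "adjuvant", "adj_tox3")
#: flat dotted ids, fixing the order PSA streams are drawn in
PARAM_ORDER = tuple(f"nat.{n}" for n in NAT_PARAM_NAMES) + tuple(
    f"sf.{n}" for n in SF_PARAM_NAMES
)


@dataclass(frozen=True)
class StudyRecord:
    """One trial arm: its size, outcome counts and median survival times."""

    study_id: str
    pathway: Pathway
    design: StudyDesign
    n: int
    events: Dict[str, int] = field(default_factory=dict)
    median_os: Optional[float] = None
    median_dfs: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway", Pathway(self.pathway))
        object.__setattr__(self, "design", StudyDesign(self.design))
        if self.n < 1:
            raise ConfigError(f"study {self.study_id!r}: n must be positive, got {self.n}")
        for outcome, count in self.events.items():
            if count < 0 or count > self.n:
                raise ConfigError(
                    f"study {self.study_id!r}: event count {count} for outcome "
                    f"{outcome!r} outside [0, n={self.n}]"
                )
        for name, value in (("median_os", self.median_os), ("median_dfs", self.median_dfs)):
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ConfigError(
                    f"study {self.study_id!r}: {name} must be finite and positive, got {value}"
                )


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric family with its fitted parameters.

    ``family`` is one of the names registered in :mod:`pdacpath.distributions`;
    ``params`` maps that family's parameter names to values. ``ad_stat`` is the
    Anderson-Darling statistic of the fit when known.
    """

    family: str
    params: Dict[str, float]
    ad_stat: Optional[float] = None


@dataclass(frozen=True)
class ProportionEstimate:
    """A pooled probability with its uncertainty description.

    ``range_low``/``range_high`` are the lowest and highest values reported
    across contributing studies; ``sd`` is the standard deviation of the pooled
    estimate. ``variance`` defaults to ``sd**2`` and is checked against it when
    supplied (a mismatch beyond 5% relative is logged, and the sd wins).
    """

    point: float
    ci_low: float
    ci_high: float
    range_low: float
    range_high: float
    sd: float
    variance: Optional[float] = None
    distribution: Optional[DistributionSpec] = None

    def __post_init__(self) -> None:
        for name in ("point", "ci_low", "ci_high", "range_low", "range_high"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ConfigError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket point {self.point}"
            )
        if self.range_low > self.range_high:
            raise ConfigError(f"range ({self.range_low}, {self.range_high}) inverted")
        if self.sd < 0:
            raise ConfigError(f"sd must be non-negative, got {self.sd}")
        if self.variance is None:
            object.__setattr__(self, "variance", self.sd**2)


class UtilityTable(Dict[HealthPhase, float]):
    """Utility weight in [0, 1] per health phase; dead is implicitly 0."""

    def __init__(self, weights: Dict[HealthPhase, float]):
        cleaned = {HealthPhase(k): float(v) for k, v in weights.items()}
        for phase, w in cleaned.items():
            if not (0.0 <= w <= 1.0):
                raise ConfigError(f"utility for {phase.value} = {w} outside [0, 1]")
        super().__init__(cleaned)

    def weight(self, phase: HealthPhase) -> float:
        try:
            return self[HealthPhase(phase)]
        except KeyError:
            raise ConfigError(f"no utility defined for phase {phase!r}") from None


@dataclass(frozen=True)
class PathwayParams:
    """The transition-probability estimates for both strategies.

    NAT: grade-3+ neoadjuvant toxicity, resection, exploratory-only surgery,
    R0 share (conditional on resection), grade 3-4 and grade 5 post-operative
    complications. SF: resection, conditional R0 share, grade 3-4 / grade 5
    complications, receipt of adjuvant therapy, grade-3+ adjuvant toxicity.

    Residual branch mass is implicit: NAT no-surgery = 1 - resect - explore;
    SF exploratory-only = 1 - resect.
    """

    nat: Dict[str, ProportionEstimate]
    sf: Dict[str, ProportionEstimate]

    def __post_init__(self) -> None:
        missing = [n for n in NAT_PARAM_NAMES if n not in self.nat]
        missing += [f"sf.{n}" for n in SF_PARAM_NAMES if n not in self.sf]
        if missing:
            raise ConfigError(f"missing parameters: {missing}")
        if self.nat["resect"].point + self.nat["explore"].point > 1.0 + 1e-9:
            raise ConfigError(
                "NAT resect + explore exceeds 1: no-surgery residual would be negative"
            )

    def get(self, param_id: str) -> ProportionEstimate:
        strategy, name = _split_id(param_id)
        return (self.nat if strategy == "nat" else self.sf)[name]

    def with_value(self, param_id: str, point: float) -> "PathwayParams":
        """Return a copy with the named point estimate replaced.

        The CI is widened if needed so that it still brackets the new point;
        the residual-branch invariants are re-checked by the constructor.
        """
        if not (0.0 <= point <= 1.0):
            raise ConfigError(f"override {param_id}={point} outside [0, 1]")
        strategy, name = _split_id(param_id)
        block = dict(self.nat if strategy == "nat" else self.sf)
        est = block[name]
        block[name] = replace(
            est,
            point=point,
            ci_low=min(est.ci_low, point),
            ci_high=max(est.ci_high, point),
        )
        if strategy == "nat":
            return PathwayParams(nat=block, sf=self.sf)
        return PathwayParams(nat=self.nat, sf=block)

    def points(self) -> Dict[str, float]:
        return {pid: self.get(pid).point for pid in PARAM_ORDER}


def _split_id(param_id: str) -> tuple[str, str]:
    try:
        strategy, name = param_id.split(".", 1)
    except ValueError:
        raise ConfigError(f"parameter id {param_id!r} is not of the form 'nat.name'/'sf.name'")
    if strategy not in ("nat", "sf"):
        raise ConfigError(f"unknown strategy {strategy!r} in parameter id {param_id!r}")
    names = NAT_PARAM_NAMES if strategy == "nat" else SF_PARAM_NAMES
    if name not in names:
        raise ConfigError(f"unknown parameter {name!r} for strategy {strategy!r}")
    return strategy, name


@dataclass(frozen=True)
class CohortPayoff:
    """Cumulative life-months and QALMs for one terminal treatment cohort.

    ``variants`` holds the QALM payoff under post-operative complication (POC),
    grade-3+ adjuvant toxicity (AT), or both; absent variants fall back to the
    baseline QALM.
    """

    label: str
    life_months: float
    qalms: float
    variants: Dict[str, float] = field(default_factory=dict)

    _VARIANT_KEYS = ("POC", "AT", "POC+AT")

    def __post_init__(self) -> None:
        if self.life_months < 0 or self.qalms < 0:
            raise ConfigError(f"cohort {self.label!r}: negative payoff")
        if self.qalms > self.life_months + 1e-9:
            raise ConfigError(
                f"cohort {self.label!r}: QALMs {self.qalms} exceed life-months "
                f"{self.life_months}"
            )
        for key, q in self.variants.items():
            if key not in self._VARIANT_KEYS:
                raise ConfigError(f"cohort {self.label!r}: unknown variant {key!r}")
            if q > self.qalms + 1e-9:
                raise ConfigError(
                    f"cohort {self.label!r}: variant {key} QALM {q} exceeds baseline"
                )

    def qalm_variant(self, poc: bool = False, at: bool = False) -> float:
        key = {(False, False): None, (True, False): "POC", (False, True): "AT", (True, True): "POC+AT"}[
            (poc, at)
        ]
        if key is None:
            return self.qalms
        return self.variants.get(key, self.qalms)


class ModelInputs(NamedTuple):
    """Everything the decision model needs: probabilities, utilities, payoffs."""

    params: PathwayParams
    utilities: UtilityTable
    payoffs: Dict[str, CohortPayoff]


# ---------------------------------------------------------------------------
# YAML config IO


def _parse_estimate(name: str, node: dict) -> ProportionEstimate:
    try:
        dist = None
        if "distribution" in node and node["distribution"]:
            d = node["distribution"]
            dist = DistributionSpec(
                family=str(d["family"]),
                params={str(k): float(v) for k, v in d["params"].items()},
                ad_stat=float(d["ad_stat"]) if d.get("ad_stat") is not None else None,
            )
        est = ProportionEstimate(
            point=float(node["point"]),
            ci_low=float(node["ci"][0]),
            ci_high=float(node["ci"][1]),
            range_low=float(node["range"][0]),
            range_high=float(node["range"][1]),
            sd=float(node["sd"]),
            variance=float(node["variance"]) if node.get("variance") is not None else None,
            distribution=dist,
        )
        if est.sd > 0 and abs(est.variance - est.sd**2) > 0.05 * est.sd**2:
            logger.warning(
                "%s: variance %g inconsistent with sd^2 = %g (trusting sd)",
                name, est.variance, est.sd**2,
            )
        return est
    except (KeyError, TypeError, IndexError) as exc:
        raise ConfigError(f"parameter {name!r}: malformed entry ({exc})") from exc


def load_config(path: "str | Path | None" = None) -> ModelInputs:
    """Read a model config (defaults to the bundled baseline transcription)."""
    if path is None:
        path = baseline_config_path()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        nat_raw, sf_raw = raw["nat"], raw["sf"]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing strategy block {exc}") from exc
    params = PathwayParams(
        nat={n: _parse_estimate(f"nat.{n}", nat_raw[n]) for n in NAT_PARAM_NAMES if n in nat_raw},
        sf={n: _parse_estimate(f"sf.{n}", sf_raw[n]) for n in SF_PARAM_NAMES if n in sf_raw},
    )
    utilities = UtilityTable(raw.get("utilities", {}))
    payoffs: Dict[str, CohortPayoff] = {}
    for label, node in raw.get("cohort_payoffs", {}).items():
        payoffs[label] = CohortPayoff(
            label=label,
            life_months=float(node["life_months"]),
            qalms=float(node["qalms"]),
            variants={str(k): float(v) for k, v in (node.get("variants") or {}).items()},
        )
    return ModelInputs(params=params, utilities=utilities, payoffs=payoffs)


def _estimate_to_node(est: ProportionEstimate) -> dict:
    node = {
        "point": est.point,
        "ci": [est.ci_low, est.ci_high],
        "range": [est.range_low, est.range_high],
        "sd": est.sd,
        "variance": est.variance,
    }
    if est.distribution is not None:
        node["distribution"] = {
            "family": est.distribution.family,
            "params": dict(est.distribution.params),
            "ad_stat": est.distribution.ad_stat,
        }
    return node


def save_config(inputs: ModelInputs, path: "str | Path") -> None:
    raw = {
        "nat": {n: _estimate_to_node(inputs.params.nat[n]) for n in NAT_PARAM_NAMES},
        "sf": {n: _estimate_to_node(inputs.params.sf[n]) for n in SF_PARAM_NAMES},
        "utilities": {phase.value: w for phase, w in inputs.utilities.items()},
        "cohort_payoffs": {
            label: {
                "life_months": p.life_months,
                "qalms": p.qalms,
                **({"variants": dict(p.variants)} if p.variants else {}),
            }
            for label, p in inputs.payoffs.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Study-record CSV IO

_STUDY_COLUMNS = ("study_id", "pathway", "design", "n", "median_os", "median_dfs")


def load_study_records(path: "str | Path") -> List[StudyRecord]:
    """Read trial arms from CSV.

    Required columns: study_id, pathway, design, n. Optional: median_os,
    median_dfs (blank allowed) and any number of ``events_<outcome>`` count
    columns.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"study-record file not found: {path}")
    records: List[StudyRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty study-record file", path)
            return []
        missing = [c for c in ("study_id", "pathway", "design", "n") if c not in reader.fieldnames]
        if missing:
            raise ConfigError(f"{path}: missing required columns {missing}")
        event_cols = [c for c in reader.fieldnames if c.startswith("events_")]
        for i, row in enumerate(reader, start=2):
            try:
                events = {
                    c[len("events_") :]: int(row[c])
                    for c in event_cols
                    if row.get(c) not in (None, "")
                }
                records.append(
                    StudyRecord(
                        study_id=row["study_id"],
                        pathway=Pathway(row["pathway"]),
                        design=StudyDesign(row["design"]),
                        n=int(row["n"]),
                        events=events,
                        median_os=float(row["median_os"]) if row.get("median_os") else None,
                        median_dfs=float(row["median_dfs"]) if row.get("median_dfs") else None,
                    )
                )
            except (ValueError, ConfigError) as exc:
                raise ConfigError(f"{path} line {i}: {exc}") from exc
    if not records:
        logger.warning("%s: no study records", path)
    return records


def save_study_records(records: List[StudyRecord], path: "str | Path") -> None:
    outcomes = sorted({o for r in records for o in r.events})
    cols = list(_STUDY_COLUMNS[:4]) + [f"events_{o}" for o in outcomes] + ["median_os", "median_dfs"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for r in records:
            row = {
                "study_id": r.study_id,
                "pathway": r.pathway.value,
                "design": r.design.value,
                "n": r.n,
                "median_os": "" if r.median_os is None else r.median_os,
                "median_dfs": "" if r.median_dfs is None else r.median_dfs,
            }
            for o in outcomes:
                row[f"events_{o}"] = r.events.get(o, "")
            writer.writerow(row)


def baseline_config_path() -> Path:
    """Path of the bundled baseline parameter transcription."""
    return Path(str(resources.files("pdacpath").joinpath("data/baseline.yaml")))


def bundled_studies_path() -> Path:
    """Path of the bundled literature-pool transcription."""
    return Path(str(resources.files("pdacpath").joinpath("data/studies.csv")))
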