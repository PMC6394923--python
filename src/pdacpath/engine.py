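"""Decision-tree construction and Markov cohort evaluation.

The model compares two strategies for potentially resectable pancreatic
cancer. Surgery-first (SF): attempt resection up front; survivors are split
by margin status (R0/R1) and by whether adjuvant therapy is received, with
grade 3-4 post-operative complications (POC) and grade 3+ adjuvant toxicity
(AT) degrading quality of life but not survival. Neoadjuvant therapy (NAT):
chemo(radio)therapy first, then restaging; patients proceed to resection,
exploratory surgery only, or no surgery at all (the residual branch). A fatal
(grade 5) complication contributes zero months.

Each terminal cohort is valued either directly — printed cumulative payoffs
in life-months (LM) and quality-adjusted life-months (QALMs) — or by running
a monthly Markov trace over {alive disease-free, alive with disease, dead}
under a constant exponential hazard for up to 60 cycles, accumulating LM and
utility-weighted QALMs according to a phase schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import (
    CohortPayoff,
    HealthPhase,
    PathwayParams,
    UtilityTable,
)

__all__ = [
    "MarkovSpec",
    "CohortTrace",
    "CohortNode",
    "StrategyOutcome",
    "OutcomeSummary",
    "median_to_hazard",
    "truncated_mean",
    "calibrate_median",
    "run_cohort_trace",
    "build_decision_tree",
    "build_strategy_tree",
    "expected_value_rollup",
    "cohort_table",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = 60
_PROB_TOL = 1e-9


def median_to_hazard(median: float) -> float:
    """Constant monthly hazard implied by an exponential median survival."""
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    return math.log(2.0) / median


def truncated_mean(hazard: float, horizon: int = DEFAULT_HORIZON) -> float:
    """Expected months alive within ``horizon`` cycles under a constant hazard.

    Computed from the discrete monthly trace (sum of end-of-cycle survival
    probabilities); agrees with the continuous-time value
    ``(1/hazard) * (1 - exp(-hazard * horizon))`` to within half a cycle.
    """
    if hazard <= 0:
        raise ValueError(f"hazard must be positive, got {hazard}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    s = math.exp(-hazard)
    # geometric sum of s^1 .. s^horizon
    return s * (1.0 - s**horizon) / (1.0 - s) if s < 1.0 else float(horizon)


def calibrate_median(
    target_mean: float, horizon: int = DEFAULT_HORIZON, tol: float = 1e-9
) -> float:
    """Median such that the truncated trace mean equals ``target_mean``.

    The trace mean is strictly increasing in the median, from 0 towards the
    horizon, so bisection on the median converges; a target at or above the
    horizon is infeasible.
    """
    if not (0.0 < target_mean < horizon):
        raise ValueError(f"target mean {target_mean} infeasible for horizon {horizon}")
    lo, hi = 1e-12, 1.0
    while truncated_mean(median_to_hazard(hi), horizon) < target_mean:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - target < horizon guards this
            raise RuntimeError("bisection bracket expansion failed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if truncated_mean(median_to_hazard(mid), horizon) < target_mean:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class MarkovSpec:
    """Survival and quality-of-life specification for one terminal cohort.

    ``schedule`` is an ordered list of ``(phase, cycles)`` entries; a ``None``
    cycle count means "all remaining cycles". ``progression_hazard`` moves
    occupancy from the disease-free to the with-disease state (both alive
    states share their phase utility, so it affects book-keeping only).
    """

    hazard: float
    horizon: int = DEFAULT_HORIZON
    schedule: Tuple[Tuple[HealthPhase, Optional[int]], ...] = (
        (HealthPhase.STABLE_DISEASE, None),
    )
    initial_state: str = "alive_disease_free"
    progression_hazard: float = 0.0

    def __post_init__(self) -> None:
        if self.hazard <= 0:
            raise ValueError("hazard must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for phase, cycles in self.schedule:
            HealthPhase(phase)
            if cycles is not None and cycles < 0:
                raise ValueError("schedule durations must be non-negative")

    def phase_for_cycle(self, cycle: int) -> HealthPhase:
        """Phase in force during cycle ``cycle`` (1-based)."""
        consumed = 0
        for phase, cycles in self.schedule:
            if cycles is None:
                return phase
            consumed += cycles
            if cycle <= consumed:
                return phase
        return self.schedule[-1][0]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and cumulative payoffs of one Markov cohort."""

    occupancy: np.ndarray  # (horizon + 1, 3): disease-free, with-disease, dead
    life_months: float
    qalms: float

    STATES = ("alive_disease_free", "alive_with_disease", "dead")


def run_cohort_trace(spec: MarkovSpec, utilities: UtilityTable) -> CohortTrace:
    """Run the monthly cohort trace, accruing LM and utility-weighted QALMs.

    Survival accrues as the end-of-cycle alive occupancy; the QALM increment
    each cycle is that occupancy times the utility of the phase in force.
    """
    q_death = 1.0 - math.exp(-spec.hazard)
    q_prog = 1.0 - math.exp(-spec.progression_hazard) if spec.progression_hazard > 0 else 0.0
    occ = np.zeros((spec.horizon + 1, 3))
    occ[0, CohortTrace.STATES.index(spec.initial_state)] = 1.0
    lm = 0.0
    qalm = 0.0
    for cycle in range(1, spec.horizon + 1):
        free, disease, dead = occ[cycle - 1]
        new_dead = dead + (free + disease) * q_death
        free_surv = free * (1.0 - q_death)
        disease_surv = disease * (1.0 - q_death)
        progressed = free_surv * q_prog
        occ[cycle] = (free_surv - progressed, disease_surv + progressed, new_dead)
        alive = occ[cycle, 0] + occ[cycle, 1]
        lm += alive
        qalm += alive * utilities.weight(spec.phase_for_cycle(cycle))
    return CohortTrace(occupancy=occ, life_months=lm, qalms=qalm)


@dataclass
class CohortNode:
    """A node of the decision tree.

    ``kind`` is ``decision`` (strategy root), ``chance`` (probability-weighted
    children) or ``terminal`` (carries a resolved ``(LM, QALM)`` payoff and the
    cohort it belongs to). Chance-node child probabilities must sum to one.
    """

    label: str
    kind: str = "chance"
    children: List[Tuple[float, "CohortNode"]] = field(default_factory=list)
    payoff_lm: Optional[float] = None
    payoff_qalm: Optional[float] = None
    cohort: Optional[str] = None

    def add(self, probability: float, child: "CohortNode") -> "CohortNode":
        if probability < -_PROB_TOL:
            raise ValueError(f"negative branch probability {probability} at {self.label!r}")
        self.children.append((max(0.0, probability), child))
        return child

    def validate(self) -> None:
        if self.kind == "terminal":
            if self.payoff_lm is None or self.payoff_qalm is None:
                raise ValueError(f"terminal node {self.label!r} has no payoff")
            return
        if not self.children:
            raise ValueError(f"{self.kind} node {self.label!r} has no children")
        if self.kind == "chance":
            total = sum(p for p, _ in self.children)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"chance node {self.label!r}: child probabilities sum to {total}"
                )
        for _, child in self.children:
            child.validate()

    def expectation(self) -> Tuple[float, float]:
        """Probability-weighted (LM, QALM) over the subtree."""
        if self.kind == "terminal":
            return float(self.payoff_lm), float(self.payoff_qalm)
        if self.kind == "decision":
            raise ValueError("decision nodes have no single expectation; roll up per strategy")
        lm = qalm = 0.0
        for p, child in self.children:
            c_lm, c_qalm = child.expectation()
            lm += p * c_lm
            qalm += p * c_qalm
        return lm, qalm

    def leaves(self, prob: float = 1.0) -> List[Tuple[float, "CohortNode"]]:
        if self.kind == "terminal":
            return [(prob, self)]
        out: List[Tuple[float, CohortNode]] = []
        for p, child in self.children:
            out.extend(child.leaves(prob * p))
        return out


@dataclass(frozen=True)
class StrategyOutcome:
    life_months: float
    qalms: float


@dataclass(frozen=True)
class OutcomeSummary:
    """Intention-to-treat expectations per strategy and their difference."""

    sf: StrategyOutcome
    nat: StrategyOutcome

    @property
    def incremental_lm(self) -> float:
        """SF minus NAT, in months."""
        return self.sf.life_months - self.nat.life_months

    @property
    def incremental_qalm(self) -> float:
        return self.sf.qalms - self.nat.qalms


# ---------------------------------------------------------------------------
# tree construction

_ZERO_PAYOFF = CohortPayoff("operative_death", 0.0, 0.0)


def _trace_qalm(
    payoff: CohortPayoff,
    utilities: UtilityTable,
    horizon: int,
    schedule: Tuple[Tuple[HealthPhase, Optional[int]], ...],
    initial_state: str = "alive_disease_free",
) -> Tuple[float, float]:
    """Leaf payoff in trace mode: LM matched to the cohort's printed months."""
    spec = MarkovSpec(
        hazard=median_to_hazard(calibrate_median(payoff.life_months, horizon)),
        horizon=horizon,
        schedule=schedule,
        initial_state=initial_state,
    )
    trace = run_cohort_trace(spec, utilities)
    return trace.life_months, trace.qalms


def _resected_schedule(
    treatment_cycles: int,
    poc: bool,
    adjuvant_cycles: int = 0,
    at: bool = False,
) -> Tuple[Tuple[HealthPhase, Optional[int]], ...]:
    """Utility schedule for a resected cohort.

    Pre-operative treatment (NAT only), one cycle of surgical recovery (worse
    under a grade 3-4 complication), optional adjuvant cycles (worse under
    grade 3+ toxicity), then stable disease for the remaining cycles.
    """
    sched: List[Tuple[HealthPhase, Optional[int]]] = []
    if treatment_cycles:
        sched.append((HealthPhase.ON_CHEMORADIOTHERAPY, treatment_cycles))
    sched.append(
        (HealthPhase.SURGICAL_COMPLICATION if poc else HealthPhase.SURGICAL_RECOVERY, 1)
    )
    if adjuvant_cycles:
        sched.append(
            (
                HealthPhase.CHEMO_TOXICITY if at else HealthPhase.ON_CHEMORADIOTHERAPY,
                adjuvant_cycles,
            )
        )
    sched.append((HealthPhase.STABLE_DISEASE, None))
    return tuple(sched)


_UNRESECTABLE_SCHEDULE = ((HealthPhase.UNRESECTABLE, None),)

#: pre-operative and adjuvant treatment durations (cycles) used in trace mode
NAT_TREATMENT_CYCLES = 3
ADJUVANT_CYCLES = 6


def _leaf(
    label: str,
    cohort: str,
    payoff: CohortPayoff,
    mode: str,
    utilities: UtilityTable,
    horizon: int,
    poc: bool = False,
    at: bool = False,
    schedule: Optional[Tuple[Tuple[HealthPhase, Optional[int]], ...]] = None,
    initial_state: str = "alive_disease_free",
) -> CohortNode:
    if payoff.life_months == 0.0 or mode == "direct":
        lm, qalm = payoff.life_months, payoff.qalm_variant(poc=poc, at=at)
    else:
        lm, qalm = _trace_qalm(payoff, utilities, horizon, schedule, initial_state)
    return CohortNode(label=label, kind="terminal", payoff_lm=lm, payoff_qalm=qalm, cohort=cohort)


def build_strategy_tree(
    strategy: str,
    params: PathwayParams,
    payoffs: Dict[str, CohortPayoff],
    utilities: UtilityTable,
    mode: str = "direct",
    horizon: int = DEFAULT_HORIZON,
) -> CohortNode:
    """Build one strategy's chance tree ("SF" or "NAT")."""
    if mode not in ("direct", "trace"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    strategy = strategy.upper()
    if strategy == "SF":
        return _build_sf(params, payoffs, utilities, mode, horizon)
    if strategy == "NAT":
        return _build_nat(params, payoffs, utilities, mode, horizon)
    raise ValueError(f"unknown strategy {strategy!r}")


def _poc_split(
    parent: CohortNode,
    p_poc: float,
    cohort: str,
    payoff: CohortPayoff,
    mode: str,
    utilities: UtilityTable,
    horizon: int,
    at: bool,
    treatment_cycles: int,
    adjuvant_cycles: int,
) -> None:
    for poc, p in ((True, p_poc), (False, 1.0 - p_poc)):
        sched = _resected_schedule(treatment_cycles, poc, adjuvant_cycles, at)
        suffix = ("POC" if poc else "noPOC") + ("+AT" if at else "")
        parent.add(
            p,
            _leaf(
                f"{cohort}[{suffix}]",
                cohort,
                payoff,
                mode,
                utilities,
                horizon,
                poc=poc,
                at=at,
                schedule=sched,
            ),
        )


def _build_sf(
    params: PathwayParams,
    payoffs: Dict[str, CohortPayoff],
    utilities: UtilityTable,
    mode: str,
    horizon: int,
) -> CohortNode:
    p = {k: est.point for k, est in params.sf.items()}
    root = CohortNode("SF")
    resect = root.add(p["resect"], CohortNode("SF resection attempted"))
    root.add(
        1.0 - p["resect"],
        _leaf(
            "sf_explore",
            "sf_explore",
            payoffs["sf_explore"],
            mode,
            utilities,
            horizon,
            schedule=_UNRESECTABLE_SCHEDULE,
            initial_state="alive_with_disease",
        ),
    )
    resect.add(
        p["poc5"],
        CohortNode("SF operative death", kind="terminal", payoff_lm=0.0, payoff_qalm=0.0,
                   cohort="sf_operative_death"),
    )
    survive = resect.add(1.0 - p["poc5"], CohortNode("SF survived resection"))
    for margin, p_margin in (("r0", p["r0"]), ("r1", 1.0 - p["r0"])):
        node = survive.add(p_margin, CohortNode(f"SF {margin.upper()}"))
        adj = node.add(p["adjuvant"], CohortNode(f"SF {margin.upper()} adjuvant"))
        for at, p_at in ((True, p["adj_tox3"]), (False, 1.0 - p["adj_tox3"])):
            at_node = adj.add(p_at, CohortNode(f"SF {margin.upper()} adjuvant {'AT' if at else 'noAT'}"))
            _poc_split(
                at_node, p["poc34"], f"sf_{margin}_adjuvant", payoffs[f"sf_{margin}_adjuvant"],
                mode, utilities, horizon, at, 0, ADJUVANT_CYCLES,
            )
        no_adj = node.add(1.0 - p["adjuvant"], CohortNode(f"SF {margin.upper()} no adjuvant"))
        _poc_split(
            no_adj, p["poc34"], f"sf_{margin}_no_adjuvant", payoffs[f"sf_{margin}_no_adjuvant"],
            mode, utilities, horizon, False, 0, 0,
        )
    return root


def _build_nat(
    params: PathwayParams,
    payoffs: Dict[str, CohortPayoff],
    utilities: UtilityTable,
    mode: str,
    horizon: int,
) -> CohortNode:
    p = {k: est.point for k, est in params.nat.items()}
    residual = 1.0 - p["resect"] - p["explore"]
    if residual < -_PROB_TOL:
        raise ValueError(
            f"NAT no-surgery residual is negative (resect={p['resect']}, explore={p['explore']})"
        )
    root = CohortNode("NAT")
    resect = root.add(p["resect"], CohortNode("NAT resection attempted"))
    root.add(
        p["explore"],
        _leaf(
            "nat_explore", "nat_explore", payoffs["nat_explore"], mode, utilities, horizon,
            schedule=_UNRESECTABLE_SCHEDULE, initial_state="alive_with_disease",
        ),
    )
    root.add(
        max(0.0, residual),
        _leaf(
            "nat_no_surgery", "nat_no_surgery", payoffs["nat_no_surgery"], mode, utilities,
            horizon, schedule=_UNRESECTABLE_SCHEDULE, initial_state="alive_with_disease",
        ),
    )
    resect.add(
        p["poc5"],
        CohortNode("NAT operative death", kind="terminal", payoff_lm=0.0, payoff_qalm=0.0,
                   cohort="nat_operative_death"),
    )
    survive = resect.add(1.0 - p["poc5"], CohortNode("NAT survived resection"))
    for margin, p_margin in (("r0", p["r0"]), ("r1", 1.0 - p["r0"])):
        node = survive.add(p_margin, CohortNode(f"NAT {margin.upper()}"))
        _poc_split(
            node, p["poc34"], f"nat_{margin}", payoffs[f"nat_{margin}"],
            mode, utilities, horizon, False, NAT_TREATMENT_CYCLES, 0,
        )
    return root


def build_decision_tree(
    params: PathwayParams,
    payoffs: Dict[str, CohortPayoff],
    utilities: UtilityTable,
    mode: str = "direct",
    horizon: int = DEFAULT_HORIZON,
) -> CohortNode:
    """Root decision node with the SF and NAT chance subtrees."""
    root = CohortNode("treatment strategy", kind="decision")
    root.add(1.0, build_strategy_tree("SF", params, payoffs, utilities, mode, horizon))
    root.add(1.0, build_strategy_tree("NAT", params, payoffs, utilities, mode, horizon))
    root.validate()
    return root


def expected_value_rollup(tree: CohortNode) -> OutcomeSummary:
    """Intention-to-treat expectation per strategy from a decision root."""
    if tree.kind != "decision":
        raise ValueError("rollup expects the decision root (SF + NAT subtrees)")
    by_label = {child.label: child for _, child in tree.children}
    sf = by_label["SF"].expectation()
    nat = by_label["NAT"].expectation()
    return OutcomeSummary(
        sf=StrategyOutcome(life_months=sf[0], qalms=sf[1]),
        nat=StrategyOutcome(life_months=nat[0], qalms=nat[1]),
    )


def cohort_table(tree: CohortNode) -> pd.DataFrame:
    """Per-cohort payoff table (one row per terminal cohort and variant).

    Columns: strategy, cohort, variant label, branch probability within the
    strategy, life-months and QALMs. Aggregating ``probability * value`` per
    strategy recovers the intention-to-treat expectations.
    """
    rows = []
    strategies = (
        [(child.label, child) for _, child in tree.children]
        if tree.kind == "decision"
        else [(tree.label, tree)]
    )
    for strategy, sub in strategies:
        for prob, leaf in sub.leaves():
            variant = ""
            if "[" in leaf.label:
                variant = leaf.label.split("[", 1)[1].rstrip("]")
            rows.append(
                {
                    "strategy": strategy,
                    "cohort": leaf.cohort,
                    "variant": variant,
                    "probability": prob,
                    "life_months": leaf.payoff_lm,
                    "qalms": leaf.payoff_qalm,
                }
            )
    return pd.DataFrame(
        rows, columns=["strategy", "cohort", "variant", "probability", "life_months", "qalms"]
    )
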