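"""Model / Results surface tying the pipeline together.

``PathwayDecisionModel`` wraps the model inputs (transition probabilities,
utilities, cohort payoffs) and knows how to evaluate itself; ``fit()`` returns
a ``DecisionResults`` carrying the intention-to-treat expectations, the
per-cohort table, and a printable summary. Sensitivity analyses and the
probabilistic Monte Carlo run hang off the model object.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence

import pandas as pd

from . import engine, psa as _psa, sensitivity as _sens
from .parameters import (
    CohortPayoff,
    ModelInputs,
    PathwayParams,
    StudyRecord,
    UtilityTable,
    load_config,
)
from .pooling import pool_outcome

__all__ = ["PathwayDecisionModel", "DecisionResults"]


class PathwayDecisionModel:
    """Two-strategy decision-tree + Markov cohort model.

    Parameters
    ----------
    params : PathwayParams
        Transition probabilities for both strategies.
    utilities : UtilityTable
        QALM utility weight per health phase.
    payoffs : dict of CohortPayoff
        Terminal cohort payoffs (the printed cohort-analysis values).
    mode : {"direct", "trace"}
        ``direct`` uses the cohort payoffs as leaf values; ``trace`` re-derives
        each leaf from a monthly Markov trace whose exponential median is
        calibrated so the traced life-months match the cohort's, with QALMs
        accrued through a utility schedule.
    horizon : int
        Markov horizon in monthly cycles.
    """

    def __init__(
        self,
        params: PathwayParams,
        utilities: UtilityTable,
        payoffs: Dict[str, CohortPayoff],
        mode: str = "direct",
        horizon: int = engine.DEFAULT_HORIZON,
    ):
        if mode not in ("direct", "trace"):
            raise ValueError(f"unknown evaluation mode {mode!r}")
        self.params = params
        self.utilities = utilities
        self.payoffs = payoffs
        self.mode = mode
        self.horizon = horizon

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_config(
        cls,
        path: "str | None" = None,
        mode: str = "direct",
        horizon: int = engine.DEFAULT_HORIZON,
    ) -> "PathwayDecisionModel":
        """Build from a YAML config (bundled baseline when ``path`` is None)."""
        inputs = load_config(path)
        return cls(inputs.params, inputs.utilities, inputs.payoffs, mode=mode, horizon=horizon)

    @classmethod
    def from_study_records(
        cls,
        records: Sequence[StudyRecord],
        outcome_map: Dict[str, str],
        base: "PathwayDecisionModel | None" = None,
        mode: str = "direct",
    ) -> "PathwayDecisionModel":
        """Re-estimate transition probabilities from a study pool.

        ``outcome_map`` maps parameter ids (e.g. ``"nat.resect"``) to the
        event-outcome column name pooled for it; parameters not mapped keep the
        values of ``base`` (the bundled baseline by default). Pooling uses the
        Freeman-Tukey random-effects estimator per pathway.
        """
        if base is None:
            base = cls.from_config(mode=mode)
        params = base.params
        for param_id, outcome in outcome_map.items():
            strategy = param_id.split(".", 1)[0].upper()
            sub = [r for r in records if r.pathway.value == strategy]
            est = pool_outcome(sub, outcome)
            # keep the baseline's fitted-distribution attachment
            est = replace(est, distribution=params.get(param_id).distribution)
            block = dict(params.nat if strategy == "NAT" else params.sf)
            block[param_id.split(".", 1)[1]] = est
            params = (
                PathwayParams(nat=block, sf=params.sf)
                if strategy == "NAT"
                else PathwayParams(nat=params.nat, sf=block)
            )
        return cls(params, base.utilities, base.payoffs, mode=mode, horizon=base.horizon)

    @property
    def inputs(self) -> ModelInputs:
        return ModelInputs(self.params, self.utilities, self.payoffs)

    # -- evaluation ---------------------------------------------------------

    def build_tree(self, params: Optional[PathwayParams] = None) -> engine.CohortNode:
        return engine.build_decision_tree(
            params or self.params, self.payoffs, self.utilities, self.mode, self.horizon
        )

    def fit(self) -> "DecisionResults":
        """Evaluate the decision tree and return the results object."""
        tree = self.build_tree()
        summary = engine.expected_value_rollup(tree)
        table = engine.cohort_table(tree)
        return DecisionResults(self, tree, summary, table)

    def evaluate_at(self, params: PathwayParams) -> engine.OutcomeSummary:
        """Rollup at alternative parameter values (used by the sweeps)."""
        return engine.expected_value_rollup(self.build_tree(params))

    # -- analyses -----------------------------------------------------------

    def one_way_sweep(self, param_id: str, lo: float, hi: float, steps: int = 21):
        return _sens.one_way_sweep(self, param_id, lo, hi, steps)

    def find_threshold(self, param_id: str, lo: float, hi: float, tol: float = 1e-4,
                       objective: str = "qalm"):
        return _sens.find_threshold(self, param_id, lo, hi, tol=tol, objective=objective)

    def two_way_map(self, id_a: str, id_b: str, grid_a, grid_b, tie_tol: float = 0.01):
        return _sens.two_way_map(self, id_a, id_b, grid_a, grid_b, tie_tol=tie_tol)

    def run_psa(self, n_iter: int = 10000, seed=None, sampling: str = "range"):
        return _psa.run_psa(self, n_iter=n_iter, seed=seed, sampling=sampling)


class DecisionResults:
    """Evaluated model: intention-to-treat expectations and cohort payoffs."""

    def __init__(self, model, tree, outcomes, table):
        self.model = model
        self.tree = tree
        self.outcomes: engine.OutcomeSummary = outcomes
        self._table: pd.DataFrame = table

    @property
    def sf(self) -> engine.StrategyOutcome:
        return self.outcomes.sf

    @property
    def nat(self) -> engine.StrategyOutcome:
        return self.outcomes.nat

    @property
    def incremental_lm(self) -> float:
        return self.outcomes.incremental_lm

    @property
    def incremental_qalm(self) -> float:
        return self.outcomes.incremental_qalm

    def cohort_table(self, collapse_variants: bool = True) -> pd.DataFrame:
        """Per-cohort payoffs; with ``collapse_variants`` the complication /
        toxicity branches of a cohort are merged into baseline + variant QALM
        columns, mirroring how cohort results are usually tabulated."""
        df = self._table
        if not collapse_variants:
            return df.copy()
        rows = []
        for (strategy, cohort), grp in df.groupby(["strategy", "cohort"], sort=False):
            base = grp.loc[grp["variant"].isin(["noPOC", ""])]
            rows.append(
                {
                    "strategy": strategy,
                    "cohort": cohort,
                    "probability": grp["probability"].sum(),
                    "life_months": grp["life_months"].iloc[0],
                    "qalms": base["qalms"].iloc[0] if len(base) else grp["qalms"].iloc[0],
                    "qalms_mixed": (grp["probability"] * grp["qalms"]).sum()
                    / grp["probability"].sum()
                    if grp["probability"].sum() > 0
                    else grp["qalms"].iloc[0],
                }
            )
        return pd.DataFrame(rows)

    def strategy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": ["SF", "NAT"],
                "life_months": [self.sf.life_months, self.nat.life_months],
                "qalms": [self.sf.qalms, self.nat.qalms],
            }
        )

    def summary(self) -> str:
        lines = [
            "Two-strategy Markov decision analysis "
            f"(mode={self.model.mode}, horizon={self.model.horizon} cycles)",
            "",
            "Intention-to-treat expectations",
            self.strategy_frame().to_string(index=False, float_format=lambda x: f"{x:8.2f}"),
            "",
            f"Incremental (SF - NAT): {self.incremental_lm:+.2f} months, "
            f"{self.incremental_qalm:+.2f} QALMs",
            "",
            "Cohort analysis (probability-weighted payoffs per treatment received)",
            self.cohort_table().to_string(index=False, float_format=lambda x: f"{x:8.3f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DecisionResults SF {self.sf.life_months:.2f} LM/{self.sf.qalms:.2f} QALM, "
            f"NAT {self.nat.life_months:.2f} LM/{self.nat.qalms:.2f} QALM>"
        )
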