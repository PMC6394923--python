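"""Tabular and graphical report writers, plus the per-run manifest.

All outputs are plain CSV (and optional PNG figures) so runs diff cleanly;
every CLI stage writes a ``manifest.json`` recording the subcommand, a hash
of the config it consumed, the seeds, timestamps, the package version and the
files it produced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .engine import OutcomeSummary
from .psa import PSAResult
from .sensitivity import SuperiorityMap, ThresholdResult

__all__ = ["RunManifest", "write_report", "write_outcomes", "write_psa", "write_manifest"]


@dataclass
class RunManifest:
    subcommand: str
    config_hash: Optional[str] = None
    seeds: List[int] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    outputs: List[str] = field(default_factory=list)
    version: str = __version__

    def record(self, path: "str | Path") -> Path:
        path = Path(path)
        self.outputs.append(str(path))
        return path


def config_hash(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(manifest: RunManifest, out_dir: "str | Path") -> Path:
    out_dir = Path(out_dir)
    missing = [p for p in manifest.outputs if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists outputs that were not written: {missing}")
    payload = {
        "subcommand": manifest.subcommand,
        "config_hash": manifest.config_hash,
        "seeds": manifest.seeds,
        "started": manifest.started,
        "finished": time.time(),
        "outputs": manifest.outputs,
        "version": manifest.version,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_outcomes(summary: OutcomeSummary, cohorts: pd.DataFrame, out_dir: "str | Path",
                   manifest: Optional[RunManifest] = None) -> Dict[str, Path]:
    """Strategy expectations + cohort-analysis table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    strat = pd.DataFrame(
        {
            "strategy": ["SF", "NAT"],
            "life_months": [summary.sf.life_months, summary.nat.life_months],
            "qalms": [summary.sf.qalms, summary.nat.qalms],
        }
    )
    paths = {}
    paths["outcomes"] = out_dir / "outcomes.csv"
    strat.to_csv(paths["outcomes"], index=False)
    paths["cohorts"] = out_dir / "cohort_table.csv"
    cohorts.to_csv(paths["cohorts"], index=False)
    if manifest:
        for p in paths.values():
            manifest.record(p)
    return paths


def write_thresholds(thresholds: Sequence[ThresholdResult], out_dir: "str | Path",
                     manifest: Optional[RunManifest] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "parameter": t.param_id,
                "threshold": t.threshold,
                "superior_below": t.below,
                "superior_above": t.above,
                "objective": t.objective,
            }
            for t in thresholds
        ]
    )
    path = out_dir / "thresholds.csv"
    df.to_csv(path, index=False)
    if manifest:
        manifest.record(path)
    return path


def write_curve(curve: pd.DataFrame, out_dir: "str | Path", name: str = "one_way_curve",
                manifest: Optional[RunManifest] = None, plot: bool = False) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"curve": out_dir / f"{name}.csv"}
    curve.to_csv(paths["curve"], index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["value"], curve["sf_qalm"], label="SF")
        ax.plot(curve["value"], curve["nat_qalm"], label="NAT")
        ax.set_xlabel("parameter value")
        ax.set_ylabel("expected QALMs")
        ax.legend()
        fig.tight_layout()
        paths["figure"] = out_dir / f"{name}.png"
        fig.savefig(paths["figure"], dpi=120)
        plt.close(fig)
    if manifest:
        for p in paths.values():
            manifest.record(p)
    return paths


def write_map(smap: SuperiorityMap, out_dir: "str | Path",
              manifest: Optional[RunManifest] = None, plot: bool = False) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"map": out_dir / "two_way_map.csv"}
    smap.to_frame().to_csv(paths["map"], index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        code = np.vectorize({"SF": 1.0, "tie": 0.5, "NAT": 0.0}.get)(smap.winner)
        fig, ax = plt.subplots(figsize=(6, 5))
        mesh = ax.pcolormesh(
            smap.grid_b, smap.grid_a, code.astype(float), cmap="coolwarm", vmin=0, vmax=1
        )
        ax.set_xlabel(smap.id_b)
        ax.set_ylabel(smap.id_a)
        fig.colorbar(mesh, ax=ax, label="winner (1 = SF, 0 = NAT)")
        fig.tight_layout()
        paths["figure"] = out_dir / "two_way_map.png"
        fig.savefig(paths["figure"], dpi=120)
        plt.close(fig)
    if manifest:
        for p in paths.values():
            manifest.record(p)
    return paths


def write_psa(result: PSAResult, out_dir: "str | Path", msd: float = 3.65,
              manifest: Optional[RunManifest] = None) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "iterations": out_dir / "psa_iterations.csv",
        "summary": out_dir / "psa_summary.csv",
        "selection": out_dir / "psa_selection.csv",
    }
    result.iteration_frame().to_csv(paths["iterations"], index=False)
    result.summary_frame().to_csv(paths["summary"], index=False)
    pd.DataFrame([result.indifference(msd=msd)]).to_csv(paths["selection"], index=False)
    if manifest:
        for p in paths.values():
            manifest.record(p)
    return paths


def write_report(
    out_dir: "str | Path",
    summary: Optional[OutcomeSummary] = None,
    cohorts: Optional[pd.DataFrame] = None,
    psa: Optional[PSAResult] = None,
    thresholds: Optional[Sequence[ThresholdResult]] = None,
) -> Dict[str, Path]:
    """Write whichever report components are present (at least one required)."""
    if summary is None and psa is None and not thresholds:
        raise ValueError("nothing to report: provide outcomes, PSA results or thresholds")
    paths: Dict[str, Path] = {}
    if summary is not None:
        paths.update(write_outcomes(summary, cohorts if cohorts is not None else pd.DataFrame(),
                                    out_dir))
    if psa is not None:
        paths.update(write_psa(psa, out_dir))
    if thresholds:
        paths["thresholds"] = write_thresholds(thresholds, out_dir)
    return paths
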