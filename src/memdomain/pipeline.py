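"""End-to-end orchestration: simulate → analyze → report on synthetic cohorts.

A single config describes a cohort (condition labels × ground-truth
parameter sets × number of cells), drives the simulators and the SMLM
analysis chain, runs the split-sampling sufficiency test per metric
and the group comparisons against a designated control condition, and
writes per-ROI metric tables shaped like the standard qSMLM reporting
(detected surface density, cluster radius, molecules per cluster,
clusters per μm²) plus a provenance log.

One seed is given in the config; per-cell seeds are derived as
``seed + 1000·condition_index + cell_index`` so runs are reproducible
and parallelizable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tempfile
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import SmlmGroundTruth, simulate_smlm, write_ground_truth
from .smlm import (PhotophysicsModel, Roi, analyze_roi, auto_rois,
                   read_localizations, write_localizations)
from .stats import compare_groups, split_sufficiency_test

__all__ = ["RunConfig", "ConditionSpec", "AnalysisConfig", "PipelineStageError",
           "run", "METRICS"]

METRICS = ("detected_density", "cluster_radius", "molecules_per_cluster",
           "clusters_per_area")


class PipelineStageError(RuntimeError):
    """Failure in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class ConditionSpec:
    """One experimental condition: a label, cell count and SMLM truth."""

    label: str
    n_cells: int = 10
    smlm: dict = field(default_factory=dict)

    def ground_truth(self) -> SmlmGroundTruth:
        return SmlmGroundTruth(**self.smlm)


@dataclass
class AnalysisConfig:
    """Parameters of the per-cell SMLM analysis."""

    alpha: float = 3.3
    max_dark_frames: int = 500
    bin_width: float = 10.0
    r_max: float = 500.0
    roi_side: float = 3000.0
    n_rois: int = 3
    drift_correct: bool = True
    comparison_method: str = "welch_t"


@dataclass
class RunConfig:
    """Top-level run configuration (YAML/JSON loadable)."""

    mode: str = "full"             # simulate | analyze | full
    seed: int = 0
    outdir: str = "memdomain_run"
    control: str = "control"
    conditions: list = field(default_factory=list)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.conditions = [c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
                           for c in self.conditions]
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisConfig(**self.analysis)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cell_seed(base: int, cond_index: int, cell_index: int) -> int:
    return (base + 1000 * cond_index + cell_index) % (2 ** 31)


def _cell_dir(outdir: Path, label: str, cell: int) -> Path:
    return outdir / "data" / label / f"cell_{cell:03d}"


def _simulate(config: RunConfig, outdir: Path) -> None:
    for ci, cond in enumerate(config.conditions):
        for cell in range(cond.n_cells):
            seed = _cell_seed(config.seed, ci, cell)
            truth = cond.ground_truth()
            table, truth = simulate_smlm(truth, seed)
            d = _cell_dir(outdir, cond.label, cell)
            d.mkdir(parents=True, exist_ok=True)
            write_localizations(table, d / "localizations.csv")
            write_ground_truth(truth, d / "truth.json")


def _analyze_cell(path: Path, analysis: AnalysisConfig) -> list[dict]:
    loc_file = path / "localizations.csv"
    if not loc_file.exists():
        raise PipelineStageError("analyze", f"missing input {loc_file}")
    table = read_localizations(loc_file)
    from .smlm import correct_drift

    if analysis.drift_correct:
        table = correct_drift(table)
    phys = PhotophysicsModel(
        alpha=analysis.alpha,
        max_dark_time=analysis.max_dark_frames * 0.010,
        max_dark_frames=analysis.max_dark_frames,
    )
    rois = auto_rois(table, side=analysis.roi_side, n_rois=analysis.n_rois,
                     min_rois=1)
    rows = []
    for ri, roi in enumerate(rois):
        report, pc = analyze_roi(table, roi, phys,
                                 bin_width=analysis.bin_width,
                                 r_max=analysis.r_max)
        for metric, value in report.as_dict().items():
            rows.append({"roi": ri, "metric": metric, "value": value})
    return rows


def _analyze(config: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for ci, cond in enumerate(config.conditions):
        for cell in range(cond.n_cells):
            d = _cell_dir(outdir, cond.label, cell)
            for r in _analyze_cell(d, config.analysis):
                rows.append({"condition": cond.label, "cell": cell, **r})
    return pd.DataFrame(rows)


def _report(config: RunConfig, metrics: pd.DataFrame, outdir: Path) -> dict:
    report = {"split_tests": {}, "comparisons": {}}
    rng = np.random.default_rng(config.seed + 991)
    for cond in config.conditions:
        report["split_tests"][cond.label] = {}
        for metric in METRICS:
            vals = metrics.query("condition == @cond.label and metric == @metric")[
                "value"].dropna().to_numpy()
            if len(vals) >= 4:
                st = split_sufficiency_test(vals, seed=rng)
                report["split_tests"][cond.label][metric] = {
                    "p_split": st.p_split, "sufficient": bool(st.sufficient),
                    "n": int(len(vals)),
                }
    control = config.control
    if control in {c.label for c in config.conditions}:
        ctrl = metrics[metrics["condition"] == control]
        for cond in config.conditions:
            if cond.label == control:
                continue
            report["comparisons"][cond.label] = {}
            grp = metrics[metrics["condition"] == cond.label]
            for metric in METRICS:
                a = ctrl[ctrl["metric"] == metric]["value"].dropna().to_numpy()
                b = grp[grp["metric"] == metric]["value"].dropna().to_numpy()
                if len(a) >= 2 and len(b) >= 2:
                    cmpres = compare_groups(
                        a, b, method=config.analysis.comparison_method)
                    report["comparisons"][cond.label][metric] = {
                        "p_value": cmpres.p_value,
                        "control_mean": cmpres.means[0],
                        "mean": cmpres.means[1],
                        "control_sem": cmpres.sems[0],
                        "sem": cmpres.sems[1],
                    }
    return report


def run(config: RunConfig, write_outputs: bool = True):
    """Execute a configured run; returns ``(metrics, report)``.

    ``metrics`` is the long-format per-ROI table (condition, cell, roi,
    metric, value); ``report`` carries split tests, comparisons against
    the control condition and provenance.  In ``simulate`` mode only
    data directories are written and ``(None, provenance)`` returned.
    """
    if write_outputs:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cleanup = None
    else:
        # data still flows through disk between stages, but in a scratch
        # directory that is removed afterwards
        cleanup = tempfile.TemporaryDirectory(prefix="memdomain_")
        outdir = Path(cleanup.name)
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "mode": config.mode,
        "conditions": [c.label for c in config.conditions],
    }

    if config.mode in ("simulate", "full"):
        try:
            _simulate(config, outdir)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("simulate", str(exc)) from exc
    if config.mode == "simulate":
        if write_outputs:
            (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        return None, provenance

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = _analyze(config, outdir)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("analyze", str(exc)) from exc

    try:
        report = _report(config, metrics, outdir)
    except Exception as exc:
        raise PipelineStageError("report", str(exc)) from exc
    report["provenance"] = provenance

    if write_outputs:
        metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6g")
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    if cleanup is not None:
        cleanup.cleanup()
    return metrics, report
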