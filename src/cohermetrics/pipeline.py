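"""End-to-end pipeline: cohort -> (optional staircase measurement) ->
reading composite -> whole-sample and between-group regressions ->
cross-task correlations -> report bundle.

A single root seed deterministically spawns per-stage substreams, so the
same configuration and seed reproduce every output byte-for-byte, and any
stage can be replayed in isolation from its substream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import TASKS
from .cohort import (CohortSpec, assign_groups, default_cohort_spec,
                     generate_cohort, measure_cohort)
from .composite import pca_composite
from .stats import hierarchical_fit, task_correlations

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

READING_COLS = ["nart_raw", "towre_swe_std", "towre_pd_std"]


@dataclass
class PipelineConfig:
    """Configuration of one full simulated study."""

    cohort_spec: CohortSpec = field(default_factory=default_cohort_spec)
    seed: int = 0
    simulate_measurement: bool = False  # run staircase sessions per subject
    n_staircases: int = 4
    analysis_modes: tuple = ("whole_sample", "between_group")
    tasks: tuple = TASKS
    output_dir: str | Path | None = None

    def config_hash(self) -> str:
        payload = json.dumps({
            "cohort_spec": self.cohort_spec.to_yaml(),
            "seed": self.seed,
            "simulate_measurement": self.simulate_measurement,
            "n_staircases": self.n_staircases,
            "analysis_modes": list(self.analysis_modes),
            "tasks": list(self.tasks),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineReport:
    """In-memory result bundle of one pipeline run."""

    cohort: pd.DataFrame
    composite_report: dict
    whole_sample: dict
    between_group: dict
    correlations: dict
    manifest: dict

    def to_json(self) -> str:
        return json.dumps({
            "composite": self.composite_report,
            "whole_sample": self.whole_sample,
            "between_group": self.between_group,
            "correlations": self.correlations,
            "manifest": self.manifest,
        }, sort_keys=True, indent=2)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and (optionally) write the report bundle to disk."""
    root = np.random.SeedSequence(config.seed)
    cohort_seed, measure_seed = root.spawn(2)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(name, err) from err

    cohort = stage("cohort", lambda: generate_cohort(
        config.cohort_spec, np.random.default_rng(cohort_seed)))
    if config.simulate_measurement:
        cohort = stage("measurement", lambda: measure_cohort(
            cohort, measure_seed, n_staircases=config.n_staircases,
            tasks=config.tasks))

    comp = stage("composite", lambda: pca_composite(cohort[READING_COLS]))
    cohort = cohort.assign(reading_composite=comp.scores)

    whole, between = {}, {}
    if "whole_sample" in config.analysis_modes:
        whole = {task: stage(f"whole_sample:{task}", lambda t=task: hierarchical_fit(
            cohort, t, ["female", "spm_raw"], "reading_composite").report())
            for task in config.tasks}
    if "between_group" in config.analysis_modes:
        grouped = stage("groups", lambda: assign_groups(
            cohort, config.cohort_spec.dyslexia_cutoff))
        subset = grouped[grouped["group"] != "unassigned"].copy()
        subset["reading_group"] = (subset["group"] == "dyslexia").astype(float)
        between = {task: stage(f"between_group:{task}", lambda t=task: hierarchical_fit(
            subset, t, ["female", "spm_raw"], "reading_group").report())
            for task in config.tasks}
        cohort = grouped.assign(reading_composite=comp.scores)

    corr = stage("correlations", lambda: task_correlations(
        cohort, list(config.tasks)).report())

    manifest = {
        "package": "cohermetrics",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "n_participants": int(len(cohort)),
        "simulate_measurement": config.simulate_measurement,
        "stages": ["cohort"] + (["measurement"] if config.simulate_measurement else [])
        + ["composite", *list(config.analysis_modes), "correlations"],
    }
    report = PipelineReport(cohort, comp.report(), whole, between, corr, manifest)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        for name, payload in [("composite", report.composite_report),
                              ("whole_sample", report.whole_sample),
                              ("between_group", report.between_group),
                              ("correlations", report.correlations),
                              ("manifest", report.manifest)]:
            (outdir / f"{name}.json").write_text(
                json.dumps(payload, sort_keys=True, indent=2) + "\n")
        regression_rows = []
        for mode, block in [("whole_sample", report.whole_sample),
                            ("between_group", report.between_group)]:
            for task, rep in block.items():
                regression_rows.append({
                    "mode": mode, "task": task, "n": rep["n"],
                    "r2_step1": rep["r2_step1"], "r2_full": rep["r2_full"],
                    "delta_r2": rep["delta_r2"], "f_change": rep["f_change"],
                    "p_change": rep["p_change"], "f2_local": rep["f2_local"]})
        if regression_rows:
            pd.DataFrame(regression_rows).to_csv(outdir / "regressions.csv", index=False)
    return report
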