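"""End-to-end stages tying the cohort directory to the validation report.

Each stage is a plain function over the text artifacts of a cohort
directory, so the CLI, the analysis drivers, and the acceptance checks all
run the identical code path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as mio
from .activities import METRIC_FIELDS, extract_all
from .functional import TEST_FIELDS, assemble_test_scores
from .simulate import CohortSpec, write_cohort
from .stats import ValidationReport, build_report, grid_to_frame


def simulate_stage(spec: CohortSpec, cohort_dir) -> dict:
    """Generate and write a synthetic cohort; returns the manifest."""
    return write_cohort(spec, cohort_dir)


def extract_stage(cohort_dir, out_csv=None,
                  config: dict | None = None) -> pd.DataFrame:
    """Extract the sensor-metric row of every participant in a cohort."""
    manifest = mio.read_json(Path(cohort_dir) / "manifest.json")
    rows = {}
    for part in manifest["participants"]:
        pid = part["participant_id"]
        traces = mio.read_cohort_traces(cohort_dir, pid)
        rows[pid] = extract_all(traces)
    metrics = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=list(METRIC_FIELDS))
    metrics.index.name = "participant_id"
    if out_csv is not None:
        mio.write_csv(metrics, out_csv, config=config, index=True)
    return metrics


def score_tests_stage(cohort_dir, out_csv=None,
                      config: dict | None = None) -> pd.DataFrame:
    """Score every participant's functional-test measurements."""
    records = mio.read_cohort_tests(cohort_dir)
    rows = {pid: assemble_test_scores(rec) for pid, rec in records.items()}
    scores = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(TEST_FIELDS))
    scores.index.name = "participant_id"
    if out_csv is not None:
        mio.write_csv(scores, out_csv, config=config, index=True)
    return scores


def validate_stage(metrics: pd.DataFrame, test_scores: pd.DataFrame,
                   scores: pd.DataFrame, classes: dict[str, str],
                   config: mio.RunConfig,
                   out_json=None, out_grid_csv=None) -> ValidationReport:
    """Run the statistical validation and optionally write report artifacts."""
    mismatch = set(metrics.index).symmetric_difference(scores["participant_id"])
    if mismatch:
        raise mio.KinematicsError(
            f"participant ids differ between metrics and scores: {sorted(mismatch)[:5]}"
        )
    report = build_report(
        metrics, test_scores, scores, classes,
        alpha=config.alpha, gate_mode=config.gate_mode,
        equal_var=config.equal_var, bh_correction=config.bh_correction,
        config=config.to_dict(),
    )
    if out_json is not None:
        mio.write_json(report.to_dict(), out_json, config=config.to_dict())
    if out_grid_csv is not None:
        mio.write_csv(grid_to_frame(report.correlations), out_grid_csv,
                      config=config.to_dict())
    return report


def run_all(spec: CohortSpec, out_dir, config: mio.RunConfig | None = None):
    """simulate -> extract -> score-tests -> validate, all under ``out_dir``."""
    out = Path(out_dir)
    config = config or mio.RunConfig(seed=spec.seed)
    manifest = simulate_stage(spec, out / "cohort")
    metrics = extract_stage(out / "cohort", out / "metrics.csv",
                            config=config.to_dict())
    tests = score_tests_stage(out / "cohort", out / "test_scores.csv",
                              config=config.to_dict())
    scores = mio.read_scores(out / "cohort" / "scores.csv")
    classes = {p["participant_id"]: p["class_label"]
               for p in manifest["participants"]}
    report = validate_stage(metrics, tests, scores, classes, config,
                            out_json=out / "report.json",
                            out_grid_csv=out / "correlations.csv")
    return report
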