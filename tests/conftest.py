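import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from movemetrics import io as mio
from movemetrics.pipeline import run_all
from movemetrics.simulate import CohortSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """One full default-parameter cohort run (n = 150, seed 42), shared.

    Returns the output directory, the validation report, and the wide
    participant table (metrics + test scores + mean overall score).
    """
    out = tmp_path_factory.mktemp("cohort42")
    spec = CohortSpec(seed=42, n=150)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_all(spec, out)
    metrics = mio.read_csv(out / "metrics.csv", index_col="participant_id")
    tests = mio.read_csv(out / "test_scores.csv", index_col="participant_id")
    scores = mio.read_scores(out / "cohort" / "scores.csv")
    mean_score = scores.groupby("participant_id")["score"].mean()
    wide = metrics.join(tests).join(mean_score.rename("overall_score"))
    manifest = mio.read_json(out / "manifest.json" if (out / "manifest.json").exists()
                             else out / "cohort" / "manifest.json")
    return {
        "dir": out,
        "report": report,
        "metrics": metrics,
        "tests": tests,
        "scores": scores,
        "wide": wide,
        "manifest": manifest,
    }
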