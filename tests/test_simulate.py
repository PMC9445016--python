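"""Tests for the synthetic cohort generator."""

import warnings

import numpy as np
import pytest

from movemetrics.activities import ACTIVITIES, extract_all
from movemetrics.core import KinematicsError
from movemetrics.functional import assemble_test_scores
from movemetrics.simulate import (
    CohortSpec,
    ImpairmentProfile,
    sample_profiles,
    simulate_overall_scores,
    simulate_participant_traces,
    simulate_test_measurements,
    simulate_trace,
    write_cohort,
)


def profile_at(theta: float) -> ImpairmentProfile:
    return ImpairmentProfile("PX", 0, "healthy", theta, theta, theta, theta)


class TestProfiles:
    def test_same_seed_identical(self):
        spec = CohortSpec(seed=5, n=30)
        assert sample_profiles(spec) == sample_profiles(spec)

    def test_distinct_seeds_distinct(self):
        a = sample_profiles(CohortSpec(seed=5, n=30))
        b = sample_profiles(CohortSpec(seed=6, n=30))
        assert [p.theta for p in a] != [p.theta for p in b]

    def test_class_conditional_theta_ordering(self):
        profiles = sample_profiles(CohortSpec(seed=42, n=150))
        means = {}
        for cls in ("athlete", "healthy", "impaired"):
            thetas = [p.theta for p in profiles if p.class_label == cls]
            assert thetas, cls
            means[cls] = np.mean(thetas)
        assert means["athlete"] < means["healthy"] < means["impaired"]

    def test_degenerate_proportions(self):
        spec = CohortSpec(seed=1, n=20,
                          proportions={"athlete": 1.0, "healthy": 0.0,
                                       "impaired": 0.0})
        assert all(p.class_label == "athlete" for p in sample_profiles(spec))

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(KinematicsError):
            CohortSpec(seed=1, proportions={"athlete": 0.5, "healthy": 0.2,
                                            "impaired": 0.2})

    def test_theta_is_mean_of_subcomponents(self):
        for p in sample_profiles(CohortSpec(seed=9, n=25)):
            assert p.theta == pytest.approx(np.mean([p.m, p.s, p.p]))


class TestTraces:
    def test_same_seed_identical_trace(self):
        spec = CohortSpec(seed=8, n=1)
        prof = profile_at(0.4)
        t1 = simulate_trace("overhead_squat", prof, spec)
        t2 = simulate_trace("overhead_squat", prof, spec)
        for name in t1.channels:
            assert np.array_equal(t1.channels[name], t2.channels[name])

    def test_theta_out_of_bounds_rejected(self):
        with pytest.raises(KinematicsError):
            ImpairmentProfile("PX", 0, "healthy", 1.2, 1.2, 1.2, 1.2)

    def test_noiseless_ideal_has_no_taps_and_exact_depth(self):
        spec = CohortSpec(seed=2, n=1, noise=0.0)
        traces = simulate_participant_traces(profile_at(0.0), spec)
        metrics = extract_all(traces)
        assert metrics["toe_taps"] == 0.0
        assert metrics["ohs_pelvis_depth"] == pytest.approx(0.13, abs=1e-9)

    @pytest.mark.parametrize("metric,direction", [
        ("postural_sway", +1),
        ("toe_taps", +1),
        ("slb_trunk_var", +1),
        ("lunge_knee_ground", +1),
        ("ohs_knee_max", -1),
        ("reach_shoulder_max", -1),
        ("fts_pelvis_depth", -1),
    ])
    def test_metric_monotone_in_impairment(self, metric, direction):
        """Mean extracted metric moves with theta in the modeled direction."""
        lo, hi = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                spec = CohortSpec(seed=300 + seed, n=1)
                for theta, out in ((0.1, lo), (0.8, hi)):
                    traces = simulate_participant_traces(profile_at(theta), spec)
                    out.append(extract_all(traces)[metric])
        delta = np.mean(hi) - np.mean(lo)
        assert direction * delta > 0, (metric, delta)


class TestScoresAndTests:
    def test_noiseless_base_score(self):
        spec = CohortSpec(seed=3, n=1, noise=0.0)
        assert np.array_equal(simulate_overall_scores(profile_at(0.0), spec),
                              [95.0, 95.0, 95.0])

    def test_score_decreases_with_theta(self):
        spec = CohortSpec(seed=3, n=1, noise=0.0)
        s0 = simulate_overall_scores(profile_at(0.0), spec).mean()
        s1 = simulate_overall_scores(profile_at(1.0), spec).mean()
        assert s0 == 95.0 and s1 == 65.0

    def test_ideal_timed_balance_at_cap(self):
        spec = CohortSpec(seed=4, n=1, noise=0.0, missingness=False)
        record = simulate_test_measurements(profile_at(0.0), spec)
        scores = assemble_test_scores(record)
        assert scores["ctsib_t"] == 180.0
        assert scores["romberg_t"] == 60.0

    def test_measurements_reproducible(self):
        spec = CohortSpec(seed=4, n=1)
        r1 = simulate_test_measurements(profile_at(0.3), spec)
        r2 = simulate_test_measurements(profile_at(0.3), spec)
        assert assemble_test_scores(r1) == assemble_test_scores(r2)


class TestWriteCohort:
    def test_smoke_cohort_layout(self, tmp_path):
        spec = CohortSpec(seed=7, n=3)
        manifest = write_cohort(spec, tmp_path)
        traces = sorted((tmp_path / "traces").glob("*.csv"))
        assert len(traces) == 3 * len(ACTIVITIES)
        assert len(sorted((tmp_path / "traces").glob("*.json"))) == len(traces)
        for name in ("scores.csv", "tests.csv", "balance_acc.csv",
                     "limb_lengths.csv", "manifest.json"):
            assert (tmp_path / name).exists()
        assert len(manifest["participants"]) == 3

    def test_trace_round_trip_preserves_extraction(self, tmp_path):
        from movemetrics import io as mio
        spec = CohortSpec(seed=7, n=2)
        write_cohort(spec, tmp_path)
        profiles = sample_profiles(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for prof in profiles:
                in_memory = extract_all(simulate_participant_traces(prof, spec))
                from_disk = extract_all(
                    mio.read_cohort_traces(tmp_path, prof.participant_id))
                assert from_disk == in_memory  # bitwise: lossless round trip

    def test_test_records_round_trip(self, tmp_path):
        from movemetrics import io as mio
        spec = CohortSpec(seed=11, n=3)
        write_cohort(spec, tmp_path)
        records = mio.read_cohort_tests(tmp_path)
        for prof in sample_profiles(spec):
            expected = assemble_test_scores(
                simulate_test_measurements(prof, spec))
            got = assemble_test_scores(records[prof.participant_id])
            for key, val in expected.items():
                if np.isnan(val):
                    assert np.isnan(got[key]), key
                else:
                    assert got[key] == val, key

    def test_distinct_seeds_distinct_data(self, tmp_path):
        write_cohort(CohortSpec(seed=1, n=1), tmp_path / "a")
        write_cohort(CohortSpec(seed=2, n=1), tmp_path / "b")
        a = (tmp_path / "a" / "scores.csv").read_text()
        b = (tmp_path / "b" / "scores.csv").read_text()
        assert a != b


def test_parameter_recovery_from_extracted_metrics(cohort_run):
    """A sign-corrected composite of extracted metrics tracks true theta.

    Each metric is z-scored, oriented so that larger = more impaired, and
    averaged; across the default cohort this proxy should correlate
    strongly (r > 0.7) with the latent impairment used to generate the
    data.
    """
    from movemetrics.stats import METRIC_HYPOTHESES
    wide = cohort_run["wide"]
    theta = {p["participant_id"]: p["theta"]
             for p in cohort_run["manifest"]["participants"]}
    theta = np.array([theta[pid] for pid in wide.index])
    z = []
    for field, sign in METRIC_HYPOTHESES.items():
        col = wide[field].to_numpy()
        scaled = (col - np.nanmean(col)) / np.nanstd(col)
        z.append(-scaled if sign == "+" else scaled)
    proxy = np.nanmean(z, axis=0)
    r = np.corrcoef(proxy, theta)[0, 1]
    assert r > 0.7
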