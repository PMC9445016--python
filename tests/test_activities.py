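"""Tests for repetition segmentation and the five activity extractors."""

import math
import warnings

import numpy as np
import pytest

from movemetrics.activities import (
    EXPECTED_REPS,
    METRIC_FIELDS,
    MotionTrace,
    NoRepetitionsError,
    ExtractionError,
    Phase,
    extract_all,
    extract_forward_lunge,
    extract_overhead_squat,
    extract_single_leg_balance,
    segment_repetitions,
)
from movemetrics.core import KinematicsError
from movemetrics.simulate import CohortSpec, ImpairmentProfile, simulate_trace

FS = 60.0


def dip_signal(n, centers, depth, baseline, width=75):
    """Baseline signal with raised-cosine dips at the given sample centers."""
    z = np.full(n, baseline)
    for c in centers:
        lo, hi = c - width // 2, c + width // 2
        w = np.hanning(hi - lo)
        z[lo:hi] -= depth * w
    return z


def squat_trace(n_reps=3, depth=0.3, activity="feet_together_squat"):
    n = int(FS * (2 + 2.5 * n_reps))
    centers = [int(FS * (1 + 2.5 * (k + 0.5))) for k in range(n_reps)]
    pelvis = dip_signal(n, centers, depth, 0.95)
    flat = np.full(n, 0.5)
    ang = np.full(n, 20.0)
    channels = {
        "pelvis_z": pelvis, "knee_z_L": flat, "knee_z_R": flat,
        "hip_flexion_L": ang, "hip_flexion_R": ang,
        "knee_flexion_L": ang, "knee_flexion_R": ang,
    }
    if activity == "overhead_squat":
        channels["trunk_lateral"] = np.abs(np.sin(np.arange(n) / FS))
        channels["elbow_flexion_L"] = ang.copy()
        channels["elbow_flexion_R"] = ang.copy()
    return MotionTrace(FS, activity, channels)


def balance_trace(sway_sd=(0.1, 0.1), trunk=(1.0, 1.0), taps=(0, 0)):
    """Two 10 s stance phases; per-phase sway scale, trunk scale, tap count."""
    phase_len, gap = int(10 * FS), int(FS)
    n = 2 * phase_len + gap
    rng = np.random.default_rng(99)
    acc_x = np.empty(n)
    acc_y = np.empty(n)
    trunk_ch = np.empty(n)
    toe_L = np.where(np.arange(n) < phase_len + gap, 0.02, 0.12).astype(float)
    toe_R = np.where(np.arange(n) < phase_len + gap, 0.12, 0.02).astype(float)
    phases = [Phase("balance_left", 0, phase_len),
              Phase("balance_right", phase_len + gap, n)]
    t = np.arange(n) / FS
    for ph, sd, tr, k in zip(phases, sway_sd, trunk, taps):
        sl = slice(ph.start, ph.end)
        acc_x[sl] = rng.normal(0, sd, ph.end - ph.start)
        acc_y[sl] = rng.normal(0, sd, ph.end - ph.start)
        trunk_ch[sl] = tr * (0.5 + 0.5 * np.sin(2 * np.pi * 0.25 * t[sl]))
        raised = toe_R if ph.label == "balance_left" else toe_L
        for j in range(k):
            i0 = ph.start + int((j + 0.5) * FS)
            raised[i0:i0 + 20] -= 0.13
    acc_x[phase_len:phase_len + gap] = 0.0
    acc_y[phase_len:phase_len + gap] = 0.0
    trunk_ch[phase_len:phase_len + gap] = 0.0
    return MotionTrace(FS, "single_leg_balance", {
        "com_acc_x": acc_x, "com_acc_y": acc_y, "trunk_lateral": trunk_ch,
        "toe_z_L": toe_L, "toe_z_R": toe_R,
    }, phases)


class TestSegmentation:
    @pytest.mark.parametrize("k", [3, 6])
    def test_recovers_known_dip_count(self, k):
        trace = squat_trace(n_reps=k, activity="feet_together_squat")
        reps = segment_repetitions(trace)
        assert len(reps) == k
        # each detected window contains exactly one constructed dip center
        centers = [int(FS * (1 + 2.5 * (j + 0.5))) for j in range(k)]
        for (s, e), c in zip(reps, centers):
            assert s <= c < e

    def test_flat_channel_is_an_error(self):
        trace = squat_trace(n_reps=3)
        trace.channels["pelvis_z"] = np.full(trace.n_samples, 0.95)
        with pytest.raises(NoRepetitionsError):
            segment_repetitions(trace)

    def test_count_mismatch_warns_but_returns(self):
        trace = squat_trace(n_reps=4)
        with pytest.warns(UserWarning, match="expected 6"):
            reps = segment_repetitions(trace, expected=6)
        assert len(reps) == 4 and reps.warning is not None

    def test_windows_ordered_and_disjoint(self):
        reps = segment_repetitions(squat_trace(n_reps=6))
        flat = [i for w in reps for i in w]
        assert flat == sorted(flat)


class TestSingleLegBalance:
    def test_phase_averaging_contract(self):
        # sway differs by a known factor between feet; the metric is the mean
        tr = balance_trace(sway_sd=(0.1, 0.2))
        per = []
        from movemetrics.core import PlanarSamples, ellipse_area_95
        for ph in tr.phases:
            per.append(ellipse_area_95(PlanarSamples(
                tr.channels["com_acc_x"][ph.start:ph.end],
                tr.channels["com_acc_y"][ph.start:ph.end])))
        out = extract_single_leg_balance(tr)
        assert out["postural_sway"] == pytest.approx(np.mean(per))

    def test_tap_counts_averaged_over_feet(self):
        out = extract_single_leg_balance(balance_trace(taps=(2, 4)))
        assert out["toe_taps"] == pytest.approx(3.0)

    def test_missing_phase_annotation_rejected(self):
        tr = balance_trace()
        tr.phases = [tr.phases[0]]
        with pytest.raises(KinematicsError):
            extract_single_leg_balance(tr)

    def test_ideal_generator_trace_is_quiet(self):
        spec = CohortSpec(seed=3, n=1, noise=0.0)
        prof = ImpairmentProfile("P0", 0, "athlete", 0.0, 0.0, 0.0, 0.0)
        out = extract_single_leg_balance(
            simulate_trace("single_leg_balance", prof, spec))
        assert out["toe_taps"] == 0.0
        assert out["slb_trunk_var"] < 0.5


class TestForwardLunge:
    def _lunge_trace(self, minima_L, minima_R):
        n_reps = len(minima_L) + len(minima_R)
        n = int(FS * (2 + 2.5 * n_reps))
        kL = np.full(n, 0.45)
        kR = np.full(n, 0.45)
        it = iter(range(n_reps))
        for side, minima in (("L", minima_L), ("R", minima_R)):
            target = kL if side == "L" else kR
            for g in minima:
                k = next(it)
                c = int(FS * (1 + 2.5 * (k + 0.5)))
                w = np.hanning(100)
                target[c - 50:c + 50] -= (0.45 - g) * w
        return MotionTrace(FS, "forward_lunge", {
            "knee_z_L": kL, "knee_z_R": kR,
            "trunk_lateral": np.abs(np.sin(np.arange(n) / FS)),
        })

    def test_per_rep_minima_averaged(self):
        tr = self._lunge_trace([0.05] * 3, [0.15] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = extract_forward_lunge(tr)
        assert out["lunge_knee_ground"] == pytest.approx(0.10, abs=1e-3)

    def test_knee_touching_floor_scores_zero(self):
        tr = self._lunge_trace([0.0] * 3, [0.0] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = extract_forward_lunge(tr)
        assert out["lunge_knee_ground"] == pytest.approx(0.0, abs=1e-3)

    def test_too_few_reps_is_extraction_error(self):
        tr = self._lunge_trace([0.05], [])
        with pytest.raises((ExtractionError, NoRepetitionsError)), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            extract_forward_lunge(tr)


class TestSquatDepth:
    def test_sign_convention_pelvis_above_knees(self):
        tr = squat_trace(n_reps=3, depth=0.35)
        # pelvis min = 0.95 - 0.35 = 0.60, knee min = 0.50 -> depth -0.10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = extract_overhead_squat(squat_with_arms(tr))
        assert out["ohs_pelvis_depth"] == pytest.approx(-0.10, abs=1e-3)

    def test_depth_positive_when_pelvis_below_knees(self):
        tr = squat_trace(n_reps=3, depth=0.55)  # pelvis min 0.40, knee 0.50
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = extract_overhead_squat(squat_with_arms(tr))
        assert out["ohs_pelvis_depth"] == pytest.approx(0.10, abs=1e-3)


def squat_with_arms(tr):
    ch = dict(tr.channels)
    n = tr.n_samples
    ch.setdefault("trunk_lateral", np.abs(np.sin(np.arange(n) / FS)))
    ch.setdefault("elbow_flexion_L", np.full(n, 20.0))
    ch.setdefault("elbow_flexion_R", np.full(n, 20.0))
    return MotionTrace(tr.fs, "overhead_squat", ch)


class TestAssembly:
    @pytest.fixture()
    def ideal_traces(self):
        spec = CohortSpec(seed=11, n=1, noise=0.0)
        prof = ImpairmentProfile("P0", 0, "athlete", 0.0, 0.0, 0.0, 0.0)
        from movemetrics.simulate import simulate_participant_traces
        return simulate_participant_traces(prof, spec)

    def test_complete_set_from_ideal_templates(self, ideal_traces):
        out = extract_all(ideal_traces)
        assert set(out) == set(METRIC_FIELDS)
        assert out["toe_taps"] == 0.0
        assert not any(math.isnan(v) for v in out.values())

    def test_template_amplitude_recovered(self, ideal_traces):
        # noiseless template: flat-topped knee flexion peaks at 5 + 140 deg
        out = extract_all(ideal_traces)
        assert out["fts_knee_max"] == pytest.approx(145.0, abs=1.0)
        assert out["ohs_pelvis_depth"] == pytest.approx(0.13, abs=1e-9)

    def test_missing_activity_marks_fields_nan(self, ideal_traces):
        traces = {k: v for k, v in ideal_traces.items()
                  if k != "single_leg_balance"}
        out = extract_all(traces)
        assert math.isnan(out["postural_sway"]) and math.isnan(out["toe_taps"])
        assert not math.isnan(out["ohs_pelvis_depth"])

    def test_determinism(self, ideal_traces):
        assert extract_all(ideal_traces) == extract_all(ideal_traces)

    def test_bilateral_symmetry(self, ideal_traces):
        def swap(trace):
            ch = {}
            for k, v in trace.channels.items():
                if k.endswith("_L"):
                    ch[k[:-2] + "_R"] = v
                elif k.endswith("_R"):
                    ch[k[:-2] + "_L"] = v
                else:
                    ch[k] = v
            swap_label = {"balance_left": "balance_right",
                          "balance_right": "balance_left"}
            phases = [Phase(swap_label.get(p.label, p.label), p.start, p.end)
                      for p in trace.phases]
            return MotionTrace(trace.fs, trace.activity, ch, phases)

        base = extract_all(ideal_traces)
        mirrored = extract_all({k: swap(v) for k, v in ideal_traces.items()})
        for key in METRIC_FIELDS:
            assert mirrored[key] == pytest.approx(base[key], rel=1e-9), key

    def test_missing_channel_rejected(self, ideal_traces):
        tr = ideal_traces["feet_together_squat"]
        ch = {k: v for k, v in tr.channels.items() if k != "knee_z_L"}
        with pytest.raises(KinematicsError, match="knee_z_L"):
            MotionTrace(tr.fs, tr.activity, ch)
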