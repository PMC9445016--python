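"""Synthetic motion-capture cohort generator.

Stands in for the human-subject study data: it emits full-body kinematic
traces for the five assessment activities, overall movement-health trial
scores, and raw functional-test measurements, all driven by a latent
impairment parameter theta in [0, 1] with mobility / stability / posture
subcomponents (m, s, p). The generator is a statistical stand-in, not a
biomechanical simulation: it reproduces the *structure* the validation
analysis assumes — three ability classes with stochastically ordered
impairment, monotone degradation of every metric with its subcomponent,
trial-to-trial score noise — so the whole pipeline is testable without any
recorded data.

All randomness flows from the single cohort seed through per-participant,
per-stream ``numpy`` SeedSequences; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .activities import MotionTrace, Phase
from .core import KinematicsError, PlanarSamples

#: Class-conditional Beta parameters for the latent impairment base draw.
#: Illustrative defaults: athletes concentrate near 0, impaired near 0.67.
CLASS_BETA = {
    "athlete": (2.0, 10.0),
    "healthy": (3.0, 6.0),
    "impaired": (8.0, 4.0),
}

#: Default class proportions: 113 healthy, 17 athletes, 20 impaired of 150.
DEFAULT_PROPORTIONS = {"healthy": 113 / 150, "athlete": 17 / 150, "impaired": 20 / 150}

#: Completion rates per test (completed participants out of 150).
TEST_COMPLETION = {
    "plumb_line": 150 / 150,
    "rbb_i": 148 / 150,
    "rbb_s": 148 / 150,
    "ckcue": 130 / 150,
    "y_balance": 137 / 150,
    "sit_reach": 149 / 150,
    "functional_reach": 149 / 150,
    "star_excursion": 149 / 150,
    "hurdle_step": 147 / 150,
    "uhbe": 148 / 150,
    "single_leg_hop": 133 / 150,
    "ctsib": 149 / 150,
    "romberg": 149 / 150,
}

_STREAMS = {
    "profile": 0,
    "single_leg_balance": 1,
    "forward_lunge": 2,
    "overhead_squat": 3,
    "overhead_reach": 4,
    "feet_together_squat": 5,
    "scores": 6,
    "tests": 7,
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort.

    ``noise`` is a global multiplier on every measurement/trial noise scale
    (0 disables noise while leaving the signal structure — sway, taps —
    intact); the individual scales give the defaults at noise = 1.
    """

    seed: int
    n: int = 150
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    fs: float = 60.0
    n_trials: int = 3
    noise: float = 1.0
    angle_noise_deg: float = 0.3
    position_noise_m: float = 0.003
    score_noise: float = 1.5
    tap_rate: float = 3.0
    sway_sd_base: float = 0.2
    missingness: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise KinematicsError("CohortSpec requires an explicit seed")
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise KinematicsError(f"class proportions sum to {total}, not 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ImpairmentProfile:
    """Latent ability of one synthetic participant.

    theta is the mean of the mobility (m), stability (s) and posture (p)
    deficit subcomponents, each in [0, 1]; class-conditional distributions
    are stochastically ordered athlete < healthy < impaired.
    """

    participant_id: str
    index: int
    class_label: str
    theta: float
    m: float
    s: float
    p: float

    def __post_init__(self):
        for name in ("theta", "m", "s", "p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise KinematicsError(f"{name} = {v} outside [0, 1]")


def _rng(spec: CohortSpec, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), _STREAMS[stream], int(index)])
    )


def sample_profiles(spec: CohortSpec) -> list[ImpairmentProfile]:
    """Draw the cohort's class labels and impairment profiles.

    Class is sampled from the cohort proportions; the subcomponents share a
    class-conditional Beta base draw plus independent jitter (sd 0.08), so
    they are correlated but distinct, and theta is their mean.
    """
    rng = _rng(spec, "profile")
    labels = list(spec.proportions)
    probs = np.array([spec.proportions[c] for c in labels])
    profiles = []
    for i in range(spec.n):
        cls = str(rng.choice(labels, p=probs))
        a, b = CLASS_BETA[cls]
        base = rng.beta(a, b)
        msp = np.clip(base + rng.normal(0.0, 0.08, size=3), 0.0, 1.0)
        profiles.append(ImpairmentProfile(
            participant_id=f"P{i:03d}", index=i, class_label=cls,
            theta=float(msp.mean()), m=float(msp[0]), s=float(msp[1]),
            p=float(msp[2]),
        ))
    return profiles


# ---------------------------------------------------------------------------
# trace templates

def _ou(rng: np.random.Generator, n: int, sd: float, fs: float,
        tau: float = 0.5) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (sd, mean-reversion time tau).

    Mean-reverting rather than white so that the sway ellipse is
    well-defined and robust to the sampling rate.
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (tau * fs))
    w = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    w[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -a], w)


def _rep_profile(n: int) -> np.ndarray:
    """One repetition's 0..1 excursion profile with a flat top.

    A clipped sin^2 bump: the plateau makes the decile-median robust
    extremum recover the template amplitude exactly (up to noise).
    """
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.clip(1.15 * np.sin(np.pi * t) ** 2, 0.0, 1.0)


def _rep_track(n_total: int, pad: int, rep_len: int, n_reps: int) -> np.ndarray:
    track = np.zeros(n_total)
    prof = _rep_profile(rep_len)
    for k in range(n_reps):
        s = pad + k * rep_len
        track[s:s + rep_len] = prof
    return track


def _trunk_channel(rng, n, fs, p, base_amp, noise_sd):
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    amp = base_amp * (1.0 + 4.0 * p)
    trunk = amp * (0.5 + 0.5 * np.sin(2.0 * np.pi * 0.25 * t + phase))
    trunk = trunk + rng.normal(0.0, noise_sd, n)
    return np.clip(trunk, 0.0, None)


def _elbow_channel(rng, n, fs, s, noise_sd):
    # impaired stability shows as bent, wobbly elbows: baseline and wobble
    # amplitude both grow with the stability deficit
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    base = 5.0 + 25.0 * s
    wobble = 1.5 * (1.0 + 4.0 * s) * np.sin(2.0 * np.pi * 1.2 * t + phase)
    return base + wobble + rng.normal(0.0, noise_sd, n)


def simulate_trace(activity: str, profile: ImpairmentProfile,
                   spec: CohortSpec) -> MotionTrace:
    """Generate one annotated motion trace for a participant and activity.

    Impairment effects: squat/lunge depths and joint-angle amplitudes scale
    with (1 - 0.6 m); lateral trunk amplitude with (1 + 4 p); COM
    acceleration is Ornstein-Uhlenbeck noise with sd scaled by (1 + 5 s);
    toe taps arrive as a Poisson count with rate ``tap_rate * s`` per
    balance phase. Gaussian measurement noise (defaults 0.3 deg / 3 mm) is
    added to angle and position channels; phase and repetition structure is
    written to the annotations.
    """
    rng = _rng(spec, activity, profile.index)
    fs = spec.fs
    m, s, p = profile.m, profile.s, profile.p
    ang_sd = spec.noise * spec.angle_noise_deg
    pos_sd = spec.noise * spec.position_noise_m
    amp = 1.0 - 0.6 * m  # mobility scaling of depths and angle amplitudes

    if activity == "single_leg_balance":
        phase_len, gap = int(round(10 * fs)), int(round(1 * fs))
        n = 2 * phase_len + gap
        sway_sd = spec.sway_sd_base * (1.0 + 5.0 * s)
        channels = {
            "com_acc_x": _ou(rng, n, sway_sd, fs),
            "com_acc_y": _ou(rng, n, sway_sd, fs),
            "trunk_lateral": _trunk_channel(rng, n, fs, p, 1.0, ang_sd),
        }
        # left-stance phase: right foot raised (plant toes sit at 0.02 m,
        # the raised toe at 0.12 m); roles swap for the right-stance phase
        phases = [Phase("balance_left", 0, phase_len),
                  Phase("balance_right", phase_len + gap, n)]
        left_half = np.arange(n) < phase_len + gap
        toe_L = np.where(left_half, 0.02, 0.12) + rng.normal(0.0, pos_sd, n)
        toe_R = np.where(left_half, 0.12, 0.02) + rng.normal(0.0, pos_sd, n)
        dip_len = int(round(0.4 * fs))
        dip = 0.13 * np.sin(np.pi * np.linspace(0, 1, dip_len, endpoint=False)) ** 2
        for ph, raised in ((phases[0], "R"), (phases[1], "L")):
            count = int(rng.poisson(spec.tap_rate * s))
            slot = int(round(0.7 * fs))
            slots = (ph.end - ph.start - dip_len) // slot
            count = min(count, max(slots, 0))
            if count > 0:
                starts = rng.choice(slots, size=count, replace=False)
                tgt = toe_R if raised == "R" else toe_L
                for st in np.sort(starts):
                    i0 = ph.start + int(st) * slot
                    tgt[i0:i0 + dip_len] -= dip
        channels["toe_z_L"] = toe_L
        channels["toe_z_R"] = toe_R
        return MotionTrace(fs, activity, channels, phases,
                           participant_id=profile.participant_id)

    if activity == "forward_lunge":
        rep_len, pad, n_reps = int(round(2.5 * fs)), int(round(1.0 * fs)), 6
        n = 2 * pad + n_reps * rep_len
        g = 0.01 + 0.12 * m  # minimum knee-ground clearance grows with deficit
        knee_l = np.full(n, 0.45) + rng.normal(0.0, pos_sd, n)
        knee_r = np.full(n, 0.45) + rng.normal(0.0, pos_sd, n)
        prof = _rep_profile(rep_len)
        for k in range(n_reps):
            s0 = pad + k * rep_len
            target = knee_l if k % 2 == 0 else knee_r
            target[s0:s0 + rep_len] -= (0.45 - g) * prof
        channels = {
            "knee_z_L": knee_l,
            "knee_z_R": knee_r,
            "trunk_lateral": _trunk_channel(rng, n, fs, p, 1.5, ang_sd),
        }
        return MotionTrace(fs, activity, channels,
                           participant_id=profile.participant_id)

    if activity in ("overhead_squat", "feet_together_squat"):
        n_reps = 6 if activity == "overhead_squat" else 3
        rep_len, pad = int(round(2.5 * fs)), int(round(1.0 * fs))
        n = 2 * pad + n_reps * rep_len
        track = _rep_track(n, pad, rep_len, n_reps)
        depth = (-0.05 + 0.18 * amp) if activity == "overhead_squat" \
            else (-0.05 + 0.16 * amp)
        knee_base, knee_dip = 0.50, 0.02
        pelvis_min = (knee_base - knee_dip) - depth
        channels = {
            "pelvis_z": 0.95 - (0.95 - pelvis_min) * track
                        + rng.normal(0.0, pos_sd, n),
            "knee_z_L": knee_base - knee_dip * track + rng.normal(0.0, pos_sd, n),
            "knee_z_R": knee_base - knee_dip * track + rng.normal(0.0, pos_sd, n),
        }
        a_hip = (110.0 if activity == "overhead_squat" else 120.0) * amp
        a_knee = (130.0 if activity == "overhead_squat" else 140.0) * amp
        for side in ("L", "R"):
            channels[f"hip_flexion_{side}"] = 5.0 + a_hip * track \
                + rng.normal(0.0, ang_sd, n)
            channels[f"knee_flexion_{side}"] = 5.0 + a_knee * track \
                + rng.normal(0.0, ang_sd, n)
        if activity == "overhead_squat":
            channels["trunk_lateral"] = _trunk_channel(rng, n, fs, p, 1.5, ang_sd)
            for side in ("L", "R"):
                channels[f"elbow_flexion_{side}"] = _elbow_channel(
                    rng, n, fs, s, ang_sd)
        return MotionTrace(fs, activity, channels,
                           participant_id=profile.participant_id)

    if activity == "overhead_reach":
        rep_len, pad, n_reps = int(round(3.0 * fs)), int(round(1.0 * fs)), 3
        n = 2 * pad + n_reps * rep_len
        track = _rep_track(n, pad, rep_len, n_reps)
        s_max = 170.0 * amp
        channels = {}
        for side in ("L", "R"):
            channels[f"shoulder_flexion_{side}"] = 10.0 + (s_max - 10.0) * track \
                + rng.normal(0.0, ang_sd, n)
            channels[f"elbow_flexion_{side}"] = _elbow_channel(rng, n, fs, s, ang_sd)
        return MotionTrace(fs, activity, channels,
                           participant_id=profile.participant_id)

    raise KinematicsError(f"unknown activity {activity!r}")


def simulate_overall_scores(profile: ImpairmentProfile,
                            spec: CohortSpec) -> np.ndarray:
    """Per-trial overall movement-health scores (0-100) for one participant.

    Base score is 95 - 30 * theta; each trial adds Gaussian noise (default
    sd 1.5, tuned to a cohort-level intrasubject CV of order 1-3%) and is
    clipped to [0, 100].
    """
    rng = _rng(spec, "scores", profile.index)
    base = 95.0 - 30.0 * profile.theta
    eps = rng.normal(0.0, spec.noise * spec.score_noise, size=spec.n_trials)
    return np.clip(base + eps, 0.0, 100.0)


def simulate_test_measurements(profile: ImpairmentProfile,
                               spec: CohortSpec) -> dict:
    """Raw functional-test measurements for one participant.

    Each test's latent mean is linear in the relevant deficit subcomponent
    with the hypothesized correlation sign (reach and depth tests decrease
    with the mobility deficit m, balance tests degrade with the stability
    deficit s, the plumb-line spread grows with the posture deficit p),
    plus Gaussian trial noise. Per-test missingness is Bernoulli with the
    study's completion rates; missing tests are absent keys. The record
    also carries ``leg_length`` / ``arm_length`` (inches) and is directly
    scorable by :func:`movemetrics.functional.assemble_test_scores`.
    """
    rng = _rng(spec, "tests", profile.index)
    m, s, p = profile.m, profile.s, profile.p
    nz = spec.noise
    fs = spec.fs

    def keep(test: str) -> bool:
        if not spec.missingness:
            return True
        return rng.random() < TEST_COMPLETION[test]

    record: dict = {}
    leg_length = float(34.0 + rng.normal(0.0, 2.0))
    arm_length = float(31.0 + rng.normal(0.0, 2.0))
    record["leg_length"] = leg_length
    record["arm_length"] = arm_length

    if keep("plumb_line"):
        record["plumb_line"] = list(
            1.0 + rng.normal(0.0, 0.25 + 1.25 * p, size=4))
    if keep("rbb_s"):
        record["rbb_s"] = list(12.0 - 8.0 * m + nz * rng.normal(0.0, 1.0, 2))
    if keep("rbb_i"):
        record["rbb_i"] = list(4.0 + 10.0 * m + nz * rng.normal(0.0, 1.0, 2))
    if keep("ckcue"):
        attempted = not (profile.theta > 0.8 and rng.random() < 0.5)
        counts = np.clip(np.round(28.0 - 18.0 * s
                                  + nz * rng.normal(0.0, 2.0, 3)), 0, None)
        record["ckcue"] = {"counts": list(counts), "attempted": attempted}
    if keep("y_balance"):
        record["y_balance"] = {
            "reaches": {
                arm: list(arm_length * (1.0 - 0.35 * s)
                          + nz * rng.normal(0.0, 1.0, 3))
                for arm in ("L", "R")
            },
            "arm_length": arm_length,
        }
    if keep("sit_reach"):
        record["sit_reach"] = list(15.0 - 10.0 * m + nz * rng.normal(0.0, 1.0, 3))
    if keep("functional_reach"):
        record["functional_reach"] = list(
            12.0 - 6.0 * s + nz * rng.normal(0.0, 1.0, 6))
    if keep("star_excursion"):
        record["star_excursion"] = {
            "reaches": {
                leg: list(leg_length * (0.95 - 0.35 * s)
                          + nz * rng.normal(0.0, 1.0, 8))
                for leg in ("L", "R")
            },
            "leg_length": leg_length,
        }
    if keep("hurdle_step"):
        record["hurdle_step"] = {
            side: [int(g) for g in np.clip(
                np.round(3.1 - 3.3 * m + nz * rng.normal(0.0, 0.45, 3)), 0, 3)]
            for side in ("left", "right")
        }
    if keep("uhbe"):
        record["uhbe"] = list(np.clip(
            35.0 * (1.0 - 0.85 * s) + nz * rng.normal(0.0, 3.0, 2), 0.0, None))
    if keep("single_leg_hop"):
        record["single_leg_hop"] = list(np.clip(
            40.0 * (1.0 - 0.6 * m) + nz * rng.normal(0.0, 2.0, 2), 0.0, None))

    acc_sd = 0.15 * (1.0 + 5.0 * s)
    if keep("ctsib"):
        durations = np.clip(30.0 * (1.15 - 1.1 * s)
                            + nz * rng.normal(0.0, 1.5, 6), 0.0, 30.0)
        record["ctsib_t"] = list(durations)
        record["ctsib_acc"] = [
            PlanarSamples(_ou(rng, max(int(round(d * fs)), 3), acc_sd, fs),
                          _ou(rng, max(int(round(d * fs)), 3), acc_sd, fs))
            for d in durations
        ]
    if keep("romberg"):
        durations = np.clip(30.0 * (1.25 - 1.5 * s)
                            + nz * rng.normal(0.0, 1.5, 2), 0.0, 30.0)
        record["romberg_t"] = list(durations)
        record["romberg_acc"] = [
            PlanarSamples(_ou(rng, max(int(round(d * fs)), 3), acc_sd, fs),
                          _ou(rng, max(int(round(d * fs)), 3), acc_sd, fs))
            for d in durations
        ]
    return record


def simulate_participant_traces(profile: ImpairmentProfile,
                                spec: CohortSpec) -> dict[str, MotionTrace]:
    """All five activity traces for one participant."""
    from .activities import ACTIVITIES
    return {act: simulate_trace(act, profile, spec) for act in ACTIVITIES}


def write_cohort(spec: CohortSpec, out_dir) -> dict:
    """Generate a full cohort and write it to ``out_dir``; returns the manifest.

    Layout: ``traces/<pid>_<activity>.csv`` (+ JSON sidecar per trace),
    ``scores.csv``, ``tests.csv``, ``balance_acc.csv``, ``limb_lengths.csv``
    and ``manifest.json``. Everything round-trips losslessly through the
    readers in :mod:`movemetrics.io`.
    """
    from . import io as mio  # local import: io depends on types above
    from .activities import ACTIVITIES
    from pathlib import Path

    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    profiles = sample_profiles(spec)

    score_rows, test_rows, acc_rows, limb_rows = [], [], [], []
    for prof in profiles:
        for act in ACTIVITIES:
            trace = simulate_trace(act, prof, spec)
            base = out / "traces" / f"{prof.participant_id}_{act}"
            mio.write_trace(trace, base.with_suffix(".csv"),
                            base.with_suffix(".json"))
        for trial, score in enumerate(simulate_overall_scores(prof, spec)):
            score_rows.append({"participant_id": prof.participant_id,
                               "trial_index": trial, "score": float(score)})
        record = simulate_test_measurements(prof, spec)
        limb_rows.append({"participant_id": prof.participant_id,
                          "leg_length": record["leg_length"],
                          "arm_length": record["arm_length"], "unit": "in"})
        test_rows.extend(mio.record_to_rows(prof.participant_id, record))
        acc_rows.extend(mio.acc_to_rows(prof.participant_id, record))

    mio.write_csv(pd.DataFrame(score_rows), out / "scores.csv")
    mio.write_csv(pd.DataFrame(test_rows), out / "tests.csv")
    mio.write_csv(pd.DataFrame(acc_rows), out / "balance_acc.csv")
    mio.write_csv(pd.DataFrame(limb_rows), out / "limb_lengths.csv")

    manifest = {
        "format": "movemetrics-cohort-v1",
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "participants": [
            {"participant_id": prof.participant_id, "index": prof.index,
             "class_label": prof.class_label, "theta": prof.theta,
             "m": prof.m, "s": prof.s, "p": prof.p}
            for prof in profiles
        ],
        "activities": list(ACTIVITIES),
    }
    mio.write_json(manifest, out / "manifest.json")
    return manifest
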