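"""Extraction of per-activity sensor metrics from annotated motion traces.

Five assessment activities are covered — single-leg balance, forward lunge,
overhead squat, overhead reach, and feet-together squat — each yielding the
named scalar metrics of the full metric set (postural sway, toe taps, trunk
angle maxima/variances, knee-ground distance, squat depths, joint-angle
maxima and elbow variances). Squat and lunge repetitions are segmented from
the pelvis / knee vertical-position channel; single-leg-balance stance
phases are required input annotations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import (
    DegenerateInputError,
    KinematicsError,
    PlanarSamples,
    TimeSeries,
    angle_variance,
    count_toe_taps,
    ellipse_area_95,
    max_trunk_deviation,
    robust_extremum,
)

ACTIVITIES = (
    "single_leg_balance",
    "forward_lunge",
    "overhead_squat",
    "overhead_reach",
    "feet_together_squat",
)

#: Channels an ingested trace must carry, per activity.
REQUIRED_CHANNELS = {
    "single_leg_balance": frozenset(
        {"com_acc_x", "com_acc_y", "toe_z_L", "toe_z_R", "trunk_lateral"}
    ),
    "forward_lunge": frozenset({"knee_z_L", "knee_z_R", "trunk_lateral"}),
    "overhead_squat": frozenset(
        {
            "pelvis_z", "knee_z_L", "knee_z_R",
            "hip_flexion_L", "hip_flexion_R",
            "knee_flexion_L", "knee_flexion_R",
            "elbow_flexion_L", "elbow_flexion_R",
            "trunk_lateral",
        }
    ),
    "overhead_reach": frozenset(
        {
            "shoulder_flexion_L", "shoulder_flexion_R",
            "elbow_flexion_L", "elbow_flexion_R",
        }
    ),
    "feet_together_squat": frozenset(
        {
            "pelvis_z", "knee_z_L", "knee_z_R",
            "hip_flexion_L", "hip_flexion_R",
            "knee_flexion_L", "knee_flexion_R",
        }
    ),
}

#: Canonical order of the extracted metric fields (one row per participant).
METRIC_FIELDS = (
    "postural_sway",
    "toe_taps",
    "slb_trunk_max",
    "slb_trunk_var",
    "lunge_knee_ground",
    "lunge_trunk_max",
    "lunge_trunk_var",
    "ohs_pelvis_depth",
    "ohs_hip_max",
    "ohs_knee_max",
    "ohs_trunk_max",
    "ohs_elbow_var",
    "reach_shoulder_max",
    "reach_elbow_max",
    "reach_elbow_var",
    "fts_pelvis_depth",
    "fts_hip_max",
    "fts_knee_max",
)

#: Expected repetition counts per activity (used for warnings only: impaired
#: participants may not complete every repetition).
EXPECTED_REPS = {"forward_lunge": 6, "overhead_squat": 6, "feet_together_squat": 3}


class ExtractionError(KinematicsError):
    """A metric could not be extracted from an otherwise valid trace."""


class NoRepetitionsError(ExtractionError):
    """The driving channel shows no usable repetition structure."""


@dataclass(frozen=True)
class Phase:
    """Half-open annotated sample span [start, end) with a label."""

    label: str
    start: int
    end: int


@dataclass
class MotionTrace:
    """Annotated multichannel kinematic recording of one activity.

    channels maps canonical channel names to equal-length sample arrays at
    a common sampling rate ``fs``; phases carry stance annotations such as
    ``balance_left`` / ``balance_right`` for single-leg balance.
    """

    fs: float
    activity: str
    channels: dict[str, np.ndarray]
    phases: list[Phase] = field(default_factory=list)
    participant_id: str | None = None

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise KinematicsError(f"unknown activity {self.activity!r}")
        if not (self.fs > 0):
            raise KinematicsError("fs must be positive")
        missing = REQUIRED_CHANNELS[self.activity] - set(self.channels)
        if missing:
            raise KinematicsError(
                f"{self.activity}: missing required channels {sorted(missing)}"
            )
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) != 1:
            raise KinematicsError(f"channel lengths differ: {sorted(lengths)}")
        n = lengths.pop()
        if n < 2:
            raise KinematicsError("trace must have >= 2 samples")
        for k, v in self.channels.items():
            if not np.isfinite(v).all():
                raise KinematicsError(f"channel {k!r} contains non-finite samples")
        self.phases = [Phase(*p) if not isinstance(p, Phase) else p for p in self.phases]
        for ph in self.phases:
            if not (0 <= ph.start < ph.end <= n):
                raise KinematicsError(
                    f"phase {ph.label!r} [{ph.start}, {ph.end}) outside trace of {n}"
                )

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    def series(self, name: str, start: int | None = None,
               end: int | None = None) -> TimeSeries:
        """A channel (optionally windowed) as a TimeSeries."""
        if name not in self.channels:
            raise KinematicsError(f"channel {name!r} not present")
        values = self.channels[name][slice(start, end)]
        t0 = 0.0 if start is None else start / self.fs
        return TimeSeries(values, self.fs, t0=t0)

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KinematicsError(f"phase {label!r} not annotated")


@dataclass
class RepetitionWindows:
    """Ordered, non-overlapping half-open repetition spans."""

    windows: list[tuple[int, int]]
    warning: str | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def _driving_channel(trace: MotionTrace) -> np.ndarray:
    if "pelvis_z" in trace.channels:
        return trace.channels["pelvis_z"]
    if "knee_z_L" in trace.channels and "knee_z_R" in trace.channels:
        # lunges: the dipping knee alternates, so track the lower of the two
        return np.minimum(trace.channels["knee_z_L"], trace.channels["knee_z_R"])
    raise KinematicsError("no driving channel (pelvis_z or knee_z pair) for segmentation")


def segment_repetitions(trace: MotionTrace,
                        expected: int | None = None) -> RepetitionWindows:
    """Locate squat/lunge repetitions from the vertical driving channel.

    The channel (pelvis height for squats, the lower of the two knee heights
    for lunges) is smoothed with a 0.5 s moving average; repetitions are
    local minima separated by at least 1 s and deeper than 25% of the
    smoothed channel's peak-to-peak range. Windows extend to the midpoints
    between adjacent minima (trace boundaries at the ends).

    If ``expected`` is given and the detected count differs, a warning is
    attached (and emitted) but the detected windows are still returned:
    participants unable to complete every repetition stay analyzable.
    """
    z = _driving_channel(trace)
    win = max(1, int(round(0.5 * trace.fs)))
    kernel = np.ones(win) / win
    smooth = np.convolve(z, kernel, mode="same")
    ptp = float(np.ptp(smooth))
    if ptp < 0.02:
        raise NoRepetitionsError(
            f"driving channel range {ptp:.4f} m < 0.02 m: no repetitions"
        )
    # minima deeper than 25% of range below the channel maximum
    height = -(smooth.max() - 0.25 * ptp)
    distance = max(1, int(round(1.0 * trace.fs)))
    minima, _ = find_peaks(-smooth, distance=distance, height=height)
    if minima.size == 0:
        raise NoRepetitionsError("no repetition minima found in driving channel")
    n = z.size
    bounds = [0] + [int((a + b) // 2) for a, b in zip(minima[:-1], minima[1:])] + [n]
    windows = [(bounds[i], bounds[i + 1]) for i in range(len(minima))]
    warning = None
    if expected is not None and len(windows) != expected:
        warning = (
            f"{trace.activity}: expected {expected} repetitions, detected {len(windows)}"
        )
        warnings.warn(warning, stacklevel=2)
    return RepetitionWindows(windows, warning=warning)


def _phase_balance_metrics(trace: MotionTrace, phase: Phase) -> dict[str, float]:
    s, e = phase.start, phase.end
    acc = PlanarSamples(trace.channels["com_acc_x"][s:e],
                        trace.channels["com_acc_y"][s:e])
    raised, plant = (("toe_z_R", "toe_z_L") if phase.label == "balance_left"
                     else ("toe_z_L", "toe_z_R"))
    taps = count_toe_taps(trace.series(raised, s, e), trace.series(plant, s, e))
    trunk = trace.series("trunk_lateral", s, e)
    return {
        "postural_sway": ellipse_area_95(acc),
        "toe_taps": float(taps),
        "slb_trunk_max": max_trunk_deviation(trunk),
        "slb_trunk_var": angle_variance(trunk),
    }


def extract_single_leg_balance(trace: MotionTrace) -> dict[str, float]:
    """Balance metrics, computed per stance phase then averaged over feet.

    During the left-stance phase the raised foot is the right one (and vice
    versa); sway is the 95% prediction-ellipse area of transverse COM
    acceleration within the phase.
    """
    per_phase = [
        _phase_balance_metrics(trace, trace.phase(label))
        for label in ("balance_left", "balance_right")
    ]
    return {k: float(np.mean([p[k] for p in per_phase])) for k in per_phase[0]}


def _bilateral(trace: MotionTrace, op, base: str, start=None, end=None) -> float:
    return float(np.mean([
        op(trace.series(f"{base}_L", start, end)),
        op(trace.series(f"{base}_R", start, end)),
    ]))


def extract_forward_lunge(trace: MotionTrace) -> dict[str, float]:
    """Knee-ground clearance and trunk control over six alternating lunges.

    Per repetition the lunging knee is the side reaching the lower minimum
    height in that window; the clearance metric is that minimum averaged
    over all detected repetitions. Trunk metrics span the whole activity.
    """
    reps = segment_repetitions(trace, expected=EXPECTED_REPS["forward_lunge"])
    if len(reps) < 2:
        raise ExtractionError(
            f"forward lunge: only {len(reps)} repetition(s) detected; need >= 2"
        )
    minima = []
    for s, e in reps:
        lo_l = float(trace.channels["knee_z_L"][s:e].min())
        lo_r = float(trace.channels["knee_z_R"][s:e].min())
        minima.append(min(lo_l, lo_r))
    trunk = trace.series("trunk_lateral")
    return {
        "lunge_knee_ground": float(np.mean(minima)),
        "lunge_trunk_max": max_trunk_deviation(trunk),
        "lunge_trunk_var": angle_variance(trunk),
    }


def _squat_depth(trace: MotionTrace, reps: RepetitionWindows) -> float:
    # depth > 0 when the pelvis descends below the knees; knee height is the
    # bilateral mean channel
    knee = 0.5 * (trace.channels["knee_z_L"] + trace.channels["knee_z_R"])
    pelvis = trace.channels["pelvis_z"]
    depths = [float(knee[s:e].min() - pelvis[s:e].min()) for s, e in reps]
    return float(np.mean(depths))


def _rep_concat_variance(trace: MotionTrace, base: str,
                         reps: RepetitionWindows) -> float:
    vals = []
    for side in ("L", "R"):
        chan = trace.channels[f"{base}_{side}"]
        joined = np.concatenate([chan[s:e] for s, e in reps])
        vals.append(angle_variance(joined))
    return float(np.mean(vals))


def extract_overhead_squat(trace: MotionTrace) -> dict[str, float]:
    """Squat depth, joint-angle maxima, trunk control and elbow steadiness.

    Depth per repetition is min knee height minus min pelvis height
    (positive when the pelvis drops below the knees), averaged over
    repetitions. Hip/knee maxima use the decile-median robust extremum over
    the whole activity, averaged across sides; elbow variance is computed
    over the concatenated repetition spans.
    """
    reps = segment_repetitions(trace, expected=EXPECTED_REPS["overhead_squat"])
    return {
        "ohs_pelvis_depth": _squat_depth(trace, reps),
        "ohs_hip_max": _bilateral(trace, lambda x: robust_extremum(x, "max"),
                                  "hip_flexion"),
        "ohs_knee_max": _bilateral(trace, lambda x: robust_extremum(x, "max"),
                                   "knee_flexion"),
        "ohs_trunk_max": max_trunk_deviation(trace.series("trunk_lateral")),
        "ohs_elbow_var": _rep_concat_variance(trace, "elbow_flexion", reps),
    }


def extract_overhead_reach(trace: MotionTrace) -> dict[str, float]:
    """Shoulder/elbow range and elbow steadiness during overhead reaches."""
    rmax = lambda x: robust_extremum(x, "max")
    return {
        "reach_shoulder_max": _bilateral(trace, rmax, "shoulder_flexion"),
        "reach_elbow_max": _bilateral(trace, rmax, "elbow_flexion"),
        "reach_elbow_var": _bilateral(trace, angle_variance, "elbow_flexion"),
    }


def extract_feet_together_squat(trace: MotionTrace) -> dict[str, float]:
    """Depth and hip/knee flexion maxima for the feet-together squat."""
    reps = segment_repetitions(trace, expected=EXPECTED_REPS["feet_together_squat"])
    return {
        "fts_pelvis_depth": _squat_depth(trace, reps),
        "fts_hip_max": _bilateral(trace, lambda x: robust_extremum(x, "max"),
                                  "hip_flexion"),
        "fts_knee_max": _bilateral(trace, lambda x: robust_extremum(x, "max"),
                                   "knee_flexion"),
    }


_EXTRACTORS = {
    "single_leg_balance": extract_single_leg_balance,
    "forward_lunge": extract_forward_lunge,
    "overhead_squat": extract_overhead_squat,
    "overhead_reach": extract_overhead_reach,
    "feet_together_squat": extract_feet_together_squat,
}


def extract_activity(trace: MotionTrace) -> dict[str, float]:
    """Dispatch to the activity-specific extractor."""
    return _EXTRACTORS[trace.activity](trace)


def extract_all(traces: dict[str, MotionTrace]) -> dict[str, float]:
    """Assemble the full metric set from one trace per activity.

    Missing activities leave their metric fields as NaN (missing-value
    markers); extraction is deterministic given the input traces.
    """
    out: dict[str, float] = {k: math.nan for k in METRIC_FIELDS}
    for activity, trace in traces.items():
        if trace is None:
            continue
        if trace.activity != activity:
            raise KinematicsError(
                f"trace labelled {trace.activity!r} supplied under {activity!r}"
            )
        out.update(extract_activity(trace))
    # physiologic sanity: angle maxima outside [0, 220] deg are suspicious
    for key in out:
        if key.endswith(("_hip_max", "_knee_max", "shoulder_max", "elbow_max")):
            v = out[key]
            if not math.isnan(v) and not (0.0 <= v <= 220.0):
                warnings.warn(f"{key} = {v:.1f} deg outside physiologic bounds",
                              stacklevel=2)
    return out
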