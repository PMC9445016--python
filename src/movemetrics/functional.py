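"""Scoring of the thirteen reference functional movement tests.

Each clinically administered test is reduced to the scalar used in the
validation analysis (15 scalars in total: the timed balance tests CTSIB and
Sharpened Romberg each contribute a time score and a sway-acceleration
score). Aggregation rules follow the clinical protocols: bilateral and
multi-trial arithmetic means, limb-length-normalized reach composites,
per-trial time caps, and the explicit zero score for an unattempted
closed-kinetic-chain test.

Units are those of the administered tests: reach distances in inches,
balance times in seconds, touch counts, 0-3 ordinal hurdle grades;
normalized composites (star excursion, upper-extremity Y balance) are
dimensionless. Missing tests propagate as NaN, never as zero — except the
explicit CKCUES rule.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .core import DegenerateInputError, KinematicsError, PlanarSamples, ellipse_area_95

#: Canonical order of the scored test fields.
TEST_FIELDS = (
    "plumb_line",
    "rbb_i",
    "rbb_s",
    "ckcue",
    "y_balance",
    "sit_reach",
    "functional_reach",
    "star_excursion",
    "hurdle_step",
    "uhbe",
    "single_leg_hop",
    "ctsib_t",
    "ctsib_acc",
    "romberg_t",
    "romberg_acc",
)

#: Per-trial and total time caps for the timed balance tests, in seconds.
TIMED_BALANCE = {"romberg": (30.0, 2, 60.0), "ctsib": (30.0, 6, 180.0)}


class ScoringError(KinematicsError):
    """Invalid raw measurements for a functional test."""


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def score_bilateral_mean(values: Sequence[float]) -> float:
    """Arithmetic mean over all provided trials/limbs.

    The generic rule for sit-and-reach (3 trials), reach-behind-back (2
    arms), single-leg hop (2 legs), UHBE (2 legs), and functional reach
    (6 trials). An empty input returns NaN: participants completed varying
    subsets of tests and missingness must propagate.
    """
    arr = _clean(values)
    if arr.size == 0:
        return math.nan
    return float(arr.mean())


def score_ckcue(touch_counts: Sequence[float], attempted: bool = True) -> float:
    """Closed Kinetic Chain Upper Extremity Stability score.

    Mean touch count over up to three 15 s trials; a participant unable to
    attempt the test scores 0 (the one test where inability is itself
    informative rather than missing data).
    """
    if not attempted:
        return 0.0
    counts = _clean(touch_counts)
    if counts.size == 0:
        return math.nan
    if counts.size > 3:
        raise ScoringError(f"CKCUES takes at most 3 trials, got {counts.size}")
    if (counts < 0).any():
        raise ScoringError("touch counts must be non-negative")
    return float(counts.mean())


def score_plumb_line(distances: Sequence[float]) -> float:
    """Static-posture score: variance of the four landmark offsets.

    Offsets of shoulder, hip, knee and ankle from the vertical plumb line;
    the score is their sample variance (n-1), so a uniformly shifted body
    scores the same as a perfectly aligned one.
    """
    arr = np.asarray(list(distances), dtype=float)
    if arr.size != 4 or np.isnan(arr).any():
        raise ScoringError(f"plumb line requires exactly 4 distances, got {arr.size}")
    return float(np.var(arr, ddof=1))


def score_star_excursion(reaches_by_leg: dict[str, Sequence[float]],
                         leg_length: float) -> float:
    """Star Excursion Balance Test composite.

    Per leg: mean of the eight directional reach distances normalized by
    leg length; final score is the mean of the two leg composites
    (dimensionless, invariant to a global unit change).
    """
    if not (leg_length > 0):
        raise ScoringError("leg length must be positive")
    per_leg = []
    for leg, reaches in reaches_by_leg.items():
        arr = _clean(reaches)
        if arr.size != 8:
            raise ScoringError(f"leg {leg!r}: expected 8 reach directions, got {arr.size}")
        per_leg.append(arr.mean() / leg_length)
    if not per_leg:
        return math.nan
    return float(np.mean(per_leg))


def score_y_balance_upper(reaches_by_arm: dict[str, Sequence[float]],
                          arm_length: float) -> float:
    """Upper-extremity Y balance composite.

    Per arm: mean of the three reach directions (medial, inferolateral,
    superolateral) normalized by arm length; final score is the mean across
    arms (dimensionless).
    """
    if not (arm_length > 0):
        raise ScoringError("arm length must be positive")
    per_arm = []
    for arm, reaches in reaches_by_arm.items():
        arr = _clean(reaches)
        if arr.size != 3:
            raise ScoringError(f"arm {arm!r}: expected 3 reach directions, got {arr.size}")
        per_arm.append(arr.mean() / arm_length)
    if not per_arm:
        return math.nan
    return float(np.mean(per_arm))


def _hurdle_leg_aggregate(grades: np.ndarray) -> float:
    # FMS-style convention: pain (grade 0) on any step zeroes the leg
    if (grades == 0).any():
        return 0.0
    return float(np.median(grades))


def score_hurdle_step(grades_left: Sequence[int],
                      grades_right: Sequence[int]) -> float:
    """Hurdle step score from three 0-3 clinician grades per leg.

    Per-leg aggregate is the median of the three step grades, with any
    grade 0 (pain) forcing that leg's aggregate to 0; the final score is
    the mean of the two leg aggregates.
    """
    legs = []
    for grades in (grades_left, grades_right):
        arr = np.asarray(list(grades), dtype=float)
        if arr.size == 0:
            continue
        if not np.isin(arr, [0, 1, 2, 3]).all():
            raise ScoringError(f"hurdle grades must be in {{0,1,2,3}}, got {arr}")
        legs.append(_hurdle_leg_aggregate(arr))
    if not legs:
        return math.nan
    return float(np.mean(legs))


def score_timed_balance(durations: Sequence[float], test: str = "romberg") -> float:
    """Total balance time for Sharpened Romberg (cap 60 s) or CTSIB (180 s).

    Each trial lasts at most 30 s (the test is ended on balance loss); the
    score sums the trial durations, clipped to the test's total cap.
    """
    try:
        per_trial_cap, n_trials, total_cap = TIMED_BALANCE[test]
    except KeyError:
        raise ScoringError(f"unknown timed balance test {test!r}") from None
    arr = _clean(durations)
    if arr.size == 0:
        return math.nan
    if arr.size > n_trials:
        raise ScoringError(f"{test}: at most {n_trials} trials, got {arr.size}")
    if (arr < 0).any() or (arr > per_trial_cap + 1e-9).any():
        raise ScoringError(f"{test}: trial durations must lie in [0, {per_trial_cap}] s")
    return float(min(arr.sum(), total_cap))


def score_balance_acc(trials: Sequence[PlanarSamples]) -> float:
    """Sway score for a timed balance test: mean 95% ellipse area over trials.

    Each trial contributes the prediction-ellipse area of its transverse
    COM-acceleration samples; all recorded samples enter, including those
    of trials ended early by balance loss.
    """
    trials = list(trials)
    if not trials:
        return math.nan
    return float(np.mean([ellipse_area_95(t) for t in trials]))


def assemble_test_scores(record: dict) -> dict[str, float]:
    """Score one participant's raw functional-test measurements.

    ``record`` maps test keys to their raw inputs (absent keys score NaN):

    - ``plumb_line``: 4 landmark distances
    - ``rbb_i`` / ``rbb_s``: per-arm reach distances
    - ``ckcue``: ``{"counts": [...], "attempted": bool}``
    - ``y_balance``: ``{"reaches": {arm: [3]}, "arm_length": float}``
    - ``sit_reach`` / ``functional_reach`` / ``uhbe`` / ``single_leg_hop``:
      trial value lists
    - ``star_excursion``: ``{"reaches": {leg: [8]}, "leg_length": float}``
    - ``hurdle_step``: ``{"left": [3 grades], "right": [3 grades]}``
    - ``ctsib_t`` / ``romberg_t``: trial durations
    - ``ctsib_acc`` / ``romberg_acc``: list of PlanarSamples
    """
    out: dict[str, float] = {k: math.nan for k in TEST_FIELDS}
    if "plumb_line" in record:
        out["plumb_line"] = score_plumb_line(record["plumb_line"])
    for key in ("rbb_i", "rbb_s", "sit_reach", "functional_reach", "uhbe",
                "single_leg_hop"):
        if key in record:
            out[key] = score_bilateral_mean(record[key])
    if "ckcue" in record:
        spec = record["ckcue"]
        out["ckcue"] = score_ckcue(spec.get("counts", []),
                                   attempted=spec.get("attempted", True))
    if "y_balance" in record:
        spec = record["y_balance"]
        out["y_balance"] = score_y_balance_upper(spec["reaches"], spec["arm_length"])
    if "star_excursion" in record:
        spec = record["star_excursion"]
        out["star_excursion"] = score_star_excursion(spec["reaches"], spec["leg_length"])
    if "hurdle_step" in record:
        spec = record["hurdle_step"]
        out["hurdle_step"] = score_hurdle_step(spec.get("left", []),
                                               spec.get("right", []))
    if "ctsib_t" in record:
        out["ctsib_t"] = score_timed_balance(record["ctsib_t"], test="ctsib")
    if "romberg_t" in record:
        out["romberg_t"] = score_timed_balance(record["romberg_t"], test="romberg")
    if "ctsib_acc" in record:
        out["ctsib_acc"] = score_balance_acc(record["ctsib_acc"])
    if "romberg_acc" in record:
        out["romberg_acc"] = score_balance_acc(record["romberg_acc"])
    return out
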