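"""Validation statistics: normality-gated correlation, group tests, reliability.

The concurrent-validity analysis correlates an overall movement-health
score against sensor metrics and functional-test scores. Correlation method
selection is gated on normality: both variables passing a Shapiro-Wilk test
at alpha selects Pearson's product-moment r, otherwise Spearman's rank
r_s. Each correlation carries a hypothesized sign; "agreement" means the
estimated coefficient has that sign and is significant at alpha. Group
separation uses two-sided Student t-tests between ability classes, and
test-retest reliability is summarized as the intrasubject coefficient of
variation over three assessment trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateInputError


#: Hypothesized correlation sign of each sensor metric with the overall
#: score: mobility metrics (depths, joint-angle maxima) improve with the
#: score; instability markers (sway, taps, trunk and elbow metrics,
#: knee-ground clearance) run against it.
METRIC_HYPOTHESES = {
    "postural_sway": "-",
    "toe_taps": "-",
    "slb_trunk_max": "-",
    "slb_trunk_var": "-",
    "lunge_knee_ground": "-",
    "lunge_trunk_max": "-",
    "lunge_trunk_var": "-",
    "ohs_pelvis_depth": "+",
    "ohs_hip_max": "+",
    "ohs_knee_max": "+",
    "ohs_trunk_max": "-",
    "ohs_elbow_var": "-",
    "reach_shoulder_max": "+",
    "reach_elbow_max": "-",
    "reach_elbow_var": "-",
    "fts_pelvis_depth": "+",
    "fts_hip_max": "+",
    "fts_knee_max": "+",
}

#: Hypothesized sign of each functional-test score with the overall score.
TEST_HYPOTHESES = {
    "plumb_line": "-",
    "rbb_i": "-",
    "rbb_s": "+",
    "ckcue": "+",
    "y_balance": "+",
    "sit_reach": "+",
    "functional_reach": "+",
    "star_excursion": "+",
    "hurdle_step": "+",
    "uhbe": "+",
    "single_leg_hop": "+",
    "ctsib_t": "+",
    "ctsib_acc": "-",
    "romberg_t": "+",
    "romberg_acc": "-",
}


class StatsError(ValueError):
    """Invalid input to a validation statistic."""


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    r: float
    method: str          # "pearson" | "spearman"
    p: float
    n: int
    hypothesized_sign: str  # "+", "-", or "none"
    agreement: bool


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, str]
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    n_a: int
    n_b: int
    t: float
    p: float


@dataclass(frozen=True)
class ReliabilitySummary:
    cv_percent: tuple[float, ...]
    mean_cv: float
    std_cv: float
    n_subjects: int


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a sample.

    Raises on fewer than 3 observations or a constant sample, for which the
    statistic is undefined.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise DegenerateInputError(f"Shapiro-Wilk needs n >= 3, got {arr.size}")
    if arr.size > 5000:
        raise StatsError("Shapiro-Wilk is unreliable beyond n = 5000")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def gated_correlation(x, y, alpha: float = 0.05,
                      hypothesized_sign: str = "none",
                      gate_mode: str = "both",
                      names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Correlation with Shapiro-Wilk-gated method selection.

    Pairs with a missing value in either variable are dropped (pairwise
    deletion). Pearson's r is used when the normality gate passes at
    ``alpha`` — by default both variables must pass; ``gate_mode="either"``
    relaxes this to one — otherwise Spearman's r_s. The agreement flag is
    true when the coefficient's sign matches ``hypothesized_sign`` and the
    two-sided p-value is below ``alpha``.
    """
    if gate_mode not in ("both", "either"):
        raise StatsError(f"gate_mode must be 'both' or 'either', got {gate_mode!r}")
    if hypothesized_sign not in ("+", "-", "none"):
        raise StatsError(f"bad hypothesized_sign {hypothesized_sign!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise DegenerateInputError(f"need >= 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one variable")
    normal = [normality_test(v)[1] > alpha for v in (x, y)]
    pearson_ok = all(normal) if gate_mode == "both" else any(normal)
    if pearson_ok:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    r, p = float(r), float(p)
    sign = "+" if r > 0 else ("-" if r < 0 else "none")
    agreement = (hypothesized_sign != "none"
                 and sign == hypothesized_sign and p < alpha)
    return CorrelationResult((names[0], names[1]), r, method, p,
                             int(x.size), hypothesized_sign, agreement)


def correlation_grid(df: pd.DataFrame, score_cols, feature_cols,
                     hypotheses: dict[str, str] | None = None,
                     alpha: float = 0.05, gate_mode: str = "both",
                     bh_correction: bool = False) -> list[CorrelationResult]:
    """One gated correlation per (score, feature) pair.

    ``hypotheses`` maps feature names to "+"/"-" (default "none").
    With ``bh_correction`` the per-cell p-values are Benjamini-Hochberg
    adjusted before significance/agreement flags are set (off by default:
    the analysis treats each cell at alpha).
    """
    hypotheses = hypotheses or {}
    results = []
    for score in score_cols:
        for feat in feature_cols:
            res = gated_correlation(
                df[score], df[feat], alpha=alpha,
                hypothesized_sign=hypotheses.get(feat, "none"),
                gate_mode=gate_mode, names=(score, feat),
            )
            results.append(res)
    if bh_correction and results:
        order = np.argsort([r.p for r in results])
        m = len(results)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, results[idx].p * m / rank)
            adj[idx] = prev
        results = [
            CorrelationResult(r.variable_pair, r.r, r.method, float(adj[i]), r.n,
                              r.hypothesized_sign,
                              r.hypothesized_sign != "none"
                              and ((r.r > 0) == (r.hypothesized_sign == "+"))
                              and r.r != 0 and adj[i] < alpha)
            for i, r in enumerate(results)
        ]
    return results


def grid_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation results as a tidy DataFrame (one row per cell)."""
    return pd.DataFrame([
        {
            "score": r.variable_pair[0],
            "feature": r.variable_pair[1],
            "r": r.r,
            "method": r.method,
            "p": r.p,
            "n": r.n,
            "hypothesized_sign": r.hypothesized_sign,
            "agreement": r.agreement,
        }
        for r in results
    ])


def group_ttests(values_by_class: dict[str, np.ndarray],
                 equal_var: bool = True) -> list[GroupComparison]:
    """All pairwise two-sided t-tests between ability classes.

    Student's equal-variance test by default (Welch via
    ``equal_var=False``). Classes are compared in their given order.
    """
    labels = list(values_by_class)
    cleaned = {}
    for lab in labels:
        arr = np.asarray(values_by_class[lab], dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise DegenerateInputError(f"group {lab!r} has < 2 observations")
        cleaned[lab] = arr
    out = []
    for a, b in combinations(labels, 2):
        xa, xb = cleaned[a], cleaned[b]
        t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
        out.append(GroupComparison(
            (a, b),
            float(xa.mean()), float(xb.mean()),
            float(xa.std(ddof=1)), float(xb.std(ddof=1)),
            int(xa.size), int(xb.size),
            float(t), float(p),
        ))
    return out


def intrasubject_cv(trials_by_subject: dict[str, np.ndarray],
                    required_trials: int = 3) -> ReliabilitySummary:
    """Test-retest reliability as the intrasubject coefficient of variation.

    Only subjects with exactly ``required_trials`` recorded scores enter.
    Per subject, CV = sample standard deviation / mean of the trials, in
    percent; the summary is the mean and standard deviation of CV across
    the retained subjects.
    """
    cvs = []
    for subject, trials in trials_by_subject.items():
        arr = np.asarray(trials, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size != required_trials:
            continue
        mean = arr.mean()
        if mean == 0:
            raise DegenerateInputError(f"subject {subject!r}: zero mean score")
        cvs.append(100.0 * arr.std(ddof=1) / mean)
    if not cvs:
        raise DegenerateInputError("no subject completed the required trials")
    cvs_arr = np.asarray(cvs)
    return ReliabilitySummary(
        tuple(float(c) for c in cvs_arr),
        float(cvs_arr.mean()),
        float(cvs_arr.std(ddof=1)) if cvs_arr.size > 1 else 0.0,
        int(cvs_arr.size),
    )


@dataclass
class ValidationReport:
    """Full output of the validation analysis, serializable to JSON."""

    correlations: list[CorrelationResult]
    group_comparisons: dict[str, list[GroupComparison]]
    reliability: ReliabilitySummary
    normality: dict[str, tuple[float, float]]
    config: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "normality": {k: {"W": v[0], "p": v[1]} for k, v in self.normality.items()},
            "correlations": [asdict(c) | {"variable_pair": list(c.variable_pair)}
                             for c in self.correlations],
            "group_comparisons": {
                var: [asdict(g) | {"groups": list(g.groups)} for g in comps]
                for var, comps in self.group_comparisons.items()
            },
            "reliability": {
                "mean_cv_percent": self.reliability.mean_cv,
                "std_cv_percent": self.reliability.std_cv,
                "n_subjects": self.reliability.n_subjects,
            },
        }


def build_report(metrics: pd.DataFrame, test_scores: pd.DataFrame,
                 scores: pd.DataFrame, classes: dict[str, str],
                 alpha: float = 0.05, gate_mode: str = "both",
                 equal_var: bool = True, bh_correction: bool = False,
                 config: dict | None = None) -> ValidationReport:
    """Run the full validation analysis and assemble the report.

    Parameters
    ----------
    metrics, test_scores : DataFrame
        One row per participant (indexed by participant_id), columns the
        sensor-metric / test-score field names.
    scores : DataFrame
        Long format: participant_id, trial_index, score.
    classes : mapping participant_id -> class label.
    """
    per_subject = scores.groupby("participant_id")["score"]
    mean_score = per_subject.mean().rename("overall_score")
    wide = metrics.join(test_scores, how="outer").join(mean_score, how="left")
    missing_scores = wide.index[wide["overall_score"].isna()]
    if len(missing_scores):
        raise StatsError(
            f"participants without overall scores: {sorted(missing_scores)[:5]}"
        )

    hypotheses = {**METRIC_HYPOTHESES, **TEST_HYPOTHESES}
    feature_cols = [c for c in wide.columns if c != "overall_score"]
    correlations = correlation_grid(
        wide, ["overall_score"], feature_cols, hypotheses,
        alpha=alpha, gate_mode=gate_mode, bh_correction=bh_correction,
    )

    normality = {}
    for col in ["overall_score", *feature_cols]:
        vals = wide[col].dropna().to_numpy()
        try:
            normality[col] = normality_test(vals)
        except (DegenerateInputError, StatsError):
            normality[col] = (math.nan, math.nan)

    class_series = pd.Series(classes).reindex(wide.index)
    order = ["athlete", "healthy", "impaired"]
    by_class = {
        lab: wide.loc[class_series == lab, "overall_score"].to_numpy()
        for lab in order if (class_series == lab).sum() >= 2
    }
    group_comparisons = {
        "overall_score":
            group_ttests(by_class, equal_var=equal_var) if len(by_class) >= 2
            else []
    }

    trials = {pid: grp.to_numpy() for pid, grp in per_subject}
    reliability = intrasubject_cv(trials)

    cfg = {"alpha": alpha, "gate_mode": gate_mode,
           "equal_var": equal_var, "bh_correction": bh_correction}
    if config:
        cfg.update(config)
    return ValidationReport(correlations, group_comparisons, reliability,
                            normality, cfg)
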