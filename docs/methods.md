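# Methods

This note records the models, rules and numerical choices behind
`movemetrics`, and what the synthetic cohort does and does not establish.

## Kinematic primitives

**Postural sway (95% prediction ellipse).** Sway is the area of the
ellipse expected to contain 95% of transverse-plane center-of-mass
acceleration samples under a bivariate normal model:
`A = π · q · √det(C)`, with `C` the 2×2 sample covariance (n−1
denominator) and `q = χ²₂(0.95) ≈ 5.991`. We use the chi-square
prediction ellipse rather than an F-based small-sample correction: it is
the standard stabilometry construction, has an exact closed form to test
against, and at the sample sizes involved (≥ 600 samples per balance
phase) the two differ negligibly. Singular covariances (constant or
collinear samples) return area 0; fewer than 3 samples is an error.

**Toe taps.** A tap is one downward crossing of the raised-toe height
through the plant-toe height. The difference trace is thresholded with a
±5 mm hysteresis band (configurable): a tap is counted when the trace
moves from above +5 mm to below −5 mm, so each physical ground contact
counts once and millimeter-level sensor jitter cannot generate crossings.
The count is invariant to a common vertical offset of both traces.

**Robust extrema.** Joint-angle maxima/minima are the *median of the top
(bottom) decile*: all samples at or above the empirical 90th percentile
(linear-interpolation percentile definition), reduced by the median, with
even-cardinality medians averaged. This damps isolated spikes that a raw
max would latch onto. The rule is applied uniformly to every angle
extremum, including trunk deviation and shoulder range of motion.

**Variances.** All variances (trunk angle, elbow angle, plumb-line
offsets, trial CV) use the sample (n−1) denominator, one consistent
convention for small-sample estimates.

## Activity metrics

Repetition segmentation smooths the driving channel (pelvis height for
squats; the pointwise lower of the two knee heights for lunges, since the
dipping knee alternates) with a 0.5 s moving average and takes local
minima separated by ≥ 1 s and deeper than 25% of the smoothed peak-to-peak
range; windows extend to midpoints between adjacent minima. A detected
count differing from the nominal protocol (6 lunges, 6 overhead squats, 3
feet-together squats) warns but does not fail: impaired participants may
not complete every repetition. A driving-channel range under 2 cm is
treated as "no repetitions".

Single-leg-balance metrics are computed per annotated stance phase (the
raised foot is the contralateral one) and averaged over the two feet.
Because the per-phase tap counts are integers, their two-phase mean can be
a half-integer; the aggregated `toe_taps` field is therefore a
non-negative real. Squat depth is min knee height minus min pelvis height
per repetition (positive when the pelvis descends below the knees),
averaged over repetitions; bilateral channels aggregate by arithmetic
mean. Trunk metrics for lunges and squats span the whole activity, while
elbow variance in the overhead squat is restricted to the repetition
windows; the protocol wording ties only the elbow variance to the
repetitions, and spanning the activity makes the trunk metrics robust to
segmentation boundaries.

## Functional test scoring

Aggregation follows each test's clinical rule: multi-trial and bilateral
arithmetic means; reach composites normalized by limb length (hence
dimensionless and unit-change invariant); timed balance tests capped at
30 s per trial and summed to caps of 60 s (Sharpened Romberg, 2 trials)
and 180 s (CTSIB, 6 trials); sway-acceleration balance scores as the mean
95% ellipse area across trials, using all recorded samples including
trials ended early by balance loss. The CKCUES test scores 0 when not
attempted — the one place inability maps to a score rather than missing
data; every other missing test propagates as NaN.

The hurdle-step protocol aggregates three 0–3 grades per leg "into a
single score" without stating the rule; we use the per-leg **median**,
with the screening convention that any grade 0 (pain) forces that leg's
aggregate to 0, then average the two legs. This matches common functional
movement screen practice; it is a documented choice, not a claim about
the original instrument, and is isolated in `score_hurdle_step`.

## Validation statistics

Normality is assessed per variable with Shapiro–Wilk. A correlation cell
uses Pearson's *r* only when **both** variables pass at α (the stricter
reading of "normally distributed variables"; an either-variable gate is
available via `gate_mode`). Otherwise Spearman's *r_s* is used — in
practice the overall score of a three-class cohort mixture is skewed
enough that the default cohort resolves every cell to Spearman.
"Agreement" requires the estimated sign to match the hypothesized sign
*and* two-sided p < α. No multiple-testing correction is applied by
default (each cell at α = 0.05); Benjamini–Hochberg is available behind a
flag. Missing values are deleted pairwise per cell, so each cell carries
its own n.

Group comparisons use the two-sided Student (equal-variance) t-test, with
Welch behind a flag; classes with fewer than two scored members are
skipped. Reliability is the per-subject CV = sample SD / mean of exactly
three trial scores, in percent, summarized as mean ± SD across subjects.

## Synthetic cohort generator

The generator is a statistical stand-in for a human cohort, not a
musculoskeletal simulation. Each participant has a latent impairment
θ ∈ [0, 1], the mean of mobility/stability/posture deficits (m, s, p)
drawn as a shared class-conditional Beta base (athlete Beta(2,10), healthy
Beta(3,6), impaired Beta(8,4)) plus N(0, 0.08) jitter, clipped to [0, 1].
Class proportions default to 113:17:20 of 150. Impairment acts
monotonically:

- depths and joint-angle amplitudes scale with (1 − 0.6 m);
- lateral trunk amplitude scales with (1 + 4 p);
- COM acceleration is a stationary Ornstein–Uhlenbeck process (τ = 0.5 s —
  mean-reverting rather than white, so ellipse area is well defined and
  sampling-rate robust) with sd scaled by (1 + 5 s);
- toe taps arrive as Poisson counts with rate 3 s per balance phase;
- each functional test's latent mean is linear in its relevant
  subcomponent with the physiologically expected sign, with trial noise
  and Bernoulli missingness at the study's per-test completion rates;
- overall score trials are clip(95 − 30 θ + N(0, 1.5), 0, 100); the 1.5
  trial sd puts the cohort intrasubject CV in the 1–3% regime.

Activity templates use flat-topped (clipped sin²) repetition profiles so
that noiseless extraction recovers template amplitudes exactly, 10 s
balance phases per foot, and 6/6/3/3 repetitions for lunge, overhead
squat, reach and feet-together squat at 60 Hz. Measurement noise defaults
to 0.3° on angles and 3 mm on positions; a single `noise` multiplier
scales every noise source (0 gives noiseless templates) without touching
the signal structure. All randomness flows from the one cohort seed
through per-participant, per-stream SeedSequences; there is no global
random state, and a fixed seed makes the end-to-end run bitwise
reproducible (floats are written with 17 significant digits and re-read
with round-trip parsing).

What passing tests show — and don't. The generator is constructed so that
the qualitative structure a valid score should exhibit (sign structure of
all 33 metric/test correlations, athlete > healthy > impaired ordering,
percent-level trial reliability) emerges at n = 150 under the default
effect sizes; the effect sizes were *not* tuned to reproduce any specific
correlation magnitudes, which would be circular. Consequently the
pipeline's green tests demonstrate correctness of the computations and
internal consistency of the analysis, not validity of any real scoring
product on real humans: real data bring non-Gaussian sensor artifacts,
correlated missingness, heterogeneous impairment phenotypes and ceiling
effects the generator only sketches (the timed-balance ceiling is the one
such effect modeled explicitly).

## Problem sizes and runtime choices

Default analyses use the full n = 150 cohort (five traces each, 600–1,300
samples per trace at 60 Hz). Oracle suites use 1,000 random cases per
primitive; segmentation recovery uses 100 seeds × 3 activities;
permutation-null calibration uses 200 permutations of the score column
(6,600 cells), checked against α within two binomial standard errors;
end-to-end determinism is verified on a 12-participant cohort. These sizes
keep the complete test suite around half a minute while leaving every
statistical check comfortably powered.

## Known limitations

- Stance phases for single-leg balance are required annotations; automatic
  stance detection is out of scope (the generator writes them).
- Trunk deviation is consumed as a precomputed unsigned angle channel; no
  orientation math from raw quaternions.
- The image-based scorer itself is out of scope: the generator's linear
  score model stands in for it, and nothing here validates such a scorer.
- Vendor motion-capture file formats are not parsed; the trace CSV +
  sidecar dialect is the ingestion boundary.
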