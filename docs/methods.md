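# Methods

## Model and assumptions

The classifier is a nearest-neighbor template matcher over fixed-length
windows of a single sensor stream. It assumes (i) the stream is sampled on
an (approximately) regular grid at a known nominal rate h — windowing is
index-based, and timestamps are used only to align samples with labels and
to detect gaps; (ii) the subject's own labeled training data are
representative of how they perform each activity, so a personalized
dictionary of a few seconds per activity suffices; (iii) activities are
locally stationary at the one-second scale, so a window mostly contains one
activity. Raw acceleration is used as recorded, gravity included: the method
is pattern matching and is agnostic about the source of the acceleration, so
no gravity subtraction or smoothing is performed and units (g, rad/s) are
carried as metadata, never converted.

The majority vote at timepoint t pools the matched labels of the movelet
starting at t and those starting over the following second. We read that
window inclusively as h + 1 votes (11 at 10 Hz); `MatchConfig.votes_per_point`
exposes the h-vote reading for anyone who prefers the exclusive
interpretation. Near the stream end the vote denominator shrinks to the
votes actually cast, and the final n − 1 timepoints, which have no movelet
starting at them, get no prediction.

The uncertainty model is an ordinary two-parameter logistic regression of
the correctness indicator A(t) on the vote proportion v(t), fitted by
maximum likelihood (statsmodels). Consecutive timepoints share most of
their vote windows, so the observations are strongly serially dependent;
the fitted probabilities remain valid as a calibration curve, but the
nominal standard errors of the fit understate the true uncertainty, which
is why the package reports coefficients and derived probabilities rather
than confidence intervals. Exclusion is a flag on the classification, never
a deletion, so filtered and unfiltered evaluations can both be computed.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `rate_h` | 10 Hz | nominal sampling rate; h samples per window-second |
| `window_seconds` | 1.0 | movelet length; long enough to separate gait cycles, short enough to rarely straddle two activities. n = round(window_seconds × h) |
| `duration_seconds` | 4.0 | training data used per activity; the middle 4 s of the longest labeled bout (shorter bouts, e.g. posture transitions, are used whole) |
| `metric` | `l2` | per-channel Euclidean distance averaged over channels; `correlation` (per-channel Pearson, (n−1) denominator, maximized) as alternative |
| `data_type` | `triaxial` | raw x, y, z in the phone frame; `magnitude` discards orientation |
| `votes_per_point` | h + 1 | majority-vote pool size |
| `threshold` | 0.5 | exclusion cutoff on P̂(correct); strict (`prob < c`), so c = 0 excludes nothing |
| grid step | 0.01 | threshold sweep 0, 0.01, …, 1 (101 points) |
| gap tolerance | 2/h | consecutive-sample spacing beyond this is a gap; movelets spanning a gap are dropped |

## Numerical and tie-break choices

- Scores are compared exactly, with deterministic tie-breaking: the
  dictionary's activity order first, then the earlier movelet. Vote ties
  prefer the tied label holding the single best-scoring vote, then fall
  back to activity order. Rebuilding and reclassifying are therefore
  bit-reproducible.
- L2 scores are computed by direct differencing (not an expanded inner
  product), so a movelet matched against itself scores exactly 0.
- Correlation against a zero-variance vector is defined as 0 ("no evidence
  of a match"). Stationary activities produce near-constant gyroscope
  windows, and mapping the undefined correlation to the neutral value keeps
  those windows from spuriously dominating.
- "Middle four seconds" with an odd sample surplus places the extra sample
  at the end (offset = floor((N_seg − n_target)/2)). Ties among equally
  long training bouts go to the earliest.
- Label intervals are half-open [start, end); a timepoint on a boundary
  belongs to the following interval. The annotation convention at interval
  edges is inherently arbitrary; `--boundary-trim` lets evaluations drop
  timepoints near boundaries.
- The logistic fit falls back to a Newton solver with a tiny quadratic
  penalty (1e−6 on both coefficients) when the outcome is single-class, v
  is constant, or (quasi-)separation is detected (non-convergence or
  |β̂| > 10³); the model is flagged `separation=True` so downstream users
  know the coefficients are regularized rather than MLE.
- `predict_correct_prob` uses the numerically stable two-branch logistic
  evaluation, exact for |η| up to overflow.

## The synthetic generator

`gen_stream` renders each protocol segment as baseline + sinusoids +
Gaussian noise: stationary postures are pure baselines (standing gravity
(0, 1, 0) g; sitting gravity tilted toward z, (0, 0.2, 0.98) g; gyroscope
zero); walking is a 1.8 Hz fundamental with axis-dependent amplitudes (and
a half-frequency sway component); stairs use 1.3/1.6 Hz with different
axis mixes; posture transitions are half-cosine ramps between the posture
baselines with a half-sine gyroscope pulse, their duration set by the
protocol segment. Slow and fast walking scale every sinusoid (frequency
×0.6 / amplitude ×0.7, and ×1.25 / ×1.15). `gen_study_fixture` assembles
training bouts (stand 10 s, walk 15 s, stairs 8 s each, two chair-stand
cycles), a ~150 s mixed test course, a three-speed walking segment, and
four independent course replicates emitted in the four pocket
orientations. All noise derives from one seed via spawned substreams.

Signature amplitudes, frequencies and noise levels (0.02–0.08 in sensor
units) are free choices calibrated once for between-activity separability;
they reproduce the qualitative structure of real pocket-phone data —
gravity orientation, near-zero stationary gyroscope, amplitude/frequency
contrasts between gaits — but not its hardest features: no within-activity
amplitude drift, no phase irregularity or harmonics beyond two components,
no sensor bias or duty-cycled sampling, and transitions are smooth rather
than jerky. Passing tests on this generator therefore demonstrates that
the machinery is correct and that the method behaves as designed when its
assumptions hold (near-perfect recall of well-separated activities,
gyroscope stand/sit confusion, degradation on reoriented tri-axial data and
on slow walking); they do not certify accuracy levels on real recordings,
where sensitivities are substantially lower and activity-dependent.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
dictionaries of ~170 movelets (7 activities), streams of 1.5–4.5 k samples,
logistic fits of n = 1.5–2 k, and 20 replicates for the parameter-recovery
check. These sizes were chosen so the whole pipeline, including the
brute-force oracle comparisons, completes in seconds while every code path
(edge votes, short transition bouts, separation fallback, all four
orientations, both metrics and data types) is exercised.

## Known limitations

- Irregular sampling is warned about and gaps are respected during
  windowing, but no resampling is attempted; heavily jittered streams will
  degrade silently beyond the gap warnings.
- The correctness model defaults to v(t) as the sole regressor; `fit_uq`
  accepts additional covariates (e.g. predicted-label indicators), but the
  CLI and pipeline stick to the default model.
- Dictionaries do not transfer across subjects or phone placements, by
  design; there is no demographic matching.
- No automatic threshold selection: the operating point is subject-specific
  and must be chosen from the sweep/ROC outputs.
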