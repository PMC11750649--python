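# Methods

## Scope and design

The package implements the sensor pathway (shin accelerometry → FOG-ratio →
FOG-index), the reference pathway (interval annotations → %TF → subgroups),
and the criterion-validity statistics connecting them, plus a synthetic
cohort generator so the whole analysis runs and is testable without patient
data. The two computational cores are exposed as sklearn-style estimators
(`FogIndexExtractor`, `KSCutoffClassifier`); the generator, file formats,
annotation logic and pipeline orchestration are plain modules and functions.

## Signal model of the generator

A trial is 60 s at 128 Hz (accelerometers in g, gyroscope in deg/s),
matching the usual instrumented protocol. Shin AP/ML channels are sums of
sinusoids with slow multiplicative frequency jitter (3% at a ~2 s
correlation time) and slow amplitude modulation (10%), plus white Gaussian
sensor noise (σ = 0.02 g):

- **Turning locomotion**: a stepping oscillation at the subject's cadence
  (default 1.8 ± 0.25 Hz, clipped to the 0.5–3 Hz locomotion band), left and
  right shins in antiphase. Default amplitudes 0.30 g (AP) and 0.22 g (ML).
- **Trembling episodes**: a 3–8 Hz component (default 5 ± 1 Hz, amplitude
  0.25 g) is superimposed and the stepping amplitude is reduced to 20% —
  progression stops while the legs oscillate.
- **Akinetic episodes**: all deterministic motion is scaled by the
  `akinetic_suppression` factor (default 0.05), leaving essentially sensor
  noise — cessation without visible movement.
- **Lumbar yaw**: a piecewise-constant rotation at `turn_rate_dps`
  (default 70 ± 20 deg/s) whose sign flips after each completed 360° plus a
  small overshoot (default 20°; subjects do not reverse on the exact
  degree, and the margin keeps completed turns unambiguous after
  filtering). Rotation pauses during episodes, so freezers complete fewer
  turns — both the spectral content and the turn-count denominator respond
  to the phenotype. A cadence-locked yaw oscillation (20 deg/s) emulates
  step-cycle sway; the counter's low-pass must remove it.

Episode boundaries are snapped to the sample grid, so interval %TF and
sample-mask %TF agree exactly. Episode counts are Poisson (rate default
1.35/min for freezers, the aggregate episode count per freezer-minute of
the motivating cohort), durations Gamma(shape 2) with mean 5 s (no
episode-duration statistics are published; 5 s lands cohort %TF in the
observed freezer range), placed uniformly with ≥ 1 s gaps by rejection, with
the episode count reduced when a draw cannot be packed. Episode type is
trembling with probability 0.31 (43 of 140 annotated episodes).

Cohort structure defaults mirror the motivating study: 63.4% freezer
prevalence, 21.2% awareness among freezers, 10% self-report among
episode-free subjects ("possible" freezers), questionnaire totals ~N(13.5,
6.7) clipped to 1–28 for self-reporters and 0 otherwise. Freezers always
receive at least one episode, so the ground-truth freezer flag and the
expert classification coincide by construction.

**What the generator does not emulate**: real gait harmonics and asymmetry,
inter-sensor coupling, gyroscope drift, postural transitions, annotation
noise (ground truth is exact), partially-expressed episodes, and the broad
overlap between freezer and non-freezer spectra seen in practice. Passing
tests therefore demonstrate the pipeline's correctness and its sensitivity
under a controllable signal model — not the clinical discriminative
performance of the FOG-index, which on real cohorts is far weaker than on
this clean model.

## Spectral analysis

Windows are 3 s Hann with 50% overlap by default; the window length is not
fixed by the method's published descriptions, and 3 s trades episode-scale
time resolution against 0.33 Hz frequency resolution, marginal at the
0.5 Hz locomotion edge — 4 s is the conservative alternative, one config
field away. The per-window mean is removed before the periodogram so DC
leakage cannot contaminate the locomotion band. The final partial window is
dropped, not zero-padded. Band power integrates the PSD by trapezoid with
linear interpolation at the band edges (a flat PSD of height h over width w
gives exactly h·w).

The plain band-power ratio is the default; the squared variant (as in the
original freeze-index formulation) sits behind `squared_ratio`. The
locomotion denominator is floored at 1e-8 g²: in akinetic windows both
bands collapse toward the noise floor, the denominator hits the floor
first, and the ratio rises — this floor is the mechanism by which the index
responds to akinetic freezing at all, and it makes the floor value a real
modelling choice, not a numerical nicety.

Windows from both shins are pooled before the mean/max aggregation
(default), so a unilateral trembling burst reaches the Max metrics
undiluted; per-shin aggregation then averaging is available via
`pool_shins=False`. Which convention the original analyses used is not
documented; pooling was chosen for its sensitivity to the unilateral
presentations common in freezing.

The FOG-index requires at least one completed turn: with zero turns the
normalization is undefined and the code raises (the pipeline instead
excludes such subjects and reports the exclusion count, mirroring how
technically unusable recordings are dropped in practice).

## Turn counting

The yaw rate is low-pass filtered (4th-order Butterworth, 1.5 Hz cutoff,
zero-phase `sosfiltfilt`) to suppress step-cycle oscillation without biasing
net rotation, then integrated by trapezoid within same-direction segments;
each crossing of a 360° multiple counts one turn, and the remainder of the
final segment is reported as `residual_deg`. A direction reversal is
recognized only when the filtered rate holds the opposite sign for ≥ 0.5 s,
so zero-crossings during freezing pauses do not fragment a turn.
Accumulation is per segment, not global, because alternating directions
would cancel in a net integral. Filtering and dwell are configurable;
`lowpass_hz=None` disables the filter, which is the right setting for
clean piecewise-constant profiles where the closed-form count is the
reference.

## Annotations and subgroups

Intervals are half-open `[start, end)` in seconds from trial start; %TF is
summed episode duration over the nominal trial duration, per type and
total (types are exclusive, so the parts always sum to the total). An
episode is trembling only if leg oscillation covers *strictly more than*
half of it. The human third-moderator consensus step cannot be automated:
the deterministic stand-in pairs episodes across raters by interval Jaccard
(≥ 0.5), takes the union when type labels agree, shrinks to the
intersection with rater-A precedence and a flag when they disagree, and
flags unmatched episodes. A pre-resolved consensus file can be supplied
directly instead. Subgroups are the cross of self-report and expert flags;
shares are reported against the denominators used in practice (unaware and
aware as shares of expert-rated freezers, possible as a share of
self-reporters).

## Validation statistics

ROC thresholds are the midpoints between distinct sorted scores plus ±∞
sentinels, with "score ≥ threshold" classifying positive; this makes tied
scores a single ROC step, and the trapezoidal AUC (points ordered by FPR
then TPR) equals the tie-corrected Mann–Whitney concordant-pair fraction
exactly — a property the tests assert against brute-force pair counting on
random tied instances. The operating cutoff maximizes the KS metric
sensitivity + specificity − 1; ties go to the higher-sensitivity threshold,
then the lower threshold. AR = 2·AUC − 1 is computed from the AUC, never
stored independently.

The AUC p-value tests AUC = 0.5 through the U statistic: exact permutation
over all label assignments when both classes have ≤ 10 observations,
otherwise the tie-corrected normal approximation without continuity
correction. Which test the original SPSS analysis used is not stated; this
choice is transparent and reproducible, and the two agree well at the
cohort sizes involved. Spearman's rho and its t-approximation p-value come
from `scipy.stats.spearmanr`, with constant inputs flagged explicitly.

## Pipeline and reproducibility

`run_study` chains simulate → extract → summarize → validate, excludes
zero-turn subjects with a logged count, and produces the partition,
classification (4 metrics × 4 reference groups: clinical, self-report,
aware vs non-freezers, unaware vs non-freezers) and correlation tables
(metrics × %TF outcomes × 3 subject groups). All randomness descends from
one integer seed through `numpy.random.SeedSequence.spawn`; outputs embed
the seed and a SHA-256 prefix of the configuration, and reruns are
byte-identical. A single-class reference (e.g., a cohort with no freezers)
aborts with a stage-tagged error rather than fabricating a ROC.

Default problem sizes in the test and acceptance suites (cohorts of 12–200
subjects, 60 s trials at 128 Hz) were chosen to exercise cohort-level
sampling behavior at the scale of the motivating study while keeping a full
run of the suite in the minutes range on one CPU.

## Known limitations

- The generator's clean separation means cohort-level AUCs near 1.0; it can
  demonstrate correctness and monotone sensitivity, not clinical accuracy.
- The epsilon floor makes akinetic windows produce very large FOG-ratios;
  Max metrics are therefore floor-sensitive in fully akinetic trials.
- The consensus policy is a deterministic approximation of a human
  adjudication process and has no claim to equivalence with it.
- Turn counting assumes a correctly mounted sensor (the yaw channel is the
  longitudinal axis); axis remapping is left to the I/O schema config.
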