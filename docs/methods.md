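# Methods

## Response model

Each accommodative step response is modeled as a single first-order
exponential, the minimal form consistent with the morphology of recorded
step responses:

    x(t) = baseline                                   t < t0
    x(t) = baseline ± A·(1 − exp(−(t − t0)/τ))        t ≥ t0

with amplitude `A` (D), time constant `τ` (s), and onset delay `t0` (s)
inside the 5 s movement window; the sign is + for focus (far→near) and −
for defocus (near→far). This is a feedback-dominant description: its peak
velocity is `A/τ` at onset and its final amplitude approaches `A`. These
closed forms anchor the recovery tests. An optional boxcar velocity pulse
(`pulse_velocity`, `pulse_duration` on `ResponseParams`) can superimpose a
distinct preprogrammed component for experiments that need one; it is off
by default. Defocus movements are sign-flipped focus movements with an
independently configurable gain table (defaults equal).

The generator emits no actual generative values for `τ` or noise from any
measured dataset: they are synthetic conventions. Defaults: `τ ~
Uniform(0.20, 0.35) s` per movement, giving peak velocities of roughly 4–8
D/s at a 1.5 D amplitude; per-sample Gaussian measurement noise SD 0.1 D
per eye; onset delays `Uniform(0.5, 2.0) s`.

## Study conditions emulated by the generator

- 50 Hz sampling; 5 s per movement (250 samples).
- Demand step 1.5 D between 2.5 D (40 cm) and 1.0 D (1 m).
- Seven cue conditions; 30 movements per binocular condition (BDP, BD-p,
  DP-b, D-bp: 7500 samples = 150 s per file) and 60 per monocular condition
  (BP-d, B-dp, P-bd), focus/defocus interleaved starting with focus.
- Per-cue final-amplitude gain targets: BDP 0.97, BD-p 0.97, BP-d 0.80,
  B-dp 0.71, DP-b 0.60, D-bp 0.55, P-bd 0.33 (population mean FA =
  gain × 1.5 D).
- Amplitude variability is multiplicative and two-level: one participant
  factor `1 + N(0, 0.08)` shared across that participant's cues, and one
  per-movement factor `1 + N(0, 0.10)`. The participant level makes cue
  means within a cohort move together, as individual response gains do.
- Blink/dropout artifacts: gap onsets at 0.05/s, geometric lengths with
  mean 8 samples (~160 ms), hitting both eyes (a blink) with probability
  0.5, otherwise one eye.
- Seeds: a master seed spawns one `numpy` `SeedSequence` child per
  participant, which spawns one per cue plus one for the participant
  factor. Identical configs give byte-identical file sets.

What the generator does **not** emulate: pupil dynamics, vergence traces,
instrument calibration drift, latency correlations between movements,
non-exponential (double-mode) trajectories, and non-Gaussian noise. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under these assumptions, not the physiological fidelity of real
recordings.

## QC conventions

Fellow-eye substitution runs before the rejection rules, so the rules judge
the post-substitution combined signal (`apply_rejection(substitute=False)`
evaluates raw masks instead). Threshold inclusivity follows the stated
rules literally: missing fraction ≥ 0.25 rejects; valid samples < 750
rejects; longest gap ≥ 225 samples rejects. The nominal 7500-sample session
length is used only for the completeness field of the QC report, not as a
rejection rule. Sub-threshold gaps are filled by linear interpolation
(nearest value at the edges); the pre-fill masks are retained and each
movement's interpolated fraction feeds the artifact screen.

## Signal conditioning

The 5th-order Butterworth low-pass (20 Hz cut-off at 50 Hz sampling) is
applied zero-phase (forward–backward) so it cannot bias peak-velocity
timing; the consequence is −6 dB rather than −3 dB attenuation at the
cut-off. Filtering is applied to the whole recording before segmentation so
window edges carry no filter transients. Velocity is the central difference
of the filtered position (one-sided at window edges), exact for quadratics.
Pipeline order is fixed: interpolate → filter → calibrate → align →
segment → differentiate. The calibration factor defaults to 1.0 and is a
configurable scalar per recording.

### Peak-velocity recovery bound

Discrete central differencing at 50 Hz plus the zero-phase low-pass
attenuate the sampled peak of the exponential's velocity. Measured on
noiseless movements, the recovered PV underestimates `A/τ` by 6–15%
depending on `τ` and the sub-sample phase of the onset: at the reference
parameters (`A = 1.5 D`, `τ = 0.25 s`, on-grid onset) the error is −8.3%,
within the documented 10% band; at `τ = 0.20 s` with the worst onset phase
it reaches −15%. FA is essentially exact: ≤ 3×10⁻⁵ D error for `τ ≤ 0.25`,
≤ 7×10⁻⁴ D at the slowest defaults.

## Metrics and outlier rules

PV is signed (focus positive, defocus negative); group inference uses
magnitudes within each direction stratum. FA is the mean of the last 25
samples (0.5 s) of the baseline-aligned window. Validity screening uses
configurable defaults that are conventions, not measured thresholds:
|FA| < 0.2 D → non-response; any |velocity| > 25 D/s → noise; > 10% of the
window gap-interpolated → artifact.

The intra-participant 2-SD rule is a single pass: a movement is removed iff
its value lies ≥ 2 sample SDs (n−1) from the mean of all valid movements of
that participant × cue × direction, applied independently to PV and FA.
With SD 0 or fewer than 3 movements nothing is removed. Inter-participant
outliers use the 1.5×IQR fence with quartiles by linear interpolation of
order statistics; equality with a fence is not "outside".

## Inference

Kruskal–Wallis uses mid-ranks, the tie correction `C = 1 − Σ(t³−t)/(N³−N)`,
and the χ² approximation with k−1 df (appropriate at these group sizes; the
test suite carries an exact-permutation oracle). All pooled values tied is
returned as H = 0, p = 1. DSCF ranks each pair in isolation with
tie-corrected variance and refers `|W|` to the studentized range
`q_{k,∞}`; a zero pair variance is flagged degenerate (W = 0, p = 1).
Levene defaults to mean-centering, with the Brown–Forsythe median option; a
zero denominator returns (0, 1) when the numerator is also zero and
(∞, 0) otherwise. Shapiro–Wilk delegates to scipy's Royston approximation.
The workflow removes IQR outliers per cue, records the assumption checks,
and produces the 21-pair DSCF table only when the main effect is
significant at α = 0.05 (configurable).

## Monte-Carlo studies and their conventions

`accomstep.studies.run_cohort_study` replicates default cohorts (n = 20
participants) through the full pipeline. The per-cue mean |FA| is compared
to its target with the estimator's theoretical sampling SE under the
generator:

    SE² = [ (A·σ_participant)² + ((A·σ_movement)² + σ²_FA-noise)/m ] / n

where `m` is the movements per direction and `σ²_FA-noise` is evaluated
exactly from the filter's combined impulse response
(`synth.fa_noise_variance`); the measurement-noise term contributes only a
few percent of the total. Coverage is counted over all
(replicate × cue × direction) checks. Because the participant amplitude
factor is shared across cues, checks within a replicate are positively
correlated, so the observed coverage fraction varies more between study
seeds than a binomial count would; the 2-SD movement trimming also inflates
the true estimator variance by a further ~1% in SE, slightly below the
nominal 95.45% band coverage. Both effects are properties of the trimmed estimator rather than of the SE
formula's variance components; the SE is deliberately kept as the
untrimmed-estimator theory and the study reports the coverage the pipeline
actually delivers.

Problem sizes used throughout: 100 replicate cohorts for recovery/ordering
/power studies, 1000 group-level replicates for the type-I error of the
main-effect test (k = 7 groups of 20). These sizes give Monte-Carlo SEs of
~2% on the reported rates while keeping a full study run around a minute.

## Known limitations

- The exponential response model has no latency jitter within a movement
  beyond `t0`, no overshoot, and no fatigue across the session.
- Gap artifacts are independent of the response (real blinks correlate
  with stimulus onsets).
- The CA/C utility takes an externally supplied vergence amplitude; no
  vergence traces are processed.
- Recordings are assumed continuously and uniformly sampled; timestamps
  with jitter are rejected at parse time rather than resampled.
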