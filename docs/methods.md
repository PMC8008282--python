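# Methods

This note documents the signal model behind the synthetic-experiment
generator, the estimator conventions of the analysis pipeline, the numerical
choices that were genuinely open, and what the passing test suite does and
does not establish about real recordings.

## Task and design

The simulated experiment is a sequential cue-acquisition decision task.
Each trial presents up to 6 binary cues in descending validity
(0.706, 0.688, 0.667, 0.647, 0.625, 0.62); after the first cue (2000 ms
fixed) the participant either acquires the next cue or chooses between two
alternatives. The number of acquired cues (1–6) is the trial's
cognitive-effort index. Three affective-priming groups (neutral N=8,
aversive N=7, erotic N=6) each complete 3 training and 24 decision trials.
Recordings cover the cue-presentation and decision period of each trial
(t = 0 at first-cue onset); fixation cross and prime periods carry no
analyzed signal and are not synthesized.

Cue counts are drawn per condition from bimodal distributions
(neutral .41/.10/.06/.08/.35, aversive .54/.12/.04/.01/.29, erotic
.56/.10/.07/.02/.25 over 1–5 cues; 6-cue mass 0). Epoch durations for cues
≥ 2 are lognormal (mean 1500 ms, sd 500 ms, clipped to 600–6000 ms): later
epochs are self-paced and no empirical duration distribution is available,
so this is an explicit stand-in. Choice accuracy is Bernoulli with p equal
to the validity of the best discriminating cue — cosmetic fidelity only;
accuracy is never analyzed downstream.

## Gaze signal model

Gaze is fixational: a bounded Ornstein–Uhlenbeck drift (step sd 0.001°/ms,
reversion 5·10⁻⁵/ms; stationary sd ≈ 0.1°) plus microsaccades, emitted for
both eyes as the common signal plus independent per-eye white noise
(0.005°), converted to screen pixels by the exact inverse of the pipeline's
pixel→degree transform.

Microsaccades are a Poisson process per cue epoch at rate
`max(0.05, base + slope·(cue−1))` events/s with base 2.0 and per-condition
slopes −0.355 (neutral, also erotic, whose interaction is indistinguishable
from neutral) and −0.657 (aversive). Onsets keep 60 ms from epoch edges and
100 ms from each other. Magnitudes are lognormal (mean 0.3°, sd 0.15°);
target peak velocity is `376.37·m + 12.91 + N(0, 22)` °/s, the velocity
noise chosen so that the detected-event main sequence lands at R² ≈ 0.84.

The waveform deserves a note, because the main-sequence slope is steep: a
pulse whose *sampled* 5-point peak velocity must equal `376·m + 13` cannot
be a simple minimum-jerk pulse of displacement m (its duration would be
~5 ms — shorter than the velocity estimator's support, which would bias
every measured velocity down). Each event is therefore an out-leg with a
trapezoidal speed profile (0.5 ms ramps around a 6 ms plateau at the target
peak speed — long enough that the 5-point estimator reads the plateau
exactly) followed by a slower corrective return at 40% of peak speed that
brings the net start-to-end displacement back to m. Event directions aim
toward the fixation centre (±0.25 rad), so gaze stays bounded. The
transient excursion of such an event reaches `7 ms · v_peak` ≈ 1–2°, which
drives two preprocessing defaults (below).

## Pupil signal model

Pupil (arbitrary tracker units) = participant baseline
(N(4000, 128.6²) between participants) + evoked level
`slope_condition·(cue−1)` per epoch (37.00 neutral, 98.79 aversive, −28.86
erotic; 0 in training trials) + hippus (20-unit, 0.2 Hz sinusoid with
random phase) + effort-scaled white noise (sd `10·(cue−1)`), reported in
**integer tracker units** per eye (quantization step 1, per-eye noise 0.2).
Quantization matters: it is the resting high-frequency noise floor of real
video trackers, and it is what gives the LHIPA index its operating point
(see below). Blinks arrive at 0.1/s, last ~150 ms, and blank all channels.

The ground-truth ledger records every injected event (onset, magnitude,
peak velocity, epoch) and every latent epoch mean, so recovery tests never
compare against re-derived quantities.

## Preprocessing conventions

* Blinks: maximal missing-pupil runs (either eye) padded by 100 ms per side
  and merged; all channels masked inside. Padding covers lid-closure pupil
  artifacts; the value is a config knob.
* Binocular averaging: per-sample mean of the eyes; a sample with exactly
  one eye missing falls back to the present eye, so monocular dropouts do
  not shred the cyclopean trace.
* Degrees: per-axis `atan(displacement_cm / distance_cm)` about the screen
  centre; geometry (57 cm, 1024×768 on a 44.7×33.5 cm panel) must state the
  physical panel size explicitly — a diagonal alone does not determine it.
* Pupil smoothing: 100 ms centred moving average ignoring missing samples.
* Fixations: I-DT with dispersion = (max−min summed over axes) ≤ 4.0° and
  minimum duration 100 ms. Two deliberate departures from textbook settings,
  both consequences of the steep main sequence: (i) the segmentation input
  is a 41 ms median-filtered copy of the gaze trace, so a microsaccade's
  1–2° transient excursion does not count toward window dispersion (the
  detector itself always sees the raw trace); (ii) the dispersion ceiling is
  permissive, because successive event displacements random-walk the window
  extremes. A tight ceiling truncates fixations *at* the events and the
  within-fixation detector then loses exactly the events of interest.
  Saccades between distinct screen regions are far larger than 4° and still
  segment. Both values are config knobs.

## Microsaccade detection and summaries

Detection follows the velocity-threshold family: 5-point smoothed velocity,
median-based noise estimate per axis (floored at 10⁻⁶ °/s), elliptic
criterion at λ = 6, candidate runs ≥ 6 ms (inclusive sample count), merge
gap 20 ms, magnitude cut 1.0°. Note the median-based estimate
`sqrt(median(v²) − median(v)²)` converges to 0.6745σ for Gaussian noise —
the deliberate robustness discount of this estimator family; λ is scaled
accordingly. Thresholds are estimated per fixation when it has ≥ 50
samples, else from the whole trial. Magnitude is start-to-end displacement
(not peak-to-peak excursion — the literature varies); peak velocity is the
maximum speed of the same smoothed velocity series used for detection.

Per-epoch rate divides the event count by the **exposure** — the fixation
time overlapping the epoch — rather than the raw epoch duration. Events are
only detectable within fixations and never during blink masking (~3.5% of
time at the default blink process), so a raw-duration denominator is biased
low by exactly the unobserved fraction; exposure correction is the unbiased
estimator for a homogeneous Poisson process under partial observation.
`epoch_summaries` defaults to the raw duration when no exposure is given.

The main sequence is an OLS of peak velocity on magnitude over all detected
events; slope, intercept, SEs and R² are reported.

## Pupil indices

BCPD: participant baseline = sample-weighted pooled mean of smoothed,
blink-masked pupil over all training trials (training trials are assumed
effort-free); epoch BCPD = mean smoothed epoch pupil − baseline, requiring
≥ 100 usable samples. Epoch means trim half the smoothing window from both
epoch edges so the centred moving average cannot leak the neighbouring
epoch's level into the mean. Δ measures use the epoch mean (one value per
epoch feeds the mixed models; the mean is the variance-minimizing summary).

LHIPA: symlet-16 decomposition; detail coefficients at level 1
(high-frequency band) and at half the maximal decomposition depth for the
slice length (low-frequency band), each amplitude-normalized by 2^(level/2);
the LF coefficients are paired with the HF coefficient at the same time
position to form an LF/HF ratio series; modulus maxima (strict local maxima
of |ratio|) are thresholded with the universal threshold
`σ̂·sqrt(2·ln n)`, with σ̂ the MAD-based robust scale of the ratio series;
the index is the count of maxima **exceeding** the threshold divided by the
slice duration in seconds. Missing samples are linearly interpolated first;
slices more than 30% missing are dropped (missing metric, logged).

Two properties motivate these conventions. Because the ratio is
self-normalized and σ̂ lives in ratio units, the index is invariant to
rescaling the pupil signal (exactly so for power-of-two factors; float
rounding of tied maxima can move a count by ±1 otherwise). And the index
falls with effort through a shape mechanism: at rest the HF band of a
quantized, smooth pupil trace is sparse (staircase transitions), so the
LF/HF ratio is heavy-tailed and many maxima exceed the threshold; effort
adds genuine high-frequency power, Gaussianizes the HF band, lightens the
ratio's tails and depresses the exceedance count. A below-threshold count —
a defensible alternative reading of the index's published description — is
provably insensitive here: for any stationary Gaussian-family noise the
ratio's distribution changes only by scale, which a self-normalized
below-count cannot see. The exceedance convention (inherited from the
index's predecessor) is the one under which the documented
effort-decreasing behaviour is reproducible, and the 20-seed sign test in
the suite verifies it.

Known artifact: the decomposition depth, hence the LF level and the
baseline maxima density, steps with slice length (e.g. at 2¹¹·31 samples),
so LHIPA values are comparable across epochs of similar length but carry a
length-dependent base rate. Per-trial ΔLHIPA consequently mixes effort and
epoch-length effects; the corresponding mixed model is exploratory, no
generator truth is defined for it, and no acceptance quantity depends on
it.

## Δ measures and analysis rows

Each trial contributes one analysis row: Δm = m(last epoch) − m(first
epoch) for each of the four measures. Single-cue trials are retained with
Δ ≡ 0 (last = first) — the effort regressor spans 1–6, so these rows anchor
the line's left end; dropping them would discard 49% of trials. A Δ is
missing if either endpoint metric is missing; mixed models drop missing
rows listwise. The microsaccade-rate model uses ΔMS-rate by default; a
config switch (`ms_rate_dv: per_epoch`) analyzes raw per-epoch rates
instead, with epoch index as the effort regressor.

## Inference

* Pearson correlations (participant-level means) with
  `t = r·sqrt(n−2)/sqrt(1−r²)` and two-sided p from t(n−2).
* χ² goodness of fit of the cue-count distribution against equal
  proportions over the 6 cue bins (df = 5), per condition and overall.
* Nested LMMs via maximum likelihood: random intercepts for condition and
  for participant nested in condition; fixed part intercept-only (null) or
  condition + n_cues + condition:n_cues with treatment coding, neutral
  reference (full). With only 3 condition levels the condition variance is
  weakly identified; it may estimate to 0 and is reported, never tested.
  LRT = 2·(llf_full − llf_null), df 5. Pseudo-R² (total) = squared
  correlation of fitted (fixed + predicted random) with observed values —
  one documented choice among several "total R²" conventions, isolated in
  one function. Wald t uses a residual-style df (n − p); estimates and SEs,
  not dfs, are the tested quantities. Estimation delegates to statsmodels
  MixedLM; a test cross-checks the fixed effects and log-likelihood against
  lme4 (via Rscript) on identical rows to ~3 decimal places. Two-sided
  p-values, α = 0.05, no multiplicity correction.

## What the tests show — and what they do not

The suite establishes: exact agreement of the estimators with brute-force
oracles (5-point velocity formula, exhaustive I-DT scan, loop-level
detector re-implementation, normal equations, lme4); invariances
(translation, eye-swap, λ-monotonicity, BCPD linearity, LHIPA rescaling);
calibration (χ² GOF near-nominal, LMM null false-positive rate ≤ 10%); and
end-to-end parameter recovery — injected main-sequence slope within 2%
through detection, ≥ 90% of injected events ≥ 0.1° found within ±10 ms,
detected rates within 15% of generator rates, and the injected BCPD and
MS-rate cue slopes inside 2 estimated SEs in ≥ 90% of 50 simulated
experiments.

The generator deliberately omits: ocular tremor; inter-region saccades
(cue reading is collapsed into fixational behaviour); luminance responses;
pupil foreshortening artifacts; non-stationary arousal drift; and any
dependence of accuracy on the eye signals. Main-sequence parameters are
injected, not emergent oculomotor physics, and the corrective-return
waveform is one admissible shape, not a claim about real saccade dynamics.
Passing recovery tests therefore show the *pipeline* is unbiased and
correctly implemented under the stated signal model — not that the model
exhausts real data. Problem sizes in tests (50 replicate experiments for
slope recovery, 20-seed sign tests, 10⁵ behavioral draws, ≥ 10⁴ events for
the main-sequence check) were chosen as the smallest sizes at which the
Monte-Carlo error is negligible relative to the tested tolerances.
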