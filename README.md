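# oculoeffort

Pupillary and microsaccadic markers of cognitive effort during multi-cue
decision making — a simulation and analysis pipeline for psychophysiologists
working with high-rate (1 kHz) binocular eye-tracking data.

In a sequential cue-acquisition task, the number of cues a decision maker
inspects before choosing indexes how much pre-decisional information
processing — cognitive effort — the trial demanded. Two families of ocular
measures track that effort without any overt response:

* **Pupil size.** BCPD (baseline / inter-trial change in pupil diameter) is
  the mean smoothed pupil during a cue epoch minus a per-participant baseline
  taken from training trials; it dilates with effort. LHIPA (low/high index
  of pupillary activity) is the duration-normalized count of thresholded
  modulus maxima of the ratio between low- and high-frequency wavelet detail
  coefficients of the pupil trace; it falls as effort raises high-frequency
  pupillary activity.
* **Microsaccades.** Small fixational saccades (≲1°, ~1–2/s), detected with
  the classic velocity-threshold scheme: smoothed 5-point velocity
  `v_n = (x_{n+2}+x_{n+1}-x_{n-1}-x_{n-2}) / 6Δt`, robust per-axis noise
  level `σ² = median(v²) − median(v)²`, and the elliptic criterion
  `(v_x/λσ_x)² + (v_y/λσ_y)² > 1` with λ = 6. Their rate drops with effort,
  and detected events must obey the main sequence
  `v_peak = b·magnitude + a` (here b = 376.37 1/s, a = 12.91 °/s, R² ≈ 0.84).

Per trial, each measure is summarized as a Δ (last cue epoch minus first cue
epoch) and analyzed with nested linear mixed models — random intercepts for
affective-priming condition (neutral / aversive / erotic) and for participant
nested in condition; fixed effects of condition, number of acquired cues, and
their interaction; ML estimation, likelihood-ratio tests, and a total
pseudo-R² (squared correlation of fitted and observed values).

Because no recordings are distributed with the design this package models, a
first-class synthetic-experiment generator reproduces the study conditions:
21 participants (8 neutral / 7 aversive / 6 erotic) × 24 decision trials
(+3 training), a bimodal cue-count distribution (49% single-cue, 30%
five-cue overall), fixational drift plus main-sequence-consistent
microsaccades whose rate falls by 0.355 events/s per cue (steeper under
aversive priming), and pupil traces whose epoch means rise 37 units per cue
in the neutral condition (+61.79 aversive, −65.86 erotic), in integer
tracker units. Every injected event and latent mean is kept in a
ground-truth ledger, so the whole pipeline is validated by parameter
recovery.

## Worked example

```bash
oculo-effort run --config examples/config.yaml --seed 7 --out report/
oculo-effort report --in report/
```

prints (abridged):

```
504 trials, 3102 microsaccades; main sequence slope 375.47 1/s (R^2 = 0.838)

LMM [d_bcpd]  LRT chi2(5) = 2287.692, p = 0, pseudo-R2 = 0.992
  n_cues                       b =    37.882  SE =    0.466  t =  81.352  p = 0
  condition[aversive]:n_cues   b =    61.266  SE =    0.701  t =  87.399  p = 0
  condition[erotic]:n_cues     b =   -66.823  SE =    0.749  t = -89.198  p = 0

LMM [d_ms_rate]  LRT chi2(5) = 272.321, p = 0, pseudo-R2 = 0.417
  n_cues                       b =    -0.417  SE =    0.035  t = -12.032  p = 0
```

Reading this: 504 analyzed trials yielded 3102 detected microsaccades whose
magnitude–peak-velocity regression (slope 375.5 1/s, R² 0.838) recovers the
generator's main-sequence line — the standard sanity check that detected
events are genuine saccades. The ΔBCPD mixed model recovers the injected
pupil effect structure: +37.9 units of dilation per additional cue in the
neutral condition (truth 37.00), a steeper aversive slope (+61.3 offset,
truth +61.79) and a reversed erotic slope (−66.8, truth −65.86). The ΔMS-rate
model recovers the injected −0.355 events/s/cue inhibition (−0.417 ± 0.035
in this particular replicate, within two standard errors of the truth).
`report/`
additionally contains `cue_distribution.csv` (per-condition cue-count
proportions with χ² tests against equal proportions), `correlations.csv`
(participant-level zero-order Pearson tests), `main_sequence.csv`,
`lmm_<dv>.csv`, and a machine-readable `summary.json`.

`oculo-effort simulate --config cfg.yaml --seed N --out DIR` writes
`samples.csv` (per-sample binocular gaze/pupil), `trials.csv` (behavioral
records) and `truth.json` (the ground-truth ledger) for use with external
tools; `run --in DIR` analyzes such a directory instead of simulating.

## Layout

| module | contents |
|---|---|
| `oculoeffort.gaze_io` | data model (recordings, trials, geometry, task) + CSV readers/writers |
| `oculoeffort.synthetic` | the experiment generator and its ground-truth ledger |
| `oculoeffort.preprocess` | blinks, binocular averaging, deg conversion, smoothing, I-DT fixations |
| `oculoeffort.microsaccades` | velocity-threshold detection, main sequence, epoch summaries |
| `oculoeffort.pupillometry` | baseline, BCPD, LHIPA |
| `oculoeffort.trial_metrics` | cue-epoch segmentation and Δ measures |
| `oculoeffort.stats` | correlations, χ² GOF, OLS, nested LMM with LRT / pseudo-R² |
| `oculoeffort.pipeline` / `cli` | orchestration, YAML config, report writing, `oculo-effort` |

See `docs/methods.md` for the signal model, estimator conventions, and known
limitations.
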