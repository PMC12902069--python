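# Methods

`dyadsync` analyses dual eye-tracking recordings of interacting pairs: one
*listener* (hearing emotion-inducing audio) and one *observer* (inferring the
listener's state from eye cues alone), recorded simultaneously at 200 Hz
through three trials, each consisting of three consecutive 30-s phases —
*baseline* (fixation cross), *audio* (mutual gaze, sound for the listener
only) and *silence* (post-stimulus mutual gaze) — with one emotional context
(neutral / negative / positive) per trial in counterbalanced order. This note
documents the models, parameters and numerical choices, and what the
synthetic validation does and does not establish.

## Pupil preprocessing

Pupil-diameter traces (left eye, device units assumed mm) pass through an
artifact-rejection chain in a fixed order:

1. **Blink reconstruction** — samples from 100 ms before each blink onset to
   150 ms after its offset are replaced by the line joining the nearest valid
   samples outside the padded span and marked *interpolated* (distinct from
   originally valid). Spans touching the trace boundary are invalidated, not
   extrapolated.
2. **Saccade reconstruction** — the same with a symmetric 75-ms buffer.
3. **Dilation-speed filter** — per sample, speed is the two-sided maximum
   absolute difference quotient over valid neighbours (the standard
   definition in pupillometry preprocessing guidelines); samples with speed
   strictly above median + 3×MAD are invalidated. MAD is the *unscaled*
   median absolute deviation — the rule is applied literally, with no
   normal-consistency factor. The statistics are computed per continuous
   trial, not per 30-s phase: phases are contiguous segments of one
   physiological signal, and per-phase scoping is available by calling the
   filter on a phase segment.
4. **Gap-edge trimming** — 50 ms of data on either side of any missing run
   longer than 75 ms is invalidated. Samples invalidated *by this stage* are
   excluded when locating gaps, which makes the stage idempotent; pads of
   adjacent gaps union.
5. **Sparsity filter** — valid islands shorter than 50 ms whose two flanking
   gaps both exceed 40 ms are invalidated (trace boundaries count as
   infinite gaps). All islands are judged against the input mask
   simultaneously, making the stage idempotent and order-independent.

Per phase, the missing fraction is the share of expected samples
(30 s × 200 Hz) that are neither valid nor interpolated; a phase is flagged
for exclusion when it exceeds 30% (strictly).

Conventions: all threshold comparisons are strict ("exceeding"), so a flat
trace flags nothing and an exactly-30%-missing phase is retained; no stage
ever converts an invalid sample back to valid; timestamps are never altered.
The chain runs unconditionally by default — the original procedure applied
later stages after visual inspection, which is not reproducible — and every
stage has a config switch.

## Dilation-velocity peaks

Interior missing runs of the preprocessed trace are linearly interpolated
(leading/trailing runs are left missing), the series is smoothed with a
Savitzky-Golay filter (window 11 samples, order 3) and differentiated
(central differences, one-sided at segment ends, actual sample spacing).
Candidate peaks are strict local maxima of the derivative — a flat plateau
contributes its midpoint — whose value exceeds mean + 2.5 SD of the
derivative over the analysed segment (per trial; "2.5 standard deviations"
does not specify centring or scope, so the mean-centred per-trial version is
the default and a zero-centred variant is configurable). Non-maximal
suppression then processes candidates in descending derivative value,
accepting a candidate only if it lies ≥ 1500 ms from every accepted peak.
Because the threshold is SD-relative, multiplying a trace by any positive
constant leaves peak *times* unchanged.

## Synchrony statistics

For each reference event onset (listener, by default) the nearest test event
onset (observer) is located and the signed lag *test − reference* recorded.
A reference event is *synchronized* when |lag| ≤ *w*, with *w* = 1.5 s for
blink onsets and 2.5 s for dilation-peak times; the synchronization
percentage of a dyad × trial × phase cell is the share of that cell's
reference events that are synchronized. Phases with zero reference events
yield a missing value, never 0 or 100.

Deliberate conventions, each behind a config switch where an alternative is
plausible:

* **Denominator** — the reference member's events in the phase. The
  alternative reading (both members' events pooled) leaves in-window
  membership undefined for test-only events; it is implemented for
  sensitivity analysis.
* **Ties** — equidistant earlier/later test events resolve to the earlier
  one (negative lag); ties have measure zero in continuous data.
* **Non-exclusive matching** — one test event may be the nearest neighbour
  of several reference events.
* **Inclusive window** — |lag| = *w* counts as synchronized.
* **Cross-phase search** — the analysis window is anchored on the reference
  onset, not clipped to the phase, so the nearest test event may lie just
  across a phase boundary.

Against an independent homogeneous Poisson test train of rate λ the expected
percentage has the closed form 100·(1 − exp(−2wλ)) — the chance level that
anchors the calibration tests. With coupling probability *p* and independent
observer rate λ the expected value is 100·(1 − (1 − p)·exp(−2wλ)).

An exploratory Spearman rank correlation relates blink and pupil-peak
synchrony across dyads per phase (per-dyad values are means over trials;
fewer than 3 paired dyads yields a missing value).

## Mixed-effects inference

Synchrony percentages are modelled as

    sync ~ phase * context + (1 | dyad)

by REML (statsmodels' MixedLM supplies the variance-component estimates; a
direct Nelder-Mead maximisation of the closed-form random-intercept REML
log-likelihood serves as a fallback when its optimiser fails). All reported
inference is recomputed from the closed-form GLS expressions at the
estimated components, so estimates, tests and intervals are mutually
consistent:

* **F-tests with Satterthwaite df.** For a contrast *l*, the denominator df
  is 2·f(θ̂)²/(∇f·A·∇f) with f(θ) = lᵀVar(β̂;θ)l and A the inverse of the
  numerically differentiated REML information. Multi-df terms use the
  eigen-decomposition of the contrast covariance and the standard
  df-combination rule. Main effects are tested as marginal-mean contrasts
  averaged over the other factor (Type III); the interaction as its
  coefficient block. On balanced 24-dyad data the phase denominator df
  reproduces the classical value (23 × 8 = 184).
* **Estimated marginal means and Tukey contrasts.** Cell means on the
  phase × context grid; phase EMMs average over contexts. Pairwise phase
  contrasts carry Satterthwaite df and Tukey-adjusted p-values/95% CIs via
  the studentized-range distribution.
* **Variance decomposition.** σ²_f is the population variance of the
  fixed-effect linear predictor over the modelled rows (coding-invariant);
  marginal R² = σ²_f/(σ²_f+σ²_dyad+σ²_res) and conditional
  R² = (σ²_f+σ²_dyad)/(σ²_f+σ²_dyad+σ²_res), so
  0 ≤ R²m ≤ R²c ≤ 1 holds on every fit.
* **Singular fits.** REML lands exactly at the σ²_dyad = 0 boundary only
  about half the time when the true variance is zero, so negligible-variance
  data are detected instead with the boundary-corrected REML likelihood
  ratio for the random intercept (0.5·χ²₀ + 0.5·χ²₁ mixture, 5% critical
  value 2.706). A non-significant dyad variance is reported at the boundary:
  the flag is set, fixed effects equal OLS, and tests use residual df. The
  flag therefore reads "no detectable dyad variance", and small true
  variances near the detection limit are deliberately shrunk to zero.
* Missing cells (zero-reference-event phases) are dropped listwise; no
  imputation.

The whole layer is cross-checked in the test suite against R's
lmerTest/emmeans on a fixture (F, denominator df, EMMs, contrast estimates,
Tukey p, R²).

The omnibus MANOVA/mixed-ANOVA machinery applied to the per-participant
fixation/blink/pupil measures is out of scope by design: the pipeline emits
the long-format metrics table those routine procedures consume, plus
descriptive marginal means.

## Synthetic dyad generator

The generator produces complete dyads — traces, events, schedules — with
known ground truth, so every downstream stage is testable without data
downloads. Defaults are the validation conditions; units are in the config
field comments.

**Blink trains.** Listener blinks are homogeneous Poisson (0.28/s; resting
adult rates run 15–20/min, and listeners blink more than monitoring
observers) with a 100-ms refractory merge. Each listener blink spawns an
observer blink with a per-phase coupling probability at a
Normal(0.15 s, 0.45 s) lag truncated to ±1.5 s; independent observer blinks
(0.20/s) are superposed. Per-phase coupling defaults (baseline 0.40, audio
0.10, silence 0.25) encode the attentional-coupling ordering the synchrony
statistics are designed to detect, and a per-dyad coupling offset
(SD 0.15, shared across phases) plants the interpersonal heterogeneity that
becomes the dyad random-intercept variance downstream.

**Pupil traces.** Baseline 5.1 mm plus a slow sinusoidal drift (0.10 mm,
90-s period), a hippus-like oscillation (0.03 mm at 0.15–0.40 Hz),
event-related dilation kernels, band-limited slow Gaussian noise (SD
0.03 mm, 0.3-s smoothing) and a bounded micron-scale sensor-jitter
component. The kernel is gamma-shaped, A·x^a·e^{a(1−x)} with x the time
since onset latency rescaled by the rise time: zero until 0.8 s after the
event, peaking (0.30 mm) at 2.0 s, shape a = 6; its steepest-rise lag —
the moment the velocity-peak detector should find — has the closed form
onset + rise·(1 − 1/√a).

Two generator choices deserve emphasis because they are *not* neutral:

* **The error model is not white Gaussian.** Any Gaussian-dominated speed
  distribution places ~5% of its mass beyond median + 3×MAD regardless of
  scale, so white sensor noise at 200 Hz would make the speed filter flag
  ~5% of perfectly clean samples by construction. Physiological pupil
  signals are smooth and pupillometers average many pixels per estimate;
  the residual sample-level jitter is modelled as a bounded narrowband
  oscillation (two components near 72 and 90 Hz, 2.5 mm/s total speed
  amplitude, ≈4 µm in diameter) — frequencies the Savitzky-Golay smoother
  attenuates strongly, so the jitter widens the raw speed distribution the
  MAD filter sees without contaminating the smoothed derivative the peak
  detector sees. This gives the filter the compact, bounded background its
  design presumes while planted spikes (0.30 mm in one sample ≈ 60 mm/s)
  remain unmistakable.
* **Dilation events are sparse and refractory.** Events arrive as hardcore
  Poisson (rate 0.10/s, minimum separation 2.0 s). Real recordings show
  ~9 detected velocity peaks per 30-s phase, but that figure is detector
  output on continuous fluctuation, not a count of discrete generating
  events; planting events that densely would make many of them unrecoverable
  in principle past the 1500-ms non-maximal suppression. The generator
  favours unambiguous ground truth over reproducing the observed peak count.

**Artifacts.** Missing gaps (0.02/s, 80–300 ms) and single-sample spikes
(0.02/s, ±0.30 mm) are planted at known locations, avoiding existing invalid
spans so that every recorded artifact alters at least one sample. Blink
spans additionally invalidate trace samples, as the device does.

**Fixations/saccades.** Alternating renewal tilings per phase; log-normal
fixation durations with per-phase means (baseline 2500 ms on the fixation
cross; audio 800 ms, silence 850 ms of exploratory mutual-gaze fixations),
30-ms saccades.

**Determinism.** Identical (config, seed) reproduces byte-identical output;
cohorts derive per-dyad seeds from one master seed via seed sequences.

## What the synthetic validation shows — and does not

The validation experiments (also recomputed by `scripts/acceptance.py`)
establish that: the sync estimator is calibrated to the Poisson chance level
within Monte-Carlo error; planted per-phase coupling ordering
(baseline > silence > audio) is recovered in ≥95% of 24-dyad cohorts;
planted artifacts are caught (≥95%) with <1% collateral invalidation of
clean samples; planted dilation events are recovered (recall ≥0.9, ≤0.1
false peaks per 30-s phase at SNR 10) with the NMS guarantee holding
exhaustively; and the R² decomposition recovers known generating components
within ±0.05. Problem sizes: 600-s trains for chance calibration, 90-s
trials for artifact/peak recovery (50/100 seeds), 200 cohorts for ordering,
100 replicates of 24 dyads for the mixed model.

These are *internal-consistency* results under the generator's assumptions.
Real recordings differ in ways the generator does not emulate: non-Poisson
blink dynamics (listening-related suppression/rebound), non-stationary pupil
baselines and arousal drift, correlated artifact bursts, gaze-dependent
pupil foreshortening, and any true emotional-context effects (none are
planted; the original study also found none). Passing these tests shows the
pipeline measures what it claims on data with known structure — not that
real dyads satisfy the generator's assumptions.

## Degenerate inputs and numerical details

* Readers never repair data: non-monotone timestamps and inverted/overlapping
  events are errors; empty event tables are valid (warning).
* Interpolation spans without a valid anchor on a side are invalidated.
* A flat trace has MAD = 0: the speed filter flags nothing (logged).
* Fewer valid samples than the smoothing window is an explicit
  insufficient-data error; an all-missing segment yields an empty peak train.
* Tukey p-values use the studentized-range distribution; with two levels
  they reduce to the unadjusted t-test p.
* Satterthwaite gradients/Hessians use central finite differences on the
  variance scale with relative steps (1e−5/1e−4), clamped at the parameter
  boundary; degenerate cases fall back to residual df.
* Timestamps are seconds (float64, µs precision on disk); durations are
  reported in ms.
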