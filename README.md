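# dyadsync

Analysis pipeline for **dual eye-tracking of interacting dyads**: pupillometry
preprocessing, pupil dilation-velocity peak detection, per-phase
fixation/blink metrics, windowed interpersonal synchronization statistics for
blinks and pupil peaks, and linear mixed-effects inference with variance
decomposition. A synthetic dyad generator with known ground truth makes every
stage testable end-to-end without data downloads.

It is written for researchers studying interpersonal coordination with
wearable eye trackers (200 Hz pupil/event exports) in designs where two
participants hold asymmetric roles — a *listener* exposed to audio stimuli
and an *observer* inferring the listener's state from eye cues — across
trials of three consecutive 30-s phases (baseline / audio / silence) in three
emotional contexts (neutral / negative / positive).

## What it computes

**Preprocessing.** Blink spans are linearly reconstructed (−100 ms to
+150 ms around each blink), saccades with a ±75 ms buffer; dilation-speed
outliers beyond median + 3×MAD are removed; 50 ms is trimmed around data
gaps > 75 ms; valid islands < 50 ms flanked by gaps > 40 ms are discarded;
phases with > 30% missing data are flagged for exclusion.

**Dilation-velocity peaks.** The cleaned trace is interpolated, smoothed
with a Savitzky-Golay filter (window 11, order 3) and differentiated; strict
local maxima of the derivative exceeding mean + 2.5 SD are kept, with
1500-ms non-maximal suppression. Peak times mark the moments of fastest
dilation.

**Synchrony.** For each reference event onset (listener blink, or listener
pupil peak) the nearest test event (observer) gives a signed lag
*t*<sub>test</sub> − *t*<sub>ref</sub>; the synchronization percentage of a
dyad × trial × phase cell is

&nbsp;&nbsp;&nbsp;&nbsp;sync% = 100 · #{ref events with |lag| ≤ *w*} / #{ref events},

with *w* = 1.5 s for blinks and 2.5 s for pupil peaks. Against an
independent Poisson test train of rate λ the expected value is the chance
level 100·(1 − e^(−2wλ)).

**Inference.** Synchrony is modelled as `sync ~ phase * context + (1 | dyad)`
by REML, with Satterthwaite-df F-tests, Tukey-adjusted pairwise phase
contrasts on estimated marginal means, and the variance decomposition
R²<sub>marginal</sub> = σ²<sub>f</sub>/(σ²<sub>f</sub>+σ²<sub>dyad</sub>+σ²<sub>res</sub>),
R²<sub>conditional</sub> = (σ²<sub>f</sub>+σ²<sub>dyad</sub>)/(σ²<sub>f</sub>+σ²<sub>dyad</sub>+σ²<sub>res</sub>).

See `docs/methods.md` for models, parameter defaults, and design decisions.

## Worked example

Generate a 24-dyad synthetic cohort (per-phase blink coupling baseline 0.40,
audio 0.10, silence 0.25, plus dyad-level heterogeneity), compute blink
synchrony and fit the mixed model:

```python
import dataclasses
from dyadsync import (SyncConfig, SyntheticConfig, assemble_dyad,
                      dyad_sync_table, fit_sync_lmm, sync_results_to_frame)
from dyadsync.cli_pipeline import blink_onset_times, derive_seed

dyads = [assemble_dyad(dataclasses.replace(SyntheticConfig(), seed=derive_seed(7, i)),
                       dyad_id=f"dyad{i+1:02d}")[0] for i in range(24)]
frame = sync_results_to_frame(
    dyad_sync_table(dyads, blink_onset_times(dyads), SyncConfig(modality="blink")))
print(frame.groupby("phase")["sync_pct"].mean().round(1))

result = fit_sync_lmm(frame)
print(result.anova.round(3).to_string(index=False))
print(f"marginal R2 = {result.r2_marginal:.3f}, conditional R2 = {result.r2_conditional:.3f}")
print(result.contrasts[["pair", "estimate", "df", "p_tukey"]].round(3).to_string(index=False))
```

Output:

```
phase
audio       58.1
baseline    70.7
silence     68.6
Name: sync_pct, dtype: float64
         term     F  num_df  den_df     p
        phase 6.747       2 183.010 0.001
      context 0.014       2 183.010 0.986
phase:context 0.585       4 183.009 0.674
marginal R2 = 0.059, conditional R2 = 0.196
              pair  estimate      df  p_tukey
  audio - baseline   -12.620 182.921    0.002
   audio - silence   -10.632 183.054    0.013
baseline - silence     1.988 183.054    0.854
```

Reading it: mean blink synchrony is highest at baseline (70.7%), drops during
audio (58.1%) when the partners' attentional goals diverge, and partially
recovers in silence (68.6%) — the ordering planted by the generator's
per-phase coupling. The phase effect is significant (F(2, 183) = 6.75,
p = .001) with the audio−baseline contrast at −12.6 points (Tukey p = .002),
while emotional context (not planted) shows nothing. Fixed effects explain
5.9% of variance; dyad identity raises that to 19.6% — the between-pair
heterogeneity the generator plants. The 216 cells (24 dyads × 3 trials ×
3 phases, one cell missing because a listener produced no blinks in a phase)
give the F-test ≈ 183 denominator df under the Satterthwaite approximation.

The same pipeline runs from the shell:

```bash
dyadsync run-all --seed 7 --n-dyads 24 --out run/
# run/: raw/ clean/ peaks.csv metrics.csv sync_blink.csv sync_pupil.csv
#       stats_blink.txt stats_pupil.txt sync_correlation.csv manifest.json
```

Real exports are ingested with the same readers (`read_pupil_trace`,
`read_events`, `read_schedule`); a column-name dialect maps vendor headers,
e.g. `PUPIL_LABS_NEON_DIALECT` for Pupil Labs Neon-style tables.

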