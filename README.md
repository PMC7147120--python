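# envdecode

Reconstruction of the temporal speech envelope from multichannel scalp EEG
with a backward temporal-response-function (TRF) decoder — the standard
"stimulus reconstruction" measure of cortical entrainment to running speech
— together with a time-reversed-envelope chance model, nonparametric group
statistics, and a forward-model synthetic-data generator with known ground
truth.

## Who this is for

Auditory-neuroscience and hearing-research groups who record EEG while a
subject listens to continuous speech (e.g. an audiobook, with or without a
hearing aid) and want to quantify how strongly the slow cortical activity
tracks the speech envelope, detect whether a response is present at all in a
single subject, and compare tracking strength across conditions, frequency
bands and behavioural scores.

## The model

The speech envelope is the magnitude of the analytic signal of the audio
waveform, `y(t) = |x_a(t)|` with `x_a = x + i H{x}` (Hilbert transform).
Both EEG and envelope are band-pass filtered with the same zero-phase
Hamming-window FIR specification (delta 1–4 Hz, theta 4–8 Hz, wideband
1–20 Hz), the EEG is average-referenced, and both are downsampled to 64 Hz.

The backward decoder estimates the envelope at time `t_n` as a linear
combination of all `N` channels at lags `τ_k` spanning −100…+400 ms:

    ŷ(t_n) = Σ_j Σ_k  β_{j,k} · x_j(t_n + τ_k)

Stacking the lagged channel copies gives the design matrix `X` with `N·T`
columns, and the weights solve ridge-regularized normal equations

    β = (XᵗX + λI)⁻¹ Xᵗy .

Performance is evaluated with five-fold cross-validation: 80 % of the
recording estimates β, the held-out 20 % is reconstructed, and the Pearson
correlation between `ŷ` and `y` is computed on non-overlapping 10-second
segments.  The penalty λ is selected from a 50-point grid (10⁻¹⁵…10¹⁵) by
maximizing the correlation averaged over all testing folds and segments; the
segment correlations at the optimum, pooled across folds, form the subject's
performance distribution.  Chance level comes from running the *identical*
pipeline — same folds, same λ optimization — against the time-reversed
envelope; forward and null distributions are compared with a two-sided
Wilcoxon signed-rank test.

Group-level comparisons (aided vs unaided conditions, ratio-vs-1 tests,
dispersion, presentation-order sign test, band–band and brain–behaviour
associations via Tukey-bisquare robust regression) are rank-based, with
Benjamini–Yekutieli FDR adjustment (uncapped, so adjusted p-values may
exceed 1).

## Worked example

A synthetic subject whose EEG is the envelope convolved with a known
cortical response kernel plus 1/f noise at −10 dB SNR:

```python
import numpy as np
from envdecode import (AnalysisConfig, BANDS, evaluate_subject,
                       gen_envelope, gen_kernel, gen_eeg, preprocess_band)

env = gen_envelope(duration=300.0, fs=2048.0, seed=1)
kernel = gen_kernel(n_channels=32, fs=2048.0, seed=2)
eeg = gen_eeg(env, kernel, snr_db=-10.0, seed=3,
              subject_id="S01", condition="aided")

band = BANDS["delta"]
eeg64 = preprocess_band(eeg, band)
env64 = preprocess_band(env, band)

cfg = AnalysisConfig(lambda_grid=np.logspace(-3, 7, 10))
detection = evaluate_subject(eeg64, env64, cfg)
print(detection.summary())
```

which prints

```
Cortical response detection
==========================================
forward mean r: 0.9539 (lambda 27.8256)
null mean r:    0.0585 (lambda 1e+07)
Wilcoxon p:     1.86e-09
significant at alpha=0.05: True
```

The forward decoder reconstructs the delta-band envelope at a mean segment
correlation of 0.95 (a nearly noiseless regime in this band — in-band SNR is
much higher than the broadband −10 dB), the time-reversed null sits at
chance (0.06), and the signed-rank comparison of the 30 paired segment
correlations detects the response decisively.  Real-EEG correlations are far
smaller (typically 0.05–0.3) but the detection logic is identical.

An object-oriented surface wraps the same pipeline: build an
`EnvelopeDecoder(eeg64, env64, cfg)` model, call `.fit(lam)` for a
single-penalty fit (returns a results object with the channels × lags
weight matrix and a `summary()`), `.fit_cv()` for the cross-validated
penalty sweep, or `.evaluate()` for the full forward-vs-null detection.

A command-line interface covers the file-based workflow: `envdecode
simulate` writes a synthetic cohort as EDF + WAV fixtures, `envdecode
decode` / `nulls` evaluate one recording against the forward or
time-reversed envelope, and `envdecode stats` / `report` build the group
tables.

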