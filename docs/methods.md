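# Methods

## Signal model and assumptions

The package treats cortical entrainment as a linear systems problem: the
slow cortical response is assumed to be a causal linear functional of the
speech envelope, so the envelope can in turn be estimated from the EEG by a
linear backward decoder over a window of lags.  Everything else —
band-limiting, referencing, rate reduction, cross-validation, the
time-reversed chance model — exists to make that estimate stable and its
significance testable.  The decoder is purely discriminative: no claim is
made about sources or physiology, only about mutual linear predictability
between envelope and EEG in a given frequency band.

## Preprocessing

* **Bands.** Delta 1–4 Hz (transition bandwidths 1 Hz below, 2 Hz above),
  theta 4–8 Hz (2/2 Hz), wideband 1–20 Hz (1/5 Hz).
* **Filter design.** Hamming-window band-pass FIR, tap count
  `N = round(3.3 / min(tbw) · fs)` bumped to the next odd integer (3.3 is
  the Hamming transition-width factor; the odd length gives an integer group
  delay).  At 2048 Hz this yields 6759 taps for a 1 Hz minimum transition
  and 3379 for 2 Hz.  The −6 dB cutoffs sit half a transition band outside
  the corner frequencies, so the passband reaches the corners at full gain.
  The tap sum is nulled exactly (`c −= mean(c)`), which turns the ~−50 dB
  window floor at 0 Hz into exact DC rejection at a passband perturbation of
  order 10⁻⁵.
* **Application.** One-pass forward convolution compensated by the integer
  group delay; edges are zero-padded rather than trimmed so EEG and envelope
  stay time-aligned sample for sample.  The first and last `(N−1)/2` samples
  are therefore edge-contaminated; at the recording lengths used here this
  region is a negligible fraction of the data and is retained.
* **Referencing.** Per-sample mean over all electrodes subtracted from every
  electrode (average reference), applied to EEG only.
* **Resampling.** Polyphase anti-aliased resampling to the 64 Hz working
  rate (`scipy.signal.resample_poly`, mean-padded edges so constant signals
  pass through unchanged).  The band filters already suppress everything
  above 25 Hz, so the resampler's own low-pass is defence in depth.
* **Envelope.** Magnitude of the analytic signal at the native audio rate,
  then the same band filter (designed at that rate) and the same resampling.
  A config switch (`envelope_decimate_first`) interposes a 2048 Hz
  decimation stage before filtering for pipelines that prefer to match the
  EEG rate first; the default filters at the native rate because envelope
  and EEG are then guaranteed to traverse one identical specification.

## Decoder and evaluation

* **Lags.** −100…+400 ms at 64 Hz, rounded to integer sample lags −6…26
  (T = 33).  With 32 channels the design matrix has 1056 columns.  Rows
  whose lags would reach outside the recording are zero-filled and flagged;
  they are kept in training by default (`valid_rows_only` restricts to fully
  valid rows).
* **Ridge fit.** Design columns and target are mean-centred before solving
  `(XᵗX + λI)β = Xᵗy` by Cholesky factorization (with a least-squares
  fallback if a factorization fails at extreme λ); the offset is restored at
  prediction.  Centring has no modelling content — band-passed signals are
  already near zero-mean — but it removes the undefined intercept from the
  closed form.  A single λ is shared by all columns; no per-column scaling.
* **Cross-validation.** Five contiguous test blocks tile the recording
  (sizes within one sample).  Contiguous geometry mirrors the segment
  structure of a continuous stimulus and keeps train/test leakage limited to
  the 33-sample lag spillover at the two block boundaries; a
  `trim_fold_margins` flag removes 0.5 s margins for a strict reading.  For
  each fold and each λ the decoder is fitted on the training blocks and
  scored on the held-out block in non-overlapping 10-second segments
  (Pearson r per segment; a zero-variance segment scores r = 0 with a
  warning so cardinalities stay fixed).
* **Penalty selection.** λ* maximizes the grand mean over all testing folds
  and segments; ties break toward the smaller λ.  Selecting on test-fold
  correlations mildly flatters absolute performance, but the chance model
  receives the identical optimization, so forward-vs-null comparisons are
  fair.
* **Chance model.** The envelope's sample order is inverted at the 64 Hz
  working rate (reversal and linear-phase filtering commute up to edge
  effects; `reverse_raw_audio` reverses before preprocessing instead) and
  the whole pipeline — folds, sweep, selection — is repeated.  Forward and
  null segment correlations are paired by temporal index and compared with
  a two-sided Wilcoxon signed-rank test; a subject counts as detected when
  p < α *and* the forward median exceeds the null median.
* **Shared factorizations.** The training Gram matrix depends only on the
  EEG, so the forward and time-reversed evaluations share one Cholesky
  factorization per (fold, λ); `evaluate_subject` exploits this and is
  verified against the two separate runs.

## Group statistics

* Paired aided/unaided contrasts use the Wilcoxon signed-rank test.  With up
  to 16 nonzero differences the two-sided p-value is computed by exact
  enumeration of all sign patterns with average ranks — the classical null
  tables assume distinct ranks and scipy falls back to a normal
  approximation under ties, which is too coarse for cohort-sized samples.
* The aided/unaided ratio test applies the same statistic to `ratio − 1`.
* The dispersion comparison runs Kruskal–Wallis on absolute deviations from
  each group's median (a rank-based Brown–Forsythe analogue); `raw=True`
  gives the literal location-sensitive reading.  Both are provided because a
  rank location test applied to raw values does not measure spread.
* Presentation-order effects use an exact binomial sign test, ties dropped.
* Brain–behaviour and band–band associations are fitted by iteratively
  reweighted least squares with the Tukey bisquare ψ (tuning constant 4.685,
  MAD scale).  The slope p-value references a t distribution with n − 2
  degrees of freedom; the large-sample z test is noticeably liberal at
  n ≈ 15 (measured size ≈ 0.10 at nominal 0.05) and inflates the adjusted
  family error.  The raw Pearson r is reported descriptively alongside.
* Multiplicity is controlled per analysis family (e.g. the nine band-pair
  tests across two conditions plus ratios form one family) with the
  Benjamini–Yekutieli step-up adjustment, valid under arbitrary dependence.
  Adjusted values are deliberately **not** capped at 1: the uncapped step-up
  form preserves monotonicity and values above 1 simply mean "not
  significant at any level".

## Synthetic data

The generator emulates a listening study — 17 subjects, one shared ~25-min
stimulus presented as 8 segments, aided and unaided recordings per subject —
using exactly the components the analysis assumes, so decoder misfit on
synthetic data isolates implementation error:

* **Envelope.** Jittered syllabic pulse train at 4 Hz (gamma inter-pulse
  intervals, shape 50 ≈ 14 % jitter; lognormal stress amplitudes) convolved
  with a 50 ms-rise / ~150 ms-decay gamma burst, under a ~0.5 Hz narrowband
  sentence-rate amplitude modulation of depth 0.2 whose drifting phase
  spreads its spectral line.  The modulation-spectrum argmax falls in the
  3–5 Hz syllabic range by construction.
* **Cortical kernel.** Causal difference-of-Gaussians time course (positive
  peak ≈ 100 ms, negative ≈ 200 ms) scaled by a dipolar
  frontocentral-positive / occipital-negative topography on the standard
  32-channel montage (with a small seeded perturbation), unit total energy.
  The dipolar pattern matters: a same-sign topography would be removed by
  the average reference.
* **EEG.** Envelope ⊛ kernel plus per-channel 1/f (pink) noise scaled so the
  realized per-channel SNR equals the request exactly.  The quoted SNR is
  broadband; after band-filtering the effective in-band SNR is substantially
  higher, which is why −10 dB subjects decode at r ≈ 0.9 while real-EEG
  correlations are an order of magnitude smaller.
* **Behaviour.** Expected accuracy logistic in SNR (midpoint −25 dB, scale
  5 dB) with beta-distributed observations (κ = 60); multiple-choice scores
  get a 0.25 guessing floor.  The audible regime saturates near ceiling.
* **Audio fixtures.** The envelope amplitude-modulates a 1 kHz carrier, so
  the analytic-signal magnitude of the written WAV recovers the ground
  truth; an optional 120th-order 3 kHz low-pass reproduces the presentation
  chain of the emulated design (a playback step, never part of analysis).

Not emulated: real speech acoustics, hearing-aid compression, EEG artifacts
(blinks, line noise), inter-subject latency differences, or nonlinear
cortical responses.  Passing tests therefore demonstrate correctness of the
pipeline under its own assumptions, not performance on real recordings.

## Problem sizes used by the test suite

Simulation-backed checks run at reduced scales chosen to keep the suite
fast while leaving the tested property comfortably identified:

* Single-subject detection: the canonical 25 min / 32 channels / 2048 Hz at
  −10 dB with a 10-point λ grid (the sweep extremes add nothing to a
  detection decision).
* False-positive control: 20 envelope-independent pink-noise subjects,
  10 min each, 32 channels synthesized at 512 Hz, 5-point grid; detections
  at α = 0.05 must stay within the exact binomial 95 % band (≤ 4 of 20).
* Group null regime: 20 replicate 10-subject cohorts with equal aided and
  unaided SNR, 120 s / 8 channels / 256 Hz recordings; the paired
  signed-rank test must be non-significant in ≥ 18 of 20 cohorts.
* Unit-level end-to-end checks use 100–600 s, 8-channel subjects at 512 Hz.

## Numerical choices and edge cases

* Lag-to-sample conversion uses round-to-nearest (−6.4 → −6, 25.6 → 26).
* EDF output quantizes to 16 bits over a per-channel symmetric physical
  range padded by 0.1 % and printed to 6 significant digits; round-trip
  error is bounded by half a quantization step of that printed range.  The
  writer uses 1 s records (zero-padding a final partial second) and a fixed
  epoch start date so identical data give byte-identical files.
* WAV uses 16-bit PCM with 32768-based scaling on both write and read.
* All generators accept seeds or `numpy` Generators; cohort generation
  derives per-subject streams from one `SeedSequence`, so cohorts are
  reproducible and presentation order is balanced to within one subject.
* Degenerate inputs fail loudly: empty waveforms, recordings shorter than
  the lag span, folds without a complete scoring segment, zero x-variance in
  regression, λ < 0, or a singular system at λ = 0 (with advice to
  regularize).

## Known limitations

* The evaluation assumes one contiguous recording per condition; pausing or
  concatenating sessions would require fold boundaries at session edges.
* Penalty selection on test folds means pooled correlations are not an
  unbiased estimate of out-of-sample performance; they are comparable
  between forward and null runs, which is what detection uses.
* The EDF writer covers the continuous 16-bit subset only (no annotations,
  no variable record layouts); reading arbitrary third-party EDFs relies on
  MNE.
* With long-memory (1/f) noise and very short recordings, contiguous-fold
  cross-validation leaks a small positive bias into null correlations
  (boundary adjacency); at the 10-minute-plus scales used for inference the
  effect is well inside the chance band.
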