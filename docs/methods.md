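# Methods

## Synthetic cohort model

Each subject's 16-channel recording is a sum of three components, all
in microvolts:

1. **1/f background** — white noise spectrally shaped to a
   |H(f)|² ∝ f^(−`noise_exponent`) profile, band-limited 0.5–30 Hz
   (matching a typical clinical recording filter), rescaled per channel
   to `noise_scale` (default 8 µV s.d., exponent 1.0).
2. **Band oscillators** — per band and channel, cos(θ(t)) with
   θ(t) = 2πf·t + φ₀ + W(t). The frequency f is drawn per oscillator
   from the central half of its band, so uncoupled channels have
   distinct frequencies and their phase difference sweeps through many
   cycles within a 4 s epoch — without this, same-frequency oscillators
   with slowly drifting phases stay spuriously locked and every channel
   pair shows high PLI. W(t) is a Gaussian random walk whose per-sample
   step s.d. is the `irregularity` knob: it broadens the line and
   raises fuzzy entropy monotonically while leaving total band power
   unchanged (the oscillator amplitude is fixed). Amplitudes are
   `band_amp[group][band]` × a per-subject lognormal factor
   (σ = `amp_sigma`, default 0.2) drawn **per (band, channel)**.
   Drawing the factor per channel rather than once per band is
   deliberate: a shared factor makes all 16 channel tests of a band
   rise and fall together, so a single unlucky cohort flips the whole
   band's significance map at once; per-channel factors make the
   channel tests approximately independent under the null.
3. **Coupling** — a `CouplingSpec` names a channel pair, band, constant
   phase lag and per-group mixing strength s ∈ [0,1]; the two channels'
   band component becomes (1−s)·own + s·shared, the shared oscillator
   entering the second channel with the lag. s = 1 with zero noise
   gives PLI = 1 exactly; s = 0 leaves the channels independent. A
   channel may appear in at most one spec per band (the mixture would
   otherwise be ambiguous).

Seeding: one root seed; per-subject streams derive from
`SeedSequence(root, spawn_key=(group_index, subject_index))`, so
generation is order-independent and any subject can be regenerated in
isolation.

What the generator does **not** emulate: artifacts (blinks, EMG, line
noise), non-stationarity beyond phase drift, volume conduction
(zero-lag mixing), realistic cross-channel covariance, or clinical
covariates. Recovery tests passing therefore validates the estimators
and inference machinery against known ground truth; it says nothing
about real patient contrasts.

## Preprocessing choices

- All filters are fourth-order Butterworth applied forward–backward
  (`sosfiltfilt`). Only the design order is conventionally reported;
  zero-phase application was chosen because causal phase distortion
  would corrupt instantaneous-phase estimates. The effective magnitude
  response is the squared design response.
- Decimation uses an eighth-order zero-phase low-pass at 0.8× the
  target Nyquist (50 Hz for 125 Hz), leaving 4–30 Hz untouched.
- Rhythm extraction filters **per epoch** (each 4 s segment on its
  own), accepting short edge transients on 500-sample epochs; adjacent
  band edges (8, 13 Hz) overlap only through the filters' natural
  roll-off.
- Epoch grid: starts at 0, `step` spacing, full windows only —
  ⌊(T−window)/step⌋+1 epochs.

## Estimator conventions

- **Periodogram**: rectangular window, one-sided, interior bins
  doubled so the bin sum equals Σx² (Parseval). No Welch averaging by
  default — the per-epoch spectrum is already short.
- **Band power**: trapezoidal integral over [f_l, f_h] with
  interpolated endpoints, divided by the bandwidth; a flat spectrum of
  height c yields c for any band.
- **Fuzzy entropy**: N−m mean-removed delay vectors for both m and
  m+1 (the textbook index bookkeeping is inconsistent between the two
  embedding dimensions; a single consistent count is used), Chebyshev
  distance, similarity exp(−ln2·(d/r)²), self-matches excluded.
  Defaults m = 2, r = 0.2× the epoch s.d. (`r_mode="absolute"` gives r
  in signal units). A zero-variance epoch returns FE = 0 by convention
  (all delay vectors coincide). These (m, r) defaults are the common
  choice for 500-sample biosignal epochs; both are exposed and
  serialized into output metadata.
- **PLI**: |mean(sign(Δφ))| with Δφ wrapped to (−π, π] and sign(0)=0.
  A bare difference of `angle` outputs crosses ±2π and flips sign
  spuriously; wrapping first is essential. 10% of samples are trimmed
  at each end (Hilbert edge effects; `edge_trim` configurable).
  Phases are computed on the band-limited epoch — instantaneous phase
  is only meaningful for narrowband signals.

## Statistics

- Two-group one-way ANOVA per feature (F = squared pooled t, df 1 and
  n_A+n_B−2); significance at p < α (default 0.05) with **no**
  multiple-testing correction by default, mirroring common practice in
  this literature; a Benjamini–Hochberg switch (`fdr=True`) is
  provided. With 120 pairs per band, the uncorrected expected false
  edge count is 6 per band at α = 0.05 — the FDR switch is the right
  tool when the edge *list* matters rather than the ratio pattern.
- Statistical unit: `epoch` treats every segment as an observation.
  Epochs of one subject are correlated (shared subject amplitudes),
  so epoch-level type-I error is calibrated only when rows are
  exchangeable; the unit tests verify calibration on exchangeable rows
  and use subject-level means (`unit="subject"`, one observation per
  subject — exact under the generative model) for cohort-level
  recovery checks.
- Differential-network ratios are formatted "B-higher/A-higher"
  (second group first).

## Classification protocol

- Stratified five-fold CV, repeated (default 10; repeat seeds derived
  from the report seed), metrics from confusion counts pooled over the
  five test folds of a repeat, mean ± sd over repeats, reported in
  percent. Positive class = second group label. A zero-denominator
  metric is NaN, never silently 0.
- `split_unit="epoch"` uses `StratifiedKFold` on rows;
  `split_unit="subject"` uses `StratifiedGroupKFold` so no subject
  straddles a fold (asserted structurally). Epoch-level splits let
  models recognise subjects rather than groups — per-subject amplitude
  factors are enough to push uninformative feature sets far above
  chance — so all qualitative model-comparison tests run at subject
  level.
- Models use library-default hyperparameters (none are tuned), pinned
  to single-thread, seeded per repeat; LightGBM runs with
  `deterministic=True`.

## Scaled-down study conditions

The full protocol (38+34 subjects × 600 s, 10 CV repeats) is the
package default (`pipeline.full_protocol()`), but tests and the
analysis drivers run desk-scale conditions chosen once: recovery
cohorts 10+10 subjects × 60 s (29 epochs/subject), the
connectivity-only classification cohort 8+8 × 60 s, CV grids at 2–3
repeats. At these sizes the injected effects (2× beta amplitude,
0.1 → 0.8 coupling strength) are comfortably detectable at subject
level while the whole suite stays in the minutes range.

## Known limitations

- EDF files can be read (via mne) but not written; the native cohort
  format is a delimited text matrix per subject plus a manifest CSV.
- Epoch-level inference is reported because it mirrors segment-level
  protocols in the literature, but it is anticonservative under any
  within-subject correlation; treat those columns as descriptive.
- The fuzzy-entropy irregularity contrast is only detectable when the
  band oscillator dominates the band-limited background (band SNR ≳ 1);
  at the default noise level the knob's effect on FE is real but small.
- LightGBM determinism holds single-threaded with
  `deterministic=True`; cross-platform bit-identity is not guaranteed
  for any of the boosted models.
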