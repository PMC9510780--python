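# Methods

This note documents the models, defaults, and numerical choices behind
`doa_ecog`, and what the synthetic-data experiments do and do not demonstrate.

## Synthetic ECoG generator

The generator (`doa_ecog.synthetic_data`) produces two-channel recordings
whose statistical structure carries the anesthetic modulations the analysis
assumes, with a known hidden depth trace. It is a phenomenological signal
model, not a biophysical neural-mass model.

**Hidden depth.** Administered concentration *c* (percent isoflurane) maps to
depth d = clip((c − 0.8)/(2.5 − 0.8), 0, 1). Any monotone map would do; the
linear clipped form keeps the mean concentration-given-depth relation locally
linear, which is the regime in which estimating administered concentration
approximates estimating depth itself. Segment transitions are optionally
smoothed by a first-order exponential approach (default time constant 60 s;
the shortened test cohorts use 20 s to match their shortened segments).

**Signal composition.** Each channel is

    gate · (oscillation + 1/f noise) + slow waves + 50 Hz line + evoked kernels

- *Shared oscillation (coherence mechanism).* White noise band-passed to
  5–40 Hz enters both channels as √ρ(d)·shared + √(1−ρ(d))·independent, scaled
  to 30 μV RMS. ρ(d) rises linearly from 0.15 to 0.85, so 5–40 Hz
  magnitude-squared coherence increases with depth (for equal in-band spectra
  the asymptotic coherence of the oscillatory part is ρ²; broadband noise
  dilutes it, but monotonicity in ρ is preserved).
- *Background.* Independent per-channel noise spectrally shaped to
  power ∝ f^(−2) (exponent configurable), 15 μV RMS.
- *Burst suppression.* An alternating-exponential (semi-Markov) renewal gate:
  mean burst ("on") duration 3 s at all depths; mean suppression ("off")
  duration 6·d s, evaluated at the depth when the interval starts. During
  suppression the fast components are scaled to 5 %. Suppression is applied
  identically to both channels (bursts are bilateral).
- *Slow waves (spectral slowing).* Per-channel delta-band (0.5–3 Hz) waves
  with RMS 60·d μV. During suppression a small fixed slow residual (8 μV)
  persists instead: physiological suppression is quasi-isoelectric with slow
  drifts, not a scaled replica of the burst signal. This matters for the
  scale-invariant complexity features — without it, a fully suppressed window
  is statistically identical to a burst window after normalization, and
  sample entropy/LZC would not fall at depth.
- *Line noise.* A 10 μV, 50 Hz sinusoid, never gated (mains contamination is
  independent of brain state).
- *Evoked responses.* Whisker stimuli arrive as 1 Hz trains gated by 2 s
  on/off periods; each evokes a damped half-sine kernel (25 ms latency, 40 ms
  width) of amplitude 120·(1 − 0.6·d) μV on the contralateral channel (40 %
  of that ipsilaterally). Kernels are added after the burst gate so the
  evoked-response-attenuation (ERA) target retains its closed form
  ERA(d) ≈ (1 − s·d)/(1 − s·d₁.₀) with attenuation slope s.

Mechanism toggles (`modulate_coherence/bursts/slow/evoked`) isolate single
mechanisms, e.g. coherence-only cohorts for importance-recovery checks, or a
fully unmodulated null.

The stimulus waveform itself is a single-cycle raised cosine
x(t) = A/2·(1 − cos 2πft) (default 300 μm at 120 Hz → 8.3 ms duration, peak
velocity A·π·f ≈ 113.1 mm/s); only its onset times and evoked amplitude
scaling matter to the analysis.

## Preprocessing

Zero-phase (forward-backward) filters: IIR notch at 50 Hz with Q = 30, then a
first-order Butterworth high-pass at 0.1 Hz. Both are zero-phase, so the
order is immaterial; it is fixed for reproducibility. The high-pass is padded
to ≈3 filter time constants before forward-backward application — the library
default pad of a few samples is far shorter than the 0.1 Hz filter's ~1.6 s
time constant and leaves visible edge transients. Filtered traces are assumed
input-referred (amplifier gain already removed); the loader rejects data not
flagged as such.

Blocks discard the first 5 min of each protocol segment (anesthetic
transient; configurable). Windows are consecutive, non-overlapping, 10 s;
a trailing remainder shorter than one window is dropped so all windows are
identically sized. Windowing is per block, never across block boundaries.

## Features

- **Welch PSD**: 2 s Hann segments, 50 % overlap → 0.5 Hz resolution, nine
  segments per 10 s window. Density scaling (integral ≈ variance).
- **SEF95**: smallest grid frequency whose cumulative power fraction reaches
  0.95. NaN on zero total power.
- **1/f slope**: least-squares slope of log₁₀ power vs log₁₀ frequency over
  20–40 Hz; NaN if any in-band power is nonpositive.
- **Band powers**: trapezoidal integrals; γ is capped at 45 Hz because the
  50 Hz notch and 125 Hz Nyquist make that the highest clean edge of the
  open-ended ">30 Hz" band.
- **Coherence**: magnitude-squared coherence on the Welch grid, arithmetic
  mean over 5–40 Hz bins (no Fisher-z transform). With nine segments the
  estimator bias for truly independent channels is ≈1/9. A single-segment
  estimate is identically 1 and is rejected. Computed on preprocessed traces
  by default.
- **Sample entropy**: the 80 ms template span fixes the embedding at
  m = 2 with lag = 10 samples at 250 Hz (templates (x[i], x[i+10]), extended
  by x[i+20] for order m+1); tolerance r = 0.2 × window SD, Chebyshev
  distance, self-matches excluded. Matching is exact counting via a k-d tree;
  unit tests pin it to a naive O(n²) double loop to 1e-12. Returns NaN when
  undefined (no matches, or r = 0 on a constant window).
- **LZ76 complexity**: exhaustive-history parsing — each new word is the
  shortest prefix of the remainder not reproducible from the extended
  history; the final (possibly reproducible) word counts as one. Binarization
  thresholds at the parent *block* median, not the window median. Word count
  C is normalized as C·log₂(n)/n so values are window-length invariant
  (fair-coin sequences ≈ 1). The implementation parses with C-level substring
  search and is pinned exactly to a naive reference parser.
- **Burst detection**: moving-RMS envelope (50 ms); samples at or below
  0.2 × the block's 90th-percentile envelope are suppression; off-runs
  shorter than 100 ms merge into the surrounding bursts. Detection thresholds
  are configuration, validated against the generator's known gate. BSR and
  mean on/off durations are computed per block per channel and replicated
  onto the block's windows (matching the one-row-per-window dataset
  structure).

Undefined feature values propagate as NaN, never as silent zeros.

## Evoked responses and ERA

Peri-stimulus trials span [−0.2, +0.5] s around each onset (contralateral
channel), baseline-corrected by the pre-stimulus mean; onsets too close to
the edges are skipped and counted. The per-trial amplitude is the maximum
absolute post-stimulus deflection (polarity-agnostic, since the source data's
polarity convention is not fixed). ERA is a trailing moving average over 10
stimuli of these amplitudes, divided by the animal's mean amplitude over
stimuli inside its 1.0 % blocks (stimuli in discarded segment heads are
excluded from the reference, consistent with block exclusion). ERA is
resampled onto the 10 s feature grid by latest-available value, and is a
target column, never a feature.

## Modulation statistics

Features are averaged per (animal, concentration), pooling same-concentration
segments. Every unordered concentration pair is compared with a two-sided
Mann–Whitney U test: exact p-values for combined n ≤ 12 without ties,
mid-rank normal approximation with tie correction otherwise. BH-FDR is
applied per feature across its three pairs by default; the family structure
is genuinely ambiguous (a per-pair-across-features control is equally
defensible), so the mode is a switch and is recorded in every report's
attributes. With fewer than two animals the report degrades to p = 1 with a
warning rather than failing.

## Estimator

Inputs are lag-stacked rows ([xₙ₋₂, xₙ₋₁, xₙ], yₙ) built only inside
contiguous runs of windows within one block, so no input spans a discarded
interval or concentration change. Targets: administered concentration
(values 1.0/1.5/2.3), ERA, or elapsed time (control). The regressor is
stagewise least-squares gradient boosting of depth-≤3 trees, 100 steps,
learning rate 0.1 (unstated in the source protocol; standard default,
config-exposed), via scikit-learn's `GradientBoostingRegressor`; tests pin it
to a hand-written ~20-line stagewise residual booster (exactly on separable
data, closely on noisy data where near-tie splits may break differently).

Features enter absolutely — there is no normalization fit on training data —
so leave-one-animal-out folds cannot leak through scaling statistics. Fold
metrics: MAE; R² about the *eval-set* mean (conventional; fold R² can
therefore be negative). Classification metrics quantize predictions to the
nearest protocol level (midpoint ties to the lower level — a probability-zero
event on continuous predictions, fixed for determinism) and macro-average
one-vs-all accuracy/precision/recall/F1; levels absent from both truth and
prediction are excluded with a warning. Gini-gain importances are the trees'
total split-gain per lagged feature, clipped of float-noise negatives and
normalized to sum 1. The elapsed-time control trains an identical regressor
on elapsed seconds and Spearman-correlates its per-fold R² with the DoA
estimator's; significant positive correlation would indicate the estimator
exploits time rather than anesthetic state. Exported prediction traces carry
a trailing "standard error of the past minute" band (six 10 s windows).

## Problem sizes in tests and the acceptance script

Synthetic experiments use 5-animal cohorts with the seven-segment stepped
protocol scaled to 3-min segments and a 1-min transient discard (the package's
desk-scale default for validation: 12 windows per block, 350 lagged rows per
cohort), and 5-level depth grids with 20 windows per level for the
monotonicity checks. These sizes make every statistical margin (renewal
expectations, coherence bias, Spearman monotonicity, fold metrics) testable in
minutes while leaving the full-scale defaults (15-min segments, 5-min discard)
untouched in the API.

## Known limitations

- The generator emulates modulation structure, not realism: no inter-animal
  parameter variability, electrode drift, movement or stimulation artifacts,
  tail-pinch episodes, non-stationary arousal, or realistic evoked-potential
  morphology. Synthetic cohorts are therefore *easier* than real animals;
  passing recovery tests demonstrates internal consistency of the pipeline,
  not expected field performance.
- Estimating administered concentration equates depth with the population-
  average response; the hidden-depth correlation checks only verify the
  estimator tracks a monotone transform of the generator's depth variable.
- Burst detection is a fixed-threshold envelope method; on real data with
  slow amplitude drift it would need per-recording calibration.
- Coherence is computed on preprocessed traces by default; raw-trace
  coherence is available by featurizing unfiltered blocks, but the shared
  50 Hz line then leaks into bins near the 40 Hz band edge and biases the
  estimate upward.
- Recording I/O is CSV + JSON sidecar only; a standard binary biosignal
  container (e.g. EDF) writer is intentionally out of scope.
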