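# Methods

This note records the scientific and numerical choices behind `deepscan`:
what each stage computes, the defaults and why, what the simulator does and
does not emulate, and the known limitations.

## Signal model and pipeline order

A recording is a mono, ADC-normalized waveform `y ∈ [−1, 1]` at sample rate
`fs` (field deployments: 80 kHz, 2-minute files). The pipeline per file is
strictly: snap cleaning (optional, on by default) → framed broadband SPL →
median gating → feature extraction at candidate peaks → network scoring →
per-file OR of decisions. Calibration to absolute pressure happens in
exactly one place, the SPL correction factor; everything upstream and
downstream works on dimensionless amplitudes.

## Calibrated frame SPL

Frames are consecutive and non-overlapping, `frame_length = 0.5 s`
(a compromise: long enough for stable broadband estimates at 2 Hz bin
spacing, short relative to the few-second bursts being gated); a final
partial frame is dropped. Per frame:

* Hann taper, **normalized by its mean** (coherent-gain correction) before
  the DFT. With the single-sided spectrum `P_ss = 2|DFT(w·y)/N|²` (DC and
  Nyquist not doubled) and the subsequent division by the Hann power
  bandwidth factor `B = 1.5`, both tones and noise-like signals are then
  amplitude-accurate: a sine of amplitude `A` sums to `A²/2` and white
  noise of variance `σ²` to `σ²`. Without the coherent-gain normalization
  the same formula under-reports all levels by ~6 dB; the convention here
  follows the calibrated soundscape-metrics literature the SPL formula
  comes from.
* Band sum over `[band_low, band_high]` = 1–40,000 Hz by default (clipped
  to Nyquist), i.e. broadband SPL.
* `SPL = 10 log10(Σ P_ss / B) − S`, `S = M_h + G + 20 log10(1/V_ADC)`,
  `p_ref = 1 μPa`. Defaults `M_h = −185.5` dBV/μPa, `G = 20` dB,
  `V_ADC = 1` V (DSG-Ocean recorder constants; sensitivity is configurable
  because deployed hydrophones vary by fractions of a dB).
* An all-zero frame yields `−inf` with a warning, never an exception.

## Median gating

The gate reference is the **median SPL of the whole file** — robust to the
bursts themselves, which occupy a minority of frames. Literally gating at
"above the median" marks ~half the frames of pure noise, so a configurable
margin (default 3 dB) is applied; `margin = 0` reproduces the literal rule
for fidelity experiments. Marked frames merge across gaps ≤ `merge_gap`
(default 1 s, bridging within-burst dips) and segments shorter than
`min_duration` (default 1 s) are discarded — both well below the ~6 s mean
narrow-burst duration. The segment peak is the center of the max-SPL frame,
earliest on ties.

## Feature windows

Each candidate yields a Δt × Δf patch: Δt = 5.5 s (the mean narrow-burst
duration; the useful range is ~5.0–7.5 s and Δt is configurable),
Δf = 800–10,000 Hz. Below 800 Hz spring/summer fish chorusing dominates and
would teach the classifier biology; above 10 kHz adds storage with little
vessel information. The STFT uses 2048-point Hann frames with 50% hop
(25.6 ms at 80 kHz); the band patch is converted to dB with a floor 100 dB
below the patch maximum (a *relative* floor, so amplitude scaling shifts
every cell equally), bilinearly resampled to a fixed 32 × 32
(time × frequency) grid, and standardized to zero mean / unit variance
within the window. Standardization deliberately discards loudness — stage 1
already gated on energy — so the classifier learns shape; this is what lets
it reject loud choruses. Windows at file edges are zero-padded to keep the
input shape constant. For segments longer than Δt, windows are tiled every
Δt/2 across the segment and the maximum score is taken, covering wide
bursts at bounded compute.

## Classifier

Dense network `input(1024) → 10 → 8 → 6 → 1`, tanh hidden units, sigmoid
output, binary cross-entropy, full-batch Adam (lr 0.01, up to 3000 epochs),
early stopping on a seeded 20% validation split with patience 300 and
best-weights restoration. All arithmetic is NumPy float64 with a single
seeded generator, so identical seeds give bit-identical models. Training
sets pair burst-centered positives with seeded negatives drawn ≥ Δt from
any burst, default 15 negatives per positive (mirroring the roughly 1:15
class ratio of curated field feature sets). The decision threshold (0.5) is
configurable; models serialize to JSON. The shallow architecture is a
deliberate floor, matched to few-hundred-example training sets; depth buys
nothing until the feature corpus grows.

## Snap cleaning

Snaps are ~1 ms, full-spectrum, many times the background RMS. Detection
marks samples with `|y| > spike_factor ×` a moving-RMS envelope
(`envelope_window = 50 ms`, long against a snap, short against a pass-by;
`spike_factor = 4`). Marked samples are padded by 0.5 ms and merged;
an interval is accepted if it contains ≥ 2 marked samples *or* one mark
exceeding `2 × spike_factor ×` envelope. The cluster rule exists because
Gaussian background alone crosses 4σ about 6×10⁻⁵ per sample — hundreds of
isolated single-sample crossings per 2-minute 80 kHz file — while a real
snap spans dozens of samples; the strong-single branch keeps extreme
isolated impulses. Excised samples are replaced by the centered moving
average (20 ms) of surrounding non-snap samples, falling back to linear
interpolation inside gaps wider than the window. Samples outside detected
intervals are bit-identical to the input, and the operation is idempotent.
Cleaning is a pre-filter, not a contribution: if a detected interval spans
the whole file the input is returned unchanged with a warning.

## Evaluation and exposure metrics

Accuracy is `ρ = (N − n_ε)/N` over files, an error being a false vessel
flag or a miss; it is computed with rational arithmetic before conversion
to float. Per detected segment: Peak Difference = max SPL − median;
Mean Difference = mean of above-median frames (in-segment by default; a
flag switches to file-wide) − median; Area Size = trapezoidal integral of
`max(SPL − median, 0)` in dB·s, the proxy for the sound exposure level of
the pass-by. Below-median excursions are clamped because the area measures
noise *added* above the ambient median. Because summing dB·s areas is
heuristic, a linear-energy variant (`sel_metrics_linear`, integrating
`10^(excess/10) − 1`) is provided under a distinct name. Cumulative SEL
sums areas per station; detection time series count positive files per
(date, hour) with a coverage grid so empty cells are distinguishable from
zero-detection cells.

## Synthetic soundscapes

The simulator is the test bed and defines the conditions all pipeline-level
results refer to. A scene is: Gaussian background (RMS 0.02 full scale);
Poisson snaps (5 /s, amplitude 8× background RMS, 1 ms Hann-windowed tone
pips at 2–6 kHz); optional fish chorus (band-limited 50–800 Hz noise,
+15 dB in-band — loud enough to gate stage-1 candidates, which is the
point); and vessel events as band-limited noise with a Tukey (α = 0.25)
temporal envelope. Burst-broadband events span 100 Hz–30 kHz (clipped to
0.95 Nyquist) at +12 dB in-band; narrow/wide durations draw from normals
5.9 ± 2.1 s and 15.9 ± 6.6 s truncated at 0.5 s. Component levels are
defined as dB above background *within the component's own band* (its PSD
is `10^(L/10)` times the background's). Variable-broadband and
low-frequency event generators are included as confounders even though
only burst detection is in scope. Corpora hold scene *specs*, not
waveforms; `render()` regenerates audio bit-identically from the stored
seed. Everything — event placement, durations, training-set sampling,
network initialization and shuffling — derives from explicit seeds.

What the simulator does **not** emulate: propagation (spreading loss,
multipath), engine tonals and their Doppler, tide/weather covariates,
colored ambient spectra, and snap trains correlated with temperature.
Passing tests therefore show the pipeline's internal correctness and its
shape-vs-loudness discrimination, not field performance; real deployments
require retraining the classifier on curated field features.

## Problem sizes

Pipeline-level checks simulate 2-minute files at 16 kHz — the analysis band
tops out at 10 kHz, so nothing above 20 kHz sampling affects the feature
stage — with a 60-file training corpus (prevalence 0.3, ~25 positive
windows + 15:1 negatives) and a disjoint 100-file evaluation corpus.
Snap-recall checks run at the full 80 kHz default. Oracle checks (SPL,
gating, SEL, forward pass) use closed-form or exhaustive references at
small n.

## Known limitations

* Snap detection thresholds against the *full-band* envelope; a strong
  low-frequency chorus raises the envelope and hides marginal snaps
  (recall drops well below 95% in chorus-heavy 16 kHz scenes). Residual
  snaps cost little — a 1 ms, 8× spike adds ≈ 0.1 σ² to a 0.5 s frame —
  but a band-passed envelope would be the next improvement.
* The gate is relative to the per-file median; a vessel present for most
  of a file raises the median and can suppress its own candidates.
* One score threshold and one feature geometry serve all stations; real
  archives may need per-station training sets.
* `ρ` weights false positives and misses equally, and at low vessel
  prevalence high ρ is achievable by under-flagging; the evaluation
  object reports FP/FN separately for that reason.
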