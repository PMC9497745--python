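# Methods

`entrofuse` implements a cross-subject EEG emotion-recognition pipeline:
wavelet preprocessing with threshold artifact removal, five windowed
entropy features, per-subject normalisation and feature fusion, and
sequence-to-sequence LSTM/BiLSTM classification of positive / neutral /
negative states. A synthetic film-clip EEG generator stands in for real
recordings so the whole pipeline is testable offline. This note documents
the models, the parameters that matter, the numerical conventions, and what
the synthetic experiments do and do not demonstrate.

## Preprocessing

The pipeline order is fixed: select the twelve lateral-temporal channels
(FT7, T7, TP7, P7, C5, CP5 and right homologs) → downsample to 256 Hz
(polyphase, anti-aliased) → extract clip-only segments (hints and
self-assessment intervals dropped, with a per-sample map back to clip
index) → zero-phase IIR notch at 50 Hz (Q = 30) → 5-level db6 DWT band
split → per-band wavelet threshold artifact correction.

Band mapping at 256 Hz uses the dyadic detail levels: D2 → gamma
(32–64 Hz), D3 → beta (16–32), D4 → alpha (8–16), D5 → theta (4–8), A5 →
delta (≤4). D1 (64–128 Hz) lies outside the five named bands and is
discarded. DWT uses symmetric signal extension; unmodified
decomposition/reconstruction round-trips to ~1e-15 relative error.

Artifact correction re-decomposes each band signal (db6, 5 levels) and
thresholds every coefficient sequence — the approximation included, since
blink energy concentrates there — at

    T_j = mean(C_j) + 2 · std(C_j)      (sample std, n − 1)

halving each coefficient with |c| > T_j exactly once per pass. Choices a
maintainer should know:

* The comparison is on |c|, not the raw value: a raw-value rule would never
  flag large negative transients.
* The operation is deliberately not idempotent (a halved coefficient can
  still exceed a recomputed threshold); a second pass always changes the
  signal less than the first.
* By construction roughly the top 2 % of coefficients per level are halved
  on *any* input, including artifact-free ones. For smooth signals those
  are boundary-extension coefficients, so the interior is untouched
  (< 2.5e-5 relative at a 128-sample margin) while samples near the edges
  can move a few percent.
* A constant negative coefficient sequence is degenerate: T_j equals the
  (negative) mean, so |c| > T_j flags everything. The formula is kept as
  printed; real wavelet coefficient sequences are zero-mean.

## Entropy features

All features are computed per channel, per band, in non-overlapping
1-second windows (256 samples) aligned to clip starts; windows never
straddle a clip boundary. All logarithms are natural (nats).

* **Sample entropy (SE)**: −ln(A/B), template length m = 2, Chebyshev
  distance, match when d ≤ r, self-matches excluded, with the
  Richman–Moorman convention of N − m templates for both lengths.
  SE is NaN when either count is zero.
* **Multiscale entropy (MSE)**: SE of the coarse-grained series (block
  means of length τ, remainder dropped) at scales τ = 1…5, with r fixed
  once from the scale-1 window.
* **Approximate entropy (AE)**: Φ^m − Φ^(m+1) with self-matches included,
  so every C_i ≥ 1/(N−m+1) and no log-of-zero arises; AE of a constant
  window is exactly 0.
* **Fuzzy entropy (FE)**: templates centred on their own mean, hard match
  replaced by exp(−(d/r)^n) with n = 2, self-matches excluded;
  FE = ln(O^m/O^(m+1)).
* **Rényi entropy (RE)**: order q = 2 (collision entropy) of the relative
  frequencies over a 10-bin equal-width histogram spanning the window's own
  range. Because the bins track the window range, RE is amplitude-invariant
  and responds to the *shape* of the amplitude distribution.
* **Differential entropy (DE)**: Gaussian closed form ½·ln(2πe·σ²) with the
  window's sample variance (n − 1); −∞ (flagged) for constant windows.

Tolerance convention: r = 0.2 × the *population* std (ddof = 0) of the
window — the standard SE/MSE convention — while the artifact threshold and
DE use the sample std/variance (ddof = 1). Matching uses d ≤ r ("within
r"); for continuous-valued data the choice of ≤ versus < is measure-zero,
and ≤ keeps the constant-window AE case well defined.

The O(N²) pair loops are numba-compiled; fuzzy entropy computes distances
in the kernel and applies the exponential with vectorised `np.exp`. Both
paths are checked bitwise (match counts) or to 1e-12 (values) against naive
double-loop oracles in the test suite.

Matrix assembly: each single entropy contributes channels × bands rows
(60 for the 12-channel montage), MSE contributes five rows per
channel–band pair (300). Undefined entries (zero-variance windows, vanished
match counts) are imputed with the feature row's median so the classifier
sees finite inputs.

## Normalisation, labels, fusion, split

Features are min–max scaled to [−1, 1] per subject and per feature row;
constant rows map to 0. Per-subject scaling is what removes between-subject
amplitude offsets, and test subjects are scaled with their own min/max,
consistent with cross-subject deployment. Labels in {−1, 0, 1} are
broadcast from clips to their windows. Fusion is row-wise concatenation of
aligned matrices (540 rows for all five features at 12 channels). The
cohort split is subject-wise and seeded: 18 train / 5 test for a 23-subject
cohort, 15/5 at the benchmark size.

## Sequence classifier

The cell is the standard LSTM (sigmoid input/forget/output gates, tanh
candidate, element-wise state update; forget bias initialised to 1); the
bidirectional variant runs a second cell over the reversed sequence and
concatenates hidden states before a dense softmax layer. One training
sequence is a subject's full window sequence, so the recurrence can carry
emotional context across clips. Implementation is pure NumPy — forward,
full backpropagation through time, Adam (β = 0.9/0.999), global gradient
clipping at norm 5 — which keeps training bit-reproducible for a fixed
seed; the analytic gradients are verified against finite differences in the
tests.

Defaults: 64 hidden units per direction, learning rate 1e-3, up to 100
epochs, full-batch updates. With early stopping enabled and ≥ 4 training
subjects, one subject (seeded choice) is held out and training stops when
its *accuracy* (not its loss — cross-entropy rises with overconfidence long
before accuracy degrades) has not improved for `patience` epochs, restoring
the best parameters. Optional per-element input dropout acts as feature
bagging: with several hundred partially redundant feature rows it stops the
optimiser from leaning on a single dominant block. Class codes −1/0/1 map
to indices 0/1/2; argmax ties resolve to the lowest class code. The
headline accuracy is the unweighted mean of per-subject window accuracies,
with a 3×3 confusion matrix.

## Synthetic cohort generator

The generator emulates the film-clip protocol: a picture hint (5 s) before
each 2-minute clip and a 45 s self-assessment interval after it, 15 or 21
label-balanced clips per session, 12 channels at 1000 Hz native rate (so
the downsampling path is exercised), 23 subjects by default.

Each band's clip signal is a mixture of sinusoids with random in-band
frequencies/phases plus 1/f noise synthesised within the band's own range,
with three emotion-dependent knobs:

* **Band power** (`band_power_map`): a uniform gain across all five bands
  of 1.30 / 1.06 / 1.00 for positive / negative / neutral. Gamma power is
  therefore ordered positive > negative > neutral ("greater gamma activity
  in positive states, least in neutral"), and the elevation is global —
  overall EEG energy rises with positive emotion. A uniform profile keeps
  the *relative* spectral composition identical between classes, so
  amplitude-invariant features carry no power information at all: the
  power axis is read exclusively by differential entropy.
* **Complexity** (`complexity_map`): the 1/f-noise amplitude share p of
  each band's RMS budget, 0.60 / 0.60 / 0.20 for positive / negative /
  neutral — equal for the two emotional classes, clearly above neutral.
  Mixing is in quadrature (osc = √(1−p²)·target, noise = p·target), so band
  RMS is set by the gain alone and the noise share moves regularity without
  moving power — keeping the power feature (DE) and the regularity features
  (SE/FE/RE/MSE) complementary rather than redundant.
* **Richness** (`richness_map`): sinusoidal components per band — one for
  neutral clips, three for emotional clips. Direct measurement showed that
  windowed SE/FE/RE/MSE at 256 samples are nearly blind to the within-band
  noise share but respond strongly to the component count, so this axis is
  what makes neutral clips separable by regularity features.

Because the two emotional classes share (approximately) one complexity and
one richness level, the positive-versus-negative distinction is carried by
band power alone, while the neutral-versus-emotional distinction is carried
by regularity alone: no single feature family spans all three classes, and
fusing power features (DE) with regularity features (SE/FE/RE/MSE) is
structurally necessary for full separation. That is the property the fused
classifier is expected to exploit.

Heterogeneity: a per-subject log-normal gain (sd 0.20) and per-channel
scale jitter make cross-subject normalisation non-trivial, and a per-clip,
per-band log-normal gain jitter (sd 0.15) means no single clip's power is a
perfect class indicator — single-feature accuracies land mid-range rather
than at ceiling, which is the regime in which feature fusion has something
to add. Hints and intervals are neutral-gain background at 0.7 amplitude.
Artifacts (default 6 events/minute) are blinks — raised-cosine transients
of 0.3–0.5 s, 60–120 µV — and 1–2 s broadband movement bursts; their
amplitudes scale with the local signal gain so the artifact-to-signal ratio
is the same in every emotion condition (otherwise artifact residue would
leak the power axis into the amplitude-invariant features). Artifacts draw
from a dedicated random stream, so a zero artifact rate reproduces the
artifact-free signal exactly under the same seed.

Because the class axes are deliberately exclusive — power separates
positive from negative but is invisible to regularity features; richness
and noise share separate neutral from emotional but are invisible to DE —
no single feature family can separate all three classes, and the fused
classifier measurably beats the best single feature. The separation has to
be engineered this sharply: with clip-constant labels, a sequence model
integrates even a d ≈ 0.1 per-window cue over a clip's windows and feature
rows into near-perfect clip classification, so any residual leak (relative
band composition, artifact contrast) quickly makes one feature sufficient.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, non-stationary background rhythms, eye-movement
topographies, or any quantitative property of real emotion datasets.
Passing tests therefore demonstrate that the pipeline recovers the
qualitative structure it was built to detect — band-power and complexity
differences between emotional states — not that it attains any particular
accuracy on real recordings.

## Benchmark problem sizes

The full study-scale benchmark (23 subjects × 15 two-minute clips) costs
hours of single-CPU entropy extraction, so the packaged benchmark
(`entrofuse.pipeline.run_scaled_benchmark`, the acceptance script and the
cohort-recovery test) uses a scaled session: 20 subjects, 15 balanced clips
of 20 s with 3 s hints and 10 s intervals (300 windows per subject),
12 channels, default gains/complexity/artifact rate, split 15 train /
5 test, classifiers at 32 hidden units, learning rate 3e-3, up to 40 epochs
in mini-batches of 5 sequences with input dropout 0.2 and accuracy-monitored
early stopping (patience 8) on one held-out training subject — without it
the weaker single-feature models overfit subject-specific patterns.
The cohort-recovery test holds the cohort fixed and varies
the split and training over five seeds, asserting majority-rule properties
(fused ≥ best single feature, BiLSTM ≥ LSTM, fused accuracy well above
chance) rather than point accuracies.

## Degenerate inputs and numerical notes

* Zero-variance windows: r = 0, so SE/FE are undefined and DE is −∞; all
  are flagged and row-median imputed at matrix assembly. RE of a constant
  window is 0 (single occupied bin).
* `q = 1` is rejected for RE (the Shannon limit is not implemented).
* Coarse-graining at τ > N raises an error rather than returning an empty
  series.
* MSE can return NaN at coarse scales when no template pair matches; these
  impute like other sentinels.
* Training is single-threaded deterministic NumPy; identical data, config
  and seed give bit-identical parameters.

## Known limitations

* The notch filter is a fixed-Q biquad; line-noise harmonics are not
  handled.
* The dyadic DWT band edges (4/8/16/32/64 Hz) only approximate clinical
  band definitions; alpha in particular spans 8–16 Hz here.
* RE from range-normalised histograms is non-negative by construction; a
  density-based (differential) Rényi variant would behave differently for
  signals whose distribution, not range, carries the information.
* The LSTM is CPU-bound NumPy: adequate for hundreds of windows per
  sequence and tens of subjects, not for large-scale experiments.
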