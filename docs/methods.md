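# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecgnoise`, in the spirit of a package reference manual. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort

The generator emulates a three-class, single-lead (lead II) ECG cohort at
500 Hz with record durations drawn uniformly from [8, 138] s. Default
class counts are AF 976, Normal 918, STD 784 (total 2678). Each beat is a
sum of Gaussian bumps for the P, Q, R, S and T waves on a 0 mV isoline;
per-subject rate (±8%) and R amplitude (±10%) variation is applied.

* **Normal** — mean 70 bpm, RR coefficient of variation 0.03, isoelectric
  ST segment.
* **AF** — rhythm class: RR intervals i.i.d. with CV 0.20 around a mean
  rate of 110 bpm (clipped to [0.3, 2.2] s); the P wave is removed and
  replaced by a continuous low-amplitude (0.08 mV) oscillation at a
  per-record frequency in 4–9 Hz with slow random frequency drift,
  emulating fibrillatory f waves.
* **STD** — morphology class: Normal rhythm with the ST segment depressed
  by 0.15 mV (default). The depression is flat over the annotated ST
  window (60–140 ms after the R peak) with 20 ms cosine ramps outside it,
  so the annotated window mean equals −depth up to tails of the
  neighbouring waves.

Every record carries its ground-truth R times and ST windows in `meta`, so
tests can score RR statistics and ST levels against the generator's own
annotations rather than re-detecting them.

Raw records include a white-noise floor at 30 dB SNR relative to the beat
train. This makes `raw` differ from `clean` the way lightly contaminated
field recordings differ from filtered ones; the value is a package choice
(real first-source recordings are mostly but not perfectly clean), exposed
in `MorphologyParams.raw_noise_snr_db`.

**What the generator does not emulate:** 12-lead geometry, realistic
P/QRS/T covariation, respiratory modulation, ectopy, or the heterogeneous
residual noise of real archives. Passing tests therefore demonstrate that
the *protocol* behaves correctly and that the robustness asymmetry holds
under controlled class structure — not that any absolute F1 level carries
over to clinical data.

## Noise bank

Thirty minutes of each noise type at the cohort sampling rate, zero-mean
by construction; `all` is the unweighted sum bw + em + ma (weights
configurable).

* **bw** — four sinusoids with frequencies in 0.05–0.45 Hz and smoothed
  random-walk amplitude modulation; ≥ 90% of spectral power below 1 Hz.
* **em** — Poisson transient episodes (6/min, 0.5–3 s), each a smoothed
  biphasic pulse with random sign; near-zero between episodes.
* **ma** — 5–100 Hz band-limited Gaussian noise multiplied by a slowly
  varying lognormal envelope (bursty, broadband).

Amplitude scales (0.35 / 0.8 / 0.15 mV) only set the banks' relative power;
the injection rescales everything per record.

## Filtering chain

`clean_record` applies, in order, all zero-phase (forward–backward over
second-order sections, even/reflect padding): 0.5 Hz 4th-order Butterworth
high-pass (baseline-wander removal), 150 Hz 10th-order Butterworth
low-pass, 0.05 Hz 4th-order Butterworth high-pass, 50 Hz IIR notch with
−3 dB band 49–51 Hz (Q = 25), then isoline correction (mode of a 0.01 mV
amplitude histogram subtracted) and exact mean removal.

Numerical notes: the low-pass order is chosen so the zero-phase response
is at least 20 dB down by 170 Hz — a 4th-order design leaves double-pass
attenuation near 11 dB there, which would let supra-band interference
through essentially unattenuated. The final mean subtraction completes the
DC rejection that a finite-length zero-phase high-pass leaves incomplete
(transient residuals of order 10⁻⁴ mV); it shifts the isoline estimate by
far less than one histogram bin. Signals shorter than the filter warm-up
length (3·(2·n_sections+1) samples) are rejected with an explicit error.

## Noise injection

For each clean record: draw one window offset (uniform over valid starts)
and one target SNR (uniform on [5, 10] dB); compute
α = √(Σs² / (Σn²·10^(SNR/10))) against the *combined* segment; scale all
four segments by this single α; add. SNR is total-energy based:
10·log₁₀(Σs²/Σn²) over the whole record. Consequences, all tested: the
realized `all` SNR equals the target exactly (closed form); bw/em/ma
variants realize *higher* SNRs (each carries only part of the calibrated
power); the same bank time-window feeds all three single-noise variants of
a record. Zero-power noise raises a dedicated `UndefinedSNRError` rather
than returning infinity. Per-record draws are keyed by
(record id, master seed) via SHA-256, so dataset construction is
order-independent and reproducible.

The window is shared across the three noise types (one "segment" per
record); an independent-windows mode is not provided because nothing
downstream depends on it and the shared window is the stricter reading of
one-segment-per-record.

## Image transforms

**SPAR attractor.** τ defaults to one third of the mean cardiac cycle,
estimated as the autocorrelation peak in the 0.3–3 s lag range; if
estimation fails (constant or aperiodic input) a fixed τ = 0.33 s is used
with a warning. Embedded points (x(t), x(t−τ), x(t−2τ)) are projected with
the fixed orthonormal basis v = (x+y−2z)/√6, w = (x−y)/√2 of the plane
orthogonal to (1,1,1) — any other basis differs only by an image rotation.
The density image is a 150×150 histogram over the symmetric square
[−r, r]², r = max |projected coordinate| (per-record bounds: the shape is
scale-free), log1p-scaled and max-normalized to [0, 1] (raw counts are too
peaked at the isoline crossing to be visible; linear scaling is available
in config). Offset invariance is exact by construction, since (c, c, c)
lies in the projection's null space — this is the mechanism by which the
attractor inherently discounts baseline wander, and the test suite asserts
bit-identical images under constant shifts.

**Scalogram.** Analytic generalized Morse wavelet with γ = 3 and
time-bandwidth product P² = βγ = 60 (β = 20), the common defaults of the
toolbox family these transforms originate from, evaluated as an FFT-domain
filter bank, peak-normalized per scale. 16 voices per octave between
0.5 and 50 Hz (113 scales), a band that covers both the sub-Hz drift and
the QRS energy while keeping the filter bank compact; limits are
configurable. The |CWT| matrix is bilinearly resized to 150×150 and
max-normalized per image (linear magnitude; log-magnitude available —
per-image normalization is a known open issue for scalogram-based
classification and is deliberately explicit in config). Two numerical
shortcuts, both inconsequential to the imaged band and covered by tests:
when the sampling rate exceeds 4× the top analysis frequency the signal is
anti-alias decimated first, and the time axis is block-averaged to ≤ 600
columns before the bilinear resize.

Images store float intensities in [0, 1] (higher density/magnitude =
brighter); the PNG writer emits 8-bit greyscale with a lossless NPZ
sidecar for exact round-trips.

## Folds and training

`make_folds` builds k = 5 predefined stratified folds: within each class,
shuffled records are dealt into near-equal parts, with per-class remainder
records placed greedily on the currently smallest folds so the *total*
test-fold sizes differ by at most one (2678 → {535, 536}); validation
(5% of n) is carved stratified from each fold's non-test 80%, leaving 75%
for training. The same `FoldAssignment` is reused across all 12 image
datasets, and the evaluation harness asserts id-level disjointness of
train∪validation and test within every fold.

The classifier preserves the transfer-learning contract — frozen backbone,
replaced trainable classification head — with a deliberately compact
backbone: images are bilinearly resized to 224×224 (227 supported), block
average-pooled to 16×16 and flattened (256 features, standardized on the
training set); the head is a multinomial logistic layer trained by
full-batch gradient descent (learning rate 0.5, L2 10⁻³, max 50 epochs,
init seeded). Early stopping follows the patience rule exactly: the
validation loss is evaluated once per epoch; a counter increments on each
epoch whose loss strictly exceeds the running minimum, resets on each new
strict minimum (equal values do nothing), and training stops when the
counter reaches 5. By default the weights at the best validation loss are
restored (`restore_best=False` keeps the stopping-epoch weights). The
backbone is swappable behind `TrainConfig.backbone`; a GPU-scale
pretrained CNN can be slotted in without touching the harness.

## Evaluation

Macro F1 is the arithmetic mean of per-class F1 (harmonic mean of
precision and recall from the 3×3 confusion matrix, class order AF,
Normal, STD); any zero denominator yields 0 (conservative convention,
relevant only to degenerate folds). The three variations (`same`,
`clean_train`, `noisy_train`) always apply a fold's model to that same
fold's test partition of the target dataset — the only leakage-safe
fold-matching. Trained models are cached per (train dataset, fold) within
a variation, and per-fold predictions can be retained so any aggregate
cell is recomputable without retraining.

## Problem sizes

Defaults reproduce the full study geometry (2678 records, 12 image
datasets, 5 folds). The package's own verification runs use scaled-down
cohorts — 200 records for the SNR-calibration summary and 300 records
(study class proportions, full [8, 138] s duration range, 5 folds, 5
seeds) for the robustness comparison — sizes at which the qualitative
conclusions are stable across seeds.

## Known limitations

* Single lead only; the 12-lead adaptation of the noise recordings is out
  of scope.
* The compact backbone's absolute F1 values are not comparable to
  ImageNet-scale CNNs; only the relative train/test-condition structure is
  meaningful.
* Filtering may interact differently with pathological morphologies; no
  per-class filter adjustment is implemented.
* The scalogram's per-image normalization and fixed frequency limits are
  defensible defaults, not a resolved question.
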