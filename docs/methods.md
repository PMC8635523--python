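# Methods

## Problem and scope

`anaspec` classifies seven classes of adventitious (abnormal) respiratory
sounds from auscultation recordings: the continuous adventitious sounds
(CAS) wheeze, rhonchi, stridor and squawk — tonal, quasi-musical events
lasting tens to hundreds of milliseconds — and the discontinuous
adventitious sounds (DAS) fine crackle, coarse crackle and pleural rub —
explosive or friction transients of at most ~25 ms. The pipeline converts
audio to STFT magnitude spectrograms, applies a spectral enhancement
operator (artificial noise addition, ANA), renders the spectrograms as
images, and trains convolutional networks on a stratified 70/30 split with
horizontal-flip augmentation, reporting per-class precision/recall/F1 and
accuracy.

Because clinical corpora of all seven classes are commercial or
proprietary, the package ships a parametric simulator whose defaults
emulate a 70-recording corpus (wheeze 12, rhonchi 9, stridor 10, squawk 8,
fine crackle 11, coarse crackle 11, pleural rub 9).

## The simulator

Each class is a `ClassSpec` of pitch range, nominal event duration,
CAS/DAS category and breath-phase placement:

| class | category | pitch (Hz) | duration (ms) | phase |
|---|---|---|---|---|
| wheeze | CAS | 400–800 | 250 | both |
| rhonchi | CAS | 150–250 | 250 | both |
| stridor | CAS | 500–1000 | 300 | inspiration |
| squawk | CAS | 200–300 | 90 | inspiration |
| fine crackle | DAS | 650 | 5 | inspiration |
| coarse crackle | DAS | 350 | 15 | early inspiration + expiration |
| pleural rub | DAS | 150–350 | 15 (2–4 bursts) | both |

CAS events are harmonic tones: fundamental drawn uniformly from the pitch
range, two decaying harmonics (0.35, 0.15 relative amplitude, dropped above
0.45·fs), 1 % vibrato at 5 Hz, under a Tukey(0.25) taper. DAS events are
sinusoidal bursts under a Tukey(0.5) taper; a pleural-rub event is a train
of 2–4 bursts separated by 10 ms of silence. Squawk is modeled as a short
CAS (90 ms tonal event): its 200–300 Hz musical description is tonal even
though its duration sits near the CAS/DAS boundary.

**Duration convention.** An event's duration is defined operationally as
the span where the Hilbert amplitude envelope exceeds 10 % of its peak
(for burst trains: the longest contiguous such span, i.e. one burst). The
synthesis window is sized so the measured support equals the nominal
duration — for a Tukey(α) taper the support fraction is
`1 − α·acos(0.8)/π`, so a 5 ms fine crackle measures 5.0 ms at 8 kHz.

Recordings place events over `n_cycles` breath cycles (default 2) of 1.5 s
inspiration + 2.0 s expiration, on a vesicular background of 100–1000 Hz
band-passed Gaussian noise at 0.1 relative amplitude, so events dominate
the spectrogram. Event onsets are drawn uniformly inside the
phase-appropriate windows; CAS classes place one event per window, DAS
classes 3–6 bursts per window. Per-recording jitter (default 5 %)
perturbs pitch and duration multiplicatively. All randomness flows from
one seed through `numpy` generators; a fixed configuration + seed is
byte-reproducible.

**What the simulator does not model:** heart sounds, speech, ambient
noise, airflow physiology, inter-patient variability, recording-chain
coloration, or class co-occurrence. Synthetic classes are separable by
construction (with deliberate pitch overlap between wheeze/stridor and
between the low-pitched classes), so passing the classification surrogate
shows the pipeline learns time-frequency signatures end to end — not that
it would reach the same accuracy on clinical audio.

## Spectral core

The canonical internal rate is 8000 Hz (all class pitches are ≤ 1 kHz).
`complete_fft`/`positive_fft` are the two-sided and one-sided DFT magnitude
spectra; the one-sided spectrum has `n//2 + 1` bins and equals the
two-sided magnitudes on shared bins (no energy-doubling convention).
Spectrograms use an unpadded STFT: Hann window of 256 samples (32 ms),
hop 128, giving `1 + (n − w)//h` frames and 31.25 Hz resolution — enough
to localize 5 ms crackles as transients while resolving the pitch classes.

**ANA** is coherent self-addition of a spectrum: adding a spectrum to an
identical copy doubles every magnitude (gain 2, configurable ≥ 1) and
changes nothing else — bin ratios, axes and dimensions are preserved, and
total energy scales by gain². It is *not* additive random noise. By
linearity of the DFT it equals doubling the waveform amplitude before
transformation (tested, not assumed).

**Rendering.** Magnitudes are log-scaled (`20·log10(m + 1e-10)`), mapped
linearly over an 80 dB range below an intensity ceiling, colormapped
(viridis by default; one colormap for all classes, since per-class
coloring would leak labels into pixels) with time left→right and frequency
bottom→top. Two ceiling modes matter for ANA:

* `per_image_max` — each image scaled to its own maximum. A global gain is
  exactly annihilated; ANA-on and ANA-off renderings are pixel-identical.
* fixed absolute ceiling (pipeline default) — calibrated as the maximum
  raw training-set magnitude, so the mapping is monotone and ANA genuinely
  brightens faint structure toward the ceiling.

When the spectrogram grid is larger than the output image, it is first
decimated by whole-block local maxima and only then bilinearly resized.
Plain bilinear averaging attenuates transients that occupy one or two STFT
frames — precisely the DAS signatures; max-decimation preserves them (this
single choice moved the VGG surrogate from 0.81 to ≥ 0.95 accuracy).

Texture descriptors (mean, variance, horizontal/vertical contrast as mean
squared adjacent-pixel differences, histogram energy and entropy on 32
bins) are one reasonable reading of "spectrogram texture"; they are
reported for inspection and are all invariant under horizontal flips.
Feature maps are valid-mode 2-D cross-correlations of the grayscale image
with user kernels.

## Dataset handling

The split is stratified per class: round-half-up(count × 0.7) recordings
to train, the rest to test, at least one test item per class (with 8–12
recordings per class a plain random 30 % draw can empty a class's test
cell). The default corpus splits 49/21 and wheeze contributes 8/4.
Augmentation adds exactly one horizontally flipped copy of every training
image (a probabilistic mode exists but is non-default, making the
doubling deterministic) and never touches the test set.

## Classifiers

Three registered blueprints (see `cnn.build_architecture`):

* `alexnet_paper` — five conv + three dense layers as specified layer by
  layer: conv 96×(11×11)/4 valid → pool 2×2/2 → conv 256×(11×11)/2 valid →
  pool → 3× conv 3×3/1 same (384, 384, 256) → pool → dense 4096 → 4096 →
  7 softmax. Two constructibility notes: CL2's 11×11 stride 2 is kept as
  written (canonical AlexNet uses 5×5/1), and CL3–CL5 use same padding
  because valid 3×3 convolutions would collapse the 4×4 MP2 output below
  1×1 before MP3. On 227×227 input CL1 gives 55×55×96 and the flatten is
  1024; the smallest admissible input is 143×143.
* `lenet5` — the classical stack (6×5×5, pool, 16×5×5, pool, 120-84-n).
* `vgg_small` — three blocks of two 3×3 convolutions (32, 64, 128) each
  followed by 2×2 pooling, then dense 256; a compact stand-in for the VGG
  family variants whose internals are not public.

The training backend is a self-contained NumPy implementation (im2col
convolution, max-pooling with argmax routing, inverted dropout, softmax
cross-entropy, SGD-momentum and Adam) in float32; it is deterministic for
a fixed seed and the analytic shape rules (`output_shape`: valid
`floor((n−k)/s)+1`, same `ceil(n/s)`) are audited against the real forward
pass in tests.

**Optimization.** The reference protocol is 500 epochs. Desk-scale runs
use Adam (batch 8) with halve-on-plateau decay of the learning rate
(plateau = 6 epochs without train-loss improvement), early-stopped when
the running train loss falls below 0.01 or train accuracy stays perfect
for several epochs. SGD with momentum 0.9 is available but converges far
too slowly on this problem at any learning rate we tried. Inputs are
centered to [−1, 1]; all-positive pixel inputs measurably slowed
ReLU-network convergence.

Fast profiles (pipeline defaults): `vgg_small`/`lenet5` train on 64×64
RGB renderings with dropout 0.5 and lr 1e-3; `alexnet_paper` trains on
160×160 grayscale with slim 512/512 dense layers, dropout 0.25, lr 3e-4
and a 3-epoch linear LR warmup — the big-kernel strided stack otherwise
collapses on some seeds (dead early ReLUs), while warmup measurably hurt
the small nets and is off for them. At 160 the stack flattens to a single
256-dim vector, so the full-width 4096 dense layers only slow it down.
These profiles exist because the architecture-as-written is genuinely
hard to optimize at 49 training recordings; the registry blueprint itself
is unchanged.

## Evaluation

`compute_report` produces per-class precision/recall/F1 with supports,
accuracy, and macro (unweighted) and support-weighted averages;
zero-denominator metrics are reported as 0 and zero-support classes are
flagged. The support-weighted recall equals accuracy by construction
(identity-tested). Text export mirrors the per-class table layout with
two-decimal round-half-up display; JSON/CSV keep full precision.

## Numerical and degenerate-input conventions

* Peak frequency ignores the DC bin; near-exact ties (within 1e-9
  relative) resolve to the lower frequency.
* All-zero waveforms: normalization returns them unchanged with a warning;
  peak detection raises.
* WAV output is 16-bit PCM; out-of-range samples clip with a warning.
* Pool/conv output sizes floor; `output_shape` raises before any
  non-positive dimension, naming the layer.
* The per-image-max rendering renormalizes after resizing so the maximum
  pixel is exactly 1 despite interpolation.

## Problem sizes used by the shipped experiments

The scaled-down surrogate (acceptance script and end-to-end tests) uses
the default 70-recording corpus, two breath cycles per recording at
8 kHz, a 49/21 stratified split, flip augmentation, ANA gain 2 with a
fixed train-calibrated ceiling, and three seeds per architecture with an
epoch cap of 100 (alexnet 80) under the early-stopping rules above. The
VGG surrogate reports the median test accuracy over seeds; the AlexNet
surrogate reports the best. Typical desk-scale results: VGG median ≈
0.95, AlexNet best ≈ 1.0, with single-seed spread roughly 0.8–1.0 —
expect seed-to-seed variation of a few test items (the test set has 21).

## Known limitations

* The simulator's class separability upper-bounds realism; clinical
  accuracy claims require clinical audio.
* Horizontal flipping reverses the time axis, so it destroys breath-phase
  position cues (an inspiratory event appears expiratory in the flipped
  copy); classification therefore leans on pitch, duration and event-count
  signatures.
* ANA under per-image normalization is exactly invisible; its benefit
  exists only relative to a fixed intensity reference (documented and
  tested), and the pipeline's default ceiling is calibrated on the
  training partition only.
* The NumPy backend targets CPU desk scale (seconds per epoch at the fast
  profiles); it is not a general deep-learning framework.
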