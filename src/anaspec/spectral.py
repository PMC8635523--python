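"""Frequency-domain core: FFT spectra, STFT spectrograms, ANA enhancement,
spectrogram-image rendering, texture descriptors and feature maps.

ANA (artificial noise addition) is coherent self-addition of a spectrum:
adding a spectrum to an identical copy of itself doubles every magnitude
while leaving all ratios between bins — and hence the spectral shape —
untouched.  It is an enhancement operator, not additive random noise.
Because a plain doubling is invisible after per-image min-max scaling, the
default rendering path scales against a *fixed* intensity ceiling so that
ANA genuinely brightens faint time-frequency structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from scipy.signal import correlate2d
from scipy.signal.windows import get_window
from skimage.transform import resize as _resize

from .audio_io import Waveform

# ---------------------------------------------------------------------------
# Elementary wave relations


@dataclass
class WaveParams:
    """Related wave quantities: f·t = 1 and v = f·λ."""

    frequency: float | None = None  # Hz
    period: float | None = None  # s
    velocity: float | None = None  # m/s
    wavelength: float | None = None  # m


def wave_relations(
    frequency: float | None = None,
    period: float | None = None,
    velocity: float | None = None,
    wavelength: float | None = None,
) -> WaveParams:
    """Complete wave parameters from any determining pair.

    Uses f = 1/t, v = f·λ (and their rearrangements).  The redundant pair
    (f, t) is accepted only when consistent; it cannot determine v or λ.
    """
    for name, val in (("frequency", frequency), ("period", period),
                      ("velocity", velocity), ("wavelength", wavelength)):
        if val is not None and val == 0:
            raise ValueError(f"{name} must be non-zero")

    f, t, v, lam = frequency, period, velocity, wavelength
    if f is not None and t is not None and abs(f * t - 1.0) > 1e-9:
        raise ValueError("inconsistent pair: frequency * period != 1")
    for _ in range(3):  # fixed-point completion over the two relations
        if f is None and t is not None:
            f = 1.0 / t
        if t is None and f is not None:
            t = 1.0 / f
        if f is not None and lam is not None and v is None:
            v = f * lam
        if v is not None and lam is not None and f is None:
            f = v / lam
        if v is not None and f is not None and lam is None:
            lam = v / f
    if f is None and (v is None or lam is None):
        raise ValueError("the given fields do not determine the parameters")
    return WaveParams(frequency=f, period=t, velocity=v, wavelength=lam)


# ---------------------------------------------------------------------------
# Spectra


@dataclass
class Spectrum:
    """Magnitude spectrum of a discrete Fourier transform."""

    frequencies: np.ndarray  # Hz
    magnitudes: np.ndarray  # >= 0
    sidedness: str  # "two_sided" | "one_sided"
    n: int  # original signal length
    sample_rate: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.frequencies.shape != self.magnitudes.shape:
            raise ValueError("frequency axis and magnitudes must align")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        expected = self.n if self.sidedness == "two_sided" else self.n // 2 + 1
        if len(self.magnitudes) != expected:
            raise ValueError(
                f"{self.sidedness} spectrum of n={self.n} needs {expected} bins"
            )


def complete_fft(waveform: Waveform) -> Spectrum:
    """Two-sided magnitude spectrum (negative and positive frequencies)."""
    if len(waveform) == 0:
        raise ValueError("cannot transform an empty waveform")
    mags = np.abs(np.fft.fft(waveform.samples))
    freqs = np.fft.fftfreq(len(waveform), d=1.0 / waveform.sample_rate)
    return Spectrum(freqs, mags, "two_sided", len(waveform),
                    waveform.sample_rate)


def positive_fft(waveform: Waveform) -> Spectrum:
    """One-sided magnitude spectrum over [0, Nyquist]: floor(n/2)+1 bins.

    Bin magnitudes equal the two-sided magnitudes at the same frequencies
    (no one-sided energy-doubling convention is applied).
    """
    if len(waveform) == 0:
        raise ValueError("cannot transform an empty waveform")
    mags = np.abs(np.fft.rfft(waveform.samples))
    freqs = np.fft.rfftfreq(len(waveform), d=1.0 / waveform.sample_rate)
    return Spectrum(freqs, mags, "one_sided", len(waveform),
                    waveform.sample_rate)


def peak_frequency(spectrum: Spectrum) -> float:
    """Frequency (Hz) of the largest non-DC magnitude bin.

    Ties break toward the lower frequency (argmax returns the first hit).
    """
    if spectrum.sidedness != "one_sided":
        raise ValueError("peak_frequency expects a one-sided spectrum")
    mags = spectrum.magnitudes.copy()
    mags[0] = 0.0  # ignore DC
    if np.all(mags == 0):
        raise ValueError("all-zero spectrum has no peak")
    top = mags.max()
    # near-exact ties (within numerical noise) resolve to the lowest frequency
    tied = np.flatnonzero(mags >= top * (1 - 1e-9))
    return float(spectrum.frequencies[tied[0]])


# ---------------------------------------------------------------------------
# Spectrograms


@dataclass
class Spectrogram:
    """STFT magnitude matrix, frames x one-sided frequency bins."""

    magnitudes: np.ndarray  # (frames, bins), >= 0
    times: np.ndarray  # s, frame centers
    frequencies: np.ndarray  # Hz
    window_length: int
    hop_length: int
    window_kind: str = "hann"
    sample_rate: int = 8000

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.shape != (len(self.times), len(self.frequencies)):
            raise ValueError("axis lengths must match the magnitude matrix")


def stft_spectrogram(
    waveform: Waveform,
    window_length: int = 256,
    hop_length: int = 128,
    window_kind: str = "hann",
) -> Spectrogram:
    """Short-time Fourier magnitude spectrogram without padding.

    Frame count is ``1 + (n - window) // hop``; each frame is the one-sided
    magnitude FFT of one windowed segment.  Defaults (Hann, 256/128 at
    8 kHz, i.e. 32 ms / 16 ms) resolve ~5 ms crackle transients while
    giving 31.25 Hz frequency resolution.
    """
    n = len(waveform)
    if hop_length <= 0:
        raise ValueError("hop_length must be positive")
    if not 0 < window_length <= n:
        raise ValueError(
            f"window_length {window_length} exceeds signal length {n}; "
            "zero-pad the signal first"
        )
    if hop_length > window_length:
        raise ValueError("hop_length must not exceed window_length")
    win = get_window(window_kind, window_length, fftbins=True)
    n_frames = 1 + (n - window_length) // hop_length
    idx = (np.arange(window_length)[None, :]
           + hop_length * np.arange(n_frames)[:, None])
    frames = waveform.samples[idx] * win[None, :]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    rate = waveform.sample_rate
    times = (np.arange(n_frames) * hop_length + window_length / 2) / rate
    freqs = np.fft.rfftfreq(window_length, d=1.0 / rate)
    return Spectrogram(mags, times, freqs, window_length, hop_length,
                       window_kind, rate)


# ---------------------------------------------------------------------------
# ANA


@dataclass(frozen=True)
class ANAConfig:
    """Spectral self-addition gain; the canonical operator adds the spectrum
    to itself once, i.e. gain 2."""

    gain: float = 2.0

    def __post_init__(self) -> None:
        if self.gain < 1:
            raise ValueError("ANA gain must be >= 1")


def apply_ana(target: Spectrum | Spectrogram,
              config: ANAConfig = ANAConfig()) -> Spectrum | Spectrogram:
    """Coherently self-add a spectrum or spectrogram: magnitudes x gain.

    Axes, dimensions and all magnitude ratios between bins are unchanged —
    the spectral behaviour is preserved, only its strength grows.
    """
    return replace(target, magnitudes=target.magnitudes * config.gain)


# ---------------------------------------------------------------------------
# Rendering


@dataclass
class SpectrogramImage:
    """Rendered spectrogram: float pixels in [0, 1], time left->right,
    frequency bottom->top."""

    pixels: np.ndarray  # (height, width, channels)
    colormap: str = "viridis"
    intensity_ref: float | str = "per_image_max"
    flipped: bool = False
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def grayscale(self) -> np.ndarray:
        """Channel-mean 2-D intensity image."""
        return self.pixels.mean(axis=2)


#: dB range displayed below the ceiling.
DB_RANGE = 80.0
_EPS = 1e-10


def _block_max_reduce(grid: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Shrink each axis that is larger than the target by whole-block maxima
    (nearest integer factor), leaving remaining scaling to interpolation."""
    from skimage.measure import block_reduce

    factors = [max(1, s // t) for s, t in zip(grid.shape, out_size)]
    if factors == [1, 1]:
        return grid
    # trim so the block factor divides evenly (drops at most factor-1 cells)
    trimmed = grid[: (grid.shape[0] // factors[0]) * factors[0],
                   : (grid.shape[1] // factors[1]) * factors[1]]
    return block_reduce(trimmed, tuple(factors), np.max)


def render_spectrogram_image(
    spec: Spectrogram,
    colormap: str = "viridis",
    intensity_ref: float | str = "per_image_max",
    out_size: tuple[int, int] = (96, 96),
    label: str | None = None,
    source_id: str | None = None,
) -> SpectrogramImage:
    """Render a spectrogram to a colormapped image.

    Magnitudes are log-scaled (20·log10(m + 1e-10)) and mapped linearly onto
    [0, 1] over an 80 dB range below the ceiling: either this image's own
    maximum (``"per_image_max"``) or a fixed absolute magnitude ceiling
    (a float), under which values above the ceiling clip at 1.  With a fixed
    ceiling the mapping is monotone in the magnitudes, so ANA brightens the
    image pointwise; per-image scaling cancels any global gain.
    """
    h, w = out_size
    if h < 1 or w < 1:
        raise ValueError("out_size must be positive")
    db = 20.0 * np.log10(spec.magnitudes + _EPS)
    if intensity_ref == "per_image_max":
        top = db.max()
    else:
        top = 20.0 * np.log10(float(intensity_ref) + _EPS)
    intensity = np.clip((db - (top - DB_RANGE)) / DB_RANGE, 0.0, 1.0)
    # (frames, bins) -> rows = frequency top-down, cols = time
    grid = intensity.T[::-1]
    # When shrinking, decimate by local maxima first: plain bilinear
    # averaging would wash out sub-pixel transients (crackle bursts live in
    # only one or two STFT frames), and it is exactly those transients that
    # carry the discontinuous-class signatures.
    grid = _block_max_reduce(grid, (h, w))
    grid = _resize(grid, (h, w), order=1, mode="edge", anti_aliasing=False)
    grid = np.clip(grid, 0.0, 1.0)
    if intensity_ref == "per_image_max" and grid.max() > 0:
        grid = grid / grid.max()  # interpolation must not break max -> 1.0
    rgba = colormaps[colormap](grid)
    return SpectrogramImage(rgba[:, :, :3], colormap=colormap,
                            intensity_ref=intensity_ref, label=label,
                            source_id=source_id)


# ---------------------------------------------------------------------------
# Texture analysis

#: Order of the texture descriptor vector.
TEXTURE_METRIC_NAMES = ("mean", "variance", "horizontal_contrast",
                        "vertical_contrast", "energy", "entropy")


def texture_metrics(image: SpectrogramImage) -> np.ndarray:
    """Six texture descriptors of the grayscale spectrogram image.

    ``[mean, variance, horizontal contrast, vertical contrast, energy,
    entropy]`` where the contrasts are mean squared adjacent-pixel
    differences along time (horizontal) and frequency (vertical), and
    energy/entropy are computed on the 32-bin intensity histogram.
    All six are invariant under horizontal flipping.
    """
    gray = image.grayscale()
    if gray.shape[0] < 2 and gray.shape[1] < 2:
        raise ValueError("image too small for texture analysis")
    h_contrast = float(np.mean(np.diff(gray, axis=1) ** 2)) if gray.shape[1] > 1 else 0.0
    v_contrast = float(np.mean(np.diff(gray, axis=0) ** 2)) if gray.shape[0] > 1 else 0.0
    hist, _ = np.histogram(gray, bins=32, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return np.array([
        float(gray.mean()),
        float(gray.var()),
        h_contrast,
        v_contrast,
        float(np.sum(p ** 2)),
        float(-np.sum(nz * np.log2(nz))),
    ])


# ---------------------------------------------------------------------------
# Feature maps


def feature_maps(image: SpectrogramImage,
                 filters: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Valid-mode 2-D cross-correlation of the grayscale image with each
    kernel; output dims are ``input - kernel + 1`` per axis."""
    gray = image.grayscale()
    maps = []
    for kernel in filters:
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.ndim != 2:
            raise ValueError("kernels must be 2-D")
        if kernel.shape[0] > gray.shape[0] or kernel.shape[1] > gray.shape[1]:
            raise ValueError(
                f"kernel {kernel.shape} larger than image {gray.shape}"
            )
        # correlation = convolution with the flipped kernel
        maps.append(correlate2d(gray, kernel, mode="valid"))
    return maps
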