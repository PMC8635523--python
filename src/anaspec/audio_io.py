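"""Reading, writing and standardizing respiratory-sound audio.

Every recording entering the pipeline is reduced to a mono :class:`Waveform`
with samples in ``[-1, 1]``.  The canonical internal rate is 8000 Hz: all
adventitious-sound energy of interest lies well below 1 kHz, so 8 kHz leaves
ample Nyquist headroom while keeping spectrogram frames small.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Canonical sample rate (Hz) assumed by every stage after ingestion.
CANONICAL_RATE = 8000

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31}


@dataclass
class Waveform:
    """A sampled mono audio signal.

    Parameters
    ----------
    samples:
        1-D float array of amplitudes, nominal range ``[-1, 1]``.
    sample_rate:
        Sampling rate in Hz (positive).
    label:
        Optional adventitious-class tag.
    source_id:
        Optional provenance string (file stem, synthesis seed, ...).
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF/WAVE file into a mono, ``[-1, 1]``-scaled :class:`Waveform`.

    Integer PCM (8/16/24/32-bit) is rescaled by its full-scale value; float
    data is taken as-is.  Multi-channel input is averaged to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"not a readable WAV file: {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples, int(rate), source_id=path.stem)


def write_wav(waveform: Waveform, path: str | Path) -> Path:
    """Write a waveform as 16-bit PCM mono WAV; returns the path written.

    Samples outside ``[-1, 1]`` are clipped with a warning.
    """
    if len(waveform) == 0:
        raise ValueError("refusing to write an empty waveform")
    path = Path(path)
    samples = waveform.samples
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        warnings.warn(
            f"samples exceed [-1, 1] (peak {peak:.3f}); clipping on write",
            stacklevel=2,
        )
        samples = np.clip(samples, -1.0, 1.0)
    pcm = np.round(samples * 32767.0).astype(np.int16)
    wavfile.write(str(path), waveform.sample_rate, pcm)
    return path


def normalize_peak(waveform: Waveform) -> Waveform:
    """Scale so the maximum absolute amplitude is exactly 1.

    An all-zero signal is returned unchanged with a warning (there is no
    meaningful gain to apply).
    """
    if len(waveform) == 0:
        raise ValueError("cannot normalize an empty waveform")
    peak = np.max(np.abs(waveform.samples))
    if peak == 0.0:
        warnings.warn("all-zero waveform left unchanged by peak normalization",
                      stacklevel=2)
        return replace(waveform)
    return replace(waveform, samples=waveform.samples / peak)


def resample(waveform: Waveform, target_rate: int) -> Waveform:
    """Band-limited resampling to ``target_rate`` via polyphase filtering."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == waveform.sample_rate:
        return replace(waveform)
    from math import gcd

    g = gcd(target_rate, waveform.sample_rate)
    up, down = target_rate // g, waveform.sample_rate // g
    out = resample_poly(waveform.samples, up, down)
    return replace(waveform, samples=out, sample_rate=target_rate)


def standardize(waveform: Waveform, rate: int = CANONICAL_RATE) -> Waveform:
    """Resample to the canonical rate and peak-normalize (ingestion step)."""
    return normalize_peak(resample(waveform, rate))
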