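"""Parametric simulator for adventitious respiratory sounds.

Seven abnormal sound classes are generated from their auscultation
signatures: continuous adventitious sounds (CAS — wheeze, rhonchi, stridor,
squawk) are quasi-periodic tonal events lasting tens to hundreds of
milliseconds, while discontinuous adventitious sounds (DAS — fine crackle,
coarse crackle, pleural rub) are brief damped bursts of at most ~25 ms.
Events are mixed at breath-phase-appropriate positions over a vesicular
background (band-passed noise), emulating what a digital stethoscope would
record over one or more breath cycles.

Event duration is defined operationally as the span where the amplitude
envelope exceeds 10% of its peak; the synthesis window length is solved so
the measured support equals the nominal class duration.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.signal.windows import tukey

from .audio_io import Waveform, normalize_peak, write_wav

#: Ordered class vocabulary used everywhere downstream.
VOCABULARY = (
    "wheeze",
    "rhonchi",
    "stridor",
    "squawk",
    "fine_crackle",
    "coarse_crackle",
    "pleural_rub",
)

#: Per-class recording counts of the emulated 70-recording corpus.
DEFAULT_COUNTS = {
    "wheeze": 12,
    "rhonchi": 9,
    "stridor": 10,
    "squawk": 8,
    "fine_crackle": 11,
    "coarse_crackle": 11,
    "pleural_rub": 9,
}


@dataclass(frozen=True)
class ClassSpec:
    """Acoustic signature of one adventitious sound class."""

    label: str
    category: str  # "CAS" or "DAS"
    f0_low: float  # Hz, lower bound of the dominant pitch
    f0_high: float  # Hz, upper bound of the dominant pitch
    event_duration_ms: float  # nominal 10%-envelope support of one event
    phase: str  # breath-phase placement
    n_bursts: tuple[int, int] = (1, 1)  # burst-train size range (pleural rub)

    def __post_init__(self) -> None:
        if not (0 < self.f0_low <= self.f0_high):
            raise ValueError("require 0 < f0_low <= f0_high")
        if self.event_duration_ms <= 0:
            raise ValueError("event_duration_ms must be positive")
        if self.category == "CAS" and self.event_duration_ms < 80:
            raise ValueError("CAS events must last at least 80 ms")
        if self.category == "DAS" and self.event_duration_ms > 25:
            raise ValueError("DAS events must last at most 25 ms")

    @property
    def f0_center(self) -> float:
        return 0.5 * (self.f0_low + self.f0_high)


_CLASS_TABLE = {
    # label:            category  f0 range (Hz)  dur(ms)  phase
    "wheeze": ClassSpec("wheeze", "CAS", 400.0, 800.0, 250.0, "both"),
    "rhonchi": ClassSpec("rhonchi", "CAS", 150.0, 250.0, 250.0, "both"),
    "stridor": ClassSpec("stridor", "CAS", 500.0, 1000.0, 300.0, "inspiration"),
    "squawk": ClassSpec("squawk", "CAS", 200.0, 300.0, 90.0, "inspiration"),
    "fine_crackle": ClassSpec("fine_crackle", "DAS", 650.0, 650.0, 5.0,
                              "inspiration"),
    "coarse_crackle": ClassSpec("coarse_crackle", "DAS", 350.0, 350.0, 15.0,
                                "early_inspiration_and_expiration"),
    "pleural_rub": ClassSpec("pleural_rub", "DAS", 150.0, 350.0, 15.0, "both",
                             n_bursts=(2, 4)),
}


def class_spec(label: str) -> ClassSpec:
    """Look up the acoustic signature for a class token."""
    try:
        return _CLASS_TABLE[label]
    except KeyError:
        raise ValueError(
            f"unknown class {label!r}; expected one of {', '.join(VOCABULARY)}"
        ) from None


@dataclass(frozen=True)
class BreathModel:
    """Breath-cycle scaffold carrying the vesicular background.

    Defaults: 1.5 s inspiration, 2.0 s expiration, 100-1000 Hz vesicular
    passband at relative level 0.1 so events stay dominant.
    """

    inspiration_s: float = 1.5
    expiration_s: float = 2.0
    vesicular_band_hz: tuple[float, float] = (100.0, 1000.0)
    background_level: float = 0.1

    def __post_init__(self) -> None:
        if self.inspiration_s <= 0 or self.expiration_s <= 0:
            raise ValueError("breath-phase durations must be positive")
        lo, hi = self.vesicular_band_hz
        if not 0 < lo < hi:
            raise ValueError("vesicular band must satisfy 0 < low < high")
        if not 0 < self.background_level < 1:
            raise ValueError("background_level must lie in (0, 1)")

    @property
    def cycle_s(self) -> float:
        return self.inspiration_s + self.expiration_s


@dataclass
class SynthConfig:
    """Corpus-level generation parameters (defaults emulate the 70-file set)."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    sample_rate: int = 8000
    n_cycles: int = 2
    jitter_pct: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            class_spec(label)  # vocabulary guard
            if n < 0:
                raise ValueError(f"negative count for {label}")
        if not 0 <= self.jitter_pct <= 50:
            raise ValueError("jitter_pct must lie in [0, 50]")


# Tukey taper fractions: wider ramps for transient bursts, gentler for tones.
_ALPHA = {"CAS": 0.25, "DAS": 0.5}
# Fraction of a Tukey ramp below the 10%-amplitude point.
_RAMP_CROSS = math.acos(1.0 - 2.0 * 0.1) / math.pi  # ~0.2048


def _window_samples(duration_ms: float, alpha: float, rate: int) -> int:
    """Window length whose 10%-envelope support equals ``duration_ms``."""
    support_frac = 1.0 - alpha * _RAMP_CROSS
    return max(8, int(round(duration_ms / 1000.0 * rate / support_frac)))


def envelope(waveform: Waveform) -> np.ndarray:
    """Amplitude envelope via the analytic-signal (Hilbert) magnitude."""
    return np.abs(hilbert(waveform.samples))


def envelope_support_ms(waveform: Waveform, frac: float = 0.1) -> float:
    """Duration (ms) of the longest contiguous region where the envelope
    exceeds ``frac`` of its peak.

    For a single event this is its effective duration; for a burst train it
    is the duration of one burst (gaps drop below the threshold).
    """
    env = envelope(waveform)
    peak = env.max()
    if peak == 0:
        return 0.0
    above = env > frac * peak
    # longest run of True
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best / waveform.sample_rate * 1000.0


def _tonal_event(f0: float, duration_ms: float, rate: int,
                 rng: np.random.Generator) -> np.ndarray:
    """CAS event: harmonic tone with slow vibrato under a raised-cosine taper."""
    n = _window_samples(duration_ms, _ALPHA["CAS"], rate)
    t = np.arange(n) / rate
    # integrate instantaneous frequency: 1% vibrato at 5 Hz around f0
    inst_f = f0 * (1.0 + 0.01 * np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(inst_f) / rate
    sig = np.sin(phase + rng.uniform(0, 2 * np.pi))
    for k, amp in ((2, 0.35), (3, 0.15)):
        if k * f0 < 0.45 * rate:
            sig = sig + amp * np.sin(k * phase + rng.uniform(0, 2 * np.pi))
    return sig * tukey(n, _ALPHA["CAS"])


def _burst(f0: float, duration_ms: float, rate: int,
           rng: np.random.Generator) -> np.ndarray:
    """DAS burst: sinusoid at f0 under a raised-cosine envelope."""
    n = _window_samples(duration_ms, _ALPHA["DAS"], rate)
    t = np.arange(n) / rate
    return np.sin(2 * np.pi * f0 * t) * tukey(n, _ALPHA["DAS"])


def synthesize_event(
    spec: ClassSpec,
    sample_rate: int,
    seed: int | np.random.Generator = 0,
    f0: float | None = None,
    duration_ms: float | None = None,
) -> Waveform:
    """Synthesize one adventitious event with peak amplitude 1.

    The fundamental is drawn uniformly from ``[f0_low, f0_high]`` unless an
    explicit ``f0`` is given (``spec.f0_center`` disables the draw entirely).
    Requires ``sample_rate >= 4 * f0_high`` of headroom above Nyquist.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample_rate < 4 * spec.f0_high:
        raise ValueError(
            f"sample_rate {sample_rate} too low for f0 up to {spec.f0_high} Hz "
            "(need at least 4x headroom)"
        )
    if f0 is None:
        f0 = float(rng.uniform(spec.f0_low, spec.f0_high))
    dur = duration_ms if duration_ms is not None else spec.event_duration_ms
    if spec.category == "CAS":
        sig = _tonal_event(f0, dur, sample_rate, rng)
    elif spec.label == "pleural_rub":
        parts: list[np.ndarray] = []
        n_bursts = int(rng.integers(spec.n_bursts[0], spec.n_bursts[1] + 1))
        gap = np.zeros(int(0.010 * sample_rate))  # 10 ms silence between bursts
        for i in range(n_bursts):
            if i:
                parts.append(gap)
            parts.append(_burst(f0, dur, sample_rate, rng)
                         * float(rng.uniform(0.7, 1.0)))
        sig = np.concatenate(parts)
    else:
        sig = _burst(f0, dur, sample_rate, rng)
    sig = sig / np.max(np.abs(sig))
    return Waveform(sig, sample_rate, label=spec.label)


def _phase_windows(spec: ClassSpec, breath: BreathModel,
                   n_cycles: int) -> list[tuple[float, float]]:
    """Time windows (s) in which events of this class may start."""
    wins = []
    for c in range(n_cycles):
        t0 = c * breath.cycle_s
        insp = (t0, t0 + breath.inspiration_s)
        exp = (t0 + breath.inspiration_s, t0 + breath.cycle_s)
        if spec.phase == "inspiration":
            wins.append(insp)
        elif spec.phase == "expiration":
            wins.append(exp)
        elif spec.phase == "early_inspiration_and_expiration":
            wins.append((t0, t0 + 0.4 * breath.inspiration_s))
            wins.append(exp)
        else:  # both
            wins.append(insp)
            wins.append(exp)
    return wins


def synthesize_recording(
    label: str,
    breath: BreathModel | None = None,
    config: SynthConfig | None = None,
    seed: int | None = None,
    with_events: bool = False,
):
    """Render ``n_cycles`` breath cycles with class events over vesicular noise.

    Returns a peak-normalized :class:`Waveform`; with ``with_events=True``
    also returns the list of ``(onset_s, duration_s, f0)`` event placements.
    Deterministic for a fixed seed.
    """
    breath = breath or BreathModel()
    config = config or SynthConfig()
    spec = class_spec(label)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.sample_rate
    total_s = config.n_cycles * breath.cycle_s
    n = int(round(total_s * rate))

    noise = rng.standard_normal(n)
    lo, hi = breath.vesicular_band_hz
    sos = butter(4, [lo, min(hi, 0.45 * rate)], btype="bandpass",
                 fs=rate, output="sos")
    background = sosfiltfilt(sos, noise)
    background *= breath.background_level / np.max(np.abs(background))
    out = background.copy()

    jit = config.jitter_pct / 100.0
    events: list[tuple[float, float, float]] = []
    for win_lo, win_hi in _phase_windows(spec, breath, config.n_cycles):
        n_events = 1 if spec.category == "CAS" else int(rng.integers(3, 7))
        if spec.label == "pleural_rub":
            n_events = 1  # the event itself is a burst train
        for _ in range(n_events):
            f0 = float(rng.uniform(spec.f0_low, spec.f0_high))
            f0 *= 1.0 + rng.uniform(-jit, jit)
            dur = spec.event_duration_ms * (1.0 + rng.uniform(-jit, jit))
            ev = synthesize_event(spec, rate, rng, f0=f0, duration_ms=dur)
            ev_len = len(ev)
            latest = win_hi - ev_len / rate
            if latest <= win_lo:
                start_s = win_lo  # event longer than window: pin to its start
            else:
                start_s = float(rng.uniform(win_lo, latest))
            i0 = int(round(start_s * rate))
            i1 = min(i0 + ev_len, n)
            amp = float(rng.uniform(0.7, 1.0))
            out[i0:i1] += amp * ev.samples[: i1 - i0]
            events.append((start_s, ev_len / rate, f0))

    wave = normalize_peak(Waveform(out, rate, label=label))
    if with_events:
        return wave, events
    return wave


def generate_dataset(config: SynthConfig | None = None,
                     out_dir: str | Path = "synth_corpus") -> Path:
    """Write one WAV per requested recording plus ``manifest.csv``.

    The default configuration produces the 70-recording corpus with the
    per-class counts wheeze 12, rhonchi 9, stridor 10, squawk 8,
    fine crackle 11, coarse crackle 11, pleural rub 9.  Returns the
    manifest path.  Byte-identical output for identical config + seed.
    """
    config = config or SynthConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total = sum(config.counts.values())
    if total == 0:
        warnings.warn("all class counts are zero; writing an empty manifest",
                      stacklevel=2)
    seeds = np.random.SeedSequence(config.seed).generate_state(max(total, 1) * 2)
    manifest = out_dir / "manifest.csv"
    rows = []
    i = 0
    for label in VOCABULARY:
        for k in range(config.counts.get(label, 0)):
            wave = synthesize_recording(label, config=config,
                                        seed=int(seeds[i] % (2 ** 31)))
            name = f"{label}_{k:03d}.wav"
            write_wav(wave, out_dir / name)
            rows.append((name, label))
            i += 1
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)
    return manifest
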