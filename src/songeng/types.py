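"""Core data containers shared across the analysis chain.

Units follow field conventions: audio amplitudes are dimensionless in
[-1, 1], neural voltages are in microvolts, times in seconds unless a
field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AUDIO_RATE = 44150.0
"""Nominal audio digitization rate (Hz)."""

ACUTE_NEURAL_RATE = 24400.0
"""Acute electrophysiology digitization rate (Hz)."""

CHRONIC_NEURAL_RATE = 30000.0
"""Default chronic electrophysiology digitization rate (Hz)."""


@dataclass
class AudioClip:
    """Mono audio waveform, the unit of vocal analysis."""

    samples: np.ndarray
    rate: float = AUDIO_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip requires a mono (1-D) waveform")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def slice(self, onset: float, offset: float) -> "AudioClip":
        """Extract [onset, offset) in absolute seconds as a new clip."""
        i0 = int(round((onset - self.start_time) * self.rate))
        i1 = int(round((offset - self.start_time) * self.rate))
        i0, i1 = max(i0, 0), min(i1, self.samples.size)
        if i1 <= i0:
            raise ValueError("empty slice")
        return AudioClip(self.samples[i0:i1], self.rate, start_time=onset)


@dataclass
class SyllableSegment:
    """A continuous sound element bounded by silent gaps."""

    onset: float
    offset: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class NeuralTraces:
    """Multichannel extracellular voltage matrix (channels x samples, uV)."""

    voltages: np.ndarray
    rate: float
    role: str = "on-nerve"  # "on-nerve" | "off-nerve"
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        if self.voltages.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.role not in ("on-nerve", "off-nerve"):
            raise ValueError("role must be 'on-nerve' or 'off-nerve'")
        if not self.channel_ids:
            self.channel_ids = list(range(self.voltages.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class FeatureTrack:
    """Five acoustic features sampled every millisecond of a segment.

    ``pitch`` is in Hz (NaN where unvoiced, see ``voiced``), ``fm`` is the
    modulation angle in radians, ``am`` the relative amplitude derivative in
    1/s, ``wiener_entropy`` the log ratio of geometric to arithmetic spectral
    mean (<= 0), and ``envelope`` the total band power in dB.
    """

    times: np.ndarray
    pitch: np.ndarray
    fm: np.ndarray
    am: np.ndarray
    wiener_entropy: np.ndarray
    envelope: np.ndarray
    voiced: np.ndarray

    FEATURES = ("pitch", "fm", "am", "wiener_entropy", "envelope")

    def __post_init__(self) -> None:
        arrays = [self.times, self.pitch, self.fm, self.am,
                  self.wiener_entropy, self.envelope, self.voiced]
        n = {np.asarray(a).size for a in arrays}
        if len(n) != 1:
            raise ValueError("all tracks must have the same length")

    def __len__(self) -> int:
        return self.times.size

    def matrix(self) -> np.ndarray:
        """Frames x 5 feature matrix (pitch NaN where unvoiced)."""
        return np.column_stack([
            self.pitch, self.fm, self.am, self.wiener_entropy, self.envelope,
        ])


@dataclass
class EnvelopeTrace:
    """Smoothed squared-voltage envelope (a.u. ~ uV^2)."""

    values: np.ndarray
    times: np.ndarray
    smoothing_window: float  # ms

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class WarpPath:
    """Monotone map from rendition time to template time (frame pairs, ms)."""

    rendition_ms: np.ndarray
    template_ms: np.ndarray
    cost: float = np.nan

    def __post_init__(self) -> None:
        r = np.asarray(self.rendition_ms, dtype=float)
        t = np.asarray(self.template_ms, dtype=float)
        if r.size != t.size or r.size < 2:
            raise ValueError("path needs matched coordinate arrays")
        if np.any(np.diff(r) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("warp path must be non-decreasing")
        self.rendition_ms, self.template_ms = r, t

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.rendition_ms, self.template_ms))


@dataclass
class EvokedTrial:
    """One peri-stimulus voltage window (-5 to +25 ms around pulse onset)."""

    current: float  # uA; positive = cathodic-leading by convention
    trace: np.ndarray  # uV
    rate: float = ACUTE_NEURAL_RATE
    pre_ms: float = 5.0
    pattern: object | None = None  # StimPattern or "bipolar-hook"
    condition: str = "baseline"
    artifact_span: tuple[float, float] = (0.0, 0.5)  # ms post-onset

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)

    def time_ms(self) -> np.ndarray:
        """Per-sample time in ms relative to stimulation onset."""
        return np.arange(self.trace.size) / self.rate * 1e3 - self.pre_ms

    def window_slice(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Samples in [lo_ms, hi_ms) relative to stimulation onset."""
        i0 = int(round((lo_ms + self.pre_ms) * self.rate / 1e3))
        i1 = int(round((hi_ms + self.pre_ms) * self.rate / 1e3))
        if i0 < 0 or i1 > self.trace.size or i1 <= i0:
            raise ValueError("window outside trace")
        return self.trace[i0:i1]
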