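"""Seed-deterministic synthetic data with the statistical structure the
downstream analyses assume.

Four generators are provided:

* :func:`make_song` -- stereotyped multi-motif song from a parametric bird
  (harmonic-stack syllables with controllable pitch, AM, FM, Wiener entropy
  and amplitude), with ground-truth syllable annotations;
* :func:`make_nerve_recording` -- six-channel multi-unit electroneurogram
  locked to the song timeline: inhomogeneous-Poisson events convolved with a
  biphasic spike kernel, riding on a rank-1 band-limited common-mode artifact
  plus independent Gaussian noise; an off-nerve variant carries artifact and
  noise only;
* :func:`make_evoked_trials` -- peri-stimulus windows containing a stimulation
  artifact and a compound response whose amplitude follows a sigmoidal
  recruitment curve;
* :func:`make_fictive_vocalizations` -- stimulation-pattern-conditioned
  syllables in which acoustics depend deterministically (plus rendition
  noise) on the pattern.

All generators take an integer seed and return bit-identical output for
identical (spec, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .types import (ACUTE_NEURAL_RATE, AUDIO_RATE, CHRONIC_NEURAL_RATE,
                    AudioClip, EvokedTrial, NeuralTraces)

# --------------------------------------------------------------------------
# specs


@dataclass
class SyllableSpec:
    """Parametric stand-in for a species-typical syllable.

    ``pitch_traj`` is the fundamental in Hz over normalized syllable time;
    ``entropy_level`` (<= 0) sets the target Wiener entropy via the tonal /
    noise power mix; ``fm_depth`` is the vibrato excursion in Hz.
    """

    duration: float
    pitch_traj: np.ndarray
    am_rate: float
    fm_depth: float
    entropy_level: float
    amplitude: float = 1.0
    am_depth: float = 0.3
    fm_rate: float = 35.0

    def __post_init__(self) -> None:
        self.pitch_traj = np.atleast_1d(np.asarray(self.pitch_traj, float))
        if not (0.02 <= self.duration <= 0.3):
            raise ValueError("syllable duration must lie in [0.02, 0.3] s")
        if np.any(self.pitch_traj < 300) or np.any(self.pitch_traj > 8000):
            raise ValueError("pitch trajectory must lie in [0.3, 8] kHz")
        if self.entropy_level > 0:
            raise ValueError("entropy_level must be <= 0")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")


@dataclass
class BirdSpec:
    """A bird's stereotyped motif: syllable inventory plus ordering."""

    bird_id: str
    syllable_params: list[SyllableSpec]
    motif_order: list[int]
    rendition_jitter: float = 0.02
    gap_s: float = 0.025  # intersyllable silence

    def __post_init__(self) -> None:
        if len(self.motif_order) == 0:
            raise ValueError("motif_order must be non-empty")
        if self.rendition_jitter < 0:
            raise ValueError("rendition_jitter must be >= 0")
        if max(self.motif_order) >= len(self.syllable_params):
            raise ValueError("motif_order indexes beyond syllable inventory")


def _bird_seed(bird_id: str) -> int:
    return zlib.crc32(bird_id.encode()) & 0x7FFFFFFF


def random_bird(bird_id: str, n_syllables: int = 3,
                rendition_jitter: float = 0.02,
                seed: int | None = None) -> BirdSpec:
    """Draw a bird with an independent syllable inventory.

    Distinct ``bird_id`` values (or distinct seeds) yield independently
    drawn syllable parameters.
    """
    rng = np.random.default_rng(_bird_seed(bird_id) if seed is None else seed)
    sylls = []
    for _ in range(n_syllables):
        f0 = rng.uniform(500, 2200)
        f1 = f0 * rng.uniform(0.75, 1.3)
        f1 = float(np.clip(f1, 400, 3500))
        k = rng.uniform(-0.5, 0.5)  # curvature of the sweep
        u = np.linspace(0, 1, 32)
        traj = f0 + (f1 - f0) * (u + k * u * (1 - u))
        sylls.append(SyllableSpec(
            duration=float(rng.uniform(0.06, 0.18)),
            pitch_traj=np.clip(traj, 350, 3800),
            am_rate=float(rng.uniform(8, 40)),
            fm_depth=float(rng.uniform(0, 120)),
            entropy_level=float(rng.uniform(-3.5, -0.8)),
            amplitude=float(rng.uniform(0.6, 1.0)),
        ))
    order = list(rng.permutation(n_syllables))
    return BirdSpec(bird_id, sylls, order, rendition_jitter,
                    gap_s=float(rng.uniform(0.015, 0.04)))


# --------------------------------------------------------------------------
# song synthesis


def _band_noise(n: int, rng: np.random.Generator, rate: float,
                lo: float = 300.0, hi: float = 8000.0) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfilt(sos, x)
    return y / (np.std(y) + 1e-12)


def synth_syllable(spec: SyllableSpec, rng: np.random.Generator,
                   rate: float = AUDIO_RATE,
                   jitter: float = 0.0) -> np.ndarray:
    """Render one syllable as a harmonic stack plus shaped noise.

    ``jitter`` is the fractional SD of per-rendition feature scaling.
    """
    def j() -> float:
        return float(1.0 + jitter * rng.standard_normal()) if jitter else 1.0

    dur = float(np.clip(spec.duration * j(), 0.02, 0.3))
    n = max(int(round(dur * rate)), int(0.02 * rate))
    t = np.arange(n) / rate
    u = t / t[-1]

    f0 = np.interp(u, np.linspace(0, 1, spec.pitch_traj.size),
                   spec.pitch_traj) * j()
    f0 = f0 + spec.fm_depth * j() * np.sin(2 * np.pi * spec.fm_rate * t)
    f0 = np.clip(f0, 320, 7800)
    phase = 2 * np.pi * np.cumsum(f0) / rate

    n_harm = max(1, int(7800 / float(np.max(f0))))
    harm = np.zeros(n)
    for h in range(1, n_harm + 1):
        mask = h * f0 < 7800  # keep partials inside the analysis band
        harm += (h ** -0.8) * np.sin(h * phase) * mask
    harm /= np.std(harm) + 1e-12

    w = float(np.exp(spec.entropy_level))  # noise power fraction
    wave = np.sqrt(1 - w) * harm + np.sqrt(w) * _band_noise(n, rng, rate)

    am = 1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate * j() * t)
    am /= 1.0 + spec.am_depth
    ramp = int(0.004 * rate)
    edge = np.ones(n)
    win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    edge[:ramp] = win
    edge[-ramp:] = win[::-1]

    wave = wave * am * edge
    peak = np.max(np.abs(wave)) + 1e-12
    return wave / peak * spec.amplitude * j()


def make_song(bird: BirdSpec, n_motifs: int, seed: int,
              rate: float = AUDIO_RATE,
              intermotif_silence: float = 0.4,
              edge_silence: float = 0.1,
              ) -> tuple[AudioClip, pd.DataFrame]:
    """Synthesize ``n_motifs`` renditions of the bird's motif.

    Returns the audio plus ground-truth annotations: one row per syllable
    with columns ``onset_s, offset_s, label, motif``.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = np.random.default_rng(seed)
    pieces: list[np.ndarray] = [np.zeros(int(edge_silence * rate))]
    rows = []
    cursor = int(edge_silence * rate)
    for m in range(n_motifs):
        for k, idx in enumerate(bird.motif_order):
            wave = synth_syllable(bird.syllable_params[idx], rng, rate,
                                  jitter=bird.rendition_jitter)
            rows.append({"onset_s": cursor / rate,
                         "offset_s": (cursor + wave.size) / rate,
                         "label": f"s{idx}", "motif": m})
            pieces.append(wave)
            cursor += wave.size
            if k < len(bird.motif_order) - 1:
                gap = np.zeros(int(bird.gap_s * rate))
                pieces.append(gap)
                cursor += gap.size
        if m < n_motifs - 1:
            sil = np.zeros(int(intermotif_silence * rate))
            pieces.append(sil)
            cursor += sil.size
    pieces.append(np.zeros(int(edge_silence * rate)))
    return AudioClip(np.concatenate(pieces), rate), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# nerve recordings


def default_envelope_template(n: int = 250, seed: int = 7) -> np.ndarray:
    """Smooth non-negative per-motif activity envelope, peak-normalized."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    k = signal.windows.gaussian(41, 8)
    env = np.convolve(x, k / k.sum(), mode="same")
    env = env - env.min()
    env = env ** 2 + 0.05
    return env / env.max()


@dataclass
class NerveModel:
    """Generative model of singing-locked multi-unit nerve activity.

    The off-nerve variant (``on_nerve=False``) has zero coupling to the
    envelope template; the common-mode artifact is shared across channels up
    to per-channel gain (rank-1 by construction).
    """

    envelope_template: np.ndarray = field(
        default_factory=default_envelope_template)
    unit_rate_scale: float = 600.0  # peak events/s per channel
    spike_amp_uv: float = 90.0
    artifact_gain: np.ndarray | float = 60.0  # uV RMS per channel
    noise_sd: float = 10.0  # uV
    on_nerve: bool = True
    n_channels: int = 6
    spike_width_ms: float = 0.35

    def channel_artifact_gains(self) -> np.ndarray:
        g = np.asarray(self.artifact_gain, dtype=float)
        if g.ndim == 0:
            g = g * np.linspace(0.8, 1.2, self.n_channels)
        if g.size != self.n_channels:
            raise ValueError("artifact_gain length must match channel count")
        return g


def spike_kernel(rate: float, width_ms: float = 0.35) -> np.ndarray:
    """Biphasic ms-scale extracellular spike kernel, unit peak."""
    half = int(3 * width_ms * 1e-3 * rate)
    t = np.arange(-half, half + 1) / rate * 1e3
    k = -t / width_ms * np.exp(0.5 - 0.5 * (t / width_ms) ** 2)
    return k / (np.abs(k).max() + 1e-12)


def _motif_rate_profile(annotations: pd.DataFrame, model: NerveModel,
                        n_samples: int, rate: float,
                        rng: np.random.Generator,
                        jitter: float) -> np.ndarray:
    """Per-sample event rate (events/s): template warped onto each motif."""
    profile = np.zeros(n_samples)
    tmpl = model.envelope_template
    for _, grp in annotations.groupby("motif"):
        i0 = int(grp["onset_s"].min() * rate)
        i1 = int(grp["offset_s"].max() * rate)
        i1 = min(i1, n_samples)
        if i1 <= i0:
            continue
        u = np.linspace(0, 1, i1 - i0)
        scale = 1.0 + jitter * rng.standard_normal() if jitter else 1.0
        profile[i0:i1] = np.interp(
            u, np.linspace(0, 1, tmpl.size), tmpl) * max(scale, 0.1)
    return profile * model.unit_rate_scale


def make_nerve_recording(annotations: pd.DataFrame, model: NerveModel,
                         seed: int, rate: float = CHRONIC_NEURAL_RATE,
                         duration_s: float | None = None,
                         motif_jitter: float = 0.05) -> NeuralTraces:
    """Simulate a multichannel ENG locked to the annotated song timeline.

    Each channel receives an independent inhomogeneous-Poisson event train
    whose rate follows the warped envelope template during motifs (on-nerve
    only), convolved with a biphasic spike kernel; all channels share one
    band-limited (10-500 Hz) common-mode process scaled by per-channel gain,
    plus independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = float(annotations["offset_s"].max()) + 0.5
    n = int(round(duration_s * rate))
    nch = model.n_channels
    volts = np.zeros((nch, n))

    if model.on_nerve and model.unit_rate_scale > 0:
        prof = _motif_rate_profile(annotations, model, n, rate, rng,
                                   motif_jitter)
        p = np.clip(prof / rate, 0, 1)
        kern = spike_kernel(rate, model.spike_width_ms)
        for c in range(nch):
            events = rng.random(n) < p
            amps = np.zeros(n)
            idx = np.flatnonzero(events)
            amps[idx] = model.spike_amp_uv * rng.lognormal(0, 0.35, idx.size)
            amps[idx] *= np.sign(rng.random(idx.size) - 0.15)  # mostly neg-first
            volts[c] = signal.fftconvolve(amps, kern, mode="same")

    gains = model.channel_artifact_gains()
    if np.any(gains != 0):
        shared = rng.standard_normal(n)
        sos = signal.butter(2, [10, 500], btype="bandpass", fs=rate,
                            output="sos")
        shared = signal.sosfilt(sos, shared)
        shared /= np.std(shared) + 1e-12
        volts += gains[:, None] * shared[None, :]

    if model.noise_sd > 0:
        volts += model.noise_sd * rng.standard_normal((nch, n))

    role = "on-nerve" if model.on_nerve else "off-nerve"
    return NeuralTraces(volts, rate, role=role)


# --------------------------------------------------------------------------
# evoked trials


@dataclass
class EvokedModel:
    """Sigmoidal recruitment of a compound response plus stimulation artifact.

    Response peak-to-peak amplitude at current I is
    ``vmax / (1 + exp(-(I - i50) / slope))`` (uV).
    """

    vmax: float = 300.0
    i50: float = 20.0
    slope: float = 5.0
    baseline_noise: float = 5.0  # uV RMS
    latency_span: tuple[float, float] = (0.75, 4.0)  # ms
    artifact_span: tuple[float, float] = (0.0, 0.5)  # ms
    artifact_uv_per_ua: float = 25.0

    def __post_init__(self) -> None:
        if not self.vmax > 0:
            raise ValueError("vmax must be positive")
        if not (0 <= self.latency_span[0] < self.latency_span[1] <= 25):
            raise ValueError("latency_span must lie in the 25 ms window")

    def amplitude(self, current: float) -> float:
        return self.vmax / (1.0 + np.exp(-(current - self.i50) / self.slope))


def _response_kernel(rate: float, span_ms: tuple[float, float],
                     pre_ms: float, n: int) -> np.ndarray:
    """Unit-Vpp damped oscillation centered inside the latency span."""
    t = np.arange(n) / rate * 1e3 - pre_ms
    center = span_ms[0] + 0.35 * (span_ms[1] - span_ms[0])
    width = 0.22 * (span_ms[1] - span_ms[0])
    k = np.exp(-0.5 * ((t - center) / width) ** 2) * np.sin(
        2 * np.pi * (t - center) / (2.2 * width))
    k[(t < span_ms[0]) | (t > span_ms[1])] = 0.0
    pp = k.max() - k.min()
    return k / (pp + 1e-12)


def make_evoked_trials(model: EvokedModel, currents: list[float],
                       n_per_current: int, seed: int,
                       rate: float = ACUTE_NEURAL_RATE,
                       pre_ms: float = 5.0, post_ms: float = 25.0,
                       onset_jitter_ms: float = 0.0,
                       condition: str = "baseline") -> list[EvokedTrial]:
    """Simulate peri-stimulus trials (-5 to +25 ms) over a current series."""
    if np.any(np.asarray(currents) < 0):
        raise ValueError("currents must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round((pre_ms + post_ms) * rate / 1e3))
    t_ms = np.arange(n) / rate * 1e3 - pre_ms

    art = np.zeros(n)
    a0, a1 = model.artifact_span
    mid = 0.5 * (a0 + a1)
    art[(t_ms >= a0) & (t_ms < mid)] = 1.0
    art[(t_ms >= mid) & (t_ms < a1)] = -1.0
    resp = _response_kernel(rate, model.latency_span, pre_ms, n)

    trials = []
    for cur in currents:
        amp = model.amplitude(cur)
        for _ in range(n_per_current):
            trace = cur * model.artifact_uv_per_ua * art + amp * resp
            if model.baseline_noise > 0:
                trace = trace + model.baseline_noise * rng.standard_normal(n)
            if onset_jitter_ms:
                shift = int(round(rng.uniform(-onset_jitter_ms,
                                              onset_jitter_ms) * rate / 1e3))
                trace = np.roll(trace, shift)
            trials.append(EvokedTrial(current=float(cur), trace=trace,
                                      rate=rate, pre_ms=pre_ms,
                                      condition=condition))
    return trials


# --------------------------------------------------------------------------
# fictive vocalizations


def make_fictive_vocalizations(patterns: list, trials_per_pattern: int,
                               mapping_spread: float, seed: int,
                               rate: float = AUDIO_RATE,
                               clip_duration: float = 0.25,
                               rendition_jitter: float = 0.025,
                               ) -> tuple[list[AudioClip], list[str]]:
    """Map each stimulation pattern to a distinct syllable and render trials.

    ``mapping_spread`` scales how far pattern-specific acoustics deviate
    from a common base syllable; 0 collapses all patterns onto one spec.
    Stimulation onset is at t = 0 of each clip; sound begins ~5 ms later.
    """
    ids = [getattr(p, "pattern_id", str(p)) for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stimulation patterns")
    if trials_per_pattern < 2:
        raise ValueError("need >= 2 trials per pattern")
    rng = np.random.default_rng(seed)

    # Patterns map onto a factorial grid of the syllable-parameter space
    # (pitch x AM rate x entropy x sweep) so that distinct patterns drive
    # acoustically distinct articulatory states; mapping_spread scales the
    # grid extent (0 collapses every pattern onto the base syllable).
    base_f0 = rng.uniform(1000, 1400)
    dims = (4, 3, 2, 2)  # f0, am_rate, entropy, sweep direction
    n_cells = int(np.prod(dims))

    def level(idx: int, n: int) -> float:
        return (idx / (n - 1) - 0.5) if n > 1 else 0.0

    specs = []
    for k, _ in enumerate(patterns):
        cell = np.unravel_index(k % n_cells, dims)
        wrap = (k // n_cells) * 0.13  # keep cells distinct beyond one cycle
        d = mapping_spread
        f0 = float(np.clip(
            base_f0 * (1 + d * (0.9 * level(cell[0], dims[0]) + wrap)),
            400, 3200))
        sweep = 1 + d * 0.35 * level(cell[3], dims[3]) * 2
        f1 = float(np.clip(f0 * sweep, 400, 3600))
        specs.append(SyllableSpec(
            # spans the full 200 ms analysis window (the fictive
            # vocalization outlasts the stimulation burst)
            duration=0.22,
            pitch_traj=np.linspace(f0, f1, 16),
            am_rate=float(np.clip(
                22 * (1 + d * 1.4 * level(cell[1], dims[1])), 4, 60)),
            fm_depth=60.0,
            entropy_level=float(np.clip(
                -2.0 * (1 + d * 1.1 * level(cell[2], dims[2])), -5, -0.3)),
            amplitude=0.9,
        ))

    clips, labels = [], []
    lead = int(0.005 * rate)
    total = int(clip_duration * rate)
    for pid, spec in zip(ids, specs):
        for _ in range(trials_per_pattern):
            wave = synth_syllable(spec, rng, rate, jitter=rendition_jitter)
            out = np.zeros(total)
            m = min(wave.size, total - lead)
            out[lead:lead + m] = wave[:m]
            out += 1e-4 * rng.standard_normal(total)  # mic noise floor
            clips.append(AudioClip(out, rate))
            labels.append(pid)
    return clips, labels
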