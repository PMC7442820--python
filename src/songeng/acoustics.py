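"""Millisecond-resolution acoustic feature tracks.

Five features are computed for 10 ms windows advancing in 1 ms steps, the
standard bioacoustics parameterization of zebra finch song: pitch
(fundamental, Hz), frequency modulation (spectrogram-derivative angle,
rad), amplitude modulation (relative power derivative, 1/s), Wiener
entropy (log geometric/arithmetic spectral mean, <= 0), and sound envelope
(total band power, dB). The analysis band is 0.3-8 kHz.

The segment is reflect-padded so every millisecond receives an estimate
(track length equals the segment length in ms).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .types import AudioClip, FeatureTrack, SyllableSegment

ANALYSIS_BAND = (300.0, 8000.0)
WINDOW_S = 0.010
STEP_S = 0.001
_EPS = 1e-12


def _frame_segment(x: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Reflect-pad and slice into 10 ms frames centered on each ms."""
    win = int(round(WINDOW_S * rate))
    step = rate * STEP_S
    n_ms = int(round(x.size / rate / STEP_S))
    half = win // 2
    pad = np.pad(x, (half, win), mode="reflect")
    idx = (np.round(np.arange(n_ms) * step).astype(int)[:, None]
           + np.arange(win)[None, :])
    return pad[idx], win


def _pitch_autocorr(frames: np.ndarray, rate: float,
                    fmin: float, fmax: float,
                    voicing_threshold: float = 0.35,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fundamental via autocorrelation peak with parabolic interpolation."""
    n = frames.shape[1]
    fr = frames - frames.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(fr, 2 * n, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), axis=1)[:, :n]
    ac0 = ac[:, 0].copy()
    ac0[ac0 <= _EPS] = _EPS
    acn = ac / ac0[:, None]

    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(rate / fmin)))
    search = acn[:, lag_min:lag_max + 1]
    best = np.argmax(search, axis=1) + lag_min

    # parabolic refinement around the peak lag
    l0 = best
    y_1 = acn[np.arange(len(l0)), l0 - 1]
    y0 = acn[np.arange(len(l0)), l0]
    y1 = acn[np.arange(len(l0)), l0 + 1]
    denom = y_1 - 2 * y0 + y1
    safe = np.where(np.abs(denom) > _EPS, denom, 1.0)
    delta = np.where(np.abs(denom) > _EPS, 0.5 * (y_1 - y1) / safe, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    lag = l0 + delta
    pitch = rate / lag
    conf = y0
    voiced = (conf >= voicing_threshold) & (ac0 > 1e-10)
    pitch = np.where(voiced, pitch, np.nan)
    return pitch, voiced


def compute_features(clip: AudioClip,
                     segment: SyllableSegment | None = None) -> FeatureTrack:
    """Feature track for a segment (or the whole clip), one frame per ms.

    Raises if the segment is shorter than one 10 ms analysis window.
    """
    if segment is not None:
        clip = clip.slice(segment.onset, segment.offset)
    x = clip.samples
    if x.size < int(WINDOW_S * clip.rate):
        raise ValueError("segment shorter than one analysis window")

    frames, win = _frame_segment(x, clip.rate)
    hann = np.hanning(win)
    spec = np.abs(np.fft.rfft(frames * hann, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, 1.0 / clip.rate)
    band = (freqs >= ANALYSIS_BAND[0]) & (freqs <= ANALYSIS_BAND[1])
    # light frequency smoothing tames single-periodogram variance, which
    # otherwise biases the geometric mean (hence Wiener entropy) downward;
    # the floor scales with each frame so features stay gain-invariant
    p = uniform_filter1d(spec[:, band], 9, axis=1, mode="nearest")
    p = p + np.maximum(p.max(axis=1, keepdims=True), _EPS) * 1e-10 + _EPS**2

    total = p.sum(axis=1)
    envelope = 10.0 * np.log10(total)
    wiener = np.mean(np.log(p), axis=1) - np.log(np.mean(p, axis=1))

    # time/frequency partial derivatives of the log-spectrogram
    logp = np.log(p)
    dt = np.gradient(logp, axis=0)  # per ms
    df = np.gradient(logp, axis=1)  # per bin
    wgt = p / total[:, None]
    mdt = np.sum(np.abs(dt) * wgt, axis=1)
    mdf = np.sum(np.abs(df) * wgt, axis=1)
    fm = np.arctan2(mdt, mdf + _EPS)

    lin = total
    grad = np.gradient(lin) / STEP_S  # power/s
    am = grad / lin

    pitch, voiced = _pitch_autocorr(frames * hann, clip.rate,
                                    ANALYSIS_BAND[0], ANALYSIS_BAND[1])

    times = clip.start_time + np.arange(len(total)) * STEP_S
    return FeatureTrack(times=times, pitch=pitch, fm=fm, am=am,
                        wiener_entropy=wiener, envelope=envelope,
                        voiced=voiced)


def summarize_features(track: FeatureTrack) -> dict:
    """Per-feature mean/SD; unvoiced frames are excluded from pitch stats."""
    if len(track) == 0:
        raise ValueError("empty feature track")
    out: dict = {"n_frames": len(track),
                 "n_unvoiced": int(np.sum(~track.voiced.astype(bool)))}
    for name in FeatureTrack.FEATURES:
        vals = getattr(track, name)
        if name == "pitch":
            vals = vals[track.voiced.astype(bool)]
            if vals.size == 0:
                out["pitch_mean"] = None
                out["pitch_sd"] = None
                out["pitch_absent"] = True
                continue
            out["pitch_absent"] = False
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_sd"] = float(np.std(vals))
    return out
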