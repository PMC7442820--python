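"""Song-triggered capture, amplitude segmentation, syllable annotation.

Detection emulates the song-triggered acquisition rule: frames where power
in the song band (2.5-8 kHz) exceeds ``ratio_threshold`` times the power
in the low-frequency noise band (50-250 Hz) mark song; each detected
episode is extended by a post-roll (recording continues after song ends).
Being a ratio of band powers, detection is invariant to waveform gain.

Segmentation thresholds a smoothed amplitude envelope; annotation trains a
small classifier on fixed-size log-spectrogram patches (5000 inputs) and
reports held-out accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .types import AudioClip, SyllableSegment


@dataclass
class DetectorConfig:
    song_band: tuple[float, float] = (2500.0, 8000.0)
    noise_band: tuple[float, float] = (50.0, 250.0)
    ratio_threshold: float = 20.0
    post_roll: float = 1.5
    frame: float = 0.010
    hop: float = 0.005

    def __post_init__(self) -> None:
        if self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be >= 1")
        lo1, hi1 = sorted(self.noise_band)
        lo2, hi2 = sorted(self.song_band)
        if hi1 > lo2:
            raise ValueError("bands must be non-overlapping")

    def validate_rate(self, rate: float) -> None:
        if max(self.song_band) >= rate / 2:
            raise ValueError("song band extends above Nyquist")


def _band_power(clip: AudioClip, cfg: DetectorConfig
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nper = max(int(cfg.frame * clip.rate), 16)
    hop = max(int(cfg.hop * clip.rate), 1)
    freqs, times, sxx = signal.spectrogram(
        clip.samples, fs=clip.rate, window="hann", nperseg=nper,
        noverlap=nper - hop, mode="psd")
    song = sxx[(freqs >= cfg.song_band[0]) & (freqs <= cfg.song_band[1])
               ].sum(axis=0)
    noise = sxx[(freqs >= cfg.noise_band[0]) & (freqs <= cfg.noise_band[1])
                ].sum(axis=0)
    return times, song, noise


def detect_song(clip: AudioClip, cfg: DetectorConfig | None = None
                ) -> list[tuple[float, float]]:
    """Detected episodes as (start_s, end_s), post-roll extended, merged."""
    cfg = cfg or DetectorConfig()
    cfg.validate_rate(clip.rate)
    if clip.duration <= cfg.frame:
        raise ValueError("clip shorter than one analysis frame")
    times, song, noise = _band_power(clip, cfg)
    total = song + noise
    floor = 1e-12 * max(float(total.max()), 1e-30)
    active = song >= cfg.ratio_threshold * (noise + floor)
    active &= song > floor  # silence is not song

    episodes: list[tuple[float, float]] = []
    start = None
    for t, a in zip(times, active):
        if a and start is None:
            start = t - cfg.frame / 2
        elif not a and start is not None:
            episodes.append((max(start, 0.0), t + cfg.post_roll))
            start = None
    if start is not None:
        episodes.append((max(start, 0.0),
                         min(times[-1] + cfg.post_roll, clip.duration
                             + cfg.post_roll)))
    merged: list[tuple[float, float]] = []
    for s, e in episodes:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def amplitude_envelope(clip: AudioClip, smooth_ms: float = 2.0) -> np.ndarray:
    """Rectified waveform smoothed with a boxcar (default 2 ms)."""
    w = max(int(smooth_ms * 1e-3 * clip.rate), 1)
    return ndimage.uniform_filter1d(np.abs(clip.samples), w)


def segment_syllables(clip: AudioClip, threshold: float | None = None,
                      min_dur: float = 0.010, min_gap: float = 0.005,
                      smooth_ms: float = 2.0) -> list[SyllableSegment]:
    """Threshold the smoothed amplitude envelope into syllable segments.

    ``threshold=None`` uses 5% of the envelope peak. Runs shorter than
    ``min_dur`` are dropped; gaps shorter than ``min_gap`` merged.
    """
    env = amplitude_envelope(clip, smooth_ms)
    if threshold is None:
        threshold = 0.05 * float(env.max())
    if threshold <= 0 or not np.any(env > threshold):
        return []
    above = env > threshold
    edges = np.diff(above.astype(int))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(above.size)

    # merge short gaps, then drop short runs
    runs = list(zip(onsets, offsets))
    merged: list[list[int]] = []
    gap = int(min_gap * clip.rate)
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if (e - s) / clip.rate >= min_dur:
            out.append(SyllableSegment(onset=clip.start_time + s / clip.rate,
                                       offset=clip.start_time + e / clip.rate))
    return out


# --------------------------------------------------------------------------
# annotation

_PATCH_SHAPE = (50, 100)  # freq x time -> 5000 classifier inputs


def _syllable_patch(clip: AudioClip, seg: SyllableSegment) -> np.ndarray:
    """Log-spectrogram of the segment resized to a fixed 5000-cell grid."""
    piece = clip.slice(seg.onset, seg.offset)
    nper = max(int(0.005 * clip.rate), 32)
    freqs, _, sxx = signal.spectrogram(
        piece.samples, fs=clip.rate, window="hann", nperseg=nper,
        noverlap=nper // 2, mode="psd")
    keep = freqs <= 8000
    logim = np.log10(sxx[keep] + 1e-12)
    zoom = (_PATCH_SHAPE[0] / logim.shape[0], _PATCH_SHAPE[1] / logim.shape[1])
    patch = ndimage.zoom(logim, zoom, order=1)[:_PATCH_SHAPE[0],
                                               :_PATCH_SHAPE[1]]
    out = np.full(_PATCH_SHAPE, patch.min())
    out[:patch.shape[0], :patch.shape[1]] = patch
    out = (out - out.mean()) / (out.std() + 1e-9)
    return out.ravel()


def annotate_syllables(clip: AudioClip, segments: list[SyllableSegment],
                       training_set: list[tuple[AudioClip, SyllableSegment, str]],
                       classifier: str = "mlp", holdout_fraction: float = 0.25,
                       seed: int = 0) -> tuple[list[SyllableSegment], dict]:
    """Label segments with a classifier trained on labeled exemplars.

    Returns labeled copies of ``segments`` plus a summary with held-out
    accuracy and the confusion matrix over training classes.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import train_test_split
    from sklearn.neural_network import MLPClassifier

    labels = [lbl for _, _, lbl in training_set]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training set must contain >= 2 classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"need >= 2 exemplars per class (class {c!r})")

    X = np.vstack([_syllable_patch(c, s) for c, s, _ in training_set])
    y = np.asarray(labels)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed)
    if classifier == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=600,
                            random_state=seed)
    elif classifier == "logistic":
        clf = LogisticRegression(max_iter=2000, C=1.0)
    else:
        raise ValueError("classifier must be 'mlp' or 'logistic'")
    clf.fit(Xtr, ytr)
    pred_te = clf.predict(Xte)
    summary = {
        "classes": classes,
        "holdout_accuracy": float(np.mean(pred_te == yte)),
        "confusion": confusion_matrix(yte, pred_te, labels=classes),
        "n_train": int(ytr.size), "n_test": int(yte.size),
    }
    labeled = []
    if segments:
        Xq = np.vstack([_syllable_patch(clip, s) for s in segments])
        preds = clf.predict(Xq)
        labeled = [SyllableSegment(s.onset, s.offset, str(p))
                   for s, p in zip(segments, preds)]
    return labeled, summary
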