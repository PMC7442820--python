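"""Current-steering stimulation patterns and fictive-vocalization embedding.

A stimulation pattern assigns each electrode of the 2 x 3 grid a role
(cathodic-leading source, anodic-leading source, return, or off) plus a
shared amplitude; bursts are charge-balanced biphasic pulse trains
(default 100 pulses at 1 kHz, 200 us per phase). Within an experiment the
total source current is held constant across patterns, so differences in
the evoked output reflect the spatial pattern alone.

Fictive vocalizations are vectorized as 200 ms log-spectrograms (5 ms
window, 1 ms advance, 512-point transform, bins above 8 kHz discarded:
200 timesteps x 91 bins = 18,200 values), reduced to 50 principal
components and embedded in 2-D with t-SNE (Euclidean, perplexity 35).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AudioClip

ROLES = ("cathodic", "anodic", "return", "off")
N_ELECTRODES = 6  # 2 x 3 grid
SPEC_TIMESTEPS = 200
SPEC_BINS = 91
VECTOR_LEN = SPEC_TIMESTEPS * SPEC_BINS  # 18,200


@dataclass
class StimPattern:
    """Per-electrode role assignment over the 2 x 3 grid."""

    pattern_id: str
    roles: tuple[str, ...]
    amplitude: float  # uA per source electrode
    pulses: int = 100
    pulse_rate: float = 1000.0
    phase_width: float = 200.0  # us per phase

    def __post_init__(self) -> None:
        if len(self.roles) != N_ELECTRODES:
            raise ValueError(f"need {N_ELECTRODES} electrode roles")
        bad = [r for r in self.roles if r not in ROLES]
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    @property
    def n_sources(self) -> int:
        return sum(r in ("cathodic", "anodic") for r in self.roles)

    @property
    def total_source_current(self) -> float:
        return self.amplitude * self.n_sources


@dataclass
class VocalizationVector:
    values: np.ndarray
    label: str | None = None
    shape: tuple[int, int] = (SPEC_TIMESTEPS, SPEC_BINS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size != self.shape[0] * self.shape[1]:
            raise ValueError("vector length must equal timesteps x bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("vector entries must be finite")


def validate_pattern(p: StimPattern) -> list[str]:
    """Single-pattern checks; returns a list of violations (empty = ok)."""
    violations = []
    if p.n_sources == 0:
        violations.append("no source electrode (cathodic or anodic)")
    if "return" not in p.roles:
        violations.append("no return electrode")
    if p.amplitude <= 0:
        violations.append("amplitude must be positive")
    if p.phase_width <= 0:
        violations.append("phase width must be positive (charge balance "
                          "assumes equal biphasic phases)")
    if p.pulses < 1:
        violations.append("needs at least one pulse")
    return violations


def validate_pattern_set(patterns: list[StimPattern],
                         rtol: float = 1e-6) -> dict[str, list[str]]:
    """Per-pattern violations plus the constant-total-current constraint."""
    out = {p.pattern_id: validate_pattern(p) for p in patterns}
    totals = [p.total_source_current for p in patterns
              if not out[p.pattern_id]]
    if totals and (max(totals) - min(totals)) > rtol * max(totals):
        for p in patterns:
            out[p.pattern_id].append(
                "total source current differs across the pattern set")
    return out


def grid_pattern(pattern_id: str, sources: list[int], returns: list[int],
                 amplitude: float, anodic: list[int] | None = None,
                 **kwargs) -> StimPattern:
    """Convenience constructor from electrode index lists (0..5)."""
    roles = ["off"] * N_ELECTRODES
    for i in sources:
        roles[i] = "cathodic"
    for i in anodic or []:
        roles[i] = "anodic"
    for i in returns:
        roles[i] = "return"
    return StimPattern(pattern_id, tuple(roles), amplitude, **kwargs)


def default_pattern_set(n_patterns: int = 24,
                        total_current: float = 100.0) -> list[StimPattern]:
    """A set of distinct source/return assignments at constant total current.

    Enumerates single- and dual-source configurations over the 2 x 3 grid,
    scaling per-electrode amplitude so the summed source current matches
    ``total_current`` for every pattern.
    """
    configs: list[tuple[list[int], list[int]]] = []
    for s in range(N_ELECTRODES):
        for r in range(N_ELECTRODES):
            if r != s:
                configs.append(([s], [r]))
    if len(configs) < n_patterns:
        for s1 in range(N_ELECTRODES):
            for s2 in range(s1 + 1, N_ELECTRODES):
                rest = [e for e in range(N_ELECTRODES) if e not in (s1, s2)]
                configs.append(([s1, s2], rest[:1]))
    patterns = []
    for k, (src, ret) in enumerate(configs[:n_patterns]):
        patterns.append(grid_pattern(f"p{k:02d}", src, ret,
                                     amplitude=total_current / len(src)))
    return patterns


# --------------------------------------------------------------------------
# vectorization

def vectorize_vocalization(clip: AudioClip, onset: float = 0.0,
                           nfft: int = 512, floor_db: float = -60.0
                           ) -> VocalizationVector:
    """200 ms of audio from stimulation onset as an 18,200-value vector.

    Frames are 5 ms Hann windows advancing 1 ms over a 512-point
    transform; bins above 8 kHz are discarded (the DC bin is excluded,
    leaving the 91 bins up to ~7.85 kHz at 44.15 kHz). Log magnitudes are
    clamped at ``floor_db`` so that sub-noise-floor bins do not dominate
    distances between vectors.
    """
    rate = clip.rate
    i0 = int(round((onset - clip.start_time) * rate))
    need = i0 + int(round(0.200 * rate))
    if i0 < 0 or need > clip.samples.size:
        raise ValueError("clip does not cover onset + 200 ms")
    win = int(round(0.005 * rate))
    hop = rate * 0.001
    x = clip.samples
    # reflect-pad the tail so late frames keep full 5 ms support
    pad_end = i0 + int(SPEC_TIMESTEPS * hop) + win - x.size
    if pad_end > 0:
        x = np.pad(x, (0, pad_end), mode="reflect")
    starts = i0 + np.round(np.arange(SPEC_TIMESTEPS) * hop).astype(int)
    frames = x[starts[:, None] + np.arange(win)[None, :]]
    spec = np.abs(np.fft.rfft(frames * np.hanning(win), n=nfft, axis=1)) ** 2
    sub = spec[:, 1:SPEC_BINS + 1]  # bins 1..91: 86-7847 Hz
    logspec = 10.0 * np.log10(sub + 10 ** (floor_db / 10.0))
    return VocalizationVector(values=logspec.ravel())


def embed_vocalizations(vectors: list[VocalizationVector],
                        n_components: int = 50, perplexity: float = 35.0,
                        seed: int = 0) -> pd.DataFrame:
    """PCA to 50 components, then 2-D t-SNE (Euclidean, perplexity 35).

    The t-SNE is initialized from the (scaled) PCA projection with a fixed
    seed, so coordinates are reproducible. With few samples the component
    count and perplexity are reduced with a warning.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = np.vstack([v.values for v in vectors])
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 vocalizations to embed")
    k = min(n_components, n - 1, X.shape[1])
    if k < n_components:
        warnings.warn(f"reducing PCA components to {k} for n={n} samples",
                      stacklevel=2)
    pca = PCA(n_components=k, random_state=seed)
    Z = pca.fit_transform(X)

    max_perp = (n - 1) / 3.0
    perp = perplexity
    if perp >= max_perp:
        perp = max(1.0, max_perp - 1e-3)
        warnings.warn(f"reducing perplexity to {perp:.1f} for n={n} samples",
                      stacklevel=2)
    init = Z[:, :2] / (Z[:, 0].std() + 1e-12) * 1e-4
    tsne = TSNE(n_components=2, perplexity=perp, metric="euclidean",
                init=init, random_state=seed)
    Y = tsne.fit_transform(Z)
    return pd.DataFrame({
        "x": Y[:, 0], "y": Y[:, 1],
        "label": [v.label for v in vectors],
        "trial": np.arange(n),
        "seed": seed,
    })


def knn_label_purity(coords: pd.DataFrame, k: int = 5) -> float:
    """Mean fraction of each point's k nearest neighbors sharing its label."""
    xy = coords[["x", "y"]].to_numpy()
    labels = np.asarray(coords["label"])
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k]
    return float(np.mean(labels[nn] == labels[:, None]))
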