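"""Acoustic-similarity statistic with an empirical null.

Two vocal elements are compared by pairwise millisecond-by-millisecond
distances between their five-feature tracks; the median Euclidean distance
is converted into a P-value-like score on [0, 1] using the empirical
distribution of median distances between unrelated songs (distinct birds).
A score of 1 means acoustically identical; 0 means as different as two
unrelated songs.

Features are z-scored by the null's pooled per-feature center/scale before
distance computation (the five features have incommensurate units). Frame
pairs in which either frame is unvoiced drop the pitch dimension and are
rescaled by sqrt(5/4).

Millisecond pairs are time-aligned by default (the i-th millisecond of one
rendition against the i-th of the other), which makes the scale endpoint
exact: an element compared with an identical copy has median distance 0
and scores 1 against any non-degenerate null. The all-cross-pairs
alternative is available via ``pairing='cartesian'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import FeatureTrack

_N_FEAT = 5
_PITCH = 0  # column index of pitch in FeatureTrack.matrix()


@dataclass
class SimilarityNull:
    """Empirical distance distributions from unrelated-song pairs.

    ``pair_medians`` (one median 5-D distance per cross-bird song pair)
    defines the scoring ECDF; ``distances`` keeps a capped subsample of the
    pooled per-millisecond distances underlying those medians. ``center`` /
    ``scale`` are the pooled per-feature standardization.
    """

    pair_medians: np.ndarray
    distances: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    n_songs: int = 20

    def __post_init__(self) -> None:
        self.pair_medians = np.sort(np.asarray(self.pair_medians, float))
        self.distances = np.sort(np.asarray(self.distances, float))
        if self.pair_medians.size == 0 or self.distances.size == 0:
            raise ValueError("null distributions must be non-empty")
        if np.any(np.asarray(self.scale) <= 0):
            raise ValueError("scales must be strictly positive")
        if np.any(self.pair_medians <= 0):
            warnings.warn("degenerate null: some unrelated pairs have zero "
                          "median distance; scores will collapse toward 0",
                          stacklevel=2)


@dataclass
class SimilarityScore:
    value: float
    median_distance: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("similarity score must lie in [0, 1]")


def _standardize(track: FeatureTrack, center: np.ndarray,
                 scale: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = (track.matrix() - center) / scale
    return m, track.voiced.astype(bool)


def _pair_distances(za: np.ndarray, va: np.ndarray, zb: np.ndarray,
                    vb: np.ndarray, cap: int,
                    rng: np.random.Generator,
                    pairing: str = "aligned") -> np.ndarray:
    """Millisecond-pair distances between two standardized tracks.

    ``pairing='aligned'`` compares the i-th millisecond of each track
    (truncated to the shorter length); ``'cartesian'`` takes all cross
    pairs, subsampled above ``cap``.
    """
    na, nb = za.shape[0], zb.shape[0]
    if pairing == "aligned":
        n = min(na, nb)
        ia = ib = np.arange(n)
    elif pairing == "cartesian":
        total = na * nb
        if total > cap:
            flat = rng.choice(total, size=cap, replace=False)
            ia, ib = flat // nb, flat % nb
        else:
            ia, ib = np.repeat(np.arange(na), nb), np.tile(np.arange(nb), na)
    else:
        raise ValueError("pairing must be 'aligned' or 'cartesian'")
    diff = za[ia] - zb[ib]
    both_voiced = va[ia] & vb[ib]
    sq = diff[:, 1:] ** 2  # non-pitch features
    d2 = sq.sum(axis=1)
    pitch_sq = np.where(both_voiced, np.nan_to_num(diff[:, _PITCH]) ** 2, 0.0)
    d2_full = d2 + pitch_sq
    # unvoiced pairs: 4-D distance rescaled to the 5-D scale
    d2_out = np.where(both_voiced, d2_full, d2 * (_N_FEAT / (_N_FEAT - 1)))
    return np.sqrt(d2_out)


def _fit_scaler(tracks: list[FeatureTrack]) -> tuple[np.ndarray, np.ndarray]:
    mats = np.vstack([t.matrix() for t in tracks])
    center = np.zeros(_N_FEAT)
    scale = np.zeros(_N_FEAT)
    for j in range(_N_FEAT):
        col = mats[:, j]
        col = col[np.isfinite(col)]
        center[j] = np.mean(col) if col.size else 0.0
        sd = np.std(col) if col.size else 1.0
        scale[j] = sd if sd > 0 else 1.0
    return center, scale


def build_null(tracks: list[FeatureTrack], bird_ids: list[str],
               pooled_cap: int = 100_000, per_pair_cap: int = 40_000,
               seed: int = 0, pairing: str = "aligned") -> SimilarityNull:
    """Build the unrelated-song null from feature tracks of distinct birds.

    Every cross-bird track pair contributes one median distance to the
    scoring ECDF; pooled per-ms distances (capped) define the z-scaler
    retrospective record. Raises if all tracks come from a single bird.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two songs")
    if len(set(bird_ids)) < 2:
        raise ValueError("null requires songs from >= 2 distinct birds")
    rng = np.random.default_rng(seed)
    center, scale = _fit_scaler(tracks)
    zs = [_standardize(t, center, scale) for t in tracks]

    medians, pooled = [], []
    pairs = [(i, j) for i in range(len(tracks))
             for j in range(i + 1, len(tracks))
             if bird_ids[i] != bird_ids[j]]
    keep_per_pair = max(1, pooled_cap // max(len(pairs), 1))
    for i, j in pairs:
        d = _pair_distances(zs[i][0], zs[i][1], zs[j][0], zs[j][1],
                            per_pair_cap, rng, pairing)
        medians.append(np.median(d))
        if d.size > keep_per_pair:
            pooled.append(rng.choice(d, size=keep_per_pair, replace=False))
        else:
            pooled.append(d)
    return SimilarityNull(pair_medians=np.asarray(medians),
                          distances=np.concatenate(pooled),
                          center=center, scale=scale,
                          n_songs=len(set(bird_ids)))


def similarity(a: FeatureTrack, b: FeatureTrack, null: SimilarityNull,
               pair_cap: int = 1_000_000, seed: int = 0,
               pairing: str = "aligned") -> SimilarityScore:
    """Score two tracks against the null: 1 - ECDF(median 5-D distance).

    The ECDF is right-continuous with ties favoring similarity, so the
    score is the fraction of null pair-medians >= the observed median;
    identical tracks score exactly 1 whenever the null has no zero
    distances. Symmetric in (a, b). ``pairing`` should match the null's
    construction (default: time-aligned millisecond pairs).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty feature track")
    rng = np.random.default_rng(seed)
    za, va = _standardize(a, null.center, null.scale)
    zb, vb = _standardize(b, null.center, null.scale)
    d = _pair_distances(za, va, zb, vb, pair_cap, rng, pairing)
    med = float(np.median(d))
    value = float(np.mean(null.pair_medians >= med))
    return SimilarityScore(value=value, median_distance=med, n_pairs=d.size)


def baseline_similarity_course(pre_tracks: dict[str, list[FeatureTrack]],
                               post_tracks_by_day: dict[int, dict[str, list[FeatureTrack]]],
                               null: SimilarityNull,
                               max_pairs_per_type: int = 100,
                               seed: int = 0) -> "pd.DataFrame":
    """Per-day mean similarity of post-manipulation song to baseline.

    ``pre_tracks`` maps syllable label -> baseline renditions; each day of
    ``post_tracks_by_day`` maps label -> renditions. Days are compared on
    the label intersection (missing classes reported); the course is
    normalized to the pre-vs-pre (split-half) baseline mean.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)

    def mean_sim(xs: list[FeatureTrack], ys: list[FeatureTrack]) -> float:
        pairs = [(x, y) for x in xs for y in ys if x is not y]
        if len(pairs) > max_pairs_per_type:
            idx = rng.choice(len(pairs), max_pairs_per_type, replace=False)
            pairs = [pairs[i] for i in idx]
        return float(np.mean([similarity(x, y, null).value
                              for x, y in pairs]))

    base = np.mean([mean_sim(v, v) for v in pre_tracks.values()
                    if len(v) >= 2])
    rows = []
    for day in sorted(post_tracks_by_day):
        day_tracks = post_tracks_by_day[day]
        common = sorted(set(pre_tracks) & set(day_tracks))
        missing = sorted(set(pre_tracks) ^ set(day_tracks))
        vals = [mean_sim(pre_tracks[lbl], day_tracks[lbl]) for lbl in common]
        rows.append({"day": day, "mean_similarity": float(np.mean(vals)),
                     "normalized": float(np.mean(vals) / base),
                     "n_types": len(common),
                     "missing_types": ";".join(missing)})
    return pd.DataFrame(rows)


def within_across_similarity(tracks: list[FeatureTrack], labels: list[str],
                             null: SimilarityNull | None = None,
                             max_pairs: int = 2000, seed: int = 0,
                             ) -> dict:
    """Mean pairwise similarity within vs. across label groups.

    If no null is supplied one is built treating the labels as the
    unrelated-group identities. Labels with a single trial are excluded
    from the within-group mean and reported.
    """
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 labels")
    labels = list(labels)
    if null is None:
        null = build_null(tracks, labels, seed=seed)
    rng = np.random.default_rng(seed)

    idx_by_label: dict[str, list[int]] = {}
    for i, lbl in enumerate(labels):
        idx_by_label.setdefault(lbl, []).append(i)
    singletons = [lbl for lbl, ix in idx_by_label.items() if len(ix) < 2]

    within_pairs = [(i, j) for ix in idx_by_label.values()
                    for a, i in enumerate(ix) for j in ix[a + 1:]]
    across_pairs = [(i, j) for i in range(len(tracks))
                    for j in range(i + 1, len(tracks))
                    if labels[i] != labels[j]]

    def sample(pairs: list) -> list:
        if len(pairs) > max_pairs:
            sel = rng.choice(len(pairs), max_pairs, replace=False)
            return [pairs[k] for k in sel]
        return pairs

    def mean_score(pairs: list) -> float:
        return float(np.mean([similarity(tracks[i], tracks[j], null).value
                              for i, j in pairs]))

    return {"within_mean": mean_score(sample(within_pairs)),
            "across_mean": mean_score(sample(across_pairs)),
            "excluded_singleton_labels": singletons,
            "n_within_pairs": min(len(within_pairs), max_pairs),
            "n_across_pairs": min(len(across_pairs), max_pairs)}
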