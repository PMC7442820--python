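"""Shared fixtures: synthetic birds, songs, feature tracks, and a
20-song similarity null, built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from songeng import acoustics, similarity, songdetect, synthgen

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def motif_tracks(bird_id: str, seed: int, n_motifs: int = 1):
    """Feature track per motif rendition of one bird's song."""
    bird = synthgen.random_bird(bird_id)
    clip, ann = synthgen.make_song(bird, n_motifs, seed=seed)
    tracks = []
    for _, grp in ann.groupby("motif"):
        seg = songdetect.SyllableSegment(grp.onset_s.min(),
                                         grp.offset_s.max())
        tracks.append(acoustics.compute_features(clip, seg))
    return tracks


@pytest.fixture(scope="session")
def make_motif_tracks():
    return motif_tracks


@pytest.fixture(scope="session")
def bird_a():
    return synthgen.random_bird("A")


@pytest.fixture(scope="session")
def song_a(bird_a):
    clip, ann = synthgen.make_song(bird_a, 2, seed=1)
    return clip, ann


@pytest.fixture(scope="session")
def null_tracks():
    """Tracks and ids from 20 unrelated synthetic songs (3 renditions)."""
    tracks, ids = [], []
    for i in range(20):
        for tr in motif_tracks(f"null{i}", seed=1000 + i, n_motifs=3):
            tracks.append(tr)
            ids.append(f"null{i}")
    return tracks, ids


@pytest.fixture(scope="session")
def similarity_null(null_tracks):
    tracks, ids = null_tracks
    return similarity.build_null(tracks, ids, seed=0)


@pytest.fixture(scope="session")
def tone_clip():
    t = np.arange(int(0.2 * 44150)) / 44150
    return synthgen.AudioClip(0.5 * np.sin(2 * np.pi * 1000 * t))
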