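"""File I/O for the standard interchange formats.

Audio is 16-bit PCM WAV at 44,150 Hz nominal; annotations travel as CSV
(onset_s, offset_s, label); neural traces as an HDF5 container with rate
and on/off-nerve role attributes; similarity nulls as versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .similarity import SimilarityNull
from .types import AudioClip, NeuralTraces, SyllableSegment

NULL_FORMAT_VERSION = 1


def write_wav(path: str | Path, clip: AudioClip) -> None:
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(clip.rate)),
                  (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> AudioClip:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioClip(np.asarray(data, float), float(rate))


def write_annotations(path: str | Path,
                      segments: list[SyllableSegment]) -> None:
    pd.DataFrame([{"onset_s": s.onset, "offset_s": s.offset,
                   "label": s.label or ""} for s in segments]
                 ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[SyllableSegment]:
    df = pd.read_csv(path)
    return [SyllableSegment(r.onset_s, r.offset_s,
                            str(r.label) if pd.notna(r.label) and r.label
                            else None)
            for r in df.itertuples()]


def write_traces(path: str | Path, traces: NeuralTraces) -> None:
    import h5py

    with h5py.File(str(path), "w") as fh:
        ds = fh.create_dataset("voltages_uv", data=traces.voltages)
        ds.attrs["rate_hz"] = traces.rate
        ds.attrs["role"] = traces.role
        ds.attrs["channel_ids"] = traces.channel_ids


def read_traces(path: str | Path) -> NeuralTraces:
    import h5py

    with h5py.File(str(path), "r") as fh:
        ds = fh["voltages_uv"]
        return NeuralTraces(ds[()], float(ds.attrs["rate_hz"]),
                            str(ds.attrs["role"]),
                            list(ds.attrs["channel_ids"]))


def write_null(path: str | Path, null: SimilarityNull) -> None:
    payload = {
        "format_version": NULL_FORMAT_VERSION,
        "n_songs": null.n_songs,
        "center": null.center.tolist(),
        "scale": null.scale.tolist(),
        "pair_medians": null.pair_medians.tolist(),
        "distances": null.distances.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_null(path: str | Path) -> SimilarityNull:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != NULL_FORMAT_VERSION:
        raise ValueError("unsupported similarity-null format version")
    return SimilarityNull(
        pair_medians=np.asarray(payload["pair_medians"]),
        distances=np.asarray(payload["distances"]),
        center=np.asarray(payload["center"]),
        scale=np.asarray(payload["scale"]),
        n_songs=int(payload["n_songs"]))
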