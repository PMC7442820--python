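"""Pipeline orchestration, configuration, and statistical summaries.

``run_pipeline`` executes the synthetic end-to-end chain (song synthesis
-> detection -> segmentation -> features -> similarity null -> nerve
recording -> preprocessing -> alignment -> stability metrics) in
dependency order and writes metrics, logs and the resolved configuration
to an artifact directory; identical (config, seed) runs produce identical
metric files.

``summarize`` wraps the standard tests used throughout (paired/unpaired
t-tests, repeated-measures ANOVA with Dunnett contrasts) and annotates
p-values with the conventional star schema (* <0.05, ** <0.01,
*** <0.001).
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import acoustics, neuralproc, similarity, songdetect, stability, synthgen


@dataclass
class RunConfig:
    """Resolved parameters for a synthetic end-to-end run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ("synth", "detect", "features", "similarity",
                               "neural", "stability")
    n_birds: int = 3
    n_motifs: int = 5
    n_null_songs: int = 8
    ratio_threshold: float = 20.0
    envelope_window_ms: float = 5.0
    bandpass_hz: tuple[float, float] = (300.0, 6000.0)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class StatSummary:
    rows: pd.DataFrame
    design: str
    correction: str | None = None


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, sym in _STARS:
        if p < cut:
            return sym
    return ""


def summarize(groups: dict[str, np.ndarray], design: str,
              control: str | None = None) -> StatSummary:
    """Group means +/- SD with the requested test and star annotations.

    ``design``: 'paired_t' (two groups, matched), 'unpaired_t' (two
    groups), or 'rm_anova_dunnett' (>= 2 conditions, matched per subject,
    Dunnett contrasts against ``control``).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], float) for k in names]
    base_rows = [{"group": k, "n": a.size, "mean": float(a.mean()),
                  "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0}
                 for k, a in zip(names, arrays)]

    if design in ("paired_t", "unpaired_t"):
        if len(arrays) != 2:
            raise ValueError("t-test designs need exactly two groups")
        if design == "paired_t":
            if arrays[0].size != arrays[1].size:
                raise ValueError("paired design requires equal group sizes")
            t, p = stats.ttest_rel(arrays[0], arrays[1])
        else:
            t, p = stats.ttest_ind(arrays[0], arrays[1])
        rows = pd.DataFrame(base_rows)
        rows["test"] = design
        rows["statistic"] = float(t)
        rows["p"] = float(p)
        rows["stars"] = stars(float(p))
        return StatSummary(rows=rows, design=design, correction=None)

    if design == "rm_anova_dunnett":
        control = control or names[0]
        if control not in names:
            raise ValueError("control group not among the groups")
        sizes = {a.size for a in arrays}
        if len(sizes) != 1:
            raise ValueError("repeated-measures design requires matched "
                             "subjects across conditions")
        others = [k for k in names if k != control]
        res = stats.dunnett(*[np.asarray(groups[k], float) for k in others],
                            control=np.asarray(groups[control], float))
        rows = pd.DataFrame(base_rows)
        pmap = dict(zip(others, res.pvalue))
        rows["test"] = "dunnett_vs_" + control
        rows["statistic"] = [dict(zip(others, res.statistic)).get(g, np.nan)
                             for g in rows["group"]]
        rows["p"] = [pmap.get(g, np.nan) for g in rows["group"]]
        rows["stars"] = [stars(p) if np.isfinite(p) else ""
                         for p in rows["p"]]
        return StatSummary(rows=rows, design=design,
                           correction="dunnett")
    raise ValueError(f"unsupported design {design!r}")


def run_pipeline(config: RunConfig | dict) -> Path:
    """Execute the selected synthetic stages and write artifacts.

    Raises a dependency error when a stage is requested without its
    upstream stage. Returns the artifact directory.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    order = ("synth", "detect", "features", "similarity", "neural",
             "stability")
    selected = [s for s in order if s in config.stages]
    for i, s in enumerate(selected):
        upstream = order[:order.index(s)]
        missing = [u for u in upstream if u not in selected]
        if missing:
            raise ValueError(f"stage {s!r} requires upstream stages "
                             f"{missing}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    metrics: dict[str, object] = {}

    def mark(stage: str, t0: float) -> None:
        log.append({"stage": stage, "seconds": round(time.time() - t0, 3)})

    rng_seed = config.seed
    birds = [synthgen.random_bird(f"bird{i}", seed=rng_seed + i)
             for i in range(config.n_birds)]
    songs, annots = [], []
    if "synth" in selected:
        t0 = time.time()
        for i, b in enumerate(birds):
            clip, ann = synthgen.make_song(b, config.n_motifs,
                                           seed=rng_seed + 100 + i)
            songs.append(clip)
            annots.append(ann)
            ann.to_csv(outdir / f"annotations_bird{i}.csv", index=False)
        mark("synth", t0)

    if "detect" in selected:
        t0 = time.time()
        cfg = songdetect.DetectorConfig(ratio_threshold=config.ratio_threshold)
        det_rows = []
        for i, clip in enumerate(songs):
            for s, e in songdetect.detect_song(clip, cfg):
                det_rows.append({"bird": i, "start_s": s, "end_s": e})
        pd.DataFrame(det_rows).to_csv(outdir / "detections.csv", index=False)
        metrics["n_detections"] = len(det_rows)
        mark("detect", t0)

    tracks_by_bird: list[list] = []
    if "features" in selected:
        t0 = time.time()
        for i, (clip, ann) in enumerate(zip(songs, annots)):
            tracks = []
            for _, row in ann.iterrows():
                seg = songdetect.SyllableSegment(row.onset_s, row.offset_s,
                                                 row.label)
                tracks.append(acoustics.compute_features(clip, seg))
            tracks_by_bird.append(tracks)
        metrics["n_feature_tracks"] = int(sum(map(len, tracks_by_bird)))
        mark("features", t0)

    if "similarity" in selected:
        t0 = time.time()
        null_birds = [synthgen.random_bird(f"null{i}", seed=rng_seed + 500 + i)
                      for i in range(config.n_null_songs)]
        null_tracks, null_ids = [], []
        for i, b in enumerate(null_birds):
            clip, ann = synthgen.make_song(b, 1, seed=rng_seed + 600 + i)
            row = ann.iloc[0]
            seg = songdetect.SyllableSegment(row.onset_s, row.offset_s)
            null_tracks.append(acoustics.compute_features(clip, seg))
            null_ids.append(b.bird_id)
        null = similarity.build_null(null_tracks, null_ids, seed=rng_seed)
        scores = []
        for i in range(len(tracks_by_bird)):
            for j in range(i + 1, len(tracks_by_bird)):
                sc = similarity.similarity(tracks_by_bird[i][0],
                                           tracks_by_bird[j][0], null)
                scores.append({"bird_a": i, "bird_b": j,
                               "score": sc.value})
        pd.DataFrame(scores).to_csv(outdir / "cross_bird_similarity.csv",
                                    index=False)
        metrics["mean_cross_bird_similarity"] = (
            float(np.mean([s["score"] for s in scores])) if scores else None)
        mark("similarity", t0)

    records: list[stability.MotifRecord] = []
    noise_by_day: dict[int, object] = {}
    if "neural" in selected:
        t0 = time.time()
        model = synthgen.NerveModel()
        lo, hi = config.bandpass_hz
        for i, ann in enumerate(annots):
            traces = synthgen.make_nerve_recording(ann, model,
                                                   seed=rng_seed + 900 + i)
            proc = neuralproc.bandpass_filter(
                neuralproc.common_mode_subtract(traces), lo, hi)
            env = neuralproc.envelope(proc,
                                      window_ms=config.envelope_window_ms)
            for m, grp in ann.groupby("motif"):
                o, f = grp.onset_s.min(), grp.offset_s.max()
                sl = slice(int(o * 1000), int(f * 1000))
                sub = stability.MotifRecord(
                    day=1, motif_index=int(m),
                    aligned_envelope=neuralproc.EnvelopeTrace(
                        env.values[sl], env.times[sl],
                        config.envelope_window_ms),
                    raw_window=neuralproc.NeuralTraces(
                        proc.voltages[:, int(o * proc.rate):
                                      int(f * proc.rate)], proc.rate),
                    unwarped_duration=float(f - o))
                records.append(sub)
            tail = proc.voltages[:, -int(0.5 * proc.rate):]
            noise_by_day[1] = neuralproc.NeuralTraces(tail, proc.rate)
        mark("neural", t0)

    if "stability" in selected:
        t0 = time.time()
        rep_rows = []
        for r in records:
            rep_rows.append({
                "day": r.day, "motif": r.motif_index,
                "vpp_uv": stability.motif_vpp(r),
                "snr_db": stability.singing_snr(r, noise_by_day[1]),
                "event_rate_hz": stability.event_rate(r)})
        pd.DataFrame(rep_rows).to_csv(outdir / "stability_metrics.csv",
                                      index=False)
        metrics["mean_vpp_uv"] = float(np.mean([r["vpp_uv"]
                                                for r in rep_rows]))
        mark("stability", t0)

    (outdir / "config.json").write_text(config.to_json())
    (outdir / "log.json").write_text(json.dumps({
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": log}, indent=2))
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return outdir
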