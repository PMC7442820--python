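"""Nerve-function assay via acoustic similarity: compare post-manipulation
song to baseline for three synthetic conditions -- intact-like controls
(same bird, later renditions), sham (same bird), and a crush-like
disruption (song structure replaced, emulated by a different bird's
syllables).

Writes: results/02_similarity_course.csv, results/02_group_summary.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from songeng import acoustics, report, similarity, songdetect, synthgen

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 2


def syllable_tracks(bird_id, seed, n_motifs=4):
    bird = synthgen.random_bird(bird_id)
    clip, ann = synthgen.make_song(bird, n_motifs, seed=seed)
    by_label = {}
    for _, r in ann.iterrows():
        seg = songdetect.SyllableSegment(r.onset_s, r.offset_s, r.label)
        by_label.setdefault(r.label, []).append(
            acoustics.compute_features(clip, seg))
    return by_label


null_tracks, null_ids = [], []
for i in range(20):
    for label, trs in syllable_tracks(f"null{i}", seed=900 + i,
                                      n_motifs=2).items():
        null_tracks.extend(trs)
        null_ids.extend([f"null{i}"] * len(trs))
null = similarity.build_null(null_tracks, null_ids, seed=SEED)

rows = []
for cond in ("intact", "sham", "crush"):
    for b in range(3):
        pre = syllable_tracks(f"{cond}{b}", seed=100 * b + 11)
        if cond == "crush":
            post = {1: syllable_tracks(f"crushed{b}", seed=100 * b + 21),
                    8: syllable_tracks(f"crushed{b}", seed=100 * b + 31)}
        else:
            post = {1: syllable_tracks(f"{cond}{b}", seed=100 * b + 21),
                    8: syllable_tracks(f"{cond}{b}", seed=100 * b + 31)}
        course = similarity.baseline_similarity_course(pre, post, null,
                                                       seed=SEED)
        for _, r in course.iterrows():
            rows.append({"condition": cond, "bird": b, "day": int(r.day),
                         "normalized_similarity": r.normalized})

df = pd.DataFrame(rows)
df.to_csv(OUT / "02_similarity_course.csv", index=False)

summary_rows = []
for (cond, day), grp in df.groupby(["condition", "day"]):
    summary_rows.append({"condition": cond, "day": day,
                         "mean": grp.normalized_similarity.mean(),
                         "sd": grp.normalized_similarity.std(ddof=1),
                         "n_birds": len(grp)})
summary = pd.DataFrame(summary_rows)
summary.to_csv(OUT / "02_group_summary.csv", index=False)
print(summary.round(3).to_string(index=False))

day1 = df[df.day == 1]
stat = report.summarize(
    {"intact": day1[day1.condition == "intact"]
     .normalized_similarity.to_numpy(),
     "crush": day1[day1.condition == "crush"]
     .normalized_similarity.to_numpy()}, "unpaired_t")
p = stat.rows.p.iloc[0]
print(f"finding: crush-like disruption drops normalized similarity far "
      f"below intact controls on day 1 (unpaired t, p={p:.4g}); intact and "
      f"sham stay near 1.")
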