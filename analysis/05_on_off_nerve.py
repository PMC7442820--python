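"""Neuronal origin of the recorded signal: simultaneous on-nerve and
off-nerve devices on the same timeline. Only the on-nerve device couples
to the singing-locked envelope; both see the same class of common-mode
artifact. Compares per-trial SNR and envelope correlations against a
circular-shift bootstrap CI for zero correlation.

Writes: results/05_on_off_trials.csv, results/05_summary.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from songeng import neuralproc, stability, synthgen

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 5
N_TRIALS = 40

bird = synthgen.random_bird("onoff")
on_model = synthgen.NerveModel(on_nerve=True)
off_model = synthgen.NerveModel(on_nerve=False, artifact_gain=60.0,
                                noise_sd=10.0)

on_recs, off_recs = [], []
noise_on = noise_off = None
for k in range(N_TRIALS):
    clip, ann = synthgen.make_song(bird, 1, seed=SEED + 10 * k)
    tr_on = synthgen.make_nerve_recording(ann, on_model, seed=900 + k)
    tr_off = synthgen.make_nerve_recording(ann, off_model, seed=5900 + k)
    for role, tr, store in (("on", tr_on, on_recs), ("off", tr_off,
                                                     off_recs)):
        proc = neuralproc.bandpass_filter(
            neuralproc.common_mode_subtract(tr))
        env = neuralproc.envelope(proc, window_ms=5.0)
        o, f = ann.onset_s.min(), ann.offset_s.max()
        raw = neuralproc.NeuralTraces(
            proc.voltages[:, int(o * proc.rate):int(f * proc.rate)],
            proc.rate)
        rec = stability.MotifRecord(
            day=1, motif_index=k,
            aligned_envelope=neuralproc.EnvelopeTrace(
                env.values[int(o * 1000):int(f * 1000)],
                env.times[int(o * 1000):int(f * 1000)], 5.0),
            raw_window=raw, unwarped_duration=float(f - o))
        store.append(rec)
        if k == 0:
            tail = neuralproc.NeuralTraces(
                proc.voltages[:, -int(0.5 * proc.rate):], proc.rate)
            if role == "on":
                noise_on = tail
            else:
                noise_off = tail

res = stability.on_off_nerve_compare(on_recs, off_recs, noise_on,
                                     noise_off, n_boot=10_000, seed=SEED)
trials = pd.DataFrame({
    "snr_on_db": res["snr_pairs"][:, 0],
    "snr_off_db": res["snr_pairs"][:, 1],
    "envelope_correlation": res["correlations"]})
trials.to_csv(OUT / "05_on_off_trials.csv", index=False)

summary = {
    "mean_snr_on_db": round(float(trials.snr_on_db.mean()), 2),
    "mean_snr_off_db": round(float(trials.snr_off_db.mean()), 2),
    "frac_trials_on_gt_off": float((trials.snr_on_db
                                    > trials.snr_off_db).mean()),
    "mean_envelope_correlation": round(res["mean_correlation"], 4),
    "zero_correlation_ci95": [round(c, 4) for c in res["zero_corr_ci"]],
}
(OUT / "05_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
inside = (summary["zero_correlation_ci95"][0]
          < summary["mean_envelope_correlation"]
          < summary["zero_correlation_ci95"][1])
print("finding: on-nerve SNR exceeds off-nerve SNR on "
      f"{summary['frac_trials_on_gt_off']:.0%} of trials, and the on/off "
      "envelope correlation "
      + ("falls inside" if inside else "falls outside")
      + " the bootstrap zero-correlation CI, as expected for independent "
        "artifact-only off-nerve signals.")
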