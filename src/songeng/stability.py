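"""Longitudinal recording-stability metrics and on/off-nerve comparison.

Four trial-by-trial metrics quantify chronic recording stability:

* Pearson correlation of song-aligned activity envelopes to the day-1 mean
  envelope (running version: sliding window of 25 trials, advance 1);
* Vpp — max minus min of the processed voltage within the motif (uV);
* SNR — ``10 * log10(RMS_singing / RMS_noise)`` against a vocalization-free
  noise segment (the post-roll region of song-triggered recordings);
* event rate — upward crossings of a per-motif threshold (mean + 5 SD of
  the singing envelope) divided by the unwarped motif duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EnvelopeTrace, NeuralTraces


@dataclass
class MotifRecord:
    """One motif rendition: aligned envelope plus the raw voltage window."""

    day: int
    motif_index: int
    aligned_envelope: EnvelopeTrace
    raw_window: NeuralTraces | None
    unwarped_duration: float

    @property
    def envelope_values(self) -> np.ndarray:
        return self.aligned_envelope.values


@dataclass
class StabilityReport:
    per_day: pd.DataFrame
    comparisons: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def running_correlation(records: list[MotifRecord], ref_mean: np.ndarray,
                        window_trials: int = 25, advance: int = 1
                        ) -> pd.DataFrame:
    """Sliding-window mean envelope correlated against the day-1 mean.

    Zero-variance windows yield a flagged NaN row rather than being
    dropped silently.
    """
    if len(records) < window_trials:
        raise ValueError("fewer records than the window width")
    envs = np.vstack([r.envelope_values for r in records])
    rows = []
    for start in range(0, envs.shape[0] - window_trials + 1, advance):
        win = envs[start:start + window_trials].mean(axis=0)
        r = _pearson(win, ref_mean)
        rows.append({"window_start": start, "correlation": r,
                     "flagged_zero_variance": bool(np.isnan(r))})
    return pd.DataFrame(rows)


def motif_vpp(record: MotifRecord | NeuralTraces) -> float:
    """Peak-to-peak voltage (uV): max minus min over the motif window."""
    traces = record.raw_window if isinstance(record, MotifRecord) else record
    if traces is None or traces.voltages.size == 0:
        raise ValueError("no raw voltage window available")
    return float(traces.voltages.max() - traces.voltages.min())


def singing_snr(record: MotifRecord | NeuralTraces,
                noise_segment: NeuralTraces,
                expected_noise_s: float = 0.5) -> float:
    """SNR in dB: 10*log10(RMS_singing / RMS_noise), the literal RMS ratio."""
    traces = record.raw_window if isinstance(record, MotifRecord) else record
    if traces is None:
        raise ValueError("no raw voltage window available")
    rms_s = float(np.sqrt(np.mean(traces.voltages ** 2)))
    rms_n = float(np.sqrt(np.mean(noise_segment.voltages ** 2)))
    if rms_n == 0:
        raise ValueError("zero-RMS noise segment")
    return 10.0 * np.log10(rms_s / rms_n)


def event_rate(record: MotifRecord, n_sd: float = 5.0) -> float:
    """Envelope threshold crossings per second of unwarped song.

    Threshold is mean + ``n_sd`` * SD of this motif's singing envelope; an
    upward crossing is env[i-1] < theta <= env[i], with a refractory of
    one smoothing window between counted events.
    """
    env = record.envelope_values
    theta = env.mean() + n_sd * env.std()
    above = env >= theta
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return 0.0
    # envelope is on a 1 ms base; refractory = smoothing window in ms
    refractory = max(int(record.aligned_envelope.smoothing_window), 1)
    kept, last = 0, -np.inf
    for c in crossings:
        if c - last >= refractory:
            kept += 1
            last = c
    return kept / record.unwarped_duration


def daily_summary(records: list[MotifRecord],
                  noise_by_day: dict[int, NeuralTraces]) -> StabilityReport:
    """Per-day means of the four stability metrics plus day-1 comparisons.

    Comparisons use two-tailed paired t-tests of per-motif correlation
    values against day 1 when trial counts match, otherwise Welch tests;
    day-level group tests across birds are the caller's job (see
    :mod:`songeng.report`).
    """
    from scipy import stats

    days = sorted({r.day for r in records})
    if 1 not in days:
        raise ValueError("day 1 records are required as the reference")
    day1 = [r for r in records if r.day == 1]
    ref_mean = np.vstack([r.envelope_values for r in day1]).mean(axis=0)

    per_day_rows, corr_by_day = [], {}
    for d in days:
        recs = [r for r in records if r.day == d]
        corrs = [_pearson(r.envelope_values, ref_mean) for r in recs]
        vpps = [motif_vpp(r) for r in recs if r.raw_window is not None]
        snrs = [singing_snr(r, noise_by_day[d]) for r in recs
                if r.raw_window is not None and d in noise_by_day]
        rates = [event_rate(r) for r in recs]
        corr_by_day[d] = np.asarray(corrs)
        per_day_rows.append({
            "day": d, "n_motifs": len(recs),
            "correlation": float(np.nanmean(corrs)),
            "vpp_uv": float(np.mean(vpps)) if vpps else np.nan,
            "snr_db": float(np.mean(snrs)) if snrs else np.nan,
            "event_rate_hz": float(np.mean(rates)),
        })
    comps = []
    for d in days[1:]:
        a, b = corr_by_day[1], corr_by_day[d]
        if a.size == b.size:
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        comps.append({"day": d, "metric": "correlation", "t": float(t),
                      "p": float(p)})
    return StabilityReport(per_day=pd.DataFrame(per_day_rows),
                           comparisons=pd.DataFrame(comps))


def on_off_nerve_compare(on_records: list[MotifRecord],
                         off_records: list[MotifRecord],
                         noise_on: NeuralTraces, noise_off: NeuralTraces,
                         n_boot: int = 10_000, level: float = 0.95,
                         seed: int = 0) -> dict:
    """Paired on-nerve vs off-nerve comparison per simultaneous trial.

    Returns per-trial SNR pairs, per-trial envelope Pearson correlations,
    and a bootstrap CI for zero correlation built by circularly shifting
    one member of each pair (preserving autocorrelation).
    """
    if len(on_records) != len(off_records):
        raise ValueError("on/off trials must be paired")
    rng = np.random.default_rng(seed)
    snr_pairs, corrs = [], []
    envs_on, envs_off = [], []
    for on, off in zip(on_records, off_records):
        snr_pairs.append((singing_snr(on, noise_on),
                          singing_snr(off, noise_off)))
        a, b = on.envelope_values, off.envelope_values
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
        envs_on.append(a)
        envs_off.append(b)
        corrs.append(_pearson(a, b))

    null = np.empty(n_boot)
    n_trials = len(envs_on)
    for k in range(n_boot):
        i = rng.integers(n_trials)
        a, b = envs_on[i], envs_off[i]
        shift = rng.integers(1, a.size)
        null[k] = _pearson(a, np.roll(b, shift))
    alpha = (1 - level) / 2
    ci = (float(np.nanquantile(null, alpha)),
          float(np.nanquantile(null, 1 - alpha)))
    return {"snr_pairs": np.asarray(snr_pairs),
            "correlations": np.asarray(corrs),
            "zero_corr_ci": ci,
            "mean_correlation": float(np.nanmean(corrs))}
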