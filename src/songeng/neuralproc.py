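"""Electroneurogram preprocessing and motif time alignment.

Preprocessing chain: common-mode subtraction (per-sample across-channel
mean removed — cancels artifact sources shared by the six closely spaced
contacts), zero-phase two-pole Butterworth band-pass (0.3-6 kHz default),
and a squared-and-smoothed signal envelope.

Motif alignment: dynamic time warping of log-spectrogram frames (10 ms
window, 1 ms hop, Sakoe-Chiba band) against a template rendition; the
warp is then transferred to the simultaneously recorded voltage traces by
piecewise-linear resampling with no premotor time shifting.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .types import AudioClip, EnvelopeTrace, NeuralTraces, WarpPath


# --------------------------------------------------------------------------
# linear preprocessing

def common_mode_subtract(traces: NeuralTraces) -> NeuralTraces:
    """Remove the per-sample across-channel mean from every channel."""
    if traces.n_channels < 2:
        raise ValueError("common-mode subtraction undefined for one channel")
    cm = traces.voltages.mean(axis=0, keepdims=True)
    return NeuralTraces(traces.voltages - cm, traces.rate, traces.role,
                        list(traces.channel_ids))


def bandpass_filter(traces: NeuralTraces, lo: float = 300.0,
                    hi: float = 6000.0) -> NeuralTraces:
    """Zero-phase (forward-backward) two-pole Butterworth band-pass."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    if hi >= traces.rate / 2:
        raise ValueError("upper corner at or above Nyquist")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=traces.rate,
                        output="sos")
    filt = signal.sosfiltfilt(sos, traces.voltages, axis=1)
    return NeuralTraces(filt, traces.rate, traces.role,
                        list(traces.channel_ids))


def envelope(traces: NeuralTraces, window_ms: float = 5.0,
             step_ms: float | None = 1.0) -> EnvelopeTrace:
    """Square, boxcar-smooth, average channels; optional 1 ms resampling."""
    w = max(int(window_ms * 1e-3 * traces.rate), 1)
    sq = traces.voltages ** 2
    # uniform_filter1d can go infinitesimally negative on large dynamic range
    sm = np.maximum(ndimage.uniform_filter1d(sq, w, axis=1), 0.0)
    env = sm.mean(axis=0)
    times = np.arange(env.size) / traces.rate
    if step_ms is not None:
        step = int(round(step_ms * 1e-3 * traces.rate))
        if step > 1:
            env = env[::step]
            times = times[::step]
    return EnvelopeTrace(values=env, times=times, smoothing_window=window_ms)


# --------------------------------------------------------------------------
# spectrogram frames and DTW

def log_spec_frames(clip: AudioClip, win_ms: float = 10.0,
                    hop_ms: float = 1.0, nfft: int = 512) -> np.ndarray:
    """Frames x bins log-power spectrogram (band-limited to 8 kHz)."""
    nper = int(win_ms * 1e-3 * clip.rate)
    hop = max(int(hop_ms * 1e-3 * clip.rate), 1)
    freqs, _, sxx = signal.spectrogram(
        clip.samples, fs=clip.rate, window="hann", nperseg=nper,
        noverlap=nper - hop, nfft=max(nfft, nper), mode="psd")
    keep = freqs <= 8000
    return np.log10(sxx[keep].T + 1e-10)


def dtw_path(x: np.ndarray, y: np.ndarray, band_ms: float = 100.0,
             hop_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray, float]:
    """DTW of frame sequences x (rendition) onto y (template).

    Euclidean frame distance, symmetric steps, Sakoe-Chiba band of
    ``band_ms`` around the length-scaled diagonal. Returns (ix, iy, cost).
    """
    nx, ny = x.shape[0], y.shape[0]
    band = max(int(band_ms / hop_ms), abs(nx - ny) // 2 + 2)
    INF = np.inf
    cost = np.full((nx + 1, ny + 1), INF)
    cost[0, 0] = 0.0
    for i in range(1, nx + 1):
        center = int(round((i - 1) * ny / nx))
        jlo = max(1, center - band + 1)
        jhi = min(ny, center + band + 1)
        d = np.sqrt(((x[i - 1][None, :] - y[jlo - 1:jhi]) ** 2).sum(axis=1))
        prev = cost[i - 1]
        cur = cost[i]
        diag = prev[jlo - 1:jhi]
        up = prev[jlo:jhi + 1]
        best = np.minimum(diag, up)
        # left transitions need a sequential pass
        run = INF
        for k in range(jhi - jlo + 1):
            run = min(best[k], run)
            val = d[k] + run
            cur[jlo + k] = val
            run = val  # allows (0,+1) step from the freshly set cell
    total = cost[nx, ny]

    # backtrack
    i, j = nx, ny
    path_i, path_j = [i], [j]
    while i > 1 or j > 1:
        candidates = []
        if i > 1 and j > 1 and np.isfinite(cost[i - 1, j - 1]):
            candidates.append((cost[i - 1, j - 1], i - 1, j - 1))
        if i > 1 and np.isfinite(cost[i - 1, j]):
            candidates.append((cost[i - 1, j], i - 1, j))
        if j > 1 and np.isfinite(cost[i, j - 1]):
            candidates.append((cost[i, j - 1], i, j - 1))
        _, i, j = min(candidates)
        path_i.append(i)
        path_j.append(j)
    ix = np.asarray(path_i[::-1]) - 1
    iy = np.asarray(path_j[::-1]) - 1
    return ix, iy, float(total)


def choose_template(renditions: list[AudioClip], max_candidates: int = 16,
                    seed: int = 0) -> int:
    """Medoid rendition: minimum summed DTW cost over a candidate subset."""
    if len(renditions) == 1:
        return 0
    rng = np.random.default_rng(seed)
    idx = np.arange(len(renditions))
    if idx.size > max_candidates:
        idx = np.sort(rng.choice(idx, max_candidates, replace=False))
    frames = {i: log_spec_frames(renditions[i]) for i in idx}
    costs = np.zeros(idx.size)
    for a, i in enumerate(idx):
        for b, j in enumerate(idx):
            if b <= a:
                continue
            _, _, c = dtw_path(frames[i], frames[j])
            costs[a] += c
            costs[b] += c
    return int(idx[np.argmin(costs)])


def align_motifs(renditions: list[AudioClip],
                 template: AudioClip | int | None = None,
                 band_ms: float = 100.0) -> tuple[list[WarpPath], int | None]:
    """Warp each rendition onto a common template.

    ``template`` may be an AudioClip, an index into ``renditions``, or
    None (medoid chosen automatically). Returns per-rendition paths plus
    the template index (None if an external clip was supplied).
    """
    if not renditions:
        raise ValueError("no renditions to align")
    tmpl_idx: int | None
    if template is None:
        tmpl_idx = choose_template(renditions)
        tmpl_clip = renditions[tmpl_idx]
    elif isinstance(template, int):
        tmpl_idx = template
        tmpl_clip = renditions[template]
    else:
        tmpl_idx = None
        tmpl_clip = template
    tframes = log_spec_frames(tmpl_clip)
    paths = []
    for r in renditions:
        rframes = log_spec_frames(r)
        ix, iy, cost = dtw_path(rframes, tframes, band_ms=band_ms)
        paths.append(WarpPath(rendition_ms=ix.astype(float),
                              template_ms=iy.astype(float), cost=cost))
    return paths, tmpl_idx


def _monotone_map(path: WarpPath) -> tuple[np.ndarray, np.ndarray]:
    """Template ms -> mean rendition ms, strictly usable for interpolation."""
    t = path.template_ms
    r = path.rendition_ms
    uniq, inv = np.unique(t, return_inverse=True)
    sums = np.bincount(inv, weights=r)
    cnts = np.bincount(inv)
    return uniq, sums / cnts


def warp_neural(trace: EnvelopeTrace | NeuralTraces, path: WarpPath,
                rendition_duration_s: float | None = None):
    """Resample a trace onto the template time base via the warp path.

    The frame-level path is interpolated to a piecewise-linear time map
    (no premotor shift). The identity path returns the input unchanged up
    to resampling. Raises if the path does not cover the trace span.
    """
    tmpl_ms, rend_ms = _monotone_map(path)
    if isinstance(trace, EnvelopeTrace):
        values, times = trace.values, trace.times
        dur_s = rendition_duration_s or float(times[-1] - times[0])
        # tolerate sub-window mismatch between audio framing and the trace
        if dur_s * 1e3 - path.rendition_ms[-1] > 25.0:
            raise ValueError("warp path does not cover the trace span")
        src_t = times[0] + rend_ms * 1e-3
        warped = np.interp(src_t, times, values)
        return EnvelopeTrace(values=warped, times=tmpl_ms,
                             smoothing_window=trace.smoothing_window)
    if isinstance(trace, NeuralTraces):
        n = trace.n_samples
        dur_ms = n / trace.rate * 1e3
        if dur_ms - path.rendition_ms[-1] > 25.0:
            raise ValueError("warp path does not cover the trace span")
        out_t_ms = np.arange(int(tmpl_ms[-1]) + 1, dtype=float)
        src_ms = np.interp(out_t_ms, tmpl_ms, rend_ms)
        src_idx = src_ms * 1e-3 * trace.rate
        src_idx = np.clip(src_idx, 0, n - 1)
        base = np.arange(n)
        warped = np.vstack([np.interp(src_idx, base, ch)
                            for ch in trace.voltages])
        return NeuralTraces(warped, 1000.0, trace.role,
                            list(trace.channel_ids))
    raise TypeError("trace must be EnvelopeTrace or NeuralTraces")
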