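"""Longitudinal stability metrics and the on/off-nerve comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from songeng import stability
from songeng.types import EnvelopeTrace, NeuralTraces

RATE = 24400.0


def _env(values, win_ms=5.0):
    v = np.asarray(values, float)
    return EnvelopeTrace(v, np.arange(v.size) * 1e-3, win_ms)


def _record(env_values, raw=None, day=1, idx=0, duration=0.6):
    raw_tr = None if raw is None else NeuralTraces(raw, RATE)
    return stability.MotifRecord(day=day, motif_index=idx,
                                 aligned_envelope=_env(env_values),
                                 raw_window=raw_tr,
                                 unwarped_duration=duration)


class TestRunningCorrelation:
    def test_identical_records_give_unity(self):
        ref = np.abs(np.sin(np.linspace(0, 7, 400)))
        recs = [_record(ref) for _ in range(30)]
        df = stability.running_correlation(recs, ref)
        assert np.allclose(df.correlation, 1.0)

    def test_noise_windows_center_near_zero(self):
        rng = np.random.default_rng(0)
        ref = np.abs(np.sin(np.linspace(0, 7, 400)))
        recs = [_record(rng.random(400)) for _ in range(120)]
        df = stability.running_correlation(recs, ref)
        assert abs(df.correlation.mean()) < 0.15

    def test_zero_variance_window_flagged(self):
        ref = np.abs(np.sin(np.linspace(0, 7, 400)))
        recs = [_record(np.ones(400)) for _ in range(25)]
        df = stability.running_correlation(recs, ref)
        assert df.flagged_zero_variance.all()

    def test_too_few_records_rejected(self):
        ref = np.ones(10)
        with pytest.raises(ValueError):
            stability.running_correlation([_record(np.ones(10))], ref)


class TestMotifMetrics:
    def test_vpp_extremes(self):
        raw = np.zeros((2, 1000))
        raw[0, 10], raw[1, 20] = 250.0, -250.0
        assert stability.motif_vpp(_record(np.ones(10), raw)) == 500.0
        assert stability.motif_vpp(_record(np.ones(10),
                                           np.full((2, 100), 3.0))) == 0.0

    def test_snr_formula(self):
        noise = NeuralTraces(np.full((1, 100), 2.0), RATE)
        equal = _record(np.ones(10), np.full((1, 100), 2.0))
        tentimes = _record(np.ones(10), np.full((1, 100), 20.0))
        assert stability.singing_snr(equal, noise) == pytest.approx(0.0)
        assert stability.singing_snr(tentimes, noise) == pytest.approx(10.0)

    def test_zero_noise_rejected(self):
        noise = NeuralTraces(np.zeros((1, 100)), RATE)
        with pytest.raises(ValueError):
            stability.singing_snr(_record(np.ones(10), np.ones((1, 100))),
                                  noise)

    def test_snr_gain_invariance(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((3, 2000))
        noi = 0.2 * rng.standard_normal((3, 2000))
        base = stability.singing_snr(_record(np.ones(10), sig),
                                     NeuralTraces(noi, RATE))
        scaled = stability.singing_snr(_record(np.ones(10), 7 * sig),
                                       NeuralTraces(7 * noi, RATE))
        assert scaled == pytest.approx(base)

    def test_event_rate_constant_envelope(self):
        assert stability.event_rate(_record(np.ones(500))) == 0.0

    def test_event_rate_counts_bursts(self):
        """k well-separated bursts over duration d -> k/d events/s."""
        rng = np.random.default_rng(2)
        env = 1.0 + 0.01 * rng.standard_normal(1000)
        k = 6
        for pos in np.linspace(50, 950, k).astype(int):
            env[pos:pos + 3] += 50.0
        rec = _record(env, duration=0.5)
        assert stability.event_rate(rec) == pytest.approx(k / 0.5)

    @given(gain=st.floats(min_value=0.1, max_value=100.0))
    def test_event_rate_scale_invariant(self, gain):
        rng = np.random.default_rng(3)
        env = 1.0 + 0.01 * rng.standard_normal(800)
        env[100:103] += 40
        env[500:503] += 40
        r1 = stability.event_rate(_record(env, duration=1.0))
        r2 = stability.event_rate(_record(gain * env, duration=1.0))
        assert r1 == r2


class TestOnOffNerve:
    def _structured(self, rng, n=600):
        return np.abs(np.sin(np.linspace(0, 6, n))) ** 2 \
            + 0.05 * rng.random(n)

    def test_copy_control_outside_zero_ci(self):
        rng = np.random.default_rng(4)
        ons, offs = [], []
        for i in range(12):
            env = self._structured(rng)
            raw = 50 * rng.standard_normal((2, 2000))
            ons.append(_record(env, raw, idx=i))
            offs.append(_record(env.copy(), raw.copy(), idx=i))
        noise = NeuralTraces(5 * rng.standard_normal((2, 2000)), RATE)
        res = stability.on_off_nerve_compare(ons, offs, noise, noise,
                                             n_boot=2000, seed=0)
        assert np.allclose(res["correlations"], 1.0)
        assert res["mean_correlation"] > res["zero_corr_ci"][1]

    def test_independent_envelopes_inside_zero_ci(self):
        rng = np.random.default_rng(5)
        ons = [_record(self._structured(rng),
                       50 * rng.standard_normal((2, 2000)), idx=i)
               for i in range(15)]
        offs = [_record(rng.random(600),
                        5 * rng.standard_normal((2, 2000)), idx=i)
                for i in range(15)]
        noise = NeuralTraces(5 * rng.standard_normal((2, 2000)), RATE)
        res = stability.on_off_nerve_compare(ons, offs, noise, noise,
                                             n_boot=2000, seed=0)
        lo, hi = res["zero_corr_ci"]
        assert lo < res["mean_correlation"] < hi
        snr = res["snr_pairs"]
        assert np.mean(snr[:, 0] > snr[:, 1]) > 0.9

    def test_unpaired_trials_rejected(self):
        rng = np.random.default_rng(6)
        rec = _record(rng.random(100), rng.standard_normal((1, 100)))
        noise = NeuralTraces(np.ones((1, 100)), RATE)
        with pytest.raises(ValueError):
            stability.on_off_nerve_compare([rec, rec], [rec], noise, noise)
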