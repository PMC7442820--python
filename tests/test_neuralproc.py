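"""ENG preprocessing (CMS, zero-phase filtering, envelopes) and DTW
motif alignment with warp transfer."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from songeng import neuralproc, synthgen
from songeng.types import AudioClip, EnvelopeTrace, NeuralTraces

RATE = 24400.0


def _traces(v, rate=RATE):
    return NeuralTraces(np.asarray(v, float), rate)


class TestCommonModeSubtract:
    def test_rank_one_artifact_removed_exactly(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(5000)
        c = rng.standard_normal(5000)
        tr = _traces([s + c, -s + c])
        out = neuralproc.common_mode_subtract(tr)
        assert np.allclose(out.voltages[0], s, atol=1e-12)
        assert np.allclose(out.voltages[1], -s, atol=1e-12)

    def test_identical_channels_zeroed(self):
        x = np.sin(np.linspace(0, 20, 4000))
        out = neuralproc.common_mode_subtract(_traces([x, x, x]))
        assert np.allclose(out.voltages, 0.0)

    def test_idempotent_and_linear(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4, 3000))
        w = rng.standard_normal((4, 3000))
        cms = neuralproc.common_mode_subtract
        once = cms(_traces(v)).voltages
        twice = cms(_traces(once)).voltages
        assert np.allclose(once, twice)
        lin = cms(_traces(2 * v + 3 * w)).voltages
        assert np.allclose(lin, 2 * once + 3 * cms(_traces(w)).voltages)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            neuralproc.common_mode_subtract(_traces(np.zeros((1, 100))))

    def test_commutes_with_filtering(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((6, 8000))
        a = neuralproc.bandpass_filter(
            neuralproc.common_mode_subtract(_traces(v))).voltages
        b = neuralproc.common_mode_subtract(
            neuralproc.bandpass_filter(_traces(v))).voltages
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-6


class TestBandpassFilter:
    def test_dc_rejected(self):
        tr = _traces(np.full((2, 8000), 7.0))
        out = neuralproc.bandpass_filter(tr)
        assert np.max(np.abs(out.voltages[:, 2000:-2000])) < 1e-2

    def test_passband_center_amplitude(self):
        """1 kHz sits in the 0.3-6 kHz passband: amplitude within 5%."""
        t = np.arange(int(RATE)) / RATE
        x = np.sin(2 * np.pi * 1000 * t)
        out = neuralproc.bandpass_filter(_traces([x])).voltages[0]
        mid = out[int(0.2 * RATE):int(0.8 * RATE)]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_phase_pulse_unshifted(self):
        n = 8001
        pulse = np.exp(-0.5 * ((np.arange(n) - n // 2) / 30.0) ** 2)
        out = neuralproc.bandpass_filter(_traces([pulse])).voltages[0]
        assert int(np.argmax(np.abs(out))) == n // 2

    def test_corner_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            neuralproc.bandpass_filter(_traces(np.zeros((2, 100))),
                                       300.0, 13000.0)


class TestEnvelope:
    def test_constant_input_squares(self):
        tr = _traces(np.full((3, 5000), 4.0))
        env = neuralproc.envelope(tr, step_ms=None)
        assert np.allclose(env.values[200:-200], 16.0)

    @given(gain=st.floats(min_value=0.1, max_value=10.0))
    def test_quadratic_gain_scaling(self, gain):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((2, 3000))
        e1 = neuralproc.envelope(_traces(v), step_ms=None).values
        e2 = neuralproc.envelope(_traces(gain * v), step_ms=None).values
        assert np.allclose(e2, gain ** 2 * e1, rtol=1e-9)

    def test_burst_plateau_matches_power(self):
        """A burst of known RMS power shows an envelope plateau ~ power."""
        rng = np.random.default_rng(6)
        v = np.zeros((1, int(RATE)))
        sigma = 50.0
        sl = slice(int(0.3 * RATE), int(0.7 * RATE))
        v[0, sl] = sigma * rng.standard_normal(sl.stop - sl.start)
        env = neuralproc.envelope(_traces(v), window_ms=20.0, step_ms=None)
        plateau = env.values[int(0.4 * RATE):int(0.6 * RATE)].mean()
        assert plateau == pytest.approx(sigma ** 2, rel=0.05)


class TestAlignment:
    @pytest.fixture(scope="class")
    def motif(self, bird_a):
        clip, ann = synthgen.make_song(bird_a, 1, seed=8)
        return clip.slice(max(ann.onset_s.min() - 0.02, 0),
                          ann.offset_s.max() + 0.02)

    def test_template_self_alignment_identity(self, motif):
        paths, idx = neuralproc.align_motifs([motif], template=motif)
        p = paths[0]
        assert p.cost == pytest.approx(0.0, abs=1e-9)
        assert p.is_identity

    def test_stretch_recovery(self, motif):
        """A uniformly 1.25x stretched copy yields path slope ~ 1.25."""
        x = motif.samples
        idx = np.arange(int(x.size * 1.25)) / 1.25
        stretched = AudioClip(np.interp(idx, np.arange(x.size), x),
                              motif.rate)
        paths, _ = neuralproc.align_motifs([stretched], template=motif)
        p = paths[0]
        slope = (p.rendition_ms[-1] - p.rendition_ms[0]) / (
            p.template_ms[-1] - p.template_ms[0])
        assert slope == pytest.approx(1.25, rel=0.05)

    def test_paths_monotone_anchored_on_batch(self, bird_a):
        """Every warp path in a rendition batch is monotone and
        boundary-anchored."""
        clips = []
        for k in range(12):
            clip, ann = synthgen.make_song(bird_a, 1, seed=100 + k)
            clips.append(clip.slice(ann.onset_s.min(), ann.offset_s.max()))
        paths, tmpl = neuralproc.align_motifs(clips)
        assert tmpl is not None
        for p in paths:
            assert np.all(np.diff(p.rendition_ms) >= 0)
            assert np.all(np.diff(p.template_ms) >= 0)
            assert p.rendition_ms[0] == 0 and p.template_ms[0] == 0

    def test_warp_identity_returns_input(self):
        env = EnvelopeTrace(values=np.abs(np.sin(np.linspace(0, 10, 500))),
                            times=np.arange(500) * 1e-3,
                            smoothing_window=5.0)
        ident = neuralproc.WarpPath(np.arange(500.0), np.arange(500.0))
        out = neuralproc.warp_neural(env, ident)
        assert np.allclose(out.values, env.values)

    def test_envelope_round_trip(self, motif):
        """Stretch an envelope 1.25x, align audio, warp back: r > 0.95."""
        n_ms = int(motif.duration * 1000)
        base = np.abs(np.sin(np.linspace(0, 9, n_ms))) ** 2
        x = motif.samples
        idx = np.arange(int(x.size * 1.25)) / 1.25
        stretched = AudioClip(np.interp(idx, np.arange(x.size), x),
                              motif.rate)
        s_env = np.interp(np.arange(int(n_ms * 1.25)) / 1.25,
                          np.arange(n_ms), base)
        paths, _ = neuralproc.align_motifs([stretched], template=motif)
        warped = neuralproc.warp_neural(
            EnvelopeTrace(s_env, np.arange(s_env.size) * 1e-3, 5.0),
            paths[0])
        m = min(warped.values.size, base.size)
        r = np.corrcoef(warped.values[:m], base[:m])[0, 1]
        assert r > 0.95

    def test_span_mismatch_rejected(self):
        env = EnvelopeTrace(values=np.ones(2000),
                            times=np.arange(2000) * 1e-3,
                            smoothing_window=5.0)
        short = neuralproc.WarpPath(np.arange(100.0), np.arange(100.0))
        with pytest.raises(ValueError):
            neuralproc.warp_neural(env, short)
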