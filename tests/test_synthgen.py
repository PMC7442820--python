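"""Generator contracts: determinism, bookkeeping, and the statistical
structure the downstream stages rely on."""

import numpy as np
import pytest

from songeng import similarity, songdetect, synthgen
from songeng.evoked import response_metrics
from songeng.steering import default_pattern_set


class TestMakeSong:
    def test_annotation_bookkeeping(self, bird_a):
        clip, ann = synthgen.make_song(bird_a, 2, seed=1)
        assert len(ann) == 2 * len(bird_a.motif_order)
        assert (ann.offset_s > ann.onset_s).all()
        assert ann.offset_s.max() < clip.duration

    def test_seed_determinism(self, bird_a):
        c1, a1 = synthgen.make_song(bird_a, 1, seed=1)
        c2, a2 = synthgen.make_song(bird_a, 1, seed=1)
        assert np.array_equal(c1.samples, c2.samples)
        assert a1.equals(a2)
        c3, _ = synthgen.make_song(bird_a, 1, seed=2)
        assert not np.array_equal(c1.samples, c3.samples)

    def test_invalid_syllable_spec_rejected(self):
        with pytest.raises(ValueError):
            synthgen.SyllableSpec(duration=0.5, pitch_traj=[1000.0],
                                  am_rate=20, fm_depth=0, entropy_level=-1)
        with pytest.raises(ValueError):
            synthgen.SyllableSpec(duration=0.1, pitch_traj=[100.0],
                                  am_rate=20, fm_depth=0, entropy_level=-1)
        with pytest.raises(ValueError):
            synthgen.SyllableSpec(duration=0.1, pitch_traj=[1000.0],
                                  am_rate=20, fm_depth=0, entropy_level=0.5)

    def test_distinct_birds_less_similar_than_renditions(
            self, similarity_null, make_motif_tracks):
        """Cross-bird song similarity falls well below the same-bird
        rendition similarity (unrelated pairs spread over the null scale)."""
        a1 = make_motif_tracks("A", seed=11)[0]
        a2 = make_motif_tracks("A", seed=12)[0]
        b1 = make_motif_tracks("B", seed=13)[0]
        same = similarity.similarity(a1, a2, similarity_null).value
        cross = similarity.similarity(a1, b1, similarity_null).value
        assert same > 0.9
        assert cross < same - 0.2

    def test_segmentation_round_trip(self, bird_a):
        """Amplitude segmentation on clean song recovers >= 95% of
        annotated boundaries within 5 ms."""
        clip, ann = synthgen.make_song(bird_a, 5, seed=3)
        segs = songdetect.segment_syllables(clip)
        truth = [(r.onset_s, r.offset_s) for _, r in ann.iterrows()]
        hits = 0
        for on, off in truth:
            if any(abs(s.onset - on) < 0.005 and abs(s.offset - off) < 0.005
                   for s in segs):
                hits += 1
        assert hits / len(truth) >= 0.95


class TestMakeNerveRecording:
    def test_zero_model_gives_zero_traces(self, song_a):
        _, ann = song_a
        model = synthgen.NerveModel(unit_rate_scale=0.0, noise_sd=0.0,
                                    artifact_gain=0.0)
        tr = synthgen.make_nerve_recording(ann, model, seed=1)
        assert np.all(tr.voltages == 0)

    def test_artifact_is_rank_one(self, song_a):
        _, ann = song_a
        model = synthgen.NerveModel(unit_rate_scale=0.0, noise_sd=0.0)
        tr = synthgen.make_nerve_recording(ann, model, seed=1)
        s = np.linalg.svd(tr.voltages, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_six_channels_and_determinism(self, song_a):
        _, ann = song_a
        model = synthgen.NerveModel()
        t1 = synthgen.make_nerve_recording(ann, model, seed=5)
        t2 = synthgen.make_nerve_recording(ann, model, seed=5)
        assert t1.n_channels == 6
        assert np.array_equal(t1.voltages, t2.voltages)

    def test_off_nerve_has_no_singing_coupling(self, song_a):
        """Off-nerve traces carry artifact+noise only: the envelope is not
        elevated during singing."""
        from songeng import neuralproc
        _, ann = song_a
        model = synthgen.NerveModel(on_nerve=False)
        tr = synthgen.make_nerve_recording(ann, model, seed=6)
        env = neuralproc.envelope(
            neuralproc.bandpass_filter(neuralproc.common_mode_subtract(tr)))
        sing = np.zeros(env.values.size, bool)
        for _, r in ann.iterrows():
            sing[int(r.onset_s * 1000):int(r.offset_s * 1000)] = True
        ratio = env.values[sing].mean() / env.values[~sing].mean()
        assert 0.8 < ratio < 1.25


class TestMakeEvokedTrials:
    MODEL = synthgen.EvokedModel(vmax=300, i50=20, slope=5,
                                 baseline_noise=0.0)

    def test_amplitude_at_zero_current(self):
        trials = synthgen.make_evoked_trials(self.MODEL, [0.0], 1, seed=1)
        vpp, _ = response_metrics(trials[0])
        expected = self.MODEL.vmax / (1 + np.exp(self.MODEL.i50
                                                 / self.MODEL.slope))
        assert vpp == pytest.approx(expected, rel=0.05)

    def test_saturation_vpp_approaches_vmax(self):
        trials = synthgen.make_evoked_trials(self.MODEL, [500.0], 1, seed=1)
        vpp, _ = response_metrics(trials[0])
        assert vpp == pytest.approx(self.MODEL.vmax, rel=0.02)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            synthgen.make_evoked_trials(self.MODEL, [-5.0], 1, seed=1)

    def test_window_span(self):
        trials = synthgen.make_evoked_trials(self.MODEL, [20.0], 2, seed=1)
        t = trials[0].time_ms()
        assert t[0] == pytest.approx(-5.0, abs=0.05)
        assert t[-1] == pytest.approx(25.0, abs=0.05)


class TestMakeFictive:
    def test_duplicate_patterns_rejected(self):
        pats = default_pattern_set(2)
        with pytest.raises(ValueError):
            synthgen.make_fictive_vocalizations(pats + [pats[0]], 3, 1.0,
                                                seed=1)

    def test_trial_count_and_labels(self):
        pats = default_pattern_set(3)
        clips, labels = synthgen.make_fictive_vocalizations(pats, 4, 1.0,
                                                            seed=2)
        assert len(clips) == 12
        assert sorted(set(labels)) == sorted(p.pattern_id for p in pats)

    def test_determinism(self):
        pats = default_pattern_set(2)
        c1, _ = synthgen.make_fictive_vocalizations(pats, 2, 1.0, seed=3)
        c2, _ = synthgen.make_fictive_vocalizations(pats, 2, 1.0, seed=3)
        assert all(np.array_equal(a.samples, b.samples)
                   for a, b in zip(c1, c2))
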