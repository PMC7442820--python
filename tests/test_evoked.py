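"""Evoked compound responses: alignment, windowed metrics, bootstrap
detection, recruitment fitting, condition comparison, unit conversion."""

import numpy as np
import pandas as pd
import pytest

from songeng import evoked, synthgen
from songeng.types import EvokedTrial

CLEAN = synthgen.EvokedModel(vmax=300, i50=20, slope=5, baseline_noise=0.0)
NOISY = synthgen.EvokedModel(vmax=300, i50=20, slope=5, baseline_noise=5.0)


class TestAlignTrials:
    def test_jittered_trials_realigned(self):
        trials = synthgen.make_evoked_trials(NOISY, [60.0], 20, seed=1,
                                             onset_jitter_ms=0.2)
        aligned, flagged = evoked.align_trials(trials)
        assert not flagged
        onsets = [evoked.find_artifact_onset(t) for t in aligned]
        assert np.ptp(onsets) < 1  # residual jitter < 1 sample

    def test_artifact_free_trial_flagged(self):
        rng = np.random.default_rng(0)
        flat = EvokedTrial(current=0.0,
                           trace=0.5 * rng.standard_normal(732))
        aligned, flagged = evoked.align_trials([flat])
        assert flagged == [0]
        assert aligned == []

    def test_idempotent_on_aligned_trials(self):
        trials = synthgen.make_evoked_trials(NOISY, [60.0], 5, seed=2)
        once, _ = evoked.align_trials(trials)
        twice, _ = evoked.align_trials(once)
        assert all(np.array_equal(a.trace, b.trace)
                   for a, b in zip(once, twice))


class TestResponseMetrics:
    def test_flat_trace(self):
        tr = EvokedTrial(current=0.0, trace=np.full(732, 3.0))
        vpp, snr = evoked.response_metrics(tr)
        assert vpp == 0.0
        assert snr == pytest.approx(0.0)

    def test_noise_free_vpp_matches_generator(self):
        trials = synthgen.make_evoked_trials(CLEAN, [60.0], 1, seed=3)
        vpp, snr = evoked.response_metrics(trials[0])
        assert vpp == pytest.approx(CLEAN.amplitude(60.0), rel=0.02)
        assert snr > 40.0

    def test_gain_laws(self):
        trials = synthgen.make_evoked_trials(NOISY, [60.0], 20, seed=4)
        vpp1, snr1 = evoked.response_metrics(trials)
        scaled = [EvokedTrial(current=t.current, trace=3.0 * t.trace,
                              rate=t.rate, pre_ms=t.pre_ms)
                  for t in trials]
        vpp2, snr2 = evoked.response_metrics(scaled)
        assert vpp2 == pytest.approx(3.0 * vpp1)
        assert snr2 == pytest.approx(snr1)

    def test_windows_validation(self):
        with pytest.raises(ValueError):
            evoked.ResponseWindows(signal=(0.75, 4.0), noise=(2.0, 6.0))
        with pytest.raises(ValueError):
            evoked.ResponseWindows(signal=(0.1, 4.0))


class TestDetectResponse:
    def test_strong_response_detected(self):
        trials = synthgen.make_evoked_trials(NOISY, [100.0], 20, seed=5)
        res = evoked.detect_response(trials, n_boot=2000, seed=0)
        assert res["detected"]
        assert res["snr_db"] > res["ci"][1]

    def test_min_trial_count(self):
        trials = synthgen.make_evoked_trials(NOISY, [100.0], 5, seed=6)
        with pytest.raises(ValueError):
            evoked.detect_response(trials)

    def test_degenerate_noise_window_rejected(self):
        trials = [EvokedTrial(current=0.0, trace=np.zeros(732))
                  for _ in range(10)]
        with pytest.raises(ValueError):
            evoked.detect_response(trials)

    def test_alternative_ci_mode(self):
        trials = synthgen.make_evoked_trials(NOISY, [100.0], 20, seed=7)
        res = evoked.detect_response(trials, n_boot=500,
                                     mode="ci_of_observed", seed=0)
        assert res["detected"]


class TestRecruitmentCurve:
    def test_noise_free_sigmoid_recovered(self):
        currents = [5, 10, 15, 20, 25, 30, 40, 60]
        trials = synthgen.make_evoked_trials(CLEAN, currents, 2, seed=8)
        fit = evoked.recruitment_curve(trials, detect_kwargs={"n_boot": 500})
        assert fit.converged
        assert fit.i50 == pytest.approx(20.0, rel=0.02)
        assert fit.vmax == pytest.approx(300.0, rel=0.02)
        resid = fit.predict(np.array(currents)) - [
            evoked.response_metrics([t for t in trials
                                     if t.current == c])[0]
            for c in currents]
        assert np.abs(resid).max() < 2.0

    def test_too_few_currents_rejected(self):
        trials = synthgen.make_evoked_trials(NOISY, [10, 20, 30], 4, seed=9)
        with pytest.raises(ValueError):
            evoked.recruitment_curve(trials)

    def test_subthreshold_currents_censored(self):
        """All currents far below i50: no detection, threshold None."""
        model = synthgen.EvokedModel(vmax=300, i50=200, slope=5,
                                     baseline_noise=5.0)
        trials = synthgen.make_evoked_trials(model, [1, 2, 3, 4, 5], 10,
                                             seed=10)
        fit = evoked.recruitment_curve(trials,
                                       detect_kwargs={"n_boot": 500})
        assert fit.threshold_current is None


class TestConditionCompare:
    def _amplitudes(self, lidocaine_factor):
        rows = []
        rng = np.random.default_rng(11)
        for s in range(3):
            base = 250 + 20 * rng.standard_normal()
            for cond, f in [("baseline", 1.0), ("saline", 0.98),
                            ("lidocaine", lidocaine_factor),
                            ("washout", 0.98)]:
                rows.append({"subject": f"b{s}", "condition": cond,
                             "amplitude": base * f
                             * (1 + 0.02 * rng.standard_normal())})
        return pd.DataFrame(rows)

    def test_lidocaine_block_detected(self):
        res = evoked.condition_compare(self._amplitudes(0.05))
        contrasts = res["contrasts"].set_index("condition")
        assert contrasts.loc["lidocaine", "p"] < 0.05
        assert contrasts.loc["washout", "p"] > 0.05
        assert res["anova_p"] < 0.05

    def test_identical_conditions_not_significant(self):
        res = evoked.condition_compare(self._amplitudes(0.97))
        assert (res["contrasts"]["p"] > 0.05).all()

    def test_unpaired_subjects_rejected(self):
        df = self._amplitudes(0.5).iloc[:-1]
        with pytest.raises(ValueError):
            evoked.condition_compare(df)


class TestForceLimit:
    @pytest.mark.parametrize("pressure,area,expected", [
        (30.0, 0.03, 120.0),
        (0.0, 0.03, 0.0),
        (30.0, 0.06, 240.0),
    ])
    def test_pressure_area_to_micronewtons(self, pressure, area, expected):
        out = evoked.compression_force_limit(pressure, area)
        assert out == pytest.approx(expected, rel=0.005)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            evoked.compression_force_limit(-1.0, 0.03)
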