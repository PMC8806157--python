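import dataclasses

import numpy as np
import pytest

from ca1ensemble import ensemble
from ca1ensemble.config import AnalysisConfig
from ca1ensemble.events import Baseline, CalciumEvent
from ca1ensemble.synth import SyntheticParams, generate_session
from ca1ensemble.pipeline import run_session


def _bl(mu=0.0, sigma=0.02):
    return Baseline(mu=mu, sigma=sigma)


class TestThresholdNormalize:
    def test_subthreshold_roi_is_all_zero(self):
        m = ensemble.threshold_normalize(np.full((1, 100), 0.01), [_bl()])
        assert np.all(m.values == 0)
        assert m.session_max[0] == 0

    def test_suprathreshold_roi_attains_exactly_one(self, rng):
        tr = rng.normal(0, 0.02, (1, 500))
        tr[0, 100] = 0.5
        m = ensemble.threshold_normalize(tr, [_bl()])
        assert m.values.max() == 1.0
        assert np.all((0 <= m.values) & (m.values <= 1))

    def test_relative_magnitudes_preserved(self):
        tr = np.zeros((1, 100))
        tr[0, 10], tr[0, 50] = 0.5, 1.0  # both above thr 0.08
        m = ensemble.threshold_normalize(tr, [_bl()])
        assert m.values[0, 10] == pytest.approx(0.5)
        assert m.values[0, 50] == pytest.approx(1.0)


class TestEnsembleTrace:
    def test_single_roi_identity(self, rng):
        tr = np.abs(rng.normal(0, 1, (1, 50)))
        norm = tr / tr.max()
        assert np.array_equal(ensemble.compute_ensemble_trace(norm), norm[0])

    def test_mean_across_rois(self):
        m = np.zeros((10, 20))
        m[:5, 7] = 1.0
        out = ensemble.compute_ensemble_trace(m)
        assert out[7] == 0.5
        assert out[0] == 0.0

    def test_all_zero_rows_zero_trace(self):
        assert np.all(ensemble.compute_ensemble_trace(np.zeros((4, 9))) == 0)


class TestAverageSweeps:
    def test_identical_sweeps_average_to_one(self, rng):
        s = rng.normal(size=(1, 100))
        stack = np.repeat(s, 9, axis=0)
        np.testing.assert_allclose(ensemble.average_sweeps(stack), s[0])

    def test_noise_shrinks_as_sqrt_n(self, rng):
        sweeps = rng.normal(0, 1.0, (9, 20_000))
        avg = ensemble.average_sweeps(sweeps)
        assert avg.std() == pytest.approx(1.0 / np.sqrt(9), rel=0.05)


class TestDetectEpochs:
    def _sweep_with(self, t1=None, t2=None, t3=None, base=0.05, rate=2000.0):
        t = (np.arange(int(10 * rate)) + 0.5) / rate
        x = np.full(t.size, base)
        if t1 is not None:
            x += 0.20 * np.exp(-((t - t1) ** 2) / (2 * 0.05**2))
        if t3 is not None:
            x += 0.10 * np.exp(-((t - t3) ** 2) / (2 * 0.08**2))
        if t2 is not None:
            x -= base * np.exp(-((t - t2) ** 2) / (2 * 0.3**2))
        return np.clip(x, 0, 1)

    def test_programmed_extrema_recovered(self):
        ep = ensemble.detect_epochs(self._sweep_with(t1=0.4, t2=1.8, t3=3.5))
        assert ep.t1_s == pytest.approx(0.4, abs=0.2)
        assert ep.t2_s == pytest.approx(1.8, abs=0.2)
        assert ep.t3_s == pytest.approx(3.5, abs=0.2)
        assert ensemble.classify_pattern(ep) == "A"

    def test_trough_only_is_type_c(self):
        ep = ensemble.detect_epochs(self._sweep_with(t2=1.8))
        assert ep.t1_s is None and ep.t3_s is None
        assert ep.t2_s is not None
        assert ensemble.classify_pattern(ep) == "C"

    def test_flat_sweep_nothing_present(self):
        ep = ensemble.detect_epochs(np.zeros(20_000))
        assert ep.present == {"epoch1": False, "epoch2": False, "epoch3": False}
        assert ensemble.classify_pattern(ep) == "none"

    def test_second_max_only_is_type_b(self):
        ep = ensemble.detect_epochs(self._sweep_with(t2=1.8, t3=3.5))
        assert ep.t1_s is None and ep.t3_s is not None
        assert ensemble.classify_pattern(ep) == "B"

    def test_epoch_recovery_on_generated_sessions(self):
        """Detected latencies land within +-0.2 s of the programmed
        0.4 / 1.8 / 3.5 s structure for most seeds."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            bundle, truth = generate_session(SyntheticParams(seed=seed))
            r = run_session(bundle, AnalysisConfig(rng_seed=seed), run_null=False)
            ep = r.epochs
            ok = (
                ep.t1_s is not None and abs(ep.t1_s - 0.4) <= 0.2
                and ep.t2_s is not None and abs(ep.t2_s - 1.8) <= 0.2
                and ep.t3_s is not None and abs(ep.t3_s - 3.5) <= 0.2
            )
            hits += ok
        assert hits >= n_seeds - 1


class TestFractionAndPattern:
    def _events(self, active_rois, n_rois, t=5.0):
        return [
            [CalciumEvent(t - 0.3, t, t + 0.3, 0.1)] if i in active_rois else []
            for i in range(n_rois)
        ]

    def test_all_rois_active(self):
        evs = self._events(set(range(10)), 10)
        assert ensemble.ensemble_fraction(evs, 5.0) == 1.0

    def test_no_rois_active(self):
        evs = self._events(set(), 10)
        assert ensemble.ensemble_fraction(evs, 5.0) == 0.0

    def test_counting(self):
        evs = self._events({1, 4, 7}, 10)
        assert ensemble.ensemble_fraction(evs, 5.0) == pytest.approx(0.3)

    def test_absent_epoch_is_missing_not_zero(self):
        assert ensemble.ensemble_fraction(self._events({1}, 10), None) is None

    def test_interval_overlap_not_onset_containment(self):
        """An event spanning the window counts even when its onset is
        outside the 10 ms window."""
        evs = [[CalciumEvent(4.0, 4.5, 6.0, 0.1)]]
        assert ensemble.ensemble_fraction(evs, 5.0, window_s=0.010) == 1.0

    def test_fraction_monotone_in_active_set(self, rng):
        n = 20
        small = set(rng.choice(n, 5, replace=False).tolist())
        big = small | set(rng.choice(n, 10, replace=False).tolist())
        f_small = ensemble.ensemble_fraction(self._events(small, n), 5.0)
        f_big = ensemble.ensemble_fraction(self._events(big, n), 5.0)
        assert f_big >= f_small

    @pytest.mark.parametrize(
        "t1,t3,a1,a3,expected",
        [
            (0.4, 3.5, 0.4, 0.1, "A"),
            (0.4, 3.5, 0.1, 0.4, "B"),
            (None, 3.5, None, 0.4, "B"),
            (None, None, None, None, "C"),
        ],
    )
    def test_pattern_typing_rules(self, t1, t3, a1, a3, expected):
        ep = ensemble.EpochSet(t1, 1.8, t3, a1, 0.01, a3)
        assert ensemble.classify_pattern(ep) == expected
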