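import dataclasses

import numpy as np
import pytest

from ca1ensemble import events
from ca1ensemble.synth import SyntheticParams, generate_session, transient_shape


class TestDetrend:
    def test_linear_ramp_removed(self):
        ramp = np.linspace(0.0, 1.0, 720)
        out = events.detrend(ramp, 100)
        assert np.max(np.abs(out)) < 1e-6  # of a unit ramp range

    def test_white_noise_sd_preserved(self, rng):
        x = rng.normal(0, 0.02, 720)
        out = events.detrend(x, 100)
        assert out.std() == pytest.approx(x.std(), rel=0.10)

    def test_sharp_transient_survives(self, rng):
        """A transient much narrower than the span loses < 10% amplitude."""
        t = (np.arange(720) + 0.5) / 7.5
        tr = 0.15 * transient_shape(t - 40.0, 0.05, 0.3)  # ~2 s wide
        out = events.detrend(tr + rng.normal(0, 0.001, 720), 100)
        assert out.max() >= 0.9 * 0.15

    def test_span_validation(self):
        with pytest.raises(ValueError):
            events.detrend(np.zeros(720), 5)
        with pytest.raises(ValueError):
            events.detrend(np.zeros(50), 100)


class TestFitBaseline:
    def test_pure_gaussian_recovered(self, rng):
        x = rng.normal(0.0, 0.02, 10_000)
        b = events.fit_baseline(x)
        assert abs(b.mu) <= 0.002
        assert b.sigma == pytest.approx(0.02, rel=0.05)
        assert b.thr_event > b.thr_bound > b.mu

    def test_robust_to_transient_contamination(self, rng):
        """10% of samples inside large transients: the iterative fit stays
        within 10% of the true noise SD while the naive SD errs by > 25%."""
        n = 10_000
        x = rng.normal(0.0, 0.02, n)
        idx = rng.choice(n, n // 10, replace=False)
        x[idx] += rng.uniform(0.10, 0.20, idx.size)  # 5-10 sigma excursions
        naive = x.std()
        assert naive > 1.25 * 0.02
        b = events.fit_baseline(x)
        assert b.sigma == pytest.approx(0.02, rel=0.10)

    def test_constant_trace_degenerate(self):
        with pytest.raises(events.DegenerateTraceError):
            events.fit_baseline(np.ones(500))

    def test_short_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            events.fit_baseline(rng.normal(size=50))


class TestDetectEvents:
    def _baseline(self, sigma=0.02):
        return events.Baseline(mu=0.0, sigma=sigma)

    def test_flat_trace_no_events(self):
        assert events.detect_events(np.zeros(720), self._baseline()) == []

    def test_rectangular_excursion_boundary_convention(self):
        """5 samples at mu + 5 sigma: one event, 5-sample duration,
        amplitude 5 sigma."""
        sigma = 0.02
        tr = np.zeros(720)
        tr[100:105] = 5 * sigma
        (ev,) = events.detect_events(tr, self._baseline(sigma), frame_rate_hz=7.5)
        dt = 1 / 7.5
        assert ev.amplitude == pytest.approx(5 * sigma)
        assert ev.duration_s == pytest.approx(5 * dt)
        assert ev.start_s == pytest.approx((100 + 0.5) * dt)
        assert ev.peak_s == pytest.approx((100 + 0.5) * dt)

    def test_sub_peak_threshold_run_is_not_an_event(self):
        """An excursion crossing 2 SD but never reaching 4 SD is no event."""
        sigma = 0.02
        tr = np.zeros(720)
        tr[100:110] = 3 * sigma
        assert events.detect_events(tr, self._baseline(sigma)) == []

    def test_events_disjoint_ordered_and_above_threshold(self, rng):
        sigma = 0.02
        tr = rng.normal(0, sigma, 2000)
        tr[200:210] += 8 * sigma
        tr[900:905] += 10 * sigma
        b = events.fit_baseline(tr)
        evs = events.detect_events(tr, b)
        for a, c in zip(evs, evs[1:]):
            assert a.end_s <= c.start_s
        for e in evs:
            assert e.amplitude >= b.event_peak_sd * b.sigma - 1e-12

    def test_noise_only_false_event_rate(self):
        """On 720-frame pure-noise traces, the 4 SD rule averages <= 1
        spurious event per trace over 100 seeds."""
        total = 0
        for seed in range(100):
            tr = np.random.default_rng(seed).normal(0, 0.02, 720)
            b = events.Baseline(mu=0.0, sigma=0.02)
            total += len(events.detect_events(tr, b))
        assert total / 100 <= 1.0

    def test_planted_transient_recovery(self):
        """>= 95% of planted >= 6 sigma transients recovered, <= 5% extras,
        over 50 seeded synthetic ROIs."""
        params = SyntheticParams(
            seed=7, n_rois=50, spont_rate_hz=0.05,
            epoch_structure=dataclasses.replace(
                SyntheticParams().epoch_structure, pattern="none"
            ),
        )
        bundle, truth = generate_session(params)
        found = planted = extras = 0
        for i in range(50):
            det = events.detrend(bundle.roi_traces.dff[i], 100)
            b = events.fit_baseline(det)
            evs = events.detect_events(det, b)
            true_onsets = [on for on, _ in truth.events[i]]
            planted += len(true_onsets)
            matched = set()
            for on in true_onsets:
                hit = [
                    j for j, e in enumerate(evs)
                    if j not in matched and e.start_s - 0.5 <= on <= e.end_s
                ]
                if hit:
                    matched.add(hit[0])
                    found += 1
            extras += len(evs) - len(matched)
        assert found / planted >= 0.95
        assert extras / max(planted, 1) <= 0.05


class TestSummaries:
    def test_no_events_summary(self):
        f = events.summarize_events([], 96.0, "r0")
        assert (f.n_events, f.frequency_hz, f.active) == (0, 0.0, False)
        assert f.mean_iei_s is None and f.mean_amplitude is None

    def test_iei_onset_to_onset(self):
        evs = [
            events.CalciumEvent(10.0, 10.5, 11.0, 0.1),
            events.CalciumEvent(25.0, 25.5, 26.0, 0.1),
        ]
        f = events.summarize_events(evs, 96.0)
        assert f.mean_iei_s == pytest.approx(15.0)

    def test_frequency_is_count_over_duration(self):
        evs = [events.CalciumEvent(i * 10.0, i * 10.0, i * 10.0 + 1, 0.1) for i in range(6)]
        f = events.summarize_events(evs, 96.0)
        assert f.frequency_hz == pytest.approx(0.0625)

    @pytest.mark.parametrize("n_active,expected", [(2, False), (3, True), (50, True)])
    def test_min_active_rois_boundary(self, n_active, expected):
        feats = [
            events.EventFeatures(f"r{i}", 1, 0.01, None, 0.1, 0.5, True)
            for i in range(n_active)
        ] + [
            events.EventFeatures(f"q{i}", 0, 0.0, None, None, None, False)
            for i in range(5)
        ]
        assert events.session_activity_filter(feats) is expected
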