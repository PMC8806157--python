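import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ca1ensemble import similarity
from ca1ensemble.config import AnalysisConfig
from ca1ensemble.ensemble import EpochSet
from ca1ensemble.events import CalciumEvent
from ca1ensemble.synth import SyntheticParams, generate_session
from ca1ensemble.pipeline import run_session


binary_vec = hnp.arrays(np.int8, 32, elements=st.integers(0, 1))


class TestHamming:
    def test_identity(self, rng):
        p = rng.integers(0, 2, 50)
        assert similarity.hamming(p, p) == 0.0

    def test_two_zero_vectors_well_defined(self):
        z = np.zeros(20)
        assert similarity.hamming(z, z) == 0.0

    def test_complementary_vectors_maximal(self):
        p = np.array([0, 1] * 10)
        assert similarity.hamming(p, 1 - p) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity.hamming(np.zeros(3), np.zeros(4))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(binary_vec, binary_vec, binary_vec)
    def test_metric_axioms(self, p, q, r):
        d = similarity.hamming
        assert d(p, q) == d(q, p)
        assert (d(p, q) == 0) == bool(np.all(p == q))
        assert d(p, r) <= d(p, q) + d(q, r) + 1e-12


class TestPatternsAndDistance:
    def test_active_pattern_from_raster(self):
        per_roi = [[] for _ in range(10)]
        for i in (1, 4, 7):
            per_roi[i] = [CalciumEvent(4.9, 5.0, 5.1, 0.1)]
        pat = similarity.active_pattern([], (4.995, 5.005), per_roi=per_roi)
        assert set(np.flatnonzero(pat)) == {1, 4, 7}

    def test_identical_patterns_zero_distance(self):
        pats = np.tile(np.array([1, 0, 1, 1, 0], dtype=bool), (10, 1))
        d, n_pairs = similarity.epoch_distance(pats)
        assert d == 0.0
        assert n_pairs == 45

    def test_random_patterns_expect_half(self):
        """Independently uniform patterns differ in half their positions."""
        means = []
        for seed in range(100):
            pats = np.random.default_rng(seed).integers(0, 2, (10, 40))
            d, _ = similarity.epoch_distance(pats)
            means.append(d)
        assert np.mean(means) == pytest.approx(0.5, abs=0.03)

    def test_fewer_than_two_patterns_rejected(self):
        with pytest.raises(ValueError):
            similarity.epoch_distance(np.ones((1, 5), dtype=bool))

    def test_reliable_membership_gives_smaller_distance(self):
        """Cohorts with p_repeat = 0.95 show smaller epoch-1 ensemble
        distance than p_repeat = 0.6, in nearly every paired seed."""
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            dists = {}
            for p_rep in (0.95, 0.6):
                params = SyntheticParams(seed=seed)
                params = dataclasses.replace(
                    params,
                    membership=dataclasses.replace(
                        params.membership, p_repeat=p_rep
                    ),
                )
                bundle, _ = generate_session(params)
                r = run_session(bundle, AnalysisConfig(rng_seed=seed), run_null=False)
                dists[p_rep] = r.distances.get("epoch1")
            if dists[0.95] is not None and dists[0.6] is not None:
                wins += dists[0.95] < dists[0.6]
        assert wins >= n_seeds - 1


class TestPairwiseCorrelation:
    def test_identical_rows_correlate_fully(self, rng):
        row = rng.normal(size=200)
        r, skipped = similarity.pairwise_correlation(np.vstack([row, row]))
        assert r == pytest.approx(1.0)
        assert skipped == 0

    def test_negated_rows_anticorrelate(self, rng):
        row = rng.normal(size=200)
        r, _ = similarity.pairwise_correlation(np.vstack([row, -row]))
        assert r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        vals = []
        for seed in range(20):
            m = np.random.default_rng(seed).normal(size=(20, 720))
            r, _ = similarity.pairwise_correlation(m)
            vals.append(r)
        assert abs(np.mean(vals)) < 0.05

    def test_constant_rows_skipped_and_counted(self, rng):
        m = np.vstack([rng.normal(size=50), np.ones(50), rng.normal(size=50)])
        r, skipped = similarity.pairwise_correlation(m)
        assert skipped == 2
        assert r is not None

    def test_all_constant_is_missing(self):
        r, skipped = similarity.pairwise_correlation(np.ones((3, 50)))
        assert r is None
        assert skipped == 3


class TestCircularShuffle:
    def test_zero_shifts_identity(self, rng):
        m = rng.normal(size=(5, 100))
        np.testing.assert_array_equal(
            similarity.circular_shuffle(m, np.zeros(5, int)), m
        )

    def test_row_multisets_conserved(self, rng):
        m = rng.normal(size=(5, 100))
        out = similarity.circular_shuffle(m, rng.integers(0, 100, 5))
        for i in range(5):
            np.testing.assert_array_equal(np.sort(out[i]), np.sort(m[i]))

    def test_ensemble_time_average_exactly_conserved(self, rng):
        """The exactly rounded time average of the ensemble trace is
        bit-identical under any circular shuffle."""
        m = rng.normal(size=(20, 5000))
        before = similarity.ensemble_time_average(m)
        for seed in range(5):
            shifts = np.random.default_rng(seed).integers(0, 5000, 20)
            after = similarity.ensemble_time_average(
                similarity.circular_shuffle(m, shifts)
            )
            assert after == before  # exact


class TestBuildNull:
    def _epochs(self):
        return EpochSet(0.4, 1.8, 3.5, 0.2, 0.01, 0.1)

    def test_single_shuffle_cardinality(self, type_a_session):
        bundle, _ = type_a_session
        r = run_session(bundle, AnalysisConfig(rng_seed=1), run_null=False)
        null = similarity.build_null(
            r.events_per_roi,
            bundle.stimulus_onsets_s,
            r.epochs,
            bundle.roi_traces.duration_s,
            n_shuffles=1,
            seed=9,
        )
        for arr in null.fractions.values():
            assert arr.size == 1

    def test_null_reproducible_from_seed(self, type_a_session):
        bundle, _ = type_a_session
        r = run_session(bundle, AnalysisConfig(rng_seed=1), run_null=False)
        kwargs = dict(
            stimulus_onsets_s=bundle.stimulus_onsets_s,
            epochs=r.epochs,
            duration_s=bundle.roi_traces.duration_s,
            n_shuffles=50,
            seed=77,
        )
        a = similarity.build_null(r.events_per_roi, **kwargs)
        b = similarity.build_null(r.events_per_roi, **kwargs)
        for k in a.fractions:
            np.testing.assert_array_equal(a.fractions[k], b.fractions[k])

    def test_evoked_session_exceeds_null(self, type_a_session):
        """Strong stimulus locking puts the observed epoch-1 fraction above
        the 97.5th percentile of its shuffle null."""
        bundle, _ = type_a_session
        r = run_session(bundle, AnalysisConfig(rng_seed=1), run_null=False)
        null = similarity.build_null(
            r.events_per_roi,
            bundle.stimulus_onsets_s,
            r.epochs,
            bundle.roi_traces.duration_s,
            n_shuffles=200,
            seed=5,
        )
        obs = null.observed_fractions["epoch1"]
        assert obs > np.percentile(null.fractions["epoch1"], 97.5)
        assert similarity.percentile_of(obs, null.fractions["epoch1"]) > 97.5
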