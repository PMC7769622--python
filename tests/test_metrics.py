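import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazemix import (
    ModelParams,
    SaliencyMap,
    ScanPath,
    amplitude_autocorrelation,
    coefficient_of_determination,
    information_gain,
    nss,
    saccade_statistics,
    subject_moments,
)
from gazemix.metrics import (
    auc_from_scores,
    auc_borji,
    make_folds,
    score_paths,
    step_prediction_maps,
    wrap_degrees,
)


def _maps_for(values_points):
    """Build (map, location) pairs from (HxW array, (x, y)) tuples."""
    return [(np.asarray(v, dtype=float), p) for v, p in values_points]


class TestAUC:
    def test_hand_counted_instance(self):
        # exhaustive pair counting: 8 of 9 pairs rank the positive higher
        assert auc_from_scores([0.9, 0.8, 0.4], [0.7, 0.3, 0.1]) == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        assert auc_from_scores([5, 6, 7], [1, 2, 3]) == 1.0

    def test_identical_scores_chance_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert auc_from_scores([1, 1], [1, 1]) == 0.5

    def test_matches_exhaustive_pair_count_on_random_instances(self, rng):
        for _ in range(20):
            pos = rng.normal(size=rng.integers(2, 30))
            neg = rng.normal(size=rng.integers(2, 30))
            # brute-force Mann-Whitney: count wins + half ties
            wins = sum(
                1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
            )
            assert auc_from_scores(pos, neg) == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-12
            )

    def test_uniform_maps_are_chance_level(self, rng):
        maps = _maps_for(
            [(np.full((10, 10), 0.01), (int(rng.integers(10)), int(rng.integers(10))))
             for _ in range(50)]
        )
        with pytest.warns(RuntimeWarning):
            assert auc_borji(maps, n_negatives_per_positive=10, rng=rng) == 0.5


class TestNSS:
    def test_constant_map_contributes_zero(self):
        with pytest.warns(RuntimeWarning):
            assert nss(_maps_for([(np.full((4, 4), 0.0625), (1, 2))])) == 0.0

    def test_indicator_map_closed_form(self):
        # N = 4 pixels, indicator at the fixation: z = (1 - 1/N)/std
        v = np.zeros((2, 2))
        v[1, 0] = 1.0
        expected = (1.0 - 0.25) / v.std()
        assert nss(_maps_for([(v, (0, 1))])) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        v = rng.uniform(0.1, 1.0, (8, 8))
        a = nss(_maps_for([(v, (3, 4))]))
        b = nss(_maps_for([(2.7 * v + 0.3, (3, 4))]))
        assert a == pytest.approx(b, abs=1e-10)


class TestInformationGain:
    def test_uniform_baseline_is_zero(self):
        n = 64
        v = np.full((8, 8), 1.0 / n)
        assert information_gain(_maps_for([(v, (2, 5))])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_on_16_pixel_toy(self):
        # probabilities 1/4, 1/8, 1/2 on a 16-pixel grid:
        # IG = mean(4-2, 4-3, 4-1) = 2 bit/fix
        def vmap(p):
            v = np.full((4, 4), (1.0 - p) / 15.0)
            v[0, 0] = p
            return v

        maps = _maps_for([(vmap(0.25), (0, 0)), (vmap(0.125), (0, 0)), (vmap(0.5), (0, 0))])
        assert information_gain(maps) == pytest.approx(2.0, abs=1e-12)

    def test_half_probability_on_128_grid(self):
        v = np.full((128, 128), 0.5 / (128 * 128 - 1))
        v[3, 4] = 0.5
        assert information_gain(_maps_for([(v, (4, 3))])) == pytest.approx(13.0)

    def test_order_invariance_and_additivity(self, rng):
        maps = [(rng.uniform(0.1, 1, (6, 6)), (int(rng.integers(6)), int(rng.integers(6))))
                for _ in range(9)]
        a = information_gain(_maps_for(maps))
        b = information_gain(_maps_for(maps[::-1]))
        assert a == pytest.approx(b, abs=1e-12)
        # additive decomposition: total = weighted mean of sub-path means
        a1 = information_gain(_maps_for(maps[:4]))
        a2 = information_gain(_maps_for(maps[4:]))
        assert a == pytest.approx((4 * a1 + 5 * a2) / 9.0, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
def test_wrap_degrees_range_and_idempotence(angle):
    w = wrap_degrees(angle)
    assert -180.0 < w <= 180.0
    assert wrap_degrees(w) == pytest.approx(w, abs=1e-9)
    # wrapping is 360-periodic
    assert wrap_degrees(angle + 360.0) == pytest.approx(w, abs=1e-6)


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=20),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=20),
)
def test_auc_complement_symmetry(pos, neg):
    """Swapping the roles of positives and negatives reflects the AUC."""
    a = auc_from_scores(pos, neg)
    b = auc_from_scores(neg, pos)
    assert 0.0 <= a <= 1.0
    assert a + b == pytest.approx(1.0, abs=1e-12)


class TestSaccadeStatistics:
    def test_hand_trigonometry(self):
        stats = saccade_statistics(ScanPath([0, 3], [0, 4]))
        assert stats["amplitude"].iloc[0] == pytest.approx(5.0)
        assert stats["direction"].iloc[0] == pytest.approx(np.degrees(np.arctan2(4, 3)))

    def test_persistence_zero_change(self):
        stats = saccade_statistics(ScanPath([0, 2, 4], [0, 1, 2]))
        assert stats["direction_change"].iloc[1] == pytest.approx(0.0)

    def test_exact_return_is_half_turn(self):
        stats = saccade_statistics(ScanPath([0, 3, 0], [0, 4, 0]))
        assert abs(stats["direction_change"].iloc[1]) == pytest.approx(180.0)

    def test_wrap_convention(self):
        assert wrap_degrees(181.0) == pytest.approx(-179.0)
        assert wrap_degrees(-180.0) == pytest.approx(180.0)
        assert wrap_degrees(180.0) == pytest.approx(180.0)


class TestAmplitudeAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        paths = {("s", i, 1): ScanPath(rng.uniform(0, 20, 12), rng.uniform(0, 20, 12))
                 for i in range(5)}
        ac = amplitude_autocorrelation(paths, max_lag=3)
        assert ac[0] == pytest.approx(1.0)

    def test_alternating_sequence_anticorrelated(self):
        # amplitudes alternate a, b, a, b ... -> lag-1 autocorrelation -> -1;
        # oracle: the direct sample-autocorrelation formula
        xs = np.concatenate([[0], np.cumsum([2, 10] * 15)])
        path = ScanPath(xs, np.zeros_like(xs))
        amp = path.amplitudes()
        amp_c = amp - amp.mean()
        oracle = (amp_c[:-1] * amp_c[1:]).sum() / (amp_c**2).sum()
        ac = amplitude_autocorrelation({("s", 0, 1): path}, max_lag=1)
        assert ac[1] == pytest.approx(oracle, abs=1e-10)
        assert ac[1] < -0.9

    def test_iid_amplitudes_uncorrelated(self, rng):
        paths = {}
        for i in range(500):
            steps = rng.uniform(1, 9, 12)
            xs = np.concatenate([[0], np.cumsum(steps)])
            paths[("s", i, 1)] = ScanPath(xs, np.zeros_like(xs))
        ac = amplitude_autocorrelation(paths, max_lag=1)
        # null mean of lag-1 acf is O(-1/n); CI half-width ~ 4/sqrt(500 * 11)
        assert abs(ac[1] + 1.0 / 11.0) < 0.06


class TestSubjectMoments:
    def test_moments_and_r2_identity(self):
        tab = pd.DataFrame(
            {
                "subject_id": ["a"] * 3 + ["b"] * 3,
                "image_id": ["i"] * 6,
                "trial_id": [1, 1, 1, 1, 1, 1],
                "fixation_index": [1, 2, 3] * 2,
                "x": [0, 3, 3, 0, 6, 6],
                "y": [0, 4, 4, 0, 8, 8],
            }
        )
        mom = subject_moments(tab).set_index("subject_id")
        assert mom.loc["a", "amplitude_mean"] == pytest.approx(2.5)
        assert mom.loc["b", "amplitude_mean"] == pytest.approx(5.0)
        obs = mom["amplitude_mean"].to_numpy()
        assert coefficient_of_determination(obs, obs) == 1.0

    def test_constant_predictor_nonpositive(self):
        assert coefficient_of_determination([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) <= 0.0

    def test_three_subject_hand_toy(self):
        obs = np.array([1.0, 2.0, 4.0])
        sim = np.array([1.5, 2.0, 3.0])
        ss_res = ((obs - sim) ** 2).sum()
        ss_tot = ((obs - obs.mean()) ** 2).sum()
        assert coefficient_of_determination(obs, sim) == pytest.approx(
            1.0 - ss_res / ss_tot
        )


class TestFolds:
    def test_disjoint_cover(self, rng):
        ids = list(range(11))
        folds = make_folds(ids, 4, rng)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == ids
        assert sum(len(f) for f in folds) == 11

    def test_leave_one_out(self, rng):
        folds = make_folds(list(range(6)), 6, rng)
        assert all(len(f) == 1 for f in folds)

    def test_k_bounds(self, rng):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], 4, rng)


def test_crossvalidate_schema_and_posterior_draw_bands(full_params):
    """The CV harness returns one posterior-mean row per (subject, fold)
    plus flagged rows for the requested posterior draws."""
    import warnings
    from gazemix import synthetic_dataset
    from gazemix.inference import GibbsConfig
    from gazemix.metrics import crossvalidate

    ds = synthetic_dataset(
        full_params, n_subjects=1, n_images=4, n_fix=8, shape=(24, 24),
        n_modes=2, seed=3,
    )
    cfg = GibbsConfig(n_iter=40, n_burn=15, n_chains=1, hmc_steps=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rep = crossvalidate(
            ds.table, ds.saliency_maps, variant="full", k=2, config=cfg,
            rng=5, posterior_draws_per_fold=3,
        )
    assert {"subject", "fold", "draw", "auc", "nss", "ig"} <= set(rep.columns)
    mean_rows = rep[rep["draw"] == -1]
    assert len(mean_rows) == 2  # 1 subject x 2 folds
    assert (rep["draw"] >= -1).all() and len(rep) > 2
    assert rep["auc"].between(0, 1).all()


def test_score_paths_consistency(small_map, full_params, rng):
    """The pooled scorer agrees with the metric primitives on one path."""
    from gazemix import sample_scanpath, table_to_paths, paths_to_table

    path = sample_scanpath(small_map, full_params, 10, rng, record_tags=False)
    paths = {("s", 0, 1): path}
    rep = score_paths(paths, full_params, {0: small_map}, rng=123)
    maps = list(step_prediction_maps(path, full_params, small_map))
    assert rep.ig == pytest.approx(information_gain(maps), abs=1e-10)
    assert rep.nss == pytest.approx(nss(maps), abs=1e-10)
    assert rep.n_fix == 10
    assert 0.0 <= rep.auc <= 1.0
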