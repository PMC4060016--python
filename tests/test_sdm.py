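import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from stepwise_impact import (
    Grid,
    OccurrenceSet,
    RasterLayer,
    build_bias_grid,
    compute_auc,
    fit_maxent,
    mtp_threshold,
    predict_and_binarize,
    run_ensemble,
    sample_background,
    simulate_occurrences,
    variable_importance,
)
from stepwise_impact.sdm import FeatureBuilder
from stepwise_impact.synthetic import EnvStack, _gaussian_field, _standardized_features


def brute_force_quartic(grid, points, h):
    """Cellwise double-loop quartic kernel sum (independent oracle)."""
    xs, ys = grid.cell_centres()
    out = np.zeros(grid.shape)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            for px, py in points:
                d2 = (xs[i, j] - px) ** 2 + (ys[i, j] - py) ** 2
                if d2 <= h * h:
                    out[i, j] += 3.0 / (np.pi * h * h) * (1 - d2 / (h * h)) ** 2
    return out


class TestBiasGrid:
    def test_single_point_mode_at_containing_cell(self, grid20):
        occ = OccurrenceSet(np.array([[5250.0, -5250.0]]))  # centre of cell (10, 10)
        bias = build_bias_grid(occ, grid20, bandwidth=2000.0)
        assert bias.layer.values.max() == 1.0
        assert bias.layer.values[10, 10] == 1.0

    def test_far_cells_at_floor(self, grid20):
        occ = OccurrenceSet(np.array([[250.0, -250.0]]))
        bias = build_bias_grid(occ, grid20, bandwidth=1000.0, floor_eps=1e-3)
        assert bias.layer.values[-1, -1] == 1e-3

    def test_matches_brute_force_summation(self):
        g = Grid(9, 9, cell_size=500.0)
        pts = np.array([[1100.0, -900.0], [3200.0, -2700.0]])
        occ = OccurrenceSet(pts)
        h = 1800.0
        bias = build_bias_grid(occ, g, bandwidth=h, floor_eps=0.0)
        expected = brute_force_quartic(g, pts, h)
        expected /= expected.max()
        np.testing.assert_allclose(bias.layer.values, expected, atol=1e-12)

    def test_symmetric_points_give_symmetric_grid(self):
        g = Grid(9, 9, cell_size=100.0)
        # points mirror-symmetric about the grid centre x = 450
        occ = OccurrenceSet(np.array([[150.0, -450.0], [750.0, -450.0]]))
        bias = build_bias_grid(occ, g, bandwidth=300.0)
        np.testing.assert_allclose(bias.layer.values, bias.layer.values[:, ::-1], atol=1e-12)

    def test_nonpositive_bandwidth_rejected(self, grid20):
        occ = OccurrenceSet(np.array([[250.0, -250.0]]))
        with pytest.raises(ValueError):
            build_bias_grid(occ, grid20, bandwidth=0.0)


class TestSampleBackground:
    def test_deterministic(self, grid20):
        a = sample_background(grid20, None, 50, seed=3)
        b = sample_background(grid20, None, 50, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_without_replacement(self, grid20):
        rows, cols = sample_background(grid20, None, 400, seed=1)
        assert len(set(zip(rows.tolist(), cols.tolist()))) == 400

    def test_extreme_contrast_concentrates_samples(self, grid20):
        from stepwise_impact.sdm import BiasGrid

        vals = np.full(grid20.shape, 1e-4)
        vals[:5, :5] = 1.0
        layer = RasterLayer(grid=grid20, values=vals, name="bias")
        bias = BiasGrid(layer=layer, bandwidth=1.0, floor_eps=1e-4)
        rows, cols = sample_background(grid20, bias, 20, seed=2)
        frac_in = ((rows < 5) & (cols < 5)).mean()
        assert frac_in >= 0.95

    def test_uniform_bias_is_uniform(self, grid20):
        """Chi-square over quadrants rarely rejects across 50 replicates."""
        from scipy import stats

        rejections = 0
        for rep in range(50):
            rows, cols = sample_background(grid20, None, 200, seed=rep)
            quad = 2 * (rows >= 10) + (cols >= 10)
            p = stats.chisquare(np.bincount(quad, minlength=4)).pvalue
            rejections += p < 0.01
        assert rejections <= 4

    def test_oversized_request_rejected(self, grid20):
        with pytest.raises(ValueError):
            sample_background(grid20, None, 401, seed=0)


class TestFeatureBuilder:
    def test_linear_plus_quadratic_arity(self, env20):
        bg = sample_background(env20.grid, None, 200, seed=0)
        fb = FeatureBuilder(env20, bg, quadratic=True)
        assert fb.n_features == 12  # 6 linear + 6 quadratic

    def test_constant_layer_dropped(self, env20, grid20):
        layers = dict(env20.layers)
        layers["flat"] = RasterLayer(grid=grid20, values=np.ones(grid20.shape), name="flat")
        env = EnvStack(layers)
        bg = sample_background(grid20, None, 200, seed=0)
        fb = FeatureBuilder(env, bg, quadratic=False)
        assert "flat" not in fb.variables and fb.n_features == 6

    def test_standardized_on_background(self, env20):
        bg = sample_background(env20.grid, None, 300, seed=1)
        fb = FeatureBuilder(env20, bg, quadratic=True)
        F = fb.transform(bg)
        np.testing.assert_allclose(F[:, :6].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(F[:, :6].std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(F[:, 6:], F[:, :6] ** 2, atol=1e-12)


class TestFitMaxent:
    def test_null_model_under_heavy_regularization(self, env20, rng):
        bg = sample_background(env20.grid, None, 300, seed=0)
        fb = FeatureBuilder(env20, bg, quadratic=False)
        B = fb.transform(bg)
        pres_idx = rng.choice(300, size=50, replace=False)
        m = fit_maxent(B[pres_idx], B, reg_lambda=100.0)
        np.testing.assert_allclose(m.beta, 0.0, atol=1e-6)
        np.testing.assert_allclose(m.logistic(B), 0.5, atol=1e-6)

    def test_raw_output_normalizes_over_background(self, env20, rng):
        bg = sample_background(env20.grid, None, 300, seed=0)
        fb = FeatureBuilder(env20, bg, quadratic=True)
        B = fb.transform(bg)
        m = fit_maxent(B[rng.choice(300, 40)], B, reg_lambda=0.01)
        assert m.raw(B).sum() == pytest.approx(1.0, abs=1e-10)

    def test_1d_matches_grid_search_oracle(self, rng):
        """Fitted beta agrees with a dense grid search of the same objective."""
        B = rng.normal(size=(500, 1))
        weights = np.exp(1.3 * B[:, 0])
        idx = rng.choice(500, size=100, p=weights / weights.sum())
        P = B[idx]
        lam = 0.05
        m = fit_maxent(P, B, reg_lambda=lam)

        grid_beta = np.linspace(-3, 3, 60001)
        obj = (P.mean() * grid_beta
               - logsumexp(B * grid_beta[None, :], axis=0)
               - lam * np.abs(grid_beta))
        best = grid_beta[np.argmax(obj)]
        assert m.beta[0] == pytest.approx(best, abs=1e-3)

    def test_parameter_recovery_on_simulation(self, env100, beta_true):
        """Rank correlation of fitted vs true linear predictor > 0.95 at
        n = 2,000 presences, no bias, linear features."""
        g = env100.grid
        occ = simulate_occurrences(env100, beta_true, [], n=2000, seed=8)
        bg = sample_background(g, None, 10_000, seed=9)
        fb = FeatureBuilder(env100, bg, quadratic=False)
        m = fit_maxent(fb.transform(occ.cells(g)), fb.transform(bg), reg_lambda=0.01)
        rows, cols = np.indices(g.shape)
        fitted = fb.transform((rows.ravel(), cols.ravel())) @ m.beta
        z, names = _standardized_features(env100)
        true_lp = z @ np.array([beta_true.get(v, 0.0) for v in names])
        assert spearmanr(fitted, true_lp).statistic > 0.95

    def test_too_few_presences_rejected(self, rng):
        B = rng.normal(size=(100, 2))
        with pytest.raises(ValueError):
            fit_maxent(B[:3], B)


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties(self):
        assert compute_auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_worked_example(self):
        assert compute_auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_matches_exhaustive_pair_count(self, rng):
        sp = rng.integers(0, 10, size=150) / 10.0  # many ties
        sb = rng.integers(0, 10, size=200) / 10.0
        wins = sum((p > b) + 0.5 * (p == b) for p in sp for b in sb)
        assert compute_auc(sp, sb) == pytest.approx(wins / (len(sp) * len(sb)), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        sp, sb = rng.normal(1, 1, 80), rng.normal(0, 1, 120)
        base = compute_auc(sp, sb)
        for f in (np.exp, lambda x: x**3, lambda x: 1 / (1 + np.exp(-x))):
            assert compute_auc(f(sp), f(sb)) == pytest.approx(base, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [0.5])


class TestMTPThreshold:
    def test_constant_scores(self):
        assert mtp_threshold([0.3, 0.3, 0.3]) == 0.3

    def test_singleton(self):
        assert mtp_threshold([0.42]) == 0.42

    def test_nearest_rank_convention(self):
        scores = np.arange(1, 11) / 10.0  # 0.1 .. 1.0
        assert mtp_threshold(scores) == 0.1  # ceil(0.1*10) = 1st smallest

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mtp_threshold([])


@pytest.fixture(scope="module")
def fitted(env20, beta_true):
    occ = simulate_occurrences(env20, beta_true, [], n=60, seed=5)
    bias = build_bias_grid(occ, env20.grid)
    ens = run_ensemble(occ, env20, bias, n_runs=5, seed=11, background_size=300)
    return occ, bias, ens


class TestEnsemble:
    def test_split_sizes_75_25(self, env20, beta_true):
        occ = simulate_occurrences(env20, beta_true, [], n=253, seed=5)
        ens = run_ensemble(occ, env20, None, n_runs=2, seed=1, background_size=300)
        for r in ens.runs:
            assert len(r.train_indices) == 190 and len(r.test_indices) == 63

    def test_deterministic_mean_auc(self, env20, beta_true):
        occ = simulate_occurrences(env20, beta_true, [], n=40, seed=5)
        a = run_ensemble(occ, env20, None, n_runs=3, seed=2, background_size=200)
        b = run_ensemble(occ, env20, None, n_runs=3, seed=2, background_size=200)
        assert a.mean_test_auc == b.mean_test_auc

    def test_strong_signal_gives_high_auc(self, env100):
        beta_strong = {"solar_radiation": 3.0, "elevation": -3.0}
        occ = simulate_occurrences(env100, beta_strong, [], n=200, seed=6)
        ens = run_ensemble(occ, env100, None, n_runs=5, seed=3, background_size=2000)
        assert ens.mean_test_auc > 0.9

    def test_mean_threshold_is_mean_of_run_thresholds(self, fitted):
        _, _, ens = fitted
        assert ens.mean_threshold == pytest.approx(
            np.mean([r.mtp10_threshold for r in ens.runs]))

    def test_binarize_threshold_extremes(self, fitted, env20):
        _, _, ens = fitted
        all_in = predict_and_binarize(ens, env20, threshold=0.0)
        assert all_in.suitable_mask.values.sum() == env20.grid.n_rows * env20.grid.n_cols
        none_in = predict_and_binarize(ens, env20, threshold=1.1)
        assert none_in.suitable_mask.values.sum() == 0

    def test_suitable_count_non_increasing_in_threshold(self, fitted, env20):
        _, _, ens = fitted
        counts = [predict_and_binarize(ens, env20, threshold=t).suitable_mask.values.sum()
                  for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mask_matches_threshold_rule(self, fitted, env20):
        _, _, ens = fitted
        res = predict_and_binarize(ens, env20)
        expect = res.suitability.values >= res.threshold_used
        np.testing.assert_array_equal(res.suitable_mask.values.astype(bool), expect)


@pytest.fixture(scope="module")
def noise_env():
    """One informative variable among five pure-noise variables."""
    g = Grid(40, 40)
    rng = np.random.default_rng(21)
    layers = {"signal": RasterLayer(grid=g, values=_gaussian_field(g.shape, rng, 5.0),
                                    name="signal")}
    for i in range(5):
        layers[f"noise{i}"] = RasterLayer(
            grid=g, values=_gaussian_field(g.shape, rng, 5.0), name=f"noise{i}")
    return EnvStack(layers)


@pytest.fixture(scope="module")
def importance(noise_env):
    occ = simulate_occurrences(noise_env, {"signal": 2.0}, [], n=300, seed=13)
    ens = run_ensemble(occ, noise_env, None, n_runs=3, seed=14, background_size=1000)
    return variable_importance(ens, occ, noise_env, None, seed=15)


class TestVariableImportance:
    def test_contributions_sum_to_100(self, importance):
        assert importance["percent_contribution"].sum() == pytest.approx(100.0, abs=0.1)

    def test_informative_variable_has_highest_gain_alone(self, importance):
        best = importance.loc[importance["gain_alone"].idxmax(), "variable"]
        assert best == "signal"

    def test_noise_variables_contribute_little(self, importance):
        noise = importance[importance["variable"] != "signal"]
        assert (noise["percent_contribution"] < 5.0).all()
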