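import numpy as np
import pytest
from scipy import stats

from stepwise_impact import (
    Grid,
    RasterLayer,
    compute_degree_days,
    generate_env_stack,
    generate_landcover,
    generate_sunshine_stack,
    simulate_occurrences,
    simulate_plot_surveys,
)
from stepwise_impact.synthetic import EnvStack


def morans_i_lag1(x: np.ndarray) -> float:
    """Direct-summation Moran's I with rook (lag-1) neighbours."""
    z = x - x.mean()
    num = 0.0
    n_pairs = 0
    for dr, dc in ((0, 1), (1, 0)):
        a = z[: x.shape[0] - dr, : x.shape[1] - dc]
        b = z[dr:, dc:]
        num += 2 * (a * b).sum()  # symmetric weights
        n_pairs += 2 * a.size
    return (x.size / n_pairs) * num / (z**2).sum()


class TestEnvStack:
    def test_deterministic_under_seed(self, grid20):
        a = generate_env_stack(grid20, seed=1)
        b = generate_env_stack(grid20, seed=1)
        for v in a.layers:
            np.testing.assert_array_equal(a[v].values, b[v].values)

    def test_spatial_autocorrelation_increases_with_smoothness(self):
        g = Grid(60, 60)
        env = generate_env_stack(g, seed=3, smoothness=8.0)
        assert morans_i_lag1(env["elevation"].values) > 0.5

    def test_physical_invariants(self, env20):
        assert (env20["tmax"].values >= env20["tmin"].values).all()
        assert (env20["degree_days"].values >= 0).all()
        assert (env20["elevation"].values >= 0).all()

    def test_smoothness_below_one_rejected(self, grid20):
        with pytest.raises(ValueError):
            generate_env_stack(grid20, seed=1, smoothness=0.5)


class TestDegreeDays:
    def test_at_base_is_zero(self):
        assert compute_degree_days(np.full(365, 10.0)) == 0.0

    def test_unit_excess(self):
        assert compute_degree_days(np.full(365, 11.0)) == pytest.approx(365.0)

    def test_sinusoid_matches_daywise_summation(self):
        days = np.arange(365)
        temps = 12.0 + 8.0 * np.sin(2 * np.pi * days / 365)
        expected = sum(max(0.0, t - 10.0) for t in temps)  # brute-force oracle
        assert compute_degree_days(temps) == pytest.approx(expected, abs=1e-9)

    def test_nonfinite_rejected(self):
        temps = np.full(365, 12.0)
        temps[100] = np.nan
        with pytest.raises(ValueError):
            compute_degree_days(temps)


class TestLandcover:
    def test_single_class_uniform(self, grid20):
        lc = generate_landcover(grid20, {"SAS": 1.0}, seed=0)
        assert (lc.values == 3).all()  # SAS code

    def test_class_frequencies_match_weights(self):
        g = Grid(200, 200)
        weights = {"HSV": 0.1, "BUA": 0.2, "SAS": 0.7}
        lc = generate_landcover(g, weights, seed=5)
        from stepwise_impact.landcover import CLASS_IDS

        for cls, w in weights.items():
            freq = (lc.values == CLASS_IDS[cls]).mean()
            assert abs(freq - w) < 0.03, f"{cls}: {freq} vs {w}"

    def test_deterministic(self, grid20):
        a = generate_landcover(grid20, {"HSV": 0.5, "FOR": 0.5}, seed=9)
        b = generate_landcover(grid20, {"HSV": 0.5, "FOR": 0.5}, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_class_rejected(self, grid20):
        with pytest.raises(KeyError):
            generate_landcover(grid20, {"XYZ": 1.0}, seed=0)

    def test_weights_must_sum_to_one(self, grid20):
        with pytest.raises(ValueError):
            generate_landcover(grid20, {"HSV": 0.4, "BUA": 0.4}, seed=0)


class TestSimulateOccurrences:
    def test_exact_count(self, env20):
        occ = simulate_occurrences(env20, {}, [], n=253, seed=1)
        assert len(occ) == 253

    def test_uniform_when_no_signal(self, env20):
        """beta = 0 and no bias: quadrant counts consistent with uniformity
        (chi-square at alpha=0.01 rarely rejects across 50 replicates)."""
        g = env20.grid
        rejections = 0
        for rep in range(50):
            occ = simulate_occurrences(env20, {}, [], n=200, seed=rep)
            rows, cols = occ.cells(g)
            quad = 2 * (rows >= g.n_rows // 2) + (cols >= g.n_cols // 2)
            counts = np.bincount(quad, minlength=4)
            p = stats.chisquare(counts).pvalue
            rejections += p < 0.01
        assert rejections <= 4  # E[rejections] = 0.5 under uniformity

    def test_positive_coefficient_shifts_covariate(self, env20):
        occ = simulate_occurrences(env20, {"solar_radiation": 2.0}, [], n=500, seed=2)
        solar_at_occ = env20["solar_radiation"].values[occ.cells(env20.grid)].mean()
        assert solar_at_occ > env20["solar_radiation"].values.mean()

    def test_degenerate_landscape_rejected(self, grid20):
        dead = EnvStack({
            "elevation": RasterLayer(grid=grid20, values=np.zeros(grid20.shape),
                                     nodata_mask=np.ones(grid20.shape, dtype=bool)),
        })
        with pytest.raises(ValueError, match="degenerate"):
            simulate_occurrences(dead, {}, [], n=10, seed=0)


class TestSimulatePlotSurveys:
    def test_zero_occupancy_all_empty(self):
        df = simulate_plot_surveys({"FOR": (0.0, 1.0)}, {"FOR": 200}, seed=0)
        assert (df["nests"] == 0).all()

    def test_occupancy_recovered_at_large_n(self):
        df = simulate_plot_surveys({"HSV": (0.27, 1.25)}, {"HSV": 10_000}, seed=1)
        occ_hat = (df["nests"] >= 1).mean()
        assert abs(occ_hat - 0.27) < 0.02

    def test_occupied_plots_hold_at_least_one_nest(self):
        df = simulate_plot_surveys({"BUA": (0.9, 1.5)}, {"BUA": 500}, seed=2)
        assert set(df["nests"].unique()) <= set(range(0, 10))
        occupied = df[df["nests"] > 0]
        assert (occupied["nests"] >= 1).all() and len(occupied) > 0

    def test_deterministic(self):
        a = simulate_plot_surveys({"SAS": (0.1, 1.0)}, {"SAS": 50}, seed=3)
        b = simulate_plot_surveys({"SAS": (0.1, 1.0)}, {"SAS": 50}, seed=3)
        assert a.equals(b)

    def test_lambda_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_plot_surveys({"HSV": (0.3, 0.5)}, {"HSV": 10}, seed=0)


class TestSunshineStack:
    def test_zero_fraction_all_dark(self, grid20):
        stack = generate_sunshine_stack(grid20, seed=0, mean_bright_fraction=0.0)
        assert (stack.radiation == 0).all()
        assert stack.n_hours == 89 * 12

    def test_target_seasonal_hours_recovered(self):
        g = Grid(50, 50)
        target = 540.0
        stack = generate_sunshine_stack(g, seed=4, mean_bright_fraction=target / (89 * 12))
        bright = (stack.radiation >= 0.432).sum(axis=0)
        assert abs(bright.mean() - target) < 15.0

    def test_deterministic(self, grid20):
        a = generate_sunshine_stack(grid20, season_days=5, seed=6)
        b = generate_sunshine_stack(grid20, season_days=5, seed=6)
        np.testing.assert_array_equal(a.radiation, b.radiation)

    def test_fraction_out_of_range_rejected(self, grid20):
        with pytest.raises(ValueError):
            generate_sunshine_stack(grid20, seed=0, mean_bright_fraction=1.5)
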