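"""Data-generating mechanism and scenario-runner tests."""

import math

import numpy as np
import pytest
from scipy import stats

from robustmeta import SimulationConfig, run_scenario, simulate_meta, zemba_profile
from robustmeta.simulation import (
    _truncated_normal,
    draw_study_sizes,
    selection_p,
    type_a_bias,
    type_b_limits,
)


@pytest.fixture
def base_cfg():
    return SimulationConfig(K=10, beta=0.0, n1=100, n2=5000)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n1": 5000, "n2": 100},
            {"delta": 1.5},
            {"N": 50, "n1": 100, "n2": 5000},
            {"p_min": 0.0},
            {"bias_type": "type_c"},
            {"selection_fn": "cubic"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestStudySizes:
    def test_degenerate_range(self):
        cfg = SimulationConfig(K=5, n1=399, n2=401)
        rng = np.random.default_rng(0)
        # nearly-degenerate range: sizes in {399, 400, 401}
        n, sigma = draw_study_sizes(cfg, rng)
        assert np.all((n >= 399) & (n <= 401))
        np.testing.assert_allclose(sigma, np.sqrt(4.0 / n))

    def test_se_formula(self):
        assert math.sqrt(4 / 100) == pytest.approx(0.2)
        assert math.sqrt(4 / 400) == pytest.approx(0.1)

    def test_uniform_mean(self):
        cfg = SimulationConfig(K=100_000, n1=100, n2=5000)
        n, _ = draw_study_sizes(cfg, np.random.default_rng(1))
        expected = (100 + 5000) / 2
        mc_se = (5000 - 100) / math.sqrt(12 * 100_000)
        assert abs(n.mean() - expected) < 3 * mc_se


class TestTypeABias:
    def test_threshold_and_boundary(self):
        cfg = SimulationConfig(
            K=4, bias_type="type_a", delta=1.0, b_max=0.4, N=3000, n1=100, n2=5000
        )
        rng = np.random.default_rng(0)
        n = np.array([100, 1550, 3000, 4500])
        b = type_a_bias(n, cfg, rng)
        assert b[0] == pytest.approx(0.4)  # n = n1 -> b_max
        assert b[1] == pytest.approx(0.2)  # midpoint of [n1, N]
        assert b[2] == 0.0  # n >= N
        assert b[3] == 0.0

    def test_delta_zero_no_bias(self):
        cfg = SimulationConfig(K=50, bias_type="type_a", delta=0.0)
        b = type_a_bias(
            np.full(50, 200), cfg, np.random.default_rng(0)
        )
        assert np.all(b == 0.0)

    def test_fixed_count_flags(self):
        cfg = SimulationConfig(K=10, bias_type="type_a", delta=0.3, fixed_count=True)
        b = type_a_bias(np.full(10, 100), cfg, np.random.default_rng(2))
        assert np.count_nonzero(b) == 3


class TestTypeBSelection:
    def test_no_selection_above_threshold(self, base_cfg):
        cfg = SimulationConfig(K=3, bias_type="type_b", N=3000)
        n = np.array([3000, 4000, 5000])
        lim = type_b_limits(n, cfg, np.sqrt(4.0 / n))
        assert np.all(np.isinf(lim.lower) & (lim.lower < 0))

    def test_step_function_limit(self):
        # STEP, n < N, p_min = 0.05, beta = 0 -> l = z_0.95
        cfg = SimulationConfig(
            K=1, bias_type="type_b", selection_fn="step", p_min=0.05, beta=0.0
        )
        lim = type_b_limits(np.array([500]), cfg, np.array([np.sqrt(4 / 500)]))
        assert lim.lower[0] == pytest.approx(stats.norm.ppf(0.95), abs=1e-9)
        assert lim.lower[0] == pytest.approx(1.6449, abs=1e-4)

    def test_linear_boundary_is_p_min(self):
        cfg = SimulationConfig(K=1, bias_type="type_b", selection_fn="linear")
        assert selection_p(np.array([100]), cfg)[0] == pytest.approx(0.05)

    @pytest.mark.parametrize("fn", ["linear", "sqrt", "quadratic", "step"])
    def test_p_nondecreasing_in_n(self, fn):
        cfg = SimulationConfig(K=1, bias_type="type_b", selection_fn=fn)
        n = np.linspace(100, 6000, 200)
        p = selection_p(n, cfg)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= cfg.p_min) & (p <= 1.0))

    def test_nonzero_beta_shifts_limit(self):
        cfg = SimulationConfig(
            K=1, bias_type="type_b", selection_fn="step", beta=0.02
        )
        sigma = np.array([0.2])
        lim = type_b_limits(np.array([500]), cfg, sigma)
        assert lim.lower[0] == pytest.approx(
            stats.norm.ppf(0.95) - 0.02 / 0.2, abs=1e-9
        )


class TestTruncatedNormal:
    def test_half_normal_moments(self):
        """Closed forms at l=0: E = φ(0)/(1−Φ(0)), Var = 1 − 2/π."""
        rng = np.random.default_rng(99)
        draws = _truncated_normal(
            np.zeros(100_000), np.full(100_000, np.inf), rng
        )
        e_expected = math.sqrt(2 / math.pi)  # 0.7979
        v_expected = 1 - 2 / math.pi  # 0.3634
        assert np.all(draws >= 0)
        mc_se_mean = math.sqrt(v_expected / 100_000)
        assert abs(draws.mean() - e_expected) < 3 * mc_se_mean
        assert abs(draws.var() - v_expected) < 3 * 0.002

    def test_extreme_limit_valid(self):
        rng = np.random.default_rng(0)
        draws = _truncated_normal(np.full(1000, 6.0), np.full(1000, np.inf), rng)
        assert np.all(np.isfinite(draws)) and np.all(draws >= 6.0)

    def test_untruncated_mean(self):
        rng = np.random.default_rng(1)
        draws = _truncated_normal(
            np.full(100_000, -np.inf), np.full(100_000, np.inf), rng
        )
        assert abs(draws.mean()) < 3 / math.sqrt(100_000)


class TestSimulateMeta:
    def test_unbiased_case(self):
        cfg = SimulationConfig(K=2000, beta=0.3)
        data, truth = simulate_meta(cfg, np.random.default_rng(4))
        assert np.all(truth["bias"] == 0.0)
        # mean of estimates ~ beta within MC error
        mc_se = data.std_errors.mean() / math.sqrt(2000)
        assert abs(data.estimates.mean() - 0.3) < 4 * mc_se

    def test_type_b_shifts_only_small_studies(self):
        cfg = SimulationConfig(
            K=4000, bias_type="type_b", selection_fn="step", N=2500
        )
        data, truth = simulate_meta(cfg, np.random.default_rng(8))
        small = data.sizes < 2500
        large = ~small
        small_mean = data.estimates[small].mean()
        large_mean = data.estimates[large].mean()
        assert small_mean > 0.05  # selected upward
        assert abs(large_mean) < 0.01  # exactly unbiased


class TestZembaProfile:
    def test_mixed_bias_ten_study_grouping(self):
        # b1=b2 < b3 < b4=b5=b6=0 < b7=b8=b9 < b10
        bias = np.array([-2, -2, -1, 0, 0, 0, 1, 1, 1, 3], dtype=float)
        w = np.arange(1, 11, dtype=float)
        w = w / w.sum()
        prof = zemba_profile(bias, w)
        assert prof.omega_0 == pytest.approx(w[3:6].sum())
        assert prof.omega_max == pytest.approx(w[6:9].sum())
        assert not prof.satisfied  # ω(7,8,9) = 24/55 > ω(4,5,6) = 15/55

    def test_all_unbiased(self):
        prof = zemba_profile(np.zeros(6), np.full(6, 1 / 6))
        assert prof.omega_0 == pytest.approx(1.0)
        assert prof.satisfied

    def test_strict_inequality_at_tie(self):
        bias = np.array([0.0] * 5 + [1.0] * 5)
        prof = zemba_profile(bias, np.full(10, 0.1))
        assert prof.omega_0 == pytest.approx(0.5)
        assert prof.omega_max == pytest.approx(0.5)
        assert not prof.satisfied


class TestRunScenario:
    def test_seeded_determinism(self):
        kwargs = dict(
            overrides={"K": 5},
            estimator_names=("weighted_mean", "weighted_median"),
            reps=30,
            seed=123,
            n_boot=50,
        )
        a = run_scenario(1, **kwargs)
        b = run_scenario(1, **kwargs)
        assert a.table.equals(b.table)
        assert a.mean_i2 == b.mean_i2

    def test_complementarity_under_null(self):
        s = run_scenario(
            1,
            overrides={"K": 5},
            estimator_names=("weighted_mean",),
            reps=50,
            seed=3,
            n_boot=50,
        )
        row = s.table.loc["weighted_mean"]
        assert row["rejection_rate"] == pytest.approx(1.0 - row["coverage"])

    def test_scenario_three_biases_weighted_mean_upward(self):
        null = run_scenario(
            1, overrides={"K": 30}, estimator_names=("weighted_mean",),
            reps=300, seed=10, n_boot=50,
        )
        sel = run_scenario(
            3, overrides={"K": 30}, estimator_names=("weighted_mean",),
            reps=300, seed=10, n_boot=50,
        )
        assert sel.table.loc["weighted_mean", "bias"] > 3 * (
            null.table.loc["weighted_mean", "empirical_se"] / math.sqrt(300)
        )
        assert sel.table.loc["weighted_mean", "bias"] > null.table.loc[
            "weighted_mean", "bias"
        ]

    def test_selection_induces_underdispersion(self):
        """Square-root selection truncates errors, deflating mean I²."""
        kwargs = dict(
            overrides={"K": 10}, estimator_names=("weighted_mean",),
            reps=2000, seed=77, n_boot=50,
        )
        none = run_scenario(1, **kwargs)
        sqrt_sel = run_scenario(4, **kwargs)
        assert sqrt_sel.mean_i2 < none.mean_i2

    def test_bias_monotone_in_threshold(self):
        """Raising N exposes more studies to selection: larger WM bias."""
        biases = []
        for N in (1500, 4500):
            s = run_scenario(
                3, overrides={"K": 10, "N": N},
                estimator_names=("weighted_mean",), reps=500, seed=21, n_boot=50,
            )
            biases.append(s.table.loc["weighted_mean", "bias"])
        assert biases[1] > biases[0]

    def test_power_ordering_with_true_effect(self):
        """The weighted mean is most powerful when there is no bias.

        Under a true effect of 0.02 and no small-study effects, the
        efficient weighted mean rejects the null more often than the
        robust or extrapolation-based estimators.
        """
        s = run_scenario(
            7,
            overrides={"K": 10},
            estimator_names=(
                "weighted_mean", "weighted_median", "mbe",
                "regression_extrapolation",
            ),
            reps=300, seed=70, n_boot=100,
        )
        power = s.table["rejection_rate"]
        assert power["weighted_mean"] >= power["weighted_median"]
        assert power["weighted_mean"] >= power["mbe"]
        assert power["weighted_mean"] >= power["regression_extrapolation"]

    def test_invalid_scenario_id(self):
        with pytest.raises(ValueError):
            run_scenario(8, reps=1, seed=0)

    def test_replicate_stream(self):
        s = run_scenario(
            1, overrides={"K": 5}, estimator_names=("weighted_mean",),
            reps=10, seed=0, n_boot=50, keep_replicates=True,
        )
        assert len(s.replicates) == 10
        assert set(s.replicates.columns) >= {
            "replicate", "estimator", "estimate", "se", "covered", "rejected"
        }
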