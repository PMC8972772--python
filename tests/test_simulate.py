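"""Copula samplers, model definitions, truth oracles, and the experiment driver."""

import math

import numpy as np
import pytest
from scipy import stats

import condtau as ct
from condtau import CopulaSpec, MixtureCopulaSpec


def _const(v):
    return lambda z: np.full_like(np.asarray(z, dtype=float), v)


class TestTriangularICDF:
    @pytest.mark.parametrize(
        "u, expected", [(0.5, 0.0), (0.0, -1.0), (1.0, 1.0), (0.875, 0.5), (0.125, -0.5)]
    )
    def test_values(self, u, expected):
        assert ct.triangular_icdf(u) == pytest.approx(expected)

    def test_strictly_increasing(self):
        u = np.linspace(0, 1, 201)
        assert np.all(np.diff(ct.triangular_icdf(u)) > 0)

    def test_distribution_matches_density(self, rng):
        x = ct.triangular_icdf(rng.uniform(size=4000))

        def cdf(t):
            t = np.asarray(t)
            return np.where(t < 0, (1 + t) ** 2 / 2, 1 - (1 - t) ** 2 / 2)

        d, _ = stats.kstest(x, cdf)
        assert d < 0.03

    def test_domain_check(self):
        with pytest.raises(ValueError):
            ct.triangular_icdf(1.5)


class TestArchimedeanSamplers:
    @pytest.mark.parametrize(
        "family, theta",
        [("clayton", 2.0), ("gumbel", 2.0), ("frank", 5.0), ("independence", 0.0)],
    )
    def test_marginal_uniformity(self, family, theta, rng):
        spec = CopulaSpec(family, 2, _const(theta))
        U = ct.sample_archimedean(spec, 1.0, 10_000, rng)
        for j in range(2):
            d, _ = stats.kstest(U[:, j], "uniform")
            assert d < 0.02

    @pytest.mark.parametrize(
        "family, theta",
        [
            ("clayton", 0.5),
            ("clayton", 2.0),
            ("clayton", math.exp(0.5) + 1),
            ("gumbel", 1.2),
            ("gumbel", 2.0),
            ("gumbel", math.exp(2.5) + 1),
            ("frank", 0.9),
            ("frank", 5.0),
            ("frank", math.exp(1.5 + 0.4 * 4) + 1),
        ],
    )
    def test_pairwise_tau_matches_closed_form(self, family, theta):
        """Empirical tau at n = 1e5 within 3 Monte-Carlo s.e. of the closed form."""
        rng = np.random.default_rng(hash((family, round(theta, 6))) % 2**31)
        n = 100_000
        U = ct.sample_archimedean(CopulaSpec(family, 2, _const(theta)), 0.0, n, rng)
        emp = stats.kendalltau(U[:, 0], U[:, 1]).statistic
        truth = ct.true_pairwise_tau(family, theta)
        se = 3.0 * math.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(emp - truth) < max(se, 0.01)

    def test_frank_negative_theta_bivariate(self):
        rng = np.random.default_rng(8)
        U = ct.sample_archimedean(CopulaSpec("frank", 2, _const(-5.0)), 0.0, 50_000, rng)
        emp = stats.kendalltau(U[:, 0], U[:, 1]).statistic
        assert emp == pytest.approx(ct.true_pairwise_tau("frank", -5.0), abs=0.02)

    @pytest.mark.parametrize("family", ["clayton", "gumbel"])
    def test_concordance_increases_with_theta(self, family):
        thetas = [1.1, 1.5, 2.5, 4.0] if family == "gumbel" else [0.5, 1.0, 2.0, 4.0]
        taus = []
        for th in thetas:
            rng = np.random.default_rng(77)
            U = ct.sample_archimedean(CopulaSpec(family, 2, _const(th)), 0.0, 20_000, rng)
            taus.append(stats.kendalltau(U[:, 0], U[:, 1]).statistic)
        assert np.all(np.diff(taus) > 0)

    def test_parameter_range_validation(self, rng):
        with pytest.raises(ValueError, match="clayton"):
            ct.sample_archimedean(CopulaSpec("clayton", 2, _const(-1.0)), 0.0, 10, rng)
        with pytest.raises(ValueError, match="gumbel"):
            ct.sample_archimedean(CopulaSpec("gumbel", 2, _const(0.5)), 0.0, 10, rng)
        with pytest.raises(ValueError, match="frank"):
            ct.sample_archimedean(CopulaSpec("frank", 3, _const(-2.0)), 0.0, 10, rng)

    def test_trivariate_samplers_in_unit_cube(self, rng):
        for family, theta in [("clayton", 2.0), ("gumbel", 3.0), ("frank", 4.0)]:
            U = ct.sample_archimedean(CopulaSpec(family, 3, _const(theta)), 0.0, 2000, rng)
            assert U.shape == (2000, 3)
            assert np.all((U >= 0) & (U <= 1))


class TestMixture:
    def test_tau_between_component_taus(self, rng):
        a = CopulaSpec("clayton", 2, _const(0.5))   # tau = 0.2
        b = CopulaSpec("gumbel", 2, _const(4.0))    # tau = 0.75
        U = ct.sample_mixture(MixtureCopulaSpec(a, b, 0.5), 0.0, 50_000, rng)
        emp = stats.kendalltau(U[:, 0], U[:, 1]).statistic
        assert 0.2 < emp < 0.75

    def test_degenerate_weight_approaches_component(self, rng):
        a = CopulaSpec("clayton", 2, _const(0.5))
        b = CopulaSpec("gumbel", 2, _const(4.0))
        U = ct.sample_mixture(MixtureCopulaSpec(a, b, 0.999), 0.0, 30_000, rng)
        emp = stats.kendalltau(U[:, 0], U[:, 1]).statistic
        assert emp == pytest.approx(0.2, abs=0.05)

    def test_weight_validation(self):
        a = CopulaSpec("clayton", 2, _const(1.0))
        with pytest.raises(ValueError):
            MixtureCopulaSpec(a, a, 1.0)
        with pytest.raises(ValueError):
            MixtureCopulaSpec(a, CopulaSpec("clayton", 3, _const(1.0)), 0.5)


class TestTruthOracles:
    def test_closed_forms(self):
        assert ct.true_pairwise_tau("clayton", 2.0) == pytest.approx(0.5)
        assert ct.true_pairwise_tau("gumbel", 1.0) == pytest.approx(0.0)
        assert ct.true_pairwise_tau("gumbel", 4.0) == pytest.approx(0.75)
        assert ct.true_pairwise_tau("frank", 1e-8) == pytest.approx(0.0, abs=1e-8)
        assert ct.true_pairwise_tau("independence", 0.0) == 0.0

    def test_frank_antisymmetry(self):
        assert ct.true_pairwise_tau("frank", -4.0) == pytest.approx(
            -ct.true_pairwise_tau("frank", 4.0)
        )

    def test_multivariate_mc_oracle(self):
        rng = np.random.default_rng(5)
        indep = CopulaSpec("independence", 3, _const(0.0))
        assert ct.true_multivariate_tau_mc(indep, 0.0, 50_000, rng) == pytest.approx(
            0.0, abs=0.02
        )
        near_comono = CopulaSpec("clayton", 3, _const(50.0))
        assert ct.true_multivariate_tau_mc(near_comono, 0.0, 50_000, rng) == pytest.approx(
            1.0, abs=0.05
        )
        c2 = CopulaSpec("clayton", 2, _const(2.0))
        assert ct.true_multivariate_tau_mc(c2, 0.0, 100_000, rng) == pytest.approx(
            0.5, abs=0.01
        )


class TestModels:
    def test_parameter_functions_match_definitions(self):
        m4 = ct.model_spec("4").copula
        assert m4.theta_fn(np.array([0.0]))[0] == pytest.approx(math.exp(1.5) + 1)
        m2 = ct.model_spec("2").copula
        assert m2.theta_fn(np.array([2.0]))[0] == pytest.approx(0.8)
        m9 = ct.model_spec("9").copula
        assert m9.a.theta_fn(np.array([1.0]))[0] == pytest.approx(
            math.sin(4 * math.pi / 7) + 1
        )
        assert m9.b.theta_fn(np.array([1.0]))[0] == pytest.approx(math.exp(2.5) + 1)
        assert m9.w == pytest.approx(0.7)
        m8 = ct.model_spec("8").copula
        assert m8.w == pytest.approx(0.3)
        assert m8.a.theta_fn(np.array([2.0]))[0] == pytest.approx(8.0 / 9.0)

    @pytest.mark.parametrize("mid, p, zlo, zhi", [
        ("1", 2, 0, 1), ("2", 2, 0, 6), ("3", 2, 2, 5), ("4", 2, 2, 5),
        ("5", 3, 2, 5), ("6", 3, 2, 5), ("7", 2, 0, 6), ("8", 2, 2, 5),
        ("9", 3, 0, 6), ("10", 3, 2, 5),
    ])
    def test_shapes_and_covariate_support(self, mid, p, zlo, zhi, rng):
        s = ct.generate_model(mid, 200, rng)
        assert s.p == p and s.n == 200
        assert s.Z.min() >= zlo and s.Z.max() <= zhi

    def test_model1_conditional_independence(self):
        s = ct.generate_model("1", 2000, np.random.default_rng(3))
        tau = ct.conditional_kendall_tau(s, ct.nw_weights(0.5, s.Z, 0.1)).tau
        assert abs(tau) < 0.1

    def test_model3_recovers_gumbel_tau(self):
        truth = 1.0 - 1.0 / (math.exp(0.5) + 1.0)  # ~0.6225
        s = ct.generate_model("3", 2000, np.random.default_rng(4))
        tau = ct.conditional_kendall_tau(s, ct.nw_weights(3.5, s.Z, 0.12)).tau
        assert tau == pytest.approx(truth, abs=0.1)

    def test_model_nl_recovers_gaussian_tau(self):
        truth = 2.0 / math.pi * math.asin(0.75)  # ~0.5399
        s = ct.generate_model("NL", 2000, np.random.default_rng(5))
        tau = ct.conditional_kendall_tau(s, ct.nw_weights(0.5, s.Z, 0.06)).tau
        assert tau == pytest.approx(truth, abs=0.1)

    def test_model7_constant_dependence(self):
        s = ct.generate_model("7", 3000, np.random.default_rng(6))
        t1 = ct.conditional_kendall_tau(s, ct.nw_weights(1.5, s.Z, 0.7)).tau
        t2 = ct.conditional_kendall_tau(s, ct.nw_weights(4.5, s.Z, 0.7)).tau
        assert abs(t1 - t2) < 0.12

    def test_unknown_model_id(self, rng):
        with pytest.raises(ValueError):
            ct.generate_model("42", 100, rng)

    def test_seeded_reproducibility(self):
        a = ct.generate_model("8", 150, np.random.default_rng(9))
        b = ct.generate_model("8", 150, np.random.default_rng(9))
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.Z, b.Z)


class TestScenarios:
    def test_model_pairings(self):
        assert ct.SCENARIOS == {1: ("2", "2"), 2: ("2", "4"), 3: ("8", "8"), 4: ("8", "4")}
        spec = ct.scenario_spec(2)
        assert (spec.model1, spec.model2) == ("2", "4")
        assert spec.n == 250

    def test_generation_and_determinism(self):
        a1, a2 = ct.generate_scenario(4, np.random.default_rng(7), n=60)
        b1, b2 = ct.generate_scenario(4, np.random.default_rng(7), n=60)
        np.testing.assert_array_equal(a1.Y, b1.Y)
        np.testing.assert_array_equal(a2.Y, b2.Y)
        assert a1.n == a2.n == 60

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            ct.scenario_spec(9)


class TestExperimentDriver:
    def test_reproducible_tables(self):
        kw = dict(model="3", n=100, S=4, B=100, seed=42)
        a = ct.rejection_frequency_experiment(**kw)
        b = ct.rejection_frequency_experiment(**kw)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        assert set(a.table.columns) == {
            "model", "statistic", "n", "alpha", "rejection_pct"
        }

    def test_vn1_statistic_route(self):
        res = ct.rejection_frequency_experiment(
            model="3", n=80, S=3, B=100, seed=1, statistic="Vn1"
        )
        assert np.all((res.p_values > 0) & (res.p_values <= 1))

    def test_requires_exactly_one_target(self):
        with pytest.raises(ValueError):
            ct.rejection_frequency_experiment(model="1", scenario=1)
        with pytest.raises(ValueError):
            ct.rejection_frequency_experiment()


def test_power_increases_with_sample_size():
    """Empirical power of the constant-dependence test grows with n (Model 6)."""
    rates = []
    for n, S in ((120, 40), (350, 40)):
        res = ct.rejection_frequency_experiment(model="6", n=n, S=S, B=150, seed=8)
        rates.append(res.table.loc[res.table.alpha == 0.05, "rejection_pct"].iloc[0])
    assert rates[1] > rates[0]
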