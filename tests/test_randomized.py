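"""Randomized OAT sensitivity indices against closed-form oracles.

On the production-degradation model dx/dt = k - d*x with x(0) = 0 the
solution is linear in k, so S for an alteration alpha of k equals
alpha - 1 exactly; the Monte-Carlo machinery is checked against that and
against the closed-form lognormal moments.
"""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from aucsens import (
    AlterationDistribution,
    NumericalAnomalyError,
    SimulationConfig,
    UndefinedIndexError,
    ValidationError,
    classify_parameter,
    delta_response,
    display_value,
    make_linear_chain,
    population_ensemble,
    rank_parameters,
    sample_alpha,
    sensitivity_index,
    simulate,
)

LOGNORMAL = AlterationDistribution()  # the default reduction law


class TestSampleAlpha:
    def test_lognormal_moments_match_scipy_closed_form(self):
        draws = sample_alpha(LOGNORMAL, 10**6, seed=1)
        dist = st.lognorm(s=0.61, scale=np.exp(-2.08))
        assert draws.mean() == pytest.approx(dist.mean(), abs=1e-3)
        assert np.median(draws) == pytest.approx(dist.median(), rel=5e-3)
        assert dist.median() == pytest.approx(np.exp(-2.08))

    def test_degenerate(self):
        assert np.array_equal(
            sample_alpha(AlterationDistribution(kind="degenerate", point_value=1.0), 5, 0),
            np.ones(5),
        )

    def test_custom_sampler(self):
        dist = AlterationDistribution(
            kind="custom", sampler=lambda rng, n: rng.uniform(2.0, 5.0, n),
            mode="amplification",
        )
        draws = sample_alpha(dist, 100, seed=3)
        assert np.all((draws >= 2.0) & (draws <= 5.0))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValidationError, match="log_scale"):
            AlterationDistribution(log_scale=0.0)

    @given(seed=hst.integers(0, 2**31 - 1), n=hst.integers(1, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_strict_positivity_and_reproducibility(self, seed, n):
        a = sample_alpha(LOGNORMAL, n, seed)
        b = sample_alpha(LOGNORMAL, n, seed)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)


class TestSensitivityIndex:
    def test_identical_trajectories_give_zero(self, linear_model, linear_config):
        nom = simulate(linear_model, linear_model.nominal_params, linear_config)
        delta = delta_response(nom, nom, "x")
        assert np.all(delta == 0)
        assert sensitivity_index(delta, nom, "x", 10.0) == 0.0

    def test_zeroed_output_gives_minus_one(self, linear_model, linear_config):
        nom = simulate(linear_model, linear_model.nominal_params, linear_config)
        zeroed = simulate(linear_model, {"k": 0.0, "d": 0.5}, linear_config)
        delta = delta_response(zeroed, nom, "x")
        assert sensitivity_index(delta, nom, "x", 10.0) == pytest.approx(-1.0, abs=1e-9)

    def test_doubled_output_gives_plus_one(self, linear_model, linear_config):
        nom = simulate(linear_model, linear_model.nominal_params, linear_config)
        doubled = simulate(linear_model, {"k": 2.0, "d": 0.5}, linear_config)
        delta = delta_response(doubled, nom, "x")
        assert sensitivity_index(delta, nom, "x", 10.0) == pytest.approx(1.0, abs=1e-5)

    def test_grid_mismatch_rejected(self, linear_model, linear_config):
        nom = simulate(linear_model, linear_model.nominal_params, linear_config)
        other = simulate(
            linear_model, linear_model.nominal_params,
            SimulationConfig(horizon_T=10.0, n_points=500),
        )
        with pytest.raises(ValidationError, match="time grids"):
            delta_response(other, nom, "x")

    def test_zero_nominal_output_is_undefined(self, linear_model):
        cfg = SimulationConfig(horizon_T=1.0, n_points=50)
        nom = simulate(linear_model, {"k": 0.0, "d": 0.5}, cfg)
        with pytest.raises(UndefinedIndexError):
            sensitivity_index(np.zeros(50), nom, "x", 1.0)

    @given(
        alpha=hst.floats(0.0, 3.0),
        k=hst.floats(0.1, 5.0),
        d=hst.floats(0.05, 2.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_s_bounded_below_on_nonnegative_outputs(self, alpha, k, d):
        """S >= -1 whenever nominal and altered outputs stay non-negative."""
        model = make_linear_chain(k=k, d=d)
        cfg = SimulationConfig(horizon_T=5.0, n_points=101)
        nom = simulate(model, model.nominal_params, cfg)
        alt = simulate(model, {"k": alpha * k, "d": d}, cfg)
        s = sensitivity_index(delta_response(alt, nom, "x"), nom, "x", 5.0)
        assert s >= -1.0 - 1e-9
        # linear-in-k oracle: S = alpha - 1
        assert s == pytest.approx(alpha - 1.0, abs=1e-4)


class TestDisplayAndClassify:
    @pytest.mark.parametrize("A,expected", [(0.0, 1.0), (-1.0, 0.0), (9.0, 10.0)])
    def test_display_value(self, A, expected):
        assert display_value(A) == expected

    def test_display_value_anomaly(self):
        with pytest.raises(NumericalAnomalyError):
            display_value(-1.5)

    @pytest.mark.parametrize(
        "A,expected",
        [(0.5, "amplifying"), (-0.85, "suppressing"), (0.005, "neutral")],
    )
    def test_classification(self, A, expected):
        assert classify_parameter(A, 0.01) == expected


@pytest.fixture(scope="module")
def linear_ranking_n5000():
    """Shared large ranking on the linear oracle (used by several checks)."""
    model = make_linear_chain(k=1.0, d=0.5)
    cfg = SimulationConfig(horizon_T=10.0, n_points=201)
    return rank_parameters(model, cfg, dist=LOGNORMAL, n=5000, seed=11)


class TestRankParameters:
    def test_degenerate_identity_is_neutral(self, linear_model, linear_config):
        dist = AlterationDistribution(kind="degenerate", point_value=1.0)
        ranking, _ = rank_parameters(linear_model, linear_config, dist=dist, n=3, seed=0)
        for e in ranking.entries:
            assert abs(e.A) < 1e-5
            assert e.display_value == pytest.approx(1.0, abs=1e-5)
            assert e.classification == "neutral"

    def test_linear_oracle_mean_index(self, linear_ranking_n5000):
        """A(k) = E[alpha] - 1 within Monte-Carlo error."""
        ranking, results = linear_ranking_n5000
        expected = LOGNORMAL.mean() - 1.0
        res = results["k"]
        sem = res.s_values.std(ddof=1) / np.sqrt(res.n_effective)
        assert abs(res.A - expected) < 3 * sem
        assert ranking["k"].classification == "suppressing"

    def test_s_distribution_matches_alpha_minus_one(self, linear_ranking_n5000):
        """Kolmogorov-Smirnov: S(k) sample ~ alpha - 1 at n = 5000."""
        _, results = linear_ranking_n5000
        independent = sample_alpha(LOGNORMAL, 5000, seed=999) - 1.0
        ks = st.ks_2samp(results["k"].s_values, independent).statistic
        assert ks < 0.02

    def test_monte_carlo_consistency_across_n(self, linear_ranking_n5000, linear_model):
        """A at n=200 and n=5000 agree within 3 combined SEM."""
        _, big = linear_ranking_n5000
        cfg = SimulationConfig(horizon_T=10.0, n_points=201)
        _, small = rank_parameters(linear_model, cfg, dist=LOGNORMAL, n=200, seed=77)
        rb, rs = big["k"], small["k"]
        sem = np.hypot(
            rb.s_values.std(ddof=1) / np.sqrt(rb.n_effective),
            rs.s_values.std(ddof=1) / np.sqrt(rs.n_effective),
        )
        assert abs(rb.A - rs.A) < 3 * sem

    def test_seed_reproducibility(self, linear_model, linear_config):
        r1, s1 = rank_parameters(linear_model, linear_config, n=50, seed=42)
        r2, s2 = rank_parameters(linear_model, linear_config, n=50, seed=42)
        np.testing.assert_array_equal(s1["k"].alphas, s2["k"].alphas)
        assert [e.param_name for e in r1.entries] == [e.param_name for e in r2.entries]
        assert [e.A for e in r1.entries] == [e.A for e in r2.entries]

    def test_sorted_by_abs_A_descending(self, linear_ranking_n5000):
        ranking, _ = linear_ranking_n5000
        magnitudes = [abs(e.A) for e in ranking.entries]
        assert magnitudes == sorted(magnitudes, reverse=True)

    def test_zero_nominal_parameter_reported_unrankable(self, linear_config):
        import aucsens

        model = aucsens.OdeModel(
            name="withzero", state_names=["x"], param_names=["k", "z"],
            nominal_params={"k": 1.0, "z": 0.0},
            rhs=lambda t, y, p, u: [p["k"] - 0.5 * y[0] + p["z"]],
            initial_state=np.zeros(1), output_variable="x",
        )
        ranking, _ = rank_parameters(model, linear_config, n=5, seed=0)
        assert ranking.unrankable == ["z"]
        assert [e.param_name for e in ranking.entries] == ["k"]

    def test_excluded_parameters_not_ranked(self, linear_config):
        from dataclasses import replace

        model = make_linear_chain()

        model = replace(model, non_ranked_params=frozenset({"d"}))
        ranking, _ = rank_parameters(model, linear_config, n=5, seed=0)
        assert [e.param_name for e in ranking.entries] == ["k"]


class TestPopulationEnsemble:
    def test_degenerate_identity_equals_nominal(self, linear_model, linear_config):
        dist = AlterationDistribution(kind="degenerate", point_value=1.0)
        times, ens, mean = population_ensemble(
            linear_model, linear_config, "k", dist=dist, n=4, seed=0
        )
        nom = simulate(linear_model, linear_model.nominal_params, linear_config).variable("x")
        assert ens.shape == (4, times.size)
        np.testing.assert_allclose(ens, np.broadcast_to(nom, ens.shape), atol=1e-9)
        np.testing.assert_allclose(mean, nom, atol=1e-9)

    def test_mean_trajectory_scales_by_mean_alpha(self, linear_model):
        cfg = SimulationConfig(horizon_T=10.0, n_points=101)
        _, _, mean = population_ensemble(linear_model, cfg, "k", dist=LOGNORMAL, n=1000, seed=5)
        nom = simulate(linear_model, linear_model.nominal_params, cfg).variable("x")
        np.testing.assert_allclose(mean, LOGNORMAL.mean() * nom, rtol=0.1, atol=1e-6)

    def test_seed_determinism(self, linear_model):
        cfg = SimulationConfig(horizon_T=10.0, n_points=51)
        _, e1, _ = population_ensemble(linear_model, cfg, "k", n=20, seed=9)
        _, e2, _ = population_ensemble(linear_model, cfg, "k", n=20, seed=9)
        np.testing.assert_array_equal(e1, e2)

    def test_unrankable_parameter_rejected(self, linear_model, linear_config):
        with pytest.raises(ValidationError):
            population_ensemble(linear_model, linear_config, "nope", n=2, seed=0)
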