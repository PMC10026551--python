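import numpy as np
import pytest
from scipy import stats

from thermopid.sensitivity import (
    ParamDistribution,
    build_surrogate,
    default_distributions,
    moat_screen,
    sobol_indices,
    uncertainty_pdf,
)


@pytest.fixture(scope="module")
def surrogate():
    return build_surrogate()


@pytest.fixture(scope="module")
def table_dists():
    return default_distributions()


def _uniform(name, baseline=1.0, unc=0.5):
    return ParamDistribution(name=name, baseline=baseline, uncertainty=unc,
                             family="uniform")


class TestDistributions:
    def test_uniform_ppf_spans_range(self):
        d = _uniform("x", baseline=10.0, unc=0.1)
        assert d.ppf(np.array([0.0]))[0] == pytest.approx(9.0)
        assert d.ppf(np.array([1.0]))[0] == pytest.approx(11.0)
        assert d.ppf(np.array([0.5]))[0] == pytest.approx(10.0)

    def test_normal_ppf_median_is_baseline(self):
        d = ParamDistribution(name="x", baseline=10.0, uncertainty=0.05)
        assert d.ppf(np.array([0.5]))[0] == pytest.approx(10.0)

    def test_zero_uncertainty_degenerate(self):
        d = ParamDistribution(name="x", baseline=3.0, uncertainty=0.0)
        np.testing.assert_allclose(d.ppf(np.linspace(0, 1, 5)), 3.0)

    def test_table_defaults(self, table_dists):
        by_name = {d.name: d for d in table_dists}
        assert by_name["H_gel"].baseline == pytest.approx(9.78)
        assert by_name["H_gel"].uncertainty == 0.05
        assert by_name["k_gel"].uncertainty == 0.01
        assert by_name["dist"].baseline == pytest.approx(1.3e-3)

    def test_wide_preset(self):
        wide = {d.name: d for d in default_distributions(wide_H_dist=True)}
        assert wide["H_gel"].uncertainty == 0.10
        assert wide["dist"].uncertainty == 0.10
        assert wide["k_gel"].uncertainty == 0.01


class TestMOAT:
    def test_ignored_parameter_scores_zero(self):
        dists = [_uniform("a"), _uniform("b")]
        res = moat_screen(lambda x: 3.0 * x[0], dists, n_trajectories=10, seed=0)
        i = res.names.index("b")
        assert res.moat_mean[i] == 0.0
        assert res.moat_sd[i] == 0.0

    def test_additive_linear_model_has_no_effect_spread(self):
        """Elementary effects of a linear additive model are constant,
        so their standard deviation vanishes."""
        dists = [_uniform("a"), _uniform("b"), _uniform("c")]
        res = moat_screen(lambda x: 2 * x[0] - x[1] + 0.5 * x[2], dists,
                          n_trajectories=15, seed=1)
        np.testing.assert_allclose(res.moat_sd, 0.0, atol=1e-9)

    def test_field_amplitude_dominates_phantom(self, surrogate, table_dists):
        """Field amplitude is the top-ranked input of the phantom's
        steady probe temperature."""
        res = moat_screen(surrogate, table_dists, n_trajectories=20, seed=2)
        assert res.ranking()[0] == "H_gel"

    def test_failing_model_discards_trajectory(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] <= 3:
                raise RuntimeError("solver blew up")
            return float(x[0])

        with pytest.warns(UserWarning, match="discarded"):
            res = moat_screen(flaky, [_uniform("a")], n_trajectories=6, seed=3)
        assert res.n_discarded >= 1
        assert res.n_trajectories + res.n_discarded == 6


class TestSobol:
    def test_single_parameter_explains_everything(self):
        res = sobol_indices(lambda x: x[0] ** 2, [_uniform("a")],
                            n_base_samples=512, seed=0)
        assert res.first_order[0] == pytest.approx(1.0, abs=3 * res.mc_error)
        assert res.total[0] == pytest.approx(1.0, abs=3 * res.mc_error)

    def test_additive_model_matches_analytic_decomposition(self):
        """y = 3 x1 + x2 with equal-variance inputs splits the variance
        9:1 between the inputs."""
        dists = [_uniform("x1"), _uniform("x2")]
        res = sobol_indices(lambda x: 3.0 * x[0] + x[1], dists,
                            n_base_samples=2048, seed=1)
        assert res.first_order[0] == pytest.approx(0.9, abs=3 * res.mc_error)
        assert res.first_order[1] == pytest.approx(0.1, abs=3 * res.mc_error)

    def test_index_ordering_invariants(self, surrogate, table_dists):
        """0 <= S1 <= ST <= 1 within bootstrap error, and the
        first-order indices sum to at most 1 + error."""
        res = sobol_indices(surrogate, table_dists, n_base_samples=256, seed=2)
        e = 3 * res.mc_error
        assert np.all(res.first_order >= -e)
        assert np.all(res.first_order <= res.total + e)
        assert np.all(res.total <= 1.0 + e)
        assert res.first_order.sum() <= 1.0 + len(table_dists) * res.mc_error

    def test_phantom_interactions_negligible(self, surrogate, table_dists):
        """Interaction contributions (total - first order) of the
        phantom surrogate are negligible for every input."""
        res = sobol_indices(surrogate, table_dists, n_base_samples=512, seed=3)
        assert res.ranking()[0] == "H_gel"
        interactions = res.total - res.first_order
        assert np.all(interactions < 0.05 + 3 * res.mc_error)

    def test_degenerate_output_rejected(self):
        with pytest.raises(RuntimeError, match="variance"):
            sobol_indices(lambda x: 1.0, [_uniform("a")],
                          n_base_samples=256, seed=4)

    def test_too_few_samples_rejected(self, surrogate, table_dists):
        with pytest.raises(ValueError):
            sobol_indices(surrogate, table_dists, n_base_samples=128, seed=0)

    def test_bootstrap_error_shrinks_with_n(self):
        dists = [_uniform("x1"), _uniform("x2")]
        f = lambda x: x[0] + 0.2 * x[1] ** 2
        small = sobol_indices(f, dists, n_base_samples=256, seed=5)
        big = sobol_indices(f, dists, n_base_samples=2048, seed=5)
        assert big.mc_error < small.mc_error


class TestUncertaintyPDF:
    def test_degenerate_inputs_give_point_mass(self):
        dists = [ParamDistribution(name="a", baseline=2.0, uncertainty=0.0)]
        res = uncertainty_pdf(lambda x: 5.0 * x[0], dists,
                              n_samples=1000, seed=0)
        assert res.sd == 0.0
        assert res.mean == pytest.approx(10.0)

    def test_quadratic_field_map_delta_method(self):
        """dT = c H^2 with a +/-5% normal field uncertainty: the output
        coefficient of variation is twice the field's, per the delta
        method on the quadratic map."""
        d = ParamDistribution(name="H", baseline=9.78, uncertainty=0.05)
        res = uncertainty_pdf(lambda x: 0.24 * x[0] ** 2, [d],
                              n_samples=4000, seed=1)
        rng = np.random.default_rng(1)
        h = d.ppf(rng.random(200_000))
        cv_h = h.std() / h.mean()
        assert res.sd / res.mean == pytest.approx(2 * cv_h, rel=0.1)

    def test_kde_normalized(self, surrogate, table_dists):
        res = uncertainty_pdf(surrogate, table_dists, n_samples=1000, seed=2)
        grid, dens = res.kde_grid[:, 0], res.kde_grid[:, 1]
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_phantom_output_near_normal(self, surrogate, table_dists):
        """With normal input uncertainties the probe-temperature PDF is
        itself close to normal (normality not rejected at alpha=0.01)."""
        res = uncertainty_pdf(surrogate, table_dists, n_samples=2000, seed=3)
        rng = np.random.default_rng(3)
        Q = rng.random((2000, len(table_dists)))
        X = np.column_stack([table_dists[i].ppf(Q[:, i])
                             for i in range(len(table_dists))])
        y = np.array([surrogate(row) for row in X])
        assert stats.shapiro(y[:500]).pvalue > 0.01
        assert res.mean == pytest.approx(float(y.mean()), rel=1e-9)

    def test_reproducible_given_seed(self, surrogate, table_dists):
        a = uncertainty_pdf(surrogate, table_dists, n_samples=1000, seed=7)
        b = uncertainty_pdf(surrogate, table_dists, n_samples=1000, seed=7)
        assert a.mean == b.mean and a.sd == b.sd


class TestSurrogate:
    def test_baseline_reproduces_calibration(self, surrogate):
        x = np.array([9.78, 1.3e-3, 0.566, 2.1, 3900.0, 960.0, 21.0])
        assert surrogate(x) == pytest.approx(23.0, abs=0.3)

    def test_quadratic_field_scaling(self, surrogate):
        x = np.array([9.78, 1.3e-3, 0.566, 2.1, 3900.0, 960.0, 21.0])
        x_hi = x.copy()
        x_hi[0] *= 1.05
        assert surrogate(x_hi) / surrogate(x) == pytest.approx(1.1025, rel=1e-6)

    def test_temperature_decays_away_from_source(self, surrogate):
        x = np.array([9.78, 1.3e-3, 0.566, 2.1, 3900.0, 960.0, 21.0])
        x_out = x.copy()
        x_out[1] *= 1.05
        assert surrogate(x_out) < surrogate(x)

    def test_methods_agree_on_top_parameter_across_seeds(
            self, surrogate, table_dists):
        """MOAT screening and Sobol decomposition both rank the field
        amplitude first, for five independent seeds."""
        for seed in range(5):
            m = moat_screen(surrogate, table_dists, n_trajectories=10,
                            seed=seed)
            s = sobol_indices(surrogate, table_dists, n_base_samples=256,
                              seed=seed)
            assert m.ranking()[0] == "H_gel"
            assert s.ranking()[0] == "H_gel"
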