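import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from orientbayes import (BlsInterpolator, EncodingModel, EstimatorSpec,
                         NormalizationError, bls, draw_measurements, map_ep,
                         map_vp, posterior_density, theoretical_moments,
                         vp_shrinkage)
from orientbayes.estimators import _simpson_weights


def simpson_integral(grid):
    w = _simpson_weights(len(grid.nodes), grid.nodes[0], grid.nodes[-1])
    return float(w @ grid.densities)


class TestPosterior:
    def test_ep_posterior_symmetric_at_zero(self, specs):
        g = posterior_density(0.0, specs["bls_ep"])
        assert simpson_integral(g) == pytest.approx(1.0, abs=1e-6)
        assert g.mean() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(g.densities, g.densities[::-1], rtol=1e-9)

    def test_ep_posterior_monotone_tail_at_edge(self, specs):
        g = posterior_density(23.0, specs["bls_ep"])
        assert g.densities[0] < 1e-6
        assert g.argmax() == pytest.approx(23.0)

    @pytest.mark.parametrize("model,am", [("bls_vp", 10.0), ("bls_vp", -4.0),
                                          ("bls_ep", 7.5)])
    def test_posterior_matches_adaptive_quadrature(self, specs, model, am):
        spec = specs[model]
        enc = spec.enc
        g = posterior_density(am, spec)
        assert simpson_integral(g) == pytest.approx(1.0, abs=1e-6)

        def lik(a):
            sd = enc.lam if enc.pattern == "EP" else enc.lam * abs(a)
            if sd == 0:
                return 0.0
            return stats.norm.pdf(am, loc=a, scale=sd)

        mass, _ = integrate.quad(lik, -23, 23, points=[0], limit=200)
        for node in (-20.0, -5.0, 1.0, 10.0, 22.0):
            i = int(np.argmin(np.abs(g.nodes - node)))
            assert g.densities[i] == pytest.approx(lik(g.nodes[i]) / mass,
                                                   rel=1e-6, abs=1e-10)

    def test_normalization_failure_far_outside_support(self, design):
        spec = EstimatorSpec.from_model("bls_ep", 0.5, design)
        with pytest.raises(NormalizationError):
            posterior_density(500.0, spec)


class TestMapEp:
    @pytest.mark.parametrize("am,theta_e", [(10.0, 55.0), (30.0, 68.0),
                                            (-50.0, 22.0), (0.0, 45.0)])
    def test_clip_rule(self, specs, am, theta_e):
        assert map_ep(am, specs["map_ep"]) == pytest.approx(theta_e)

    def test_matches_posterior_argmax_on_interior(self, specs):
        spec = specs["map_ep"]
        step = 46.0 / (spec.bls_grid_points - 1)
        for am in (-20.0, -3.5, 0.0, 12.2, 22.9):
            grid_mode = 45.0 + posterior_density(am, spec).argmax()
            assert abs(map_ep(am, spec) - grid_mode) <= step + 1e-12


class TestMapVp:
    def test_closed_form_against_brute_force(self, design):
        spec = EstimatorSpec.from_model("map_vp", 0.27, design)
        for am in (-15.0, -2.0, 1.0, 10.0, 20.0):
            a = np.linspace(-23, 23, 2_000_001)
            sd = 0.27 * np.abs(a)
            with np.errstate(divide="ignore", invalid="ignore"):
                loglik = -0.5 * ((am - a) / sd) ** 2 - np.log(sd)
            loglik[sd == 0] = -np.inf
            brute = 45.0 + a[np.argmax(loglik)]
            assert map_vp(am, spec) == pytest.approx(brute, abs=1e-3)

    def test_example_value(self, specs):
        assert map_vp(10.0, specs["map_vp"]) == pytest.approx(45 + 9.3612, abs=1e-3)

    def test_shrinkage_limits(self):
        assert vp_shrinkage(1e-6) == pytest.approx(1.0, abs=1e-9)
        for lam in (0.1, 0.23, 0.4, 2.0):
            assert 0.0 < vp_shrinkage(lam) < 1.0

    def test_clips_to_support_edge(self, specs):
        assert map_vp(30.0, specs["map_vp"]) == pytest.approx(68.0)


class TestBls:
    def test_ep_symmetric_measurement_gives_reference(self, specs):
        assert bls(0.0, specs["bls_ep"]) == pytest.approx(45.0, abs=1e-9)

    def test_vp_zero_measurement_gives_reference(self, specs):
        assert bls(0.0, specs["bls_vp"]) == pytest.approx(45.0, abs=1e-9)

    def test_ep_matches_truncated_normal_mean_closed_form(self, design):
        spec = EstimatorSpec.from_model("bls_ep", 3.6, design)
        for am in np.arange(-40.0, 40.5, 2.5):
            tn = stats.truncnorm((-23 - am) / 3.6, (23 - am) / 3.6,
                                 loc=am, scale=3.6)
            assert bls(am, spec) == pytest.approx(45.0 + tn.mean(), abs=1e-3)

    @pytest.mark.parametrize("model", ["bls_ep", "bls_vp"])
    def test_monotone_in_measurement(self, specs, model):
        am = np.linspace(-30, 30, 121)
        out = bls(am, specs[model])
        assert np.all(np.diff(out) >= -1e-10)

    @pytest.mark.parametrize("model", ["bls_ep", "bls_vp"])
    def test_interpolator_matches_exact_quadrature(self, specs, model):
        dec = BlsInterpolator(specs[model])
        am = np.concatenate([np.linspace(-28, 28, 113), [-0.7, 0.3, 0.0]])
        exact = np.asarray(bls(am, specs[model]))
        assert np.max(np.abs(dec(am) - exact)) < 2e-3


@settings(deadline=None, max_examples=60)
@given(st.sampled_from(["map_ep", "map_vp", "bls_ep", "bls_vp"]),
       st.floats(-60, 60, allow_nan=False))
def test_estimates_stay_inside_stimulus_range(specs_cache, model, am):
    spec = specs_cache[model]
    fn = {"map_ep": map_ep, "map_vp": map_vp}.get(model, bls)
    assert 22.0 <= fn(am, spec) <= 68.0


@pytest.fixture(scope="module")
def specs_cache(design):
    lam = {"map_ep": 3.6, "map_vp": 0.27, "bls_ep": 3.75, "bls_vp": 0.23}
    return {m: EstimatorSpec.from_model(m, v, design) for m, v in lam.items()}


class TestTheoreticalMoments:
    def test_map_ep_interior(self, design):
        enc = EncodingModel("EP", 3.6)
        mean, var = theoretical_moments("map_ep", enc, design, 0.0)
        assert (mean, var) == (45.0, pytest.approx(12.96))

    def test_map_vp_mean_is_shrunk_angle(self, design):
        enc = EncodingModel("VP", 0.27)
        mean, _ = theoretical_moments("map_vp", enc, design, 10.0)
        assert mean == pytest.approx(45 + 9.3612, abs=1e-3)

    def test_map_vp_noiseless_limit(self, design):
        enc = EncodingModel("VP", 1e-9)
        mean, var = theoretical_moments("map_vp", enc, design, 10.0)
        assert mean == pytest.approx(55.0, abs=1e-6)
        assert var == pytest.approx(0.0, abs=1e-6)

    def test_outside_support_rejected(self, design):
        with pytest.raises(ValueError):
            theoretical_moments("map_ep", EncodingModel("EP", 3.6), design, 30.0)

    @pytest.mark.parametrize("model,lam,alpha", [("map_ep", 3.6, 5.0),
                                                 ("map_vp", 0.27, 10.0)])
    def test_monte_carlo_agrees_with_closed_form(self, design, model, lam, alpha):
        """Simulated moments of the interior branch match the formulas."""
        spec = EstimatorSpec.from_model(model, lam, design)
        enc = spec.enc
        n = 1_000_000
        am = draw_measurements(alpha, enc, n, seed=17)
        est = (map_ep if model == "map_ep" else map_vp)(am, spec)
        mean, var = theoretical_moments(model, enc, design, alpha)
        # interior stimulus: clipping mass is negligible at these settings
        se_mean = np.sqrt(var / n)
        assert est.mean() == pytest.approx(mean, abs=max(3 * se_mean, 0.01))
        se_var = var * np.sqrt(2.0 / n)
        assert est.var() == pytest.approx(var, abs=3 * se_var + 1e-3)
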