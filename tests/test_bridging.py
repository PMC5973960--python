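"""Fixture generation, analytical fitting and the temperature bridge."""

import numpy as np
import pytest

from ampatemp import (
    ModelConfig,
    bridge,
    curve_metrics,
    fit_analytical,
    fit_phenomenological,
    generate_fixture,
    temperature_conductance,
)


@pytest.fixture(scope="module")
def clean_fixture():
    cfg = ModelConfig()
    return generate_fixture(cfg, noise_sd=0.0, seed=0, dt=5e-6)


class TestFixture:
    def test_zero_noise_equals_closed_form(self, config):
        t, g = generate_fixture(config, noise_sd=0.0, seed=0, dt=1e-5)
        direct = temperature_conductance(config, 25.0)(t)
        np.testing.assert_array_equal(g, direct)

    def test_seed_determinism(self, config):
        t1, g1 = generate_fixture(config, noise_sd=0.02, seed=7, dt=1e-5)
        t2, g2 = generate_fixture(config, noise_sd=0.02, seed=7, dt=1e-5)
        np.testing.assert_array_equal(g1, g2)
        _, g3 = generate_fixture(config, noise_sd=0.02, seed=8, dt=1e-5)
        assert np.any(g1 != g3)

    def test_noise_level_calibrated(self, config):
        """Empirical relative SD at the peak over many draws matches noise_sd."""
        t, clean = generate_fixture(config, noise_sd=0.0, dt=5e-5)
        k = int(np.argmax(clean))
        peaks = np.array([
            generate_fixture(config, noise_sd=0.02, seed=s, dt=5e-5)[1][k]
            for s in range(1000)
        ])
        rel_sd = peaks.std() / clean[k]
        assert rel_sd == pytest.approx(0.02, abs=0.002)

    def test_negative_noise_rejected(self, config):
        with pytest.raises(ValueError):
            generate_fixture(config, noise_sd=-0.1)


class TestFitAnalytical:
    def test_round_trip_on_clean_fixture(self, clean_fixture):
        t, g = clean_fixture
        fit = fit_analytical(t, g, n_starts=2, seed=1)
        assert fit.rel_rms < 1e-3  # curve-space recovery; parameters may be degenerate

    def test_recovery_under_measurement_noise(self, config):
        t, g = generate_fixture(config, noise_sd=0.02, seed=42, dt=5e-6)
        fit = fit_analytical(t, g, n_starts=2, seed=1)
        from ampatemp import conductance, solve_scheme2
        refit = conductance(solve_scheme2(fit.config), fit.config)
        truth = curve_metrics(temperature_conductance(config, 25.0))
        got = curve_metrics(refit)
        assert got.peak_amplitude == pytest.approx(truth.peak_amplitude, rel=0.03)
        assert got.time_to_peak_ms == pytest.approx(truth.time_to_peak_ms, rel=0.03)

    def test_degenerate_inputs_rejected(self):
        t = np.linspace(0, 1e-3, 200)
        with pytest.raises(ValueError):
            fit_analytical(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            fit_analytical(t[:10], np.ones(10))


class TestPhenomenological:
    def test_dual_exponential_self_fit_recovers_parameters(self):
        t = np.linspace(0, 5e-3, 500)
        y = 3.0 * np.exp(-800.0 * t) - 3.0 * np.exp(-6000.0 * t)
        fit = fit_phenomenological(t, y, family="dual_exp")
        assert fit.params["A"] == pytest.approx(3.0, rel=1e-6)
        assert fit.params["B"] == pytest.approx(3.0, rel=1e-6)
        assert fit.params["alpha"] == pytest.approx(-800.0, rel=1e-6)
        assert fit.params["beta"] == pytest.approx(-6000.0, rel=1e-6)
        assert fit.params["alpha"] < 0 and fit.params["beta"] < 0

    def test_alpha_fit_preserves_peak_position(self, clean_fixture):
        t, g = clean_fixture
        fit = fit_phenomenological(t, g, family="alpha")
        t_peak_model = fit.params["tau"]  # alpha function peaks at t = tau
        t_peak_data = t[np.argmax(g)]
        assert t_peak_model == pytest.approx(t_peak_data, rel=0.10)

    def test_rising_curve_needs_two_exponentials(self, clean_fixture):
        t, g = clean_fixture
        single = fit_phenomenological(t, g, family="single_exp")
        dual = fit_phenomenological(t, g, family="dual_exp")
        assert dual.rel_rms < single.rel_rms

    def test_unknown_family_rejected(self, clean_fixture):
        t, g = clean_fixture
        with pytest.raises(ValueError):
            fit_phenomenological(t, g, family="triple_exp")


class TestBridge:
    def test_identity_bridge_returns_fitted_curve(self, clean_fixture):
        t, g = clean_fixture
        res = bridge(t, g, 25.0, 25.0, q10=2.4, n_starts=2, seed=1)
        np.testing.assert_allclose(res.bridged_curve, res.source_curve, rtol=1e-12)
        for name in ("k_b", "k_u", "k_o", "k_c", "k_d", "k_r"):
            assert getattr(res.rescaled_config.rates, name) == pytest.approx(
                getattr(res.fit.config.rates, name), rel=1e-12
            )

    def test_bridged_peak_ratio_matches_direct_model(self, clean_fixture):
        t, g = clean_fixture
        res = bridge(t, g, 25.0, 35.0, q10=2.4, n_starts=2, seed=1)
        ratio = res.bridged_curve.max() / res.source_curve.max()
        direct = temperature_conductance(ModelConfig(), 35.0)(t).max() / g.max()
        assert ratio == pytest.approx(direct, rel=0.03)

    def test_round_trip_against_direct_hot_curve(self, clean_fixture):
        """Bridging a cold fixture to 35 C reproduces the directly generated
        hot closed-form curve within 3% relative RMS."""
        t, g = clean_fixture
        res = bridge(t, g, 25.0, 35.0, q10=2.4, n_starts=2, seed=1)
        direct = temperature_conductance(ModelConfig(), 35.0)(t)
        rel_rms = np.linalg.norm(res.bridged_curve - direct) / np.linalg.norm(direct)
        assert rel_rms < 0.03

    def test_degenerate_source_fits_bridge_consistently(self, clean_fixture):
        """Different multi-start solutions that fit the source equally well
        must map to (nearly) the same hot curve: the common Q10 multiplication
        is insensitive to parameter degeneracy."""
        t, g = clean_fixture
        a = bridge(t, g, 25.0, 35.0, q10=2.4, n_starts=1, seed=3)
        b = bridge(t, g, 25.0, 35.0, q10=2.4, n_starts=2, seed=11)
        assert a.fit.rel_rms < 1e-3 and b.fit.rel_rms < 1e-3
        rel_rms = np.linalg.norm(a.bridged_curve - b.bridged_curve) / np.linalg.norm(
            a.bridged_curve
        )
        assert rel_rms < 0.02

    def test_unit_q10_preserves_the_curve(self, clean_fixture):
        t, g = clean_fixture
        res = bridge(t, g, 25.0, 35.0, q10=1.0, n_starts=2, seed=1)
        np.testing.assert_allclose(res.bridged_curve, res.source_curve, rtol=1e-12)
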