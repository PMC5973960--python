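"""Closed-form cascade vs direct numerical integration of the uncoupled pairs."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ampatemp import (
    ConductanceWeights,
    FirstOrderConstants,
    ModelConfig,
    RateConstants,
    conductance,
    first_order_open,
    solve_scheme2,
    temperature_conductance,
)


def integrate_uncoupled(config, t_eval):
    """Independent numerical oracle: integrate the uncoupled pair cascade."""
    r, pulse = config.rates, config.pulse
    K = r.k_o + r.k_u + r.k_d
    n = config.n_orders

    def rhs(t, s):
        ds = np.empty(3 * n)
        lam = 1.0
        drive = r.k_b * pulse.A * np.exp(-pulse.omega * t)
        for i in range(n):
            x, y, z = s[3 * i], s[3 * i + 1], s[3 * i + 2]
            ds[3 * i] = drive * lam - K * x
            ds[3 * i + 1] = r.k_o * x - r.k_c * y
            ds[3 * i + 2] = r.k_d * x - r.k_r * z
            lam = x
        return ds

    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), np.zeros(3 * n), t_eval=t_eval,
        rtol=1e-11, atol=1e-15, method="LSODA",
    )
    assert sol.success
    return sol.y


class TestFirstOrder:
    def test_explicit_solution_has_three_exponentials(self, config):
        y1 = first_order_open(config)
        assert len(y1.terms) == 3
        assert all(n == 0 for _, _, n in y1.terms)

    def test_vanishes_at_time_zero(self, config):
        y1 = first_order_open(config)
        peak = max(abs(c) for c, _, _ in y1.terms)
        assert abs(y1(0.0)) < 1e-12 * peak

    def test_constants_identity_r_plus_s_equals_p(self, rng):
        for _ in range(200):
            rates = RateConstants(
                k_b=1e7,
                k_u=rng.uniform(1e3, 5e4),
                k_o=rng.uniform(1e3, 5e4),
                k_c=rng.uniform(1e3, 5e4),
                k_d=rng.uniform(1e2, 2e4),
                k_r=rng.uniform(1.0, 100.0),
            )
            cfg = ModelConfig(rates=rates)
            c = FirstOrderConstants.from_config(cfg)
            scale = abs(c.S) + abs(c.P) + abs(c.R)
            assert abs(c.R + c.S - c.P) <= 1e-12 * scale
            # the three Eq-coefficient reciprocals cancel exactly at t = 0
            assert abs(1 / (c.S * c.P) + 1 / (c.R * c.P) - 1 / (c.R * c.S)) <= (
                1e-10 * max(abs(1 / (c.S * c.P)), abs(1 / (c.R * c.P)), abs(1 / (c.R * c.S)))
            )

    def test_matches_numerical_integration(self, config):
        t = np.linspace(0, 3e-3, 300)
        y_num = integrate_uncoupled(replace(config, n_orders=1), t)[1]
        y1 = first_order_open(config)(t)
        np.testing.assert_allclose(y1, y_num, rtol=1e-6, atol=1e-6 * y_num.max())

    def test_rate_coincidence_falls_back_to_cascade(self):
        # k_c == omega makes S vanish; the explicit form is singular
        cfg = ModelConfig(
            rates=RateConstants(k_c=2471.0),
        )
        y1 = first_order_open(cfg)
        t = np.linspace(0, 3e-3, 200)
        y_num = integrate_uncoupled(replace(cfg, n_orders=1), t)[1]
        np.testing.assert_allclose(y1(t), y_num, rtol=1e-6, atol=1e-8 * y_num.max())


class TestCascade:
    def test_single_order_reduces_to_first_order_solution(self, config):
        cfg = replace(config, n_orders=1)
        sols = solve_scheme2(cfg)
        assert len(sols) == 1
        t = np.linspace(0, 3e-3, 100)
        np.testing.assert_allclose(sols[0].y(t), first_order_open(config)(t), rtol=1e-9,
                                   atol=1e-15)

    def test_all_orders_match_numerical_cascade(self, config):
        t = np.linspace(0, 5e-3, 500)
        num = integrate_uncoupled(config, t)
        sols = solve_scheme2(config)
        for i, sol in enumerate(sols):
            for j, traj in enumerate((sol.x, sol.y, sol.z)):
                ref = num[3 * i + j]
                np.testing.assert_allclose(
                    traj(t), ref, rtol=1e-6, atol=1e-6 * np.max(np.abs(ref)),
                    err_msg=f"order {i+1}, component {'xyz'[j]}",
                )

    def test_random_parameter_sets_match_numerical_cascade(self, rng):
        t = np.linspace(0, 5e-3, 200)
        base = RateConstants()
        for _ in range(20):
            factors = rng.uniform(0.5, 1.5, size=7)
            rates = RateConstants(
                k_b=base.k_b * factors[0], k_u=base.k_u * factors[1],
                k_o=base.k_o * factors[2], k_c=base.k_c * factors[3],
                k_d=base.k_d * factors[4], k_r=base.k_r * factors[5],
            )
            cfg = ModelConfig(rates=rates)
            cfg = replace(cfg, pulse=replace(cfg.pulse, omega=cfg.pulse.omega * factors[6]))
            num = integrate_uncoupled(cfg, t)
            for i, sol in enumerate(solve_scheme2(cfg)):
                for j, traj in enumerate((sol.x, sol.y, sol.z)):
                    ref = num[3 * i + j]
                    dev = np.max(np.abs(traj(t) - ref)) / np.max(np.abs(ref))
                    assert dev <= 1e-5, f"order {i+1} {'xyz'[j]}: rel dev {dev}"

    def test_boundary_conditions_and_nonnegativity(self, config):
        t = np.linspace(0, 10e-3, 2000)
        for sol in solve_scheme2(config):
            for traj in (sol.x, sol.y, sol.z):
                assert abs(traj(0.0)) < 1e-14
                assert np.min(traj(t)) >= -1e-14

    def test_open_peaks_decrease_with_order(self, config):
        t = np.linspace(0, 5e-3, 5000)
        peaks = [sol.y(t).max() for sol in solve_scheme2(config)]
        assert peaks == sorted(peaks, reverse=True)


class TestConductance:
    def test_null_weights_give_zero(self, config):
        cfg = replace(config, weights=ConductanceWeights(a=(0, 0, 0, 0)))
        g = conductance(solve_scheme2(cfg), cfg)
        t = np.linspace(0, 5e-3, 100)
        np.testing.assert_array_equal(g(t), np.zeros_like(t))

    def test_zero_at_stimulus_onset(self, config):
        g = conductance(solve_scheme2(config), config)
        assert abs(g(0.0)) < 1e-14

    @pytest.mark.parametrize("T", [25.0, 35.0])
    def test_nonnegative_and_unimodal(self, config, T):
        g = temperature_conductance(config, T)
        t = np.linspace(0, 10e-3, 10000)
        y = g(t)
        assert np.min(y) >= -1e-14
        rising = np.diff(y) > 0
        # a single switch from rising to falling
        assert np.sum(np.diff(rising.astype(int)) != 0) == 1

    @pytest.mark.parametrize("T", [25.0, 35.0])
    def test_third_order_with_boosted_weight_matches_fourth(self, config, T):
        """Truncating at order 3 with a_3 raised 0.7 -> 0.9 reproduces the 4-order peak."""
        t = np.linspace(0, 5e-3, 5001)
        full = temperature_conductance(config, T)(t).max()
        cfg3 = replace(
            config, n_orders=3,
            weights=ConductanceWeights(a=(0.1, 0.4, 0.9, 1.0)),
        )
        boosted = temperature_conductance(cfg3, T)(t).max()
        assert boosted == pytest.approx(full, rel=0.05)

    def test_empty_solution_list_rejected(self, config):
        with pytest.raises(ValueError):
            conductance([], config)
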