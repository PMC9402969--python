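"""Light field, Haldane kinetics, depth averaging and steady-state solving."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from thinpbr import (
    KineticParams,
    OperatingPoint,
    depth_averaged_rate,
    local_irradiance,
    mean_specific_gross_rate,
    simulate_transient,
    specific_growth_rate,
    steady_state_batch,
    steady_state_biomass,
)

from conftest import simpson_mean_rate


class TestLocalIrradiance:
    def test_surface_returns_incident(self):
        assert local_irradiance(0.0, 737.0, 0.3, 1234.0) == 737.0

    def test_half_depth(self):
        # k_a * X * z = ln 2 forces I0/2
        z = math.log(2) / (0.5 * 800.0)
        assert local_irradiance(z, 1000.0, 0.5, 800.0) == pytest.approx(500.0, rel=1e-12)

    def test_pinned_value(self):
        # 1000 * exp(-0.098 * 500 * 0.01), checked against scalar exponentiation
        assert local_irradiance(0.01, 1000.0, 0.098, 500.0) == pytest.approx(
            612.6263941844161, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            local_irradiance(-0.01, 1000.0, 0.1, 500.0)
        with pytest.raises(ValueError):
            local_irradiance(0.01, 1000.0, 0.1, -5.0)

    @given(z=st.floats(0, 0.05), ka=st.floats(0.01, 2), X=st.floats(0, 3000),
           I0=st.floats(0.1, 2000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, z, ka, X, I0):
        I = local_irradiance(z, I0, ka, X)
        assert 0.0 < I <= I0
        assert local_irradiance(z * 1.5, I0, ka, X) <= I
        assert local_irradiance(z, I0, ka * 1.5, X) <= I
        assert local_irradiance(z, I0, ka, X * 1.5) <= I


class TestSpecificGrowthRate:
    def test_maximum_at_I_opt_for_every_set(self, ref_params):
        # unimodal with maximum exactly mu_max at exactly I = I_opt
        for p in ref_params.values():
            assert specific_growth_rate(p.I_opt, p) == pytest.approx(p.mu_max, rel=1e-14)
            I = np.linspace(0.0, 4.0 * p.I_opt, 40001)
            mu = specific_growth_rate(I, p)
            assert mu.max() <= p.mu_max + 1e-12
            assert abs(I[mu.argmax()] - p.I_opt) <= I[1] - I[0]

    def test_dark_rate_zero(self, p35):
        assert specific_growth_rate(0.0, p35) == 0.0

    def test_pinned_hand_evaluation(self, p35):
        # 2.0*110/(110 + 110*(110/405 - 1)^2), independent arithmetic
        assert specific_growth_rate(110.0, p35) == pytest.approx(
            1.3067118103963353, rel=1e-12)

    def test_net_subtracts_decay(self, p35):
        gross = specific_growth_rate(200.0, p35)
        assert specific_growth_rate(200.0, p35, net=True) == pytest.approx(
            gross - p35.k_d, rel=1e-14)

    def test_negative_irradiance_rejected(self, p35):
        with pytest.raises(ValueError):
            specific_growth_rate(-1.0, p35)


class TestDepthAveragedRate:
    def test_dilute_limit_is_surface_rate(self, p35):
        op = OperatingPoint(W=0.035, I0=600.0, tau=1.0)
        X = 1e-9
        rate = depth_averaged_rate(X, op, p35)
        expected = (specific_growth_rate(600.0, p35) - p35.k_d) * X
        assert rate == pytest.approx(expected, rel=1e-6)

    def test_dark_reactor_decays(self, p35):
        op = OperatingPoint(W=0.035, I0=0.0, tau=1.0)
        assert depth_averaged_rate(400.0, op, p35) == pytest.approx(
            -p35.k_d * 400.0, rel=1e-12)

    def test_pinned_simpson_value(self, p35):
        op = OperatingPoint(W=0.035, I0=1000.0, tau=1.05)
        # frozen from a 2e5-interval Simpson oracle
        assert depth_averaged_rate(500.0, op, p35) == pytest.approx(
            713.0682163149638, rel=1e-8)

    @given(X=st.floats(1.0, 5000.0), W=st.floats(0.001, 0.05),
           I0=st.floats(1.0, 1500.0), ika=st.integers(0, 4))
    @settings(max_examples=40, deadline=None)
    def test_quadrature_matches_simpson_oracle(self, X, W, I0, ika, ref_params):
        p = list(ref_params.values())[ika]
        op = OperatingPoint(W=W, I0=I0, tau=1.0)
        oracle = (simpson_mean_rate(X, W, I0, p) - p.k_d) * X
        assert depth_averaged_rate(X, op, p) == pytest.approx(oracle, rel=1e-8, abs=1e-10)
        assert depth_averaged_rate(X, op, p, method="analytic") == pytest.approx(
            oracle, rel=1e-8, abs=1e-10)


class TestSteadyState:
    def test_washout_when_dilution_exceeds_mu_max(self, p35):
        op = OperatingPoint(W=0.035, I0=800.0, tau=1.0 / (p35.mu_max - p35.k_d + 0.5))
        sol = steady_state_biomass(op, p35)
        assert sol.washout and sol.stable_root == 0.0 and sol.roots == ()

    def test_dark_washout(self, p35):
        sol = steady_state_biomass(OperatingPoint(W=0.035, I0=0.0, tau=2.0), p35)
        assert sol.washout

    def test_thin_reactor_at_strong_light_washes_out(self, p2):
        # at I0=300 and tau=1.5 d the 2 mm parameter set cannot sustain the
        # dilution rate: max_X mu_bar ~ 0.96 d^-1 < 1/tau + k_d ~ 1.12 d^-1
        sol = steady_state_biomass(OperatingPoint(W=0.002, I0=300.0, tau=1.5), p2)
        assert sol.washout

    def test_two_roots_against_dense_oracle(self, p2):
        # independent oracle: dense scan of the Simpson-based mu_bar + brentq
        op = OperatingPoint(W=0.002, I0=100.0, tau=1.5)
        rhs = 1.0 / op.tau + p2.k_d
        grid = np.geomspace(1e-2, 1e4, 2000)
        f = np.array([simpson_mean_rate(x, op.W, op.I0, p2, n=2001) for x in grid]) - rhs
        idx = np.nonzero(np.sign(f[:-1]) != np.sign(f[1:]))[0]
        oracle_roots = [
            brentq(lambda x: simpson_mean_rate(x, op.W, op.I0, p2, n=20001) - rhs,
                   grid[i], grid[i + 1], rtol=1e-12) for i in idx
        ]
        sol = steady_state_biomass(op, p2)
        assert len(sol.roots) == len(oracle_roots) == 2
        for got, want in zip(sol.roots, oracle_roots):
            assert got == pytest.approx(want, rel=1e-6)
        assert sol.stable_root == max(sol.roots)

    def test_roots_satisfy_balance(self, ref_params):
        for w, p in ref_params.items():
            op = OperatingPoint(W=w / 1000.0, I0=150.0, tau=2.0)
            sol = steady_state_biomass(op, p)
            for r, resid in zip(sol.roots, sol.residuals):
                assert abs(resid) < 1e-6 * max(r / op.tau, 1.0)

    def test_shrinking_tau_removes_roots(self, p2):
        # washout threshold: the critical tau satisfies
        # 1/tau* + k_d = max_X mu_bar(X)
        op = lambda tau: OperatingPoint(W=0.002, I0=100.0, tau=tau)
        grid = np.geomspace(1e-3, 1e5, 4000)
        mu_bar_max = mean_specific_gross_rate(grid, 0.002, 100.0, p2).max()
        tau_crit = 1.0 / (mu_bar_max - p2.k_d)
        assert not steady_state_biomass(op(tau_crit * 1.1), p2).washout
        assert steady_state_biomass(op(tau_crit * 0.9), p2).washout

    def test_batch_matches_scalar(self, p35):
        I0 = np.array([0.0, 50.0, 200.0, 400.0, 900.0, 1200.0])
        batch = steady_state_batch(0.035, I0, np.full(6, 1.05), p35)
        for i0, b in zip(I0, batch):
            if i0 == 0:
                assert b == 0.0
                continue
            sol = steady_state_biomass(OperatingPoint(0.035, i0, 1.05), p35)
            assert b == pytest.approx(sol.stable_root, rel=1e-8, abs=1e-6)

    def test_optimal_irradiance_shifts_with_thickness(self, ref_params):
        # thin reactors peak at much lower incident light than thick ones
        I0 = np.linspace(1.0, 500.0, 200)
        x2 = steady_state_batch(0.002, I0, np.full_like(I0, 1.5), ref_params[2.0])
        I0b = np.linspace(1.0, 1200.0, 200)
        x35 = steady_state_batch(0.035, I0b, np.full_like(I0b, 1.05), ref_params[35.0])
        assert I0[np.argmax(x2)] < I0b[np.argmax(x35)]


class TestTransient:
    def test_zero_inoculum_stays_zero(self, p35):
        op = OperatingPoint(W=0.035, I0=400.0, tau=1.05)
        traj = simulate_transient(0.0, 10.0, op, p35)
        assert np.all(traj.concentrations == 0.0)

    def test_equilibrium_is_stationary(self, p35):
        op = OperatingPoint(W=0.035, I0=400.0, tau=1.05)
        xs = steady_state_biomass(op, p35).stable_root
        traj = simulate_transient(xs, 20.0, op, p35)
        assert np.all(np.abs(traj.concentrations / xs - 1.0) < 1e-4)

    def test_decay_to_stable_root(self, p35):
        op = OperatingPoint(W=0.035, I0=400.0, tau=1.05)
        xs = steady_state_biomass(op, p35).stable_root
        traj = simulate_transient(1.05 * xs, 40.0, op, p35)
        assert traj.concentrations[-1] == pytest.approx(xs, rel=1e-3)
        # monotone decay onto the attractor (tolerance for integrator wiggle)
        diffs = np.diff(traj.concentrations)
        assert np.all(diffs < 1e-6 * xs)

    def test_below_unstable_root_washes_out(self, p2):
        op = OperatingPoint(W=0.002, I0=100.0, tau=1.5)
        sol = steady_state_biomass(op, p2)
        unstable = sol.roots[0]
        traj = simulate_transient(0.5 * unstable, 60.0, op, p2)
        assert traj.concentrations[-1] < 0.05 * sol.stable_root


class TestValidation:
    def test_kinetic_params_must_be_positive(self):
        with pytest.raises(ValueError):
            KineticParams(mu_max=-1.0, K_I=110, I_opt=405, k_d=0.45, k_a=0.1)

    def test_operating_point_invariants(self):
        with pytest.raises(ValueError):
            OperatingPoint(W=0.0, I0=100, tau=1.0)
        with pytest.raises(ValueError):
            OperatingPoint(W=0.01, I0=-1, tau=1.0)
        with pytest.raises(ValueError):
            OperatingPoint(W=0.01, I0=100, tau=0.0)

    def test_operating_point_from_volumes(self):
        op = OperatingPoint.from_volumes(W=0.01, I0=100.0, V_R=2e-4, flow=1e-4)
        assert op.tau == pytest.approx(2.0)
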