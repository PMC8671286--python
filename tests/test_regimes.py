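"""Steady states, regime classification, and growth asymptotics."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from p62agg import (
    ContinuumState,
    DomainError,
    Regime,
    Trajectory,
    alpha_bar,
    asymptotic_coefficients,
    classify_regime,
    critical_kappa_minus,
    exponent_estimate,
    integrate,
    kappa_zero_limits,
    lyapunov_value,
    q_hat,
    rhs,
    steady_state,
)

from conftest import random_rates, unit_params


class TestAlphaBar:
    @pytest.mark.parametrize(
        "kappa_m, expected, tol",
        [(0.6, 0.6366, 1e-4), (0.93, 1.00211, 1e-4), (0.2, -1.42350, 1e-4)],
    )
    def test_reference_values(self, kappa_m, expected, tol):
        assert alpha_bar(unit_params(kappa_m)) == pytest.approx(expected, abs=tol)

    def test_kappa_m_zero_is_domain_error(self):
        with pytest.raises(DomainError, match="kappa_zero_limits"):
            alpha_bar(unit_params(0.0))

    def test_strictly_decreasing_in_oligomer_supply(self):
        # more free oligomers never destabilize the aggregate
        values = [
            alpha_bar(unit_params(0.6).replace(kappa2=float(k2)))
            for k2 in np.linspace(0.1, 5.0, 40)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_q_hat_relation(self):
        params = unit_params(0.6)
        ab, qh = alpha_bar(params), q_hat(params)
        assert ab == pytest.approx(
            params.n / (params.n - 2) - 2 * qh / (params.n - 2), rel=1e-14)


class TestSteadyState:
    def test_closed_form_reference(self, params_finite):
        ss = steady_state(params_finite)
        assert ss.p == pytest.approx(0.2553, abs=1e-3)
        assert ss.q == pytest.approx(0.6684, abs=1e-3)
        assert ss.r == pytest.approx(0.4326, abs=1e-3)

    def test_agrees_with_independent_root_find(self, params_finite):
        from p62agg.model_core import _rhs_raw

        ss = steady_state(params_finite)
        start = np.array([ss.p, ss.q, ss.r]) * 1.1

        def residual(y):
            return _rhs_raw(y[0], y[1], y[2], params_finite)

        root = fsolve(residual, start, full_output=False, xtol=1e-12)
        assert np.allclose(root, [ss.p, ss.q, ss.r], atol=1e-8)

    def test_none_outside_finite_size(self, params_extinction, params_growth):
        assert steady_state(params_extinction) is None
        assert steady_state(params_growth) is None

    def test_random_sets_residual_and_structure(self):
        rng = np.random.default_rng(2024)
        found = 0
        while found < 25:
            params = random_rates(rng)
            ss = steady_state(params)
            if ss is None:
                continue
            found += 1
            assert max(abs(x) for x in rhs(ss, params)) < 1e-8
            qh = q_hat(params)
            assert 1.0 < qh < params.n / 2
            assert ss.s(params.n) > 0 and ss.gap > 0
            # geometric detachment probability reproduces the closed form
            assert (params.n * ss.r - 2 * ss.q) / ((params.n - 2) * ss.r) == (
                pytest.approx(alpha_bar(params), abs=1e-10))


class TestClassification:
    @pytest.mark.parametrize(
        "kappa_m, regime",
        [(0.6, Regime.FINITE_SIZE), (0.93, Regime.EXTINCTION),
         (0.2, Regime.UNBOUNDED_GROWTH)],
    )
    def test_reference_sets(self, kappa_m, regime):
        report = classify_regime(unit_params(kappa_m))
        assert report.regime is regime
        assert not report.boundary
        assert (report.steady_state is not None) == (regime is Regime.FINITE_SIZE)

    def test_boundary_flags_at_critical_rates(self):
        base = unit_params(1.0)
        for which, bucket in (("alpha=1", Regime.EXTINCTION),
                              ("alpha=0", Regime.UNBOUNDED_GROWTH)):
            crit = critical_kappa_minus(base, which)
            report = classify_regime(base.replace(kappa_m=crit))
            assert report.regime is bucket
            assert report.boundary

    def test_sign_pattern_agreement_on_random_sets(self):
        """The alpha_bar signs and the explicit product inequalities are two
        routes to the same classification; classify_regime cross-checks them
        internally and must never trip on valid parameters."""
        rng = np.random.default_rng(5)
        counts = {r: 0 for r in Regime}
        for _ in range(200):
            report = classify_regime(random_rates(rng))
            counts[report.regime] += 1
        assert all(c > 0 for c in counts.values())  # sampling spans all regimes

    def test_integration_fate_matches_prediction(self):
        """Long-horizon trajectories end as the classification predicts:
        dissolution, convergence to the closed-form state, or unbounded
        growth.  Near-boundary sets (|alpha_bar| or |alpha_bar - 1| < 0.02)
        are excluded."""
        rng = np.random.default_rng(7)
        init = ContinuumState(1.0, 3.0, 3.0)  # admissible for every n >= 3
        total0 = init.p + init.q + init.r
        checked = 0
        while checked < 60:
            params = random_rates(rng)
            report = classify_regime(params)
            ab = report.alpha_bar
            if abs(ab) < 0.02 or abs(ab - 1.0) < 0.02:
                continue
            checked += 1
            if report.regime is Regime.UNBOUNDED_GROWTH:
                co = asymptotic_coefficients(params)
                t_end = min(1e5, max(300.0, math.sqrt(60.0 / co.r2)))
                traj = integrate(params, init, t_end)
                total = traj.p[-1] + traj.q[-1] + traj.r[-1]
                assert total > 10 * total0
            elif report.regime is Regime.EXTINCTION:
                rate = params.kappa_m * min(ab - 1.0, 1.0)
                t_end = min(5e4, max(300.0, 40.0 / rate))
                traj = integrate(params, init, t_end)
                total = traj.p[-1] + traj.q[-1] + traj.r[-1]
                assert traj.terminated_at_origin is not None or total < 0.2 * total0
            else:
                ss = report.steady_state
                scale = max(ss.p, ss.q, ss.r)
                traj = integrate(params, init, 4000.0)
                dist = max(abs(traj.p[-1] - ss.p), abs(traj.q[-1] - ss.q),
                           abs(traj.r[-1] - ss.r))
                if dist > 0.05 * scale:  # slow relaxation: extend once
                    traj = integrate(params, init, 40000.0)
                    dist = max(abs(traj.p[-1] - ss.p), abs(traj.q[-1] - ss.q),
                               abs(traj.r[-1] - ss.r))
                assert dist < 0.05 * scale


class TestCriticalKappaMinus:
    @pytest.mark.parametrize(
        "which, expected", [("alpha=1", 0.9271), ("alpha=0", 0.3708)]
    )
    def test_unit_rates(self, which, expected):
        crit = critical_kappa_minus(unit_params(1.0), which)
        assert crit == pytest.approx(expected, abs=1e-3)

    def test_against_bisection_oracle(self):
        params = unit_params(1.0).replace(kappa1=0.8, kappa2=1.7, kappa_m1=0.3)
        for which, level in (("alpha=1", 1.0), ("alpha=0", 0.0)):
            crit = critical_kappa_minus(params, which)
            oracle = brentq(
                lambda km: alpha_bar(params.replace(kappa_m=km)) - level,
                1e-6, 50.0, xtol=1e-12,
            )
            assert crit == pytest.approx(oracle, rel=1e-9)

    def test_figure_regimes_are_bracketed(self):
        # the three reference breaking rates straddle the two thresholds
        lo = critical_kappa_minus(unit_params(1.0), "alpha=0")
        hi = critical_kappa_minus(unit_params(1.0), "alpha=1")
        assert 0.2 < lo < 0.6 < hi < 0.93


class TestAsymptotics:
    def test_reference_coefficients(self, params_growth):
        co = asymptotic_coefficients(params_growth)
        assert co.p1 == pytest.approx(0.03704, abs=1e-4)
        assert co.q2 == pytest.approx(0.01816, abs=1e-4)
        assert co.r2 == pytest.approx(0.007264, abs=1e-4)
        assert co.q2 == pytest.approx(params_growth.n / 2 * co.r2, rel=1e-14)

    def test_requires_growth_regime(self, params_finite):
        with pytest.raises(DomainError):
            asymptotic_coefficients(params_finite)

    def test_p1_vanishes_at_growth_onset(self):
        crit = critical_kappa_minus(unit_params(1.0), "alpha=0")
        below = asymptotic_coefficients(unit_params(crit * (1 - 1e-6)))
        assert 0 < below.p1 < 1e-5
        with pytest.raises(DomainError):
            asymptotic_coefficients(unit_params(crit * (1 + 1e-6)))

    @pytest.mark.parametrize("kappa_m", [0.1, 0.15, 0.2])
    def test_coefficients_match_trajectory_fits(self, kappa_m):
        params = unit_params(kappa_m)
        co = asymptotic_coefficients(params)
        grid = np.concatenate([[0.0], np.geomspace(1.0, 1e4, 200)])
        traj = integrate(params, ContinuumState(2, 4, 3), 1e4, output_grid=grid)
        t_end = traj.times[-1]
        assert traj.p[-1] / t_end == pytest.approx(co.p1, rel=0.02)
        assert traj.q[-1] / t_end**2 == pytest.approx(co.q2, rel=0.02)
        assert traj.r[-1] / t_end**2 == pytest.approx(co.r2, rel=0.02)


class TestKappaZero:
    def test_reference_limits(self, params_no_breaking):
        # unit rates, n = 5: p_inf = 3/7 and s_inf = 3/2 by the nullclines
        lim = kappa_zero_limits(params_no_breaking)
        assert lim.p_inf == pytest.approx(3.0 / 7.0, rel=1e-14)
        assert lim.s_inf == 1.5
        assert lim.slope_r == pytest.approx(3.0 / 7.0, rel=1e-14)
        assert lim.slope_q == pytest.approx(15.0 / 14.0, rel=1e-14)

    def test_limits_solve_both_nullclines(self):
        # independent check: the closed forms satisfy the planar equations
        for params in (unit_params(0.0),
                       unit_params(0.0, n=7).replace(kappa1=0.4, kappa2=2.0,
                                                     kappa3=0.7, kappa_m1=0.3)):
            lim = kappa_zero_limits(params)
            n, k1, k2 = params.n, params.kappa1, params.kappa2
            k3, km1 = params.kappa3, params.kappa_m1
            dp = k1 * lim.s_inf - (k2 + km1 + k3 * lim.s_inf) * lim.p_inf
            ds = ((n - 1) * k2 + km1) * lim.p_inf - (k1 + k3 * lim.p_inf) * lim.s_inf
            assert abs(dp) < 1e-12 and abs(ds) < 1e-12

    def test_rejects_nonzero_breaking(self, params_finite):
        with pytest.raises(DomainError):
            kappa_zero_limits(params_finite)

    def test_limit_is_independent_of_initial_state(self, params_no_breaking):
        lim = kappa_zero_limits(params_no_breaking)
        for init in (ContinuumState(2, 4, 3), ContinuumState(2, 8, 4)):
            traj = integrate(params_no_breaking, init, 200.0)
            assert traj.p[-1] == pytest.approx(lim.p_inf, abs=1e-4)
            assert traj.s[-1] == pytest.approx(lim.s_inf, abs=1e-4)

    def test_linear_growth_slopes(self, params_no_breaking):
        lim = kappa_zero_limits(params_no_breaking)
        traj = integrate(params_no_breaking, ContinuumState(2, 4, 3), 500.0)
        half = len(traj) // 2
        dq = (traj.q[-1] - traj.q[half]) / (traj.times[-1] - traj.times[half])
        dr = (traj.r[-1] - traj.r[half]) / (traj.times[-1] - traj.times[half])
        assert dq == pytest.approx(lim.slope_q, rel=1e-3)
        assert dr == pytest.approx(lim.slope_r, rel=1e-3)

    def test_lyapunov_definite_and_decreasing(self, params_no_breaking):
        lim = kappa_zero_limits(params_no_breaking)
        assert lyapunov_value(lim.p_inf, lim.s_inf, lim) == 0.0
        assert lyapunov_value(2 * lim.p_inf, lim.s_inf, lim) == pytest.approx(1.0)
        with pytest.raises(DomainError):
            lyapunov_value(0.0, 1.0, lim)
        traj = integrate(params_no_breaking, ContinuumState(2, 4, 3), 100.0)
        values = [lyapunov_value(float(p), float(s), lim)
                  for p, s in zip(traj.p, traj.s)]
        assert all(b <= a + 1e-8 for a, b in zip(values, values[1:]))


class TestExponentEstimate:
    def test_exact_power_law_recovered(self):
        times = np.geomspace(10.0, 1e4, 100)
        for gamma in (0.5, 1.0, 2.0):
            traj = Trajectory(times=times, p=3.0 * times**gamma,
                              q=times**gamma, r=times**gamma, n=5)
            assert exponent_estimate(traj, "p", (10.0, 1e4)) == (
                pytest.approx(gamma, abs=1e-10))

    def test_growth_regime_exponents(self, params_growth):
        grid = np.concatenate([[0.0], np.geomspace(1.0, 1e4, 300)])
        traj = integrate(params_growth, ContinuumState(2, 4, 3), 1e4,
                         output_grid=grid)
        assert exponent_estimate(traj, "p", (1e3, 1e4)) == pytest.approx(1.0, abs=0.05)
        assert exponent_estimate(traj, "q", (1e3, 1e4)) == pytest.approx(2.0, abs=0.05)
        assert exponent_estimate(traj, "r", (1e3, 1e4)) == pytest.approx(2.0, abs=0.05)

    def test_window_and_positivity_validation(self, params_growth):
        traj = Trajectory(times=np.geomspace(10, 100, 10),
                          p=np.zeros(10), q=np.ones(10), r=np.ones(10), n=5)
        with pytest.raises(DomainError):
            exponent_estimate(traj, "p", (10.0, 100.0))
        with pytest.raises(DomainError):
            exponent_estimate(traj, "q", (1.0, 100.0))
        with pytest.raises(DomainError):
            exponent_estimate(traj, "total", (10.0, 100.0))
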