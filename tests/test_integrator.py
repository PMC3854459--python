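"""Ca2+ protocols and the adaptive Cash-Karp integrator."""

import numpy as np
import pytest

import seqpool as sp
from seqpool.integrate import Segment

STEP = sp.CalciumProtocol.step(0.5, 25.0, at=0.5)


class TestProtocol:
    def test_step_right_continuity(self):
        assert STEP.ca(0.49) == 0.5
        assert STEP.ca(0.5) == 25.0

    def test_exp_relax_value(self):
        prot = sp.CalciumProtocol([
            Segment(0.0, "exp_relax", 25.0, tau=3.0, target=0.5)])
        assert prot.ca(3.0) == pytest.approx(0.5 + 24.5 / np.e, rel=1e-12)

    def test_before_start_rejected(self):
        with pytest.raises(ValueError):
            STEP.ca(-0.1)

    def test_nonincreasing_starts_rejected(self):
        with pytest.raises(ValueError):
            sp.CalciumProtocol([Segment(0.0, "constant", 1.0),
                                Segment(0.0, "constant", 2.0)])

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            Segment(0.0, "constant", -1.0)
        with pytest.raises(ValueError):
            Segment(0.0, "exp_relax", 25.0, tau=-1.0, target=0.5)
        with pytest.raises(ValueError):
            Segment(0.0, "ramp", 1.0)


class TestIntegrate:
    def test_constant_protocol_stays_at_steady_state(self, spm):
        """From the resting state at fixed Ca2+ the pools are constant
        and the cumulative capacitance grows linearly at the steady
        fusion flux."""
        state, flux = spm.steady_state(0.5)
        tr = sp.integrate(spm, sp.CalciumProtocol.constant(0.5), (0.0, 1.0))
        np.testing.assert_allclose(tr.pools[-1, :5], state[:5],
                                   rtol=1e-9, atol=1e-12)
        slope = (tr.dCm[-1] - tr.dCm[0]) / (tr.t[-1] - tr.t[0])
        assert slope == pytest.approx(flux, rel=1e-9)

    def test_step_response_is_biphasic_then_sustained(self, spm_flash):
        """The uncaging response shows two burst phases followed by a
        near-linear sustained phase."""
        fit = spm_flash.fit
        assert fit.A1 > 50 and fit.A2 > 50
        assert fit.tau2 > 3 * fit.tau1
        assert fit.A3 > 0
        assert fit.residual_rms < 1.0  # the two-exp + line form describes it

    def test_dCm_nondecreasing_and_pools_nonnegative(self, spm_flash):
        tr = spm_flash.trace
        assert np.all(np.diff(tr.dCm) >= -1e-12)
        assert np.min(tr.pools) > -1e-9

    def test_tolerance_convergence(self, spm):
        """Halving the relative tolerance leaves the final cumulative
        release unchanged to well below 1e-6 relative."""
        out = []
        for rt in (1e-8, 5e-9):
            s = sp.SolverSettings(rel_tol=rt)
            tr = sp.integrate(spm, STEP, (0.0, 1.5), settings=s)
            out.append(tr.dCm[-1])
        assert abs(out[1] - out[0]) / out[1] < 1e-6

    def test_agrees_with_fixed_step_rk4(self, spm):
        """Independent oracle: classical fixed-step RK4 at dt = 1e-5 s
        on the uncaging step protocol (scalar arithmetic, no shared
        code path)."""
        p = spm.params
        km2cat = p.k_minus2cat

        def rhs(y, ca):
            g = ca / (p.K_D + ca)
            k2 = p.k20 + p.k2cat * g
            km2 = p.k_minus20 + km2cat * g
            k1 = p.k1max * ca / (p.K_M + ca)
            n_, r0, r1, r2, r3, _ = y
            k3ca = p.k3 * ca
            km3 = p.k_minus3
            return (k1 - (p.k_minus1 + k2) * n_ + km2 * r0,
                    k2 * n_ - (km2 + 3 * k3ca) * r0 + km3 * r1,
                    3 * k3ca * r0 - (km3 + 2 * k3ca) * r1 + 2 * km3 * r2,
                    2 * k3ca * r1 - (2 * km3 + k3ca) * r2 + 3 * km3 * r3,
                    k3ca * r2 - (3 * km3 + p.k4) * r3,
                    p.k4 * r3)

        def rk4(y, t0, t1, dt, ca):
            for _ in range(int(round((t1 - t0) / dt))):
                k1 = rhs(y, ca)
                k2 = rhs(tuple(a + 0.5 * dt * b for a, b in zip(y, k1)), ca)
                k3 = rhs(tuple(a + 0.5 * dt * b for a, b in zip(y, k2)), ca)
                k4 = rhs(tuple(a + dt * b for a, b in zip(y, k3)), ca)
                y = tuple(a + dt / 6 * (b + 2 * c + 2 * d + e)
                          for a, b, c, d, e in zip(y, k1, k2, k3, k4))
            return y

        ss, _ = spm.steady_state(0.5)
        y = rk4(tuple(ss), 0.0, 0.5, 1e-5, 0.5)
        y = rk4(y, 0.5, 2.0, 1e-5, 25.0)
        tr = sp.integrate(spm, STEP, (0.0, 2.0))
        assert abs(y[5] - tr.dCm[-1]) / y[5] < 1e-6

    def test_agrees_with_scipy_dop853(self, spm):
        """Second independent oracle: scipy's high-order Dormand-Prince
        solver at tight tolerance."""
        from scipy.integrate import solve_ivp

        ss, _ = spm.steady_state(0.5)
        sol = solve_ivp(lambda t, y: spm.rhs(y, 25.0), (0.5, 2.0), ss,
                        method="DOP853", rtol=1e-12, atol=1e-12)
        tr = sp.integrate(spm, STEP, (0.0, 2.0))
        i_step = np.searchsorted(tr.t, 0.5)  # sample holds the pre-step state
        post_step_release = tr.dCm[-1] - tr.dCm[i_step]
        assert post_step_release == pytest.approx(sol.y[5, -1], rel=1e-7)

    def test_mass_conservation(self, spm):
        """Total mass plus fused mass minus the integrated Depot
        exchange is a linear invariant; the residual stays at solver
        tolerance."""
        p = spm.params

        class Augmented:
            state_names = spm.state_names + ("influx",)
            fused_names = ("F",)
            n_states = 7

            def rhs(self, y, ca):
                d = np.empty(7)
                d[:6] = spm.rhs(y[:6], ca)
                d[6] = sp.recruitment_rate(ca, p) - p.k_minus1 * y[0]
                return d

            def steady_state(self, ca):
                s, flux = spm.steady_state(ca)
                return np.append(s, 0.0), flux

        tr = sp.integrate(Augmented(), STEP, (0.0, 3.0))
        mass0 = tr.pools[0, :6].sum()
        resid = tr.pools[:, :6].sum(axis=1) - tr.pools[:, 6] - mass0
        assert np.max(np.abs(resid)) < 10 * sp.SolverSettings().abs_tol

    def test_exp_relax_drives_integration(self, spm):
        """After a relaxing flash the Ca2+ (and hence release rate)
        returns toward baseline."""
        prot = sp.CalciumProtocol([
            Segment(0.0, "constant", 0.5),
            Segment(0.5, "exp_relax", 25.0, tau=2.0, target=0.5)])
        tr = sp.integrate(spm, prot, (0.0, 12.0))
        assert tr.ca[-1] == pytest.approx(0.5, abs=0.1)
        late_slope = (tr.dCm[-1] - tr.dCm[-501]) / (tr.t[-1] - tr.t[-501])
        assert late_slope < 10.0  # far below the peak release rate

    def test_step_underflow_reports_time(self, spm):
        s = sp.SolverSettings(rel_tol=1e-14, abs_tol=1e-16, h_min=1e-4,
                              h_init=1e-4)
        with pytest.raises(RuntimeError, match="t="):
            sp.integrate(spm, STEP, (0.0, 1.0), settings=s)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            sp.SolverSettings(rel_tol=-1.0)
        with pytest.raises(ValueError):
            sp.SolverSettings(h_init=1.0, h_min=2.0)
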