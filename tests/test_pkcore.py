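"""Closed-form two-compartment kinetics against independent numeric oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from mvpk import (
    DoseEvent,
    StructuralParams,
    auc,
    cmax_first_interval,
    concentration,
    macro_constants,
    micro_rates,
    urine_amount,
)
from mvpk.pkcore import InvalidParameterError

from conftest import random_params


def ode_concentration(p, doses, times):
    """Stiff ODE integration of the two-compartment system (oracle)."""
    k10, k12, k21 = micro_rates(p)

    def rate_in(t):
        r = 0.0
        for d in doses:
            if d.start_time < t <= d.start_time + d.duration:
                r += d.rate
        return r

    def rhs(t, y):
        a1, a2 = y
        return [rate_in(t) - (k10 + k12) * a1 + k21 * a2,
                k12 * a1 - k21 * a2]

    knots = np.unique([0.0] + [d.start_time for d in doses]
                      + [d.start_time + d.duration for d in doses])
    tmax = float(max(times))
    gaps = np.diff(np.append(knots, tmax + 1.0))
    max_step = float(min(gaps[gaps > 0].min(), 1.0))
    sol = solve_ivp(rhs, (0.0, tmax + 1e-9), [0.0, 0.0], method="Radau",
                    rtol=1e-11, atol=1e-12, dense_output=True,
                    max_step=max_step)
    return sol.sol(times)[0] / p.Vc


class TestMicroMacro:
    def test_micro_rates_typical(self, typical_mero):
        k10, k12, k21 = micro_rates(typical_mero)
        assert k10 == pytest.approx(0.5580, abs=2e-4)
        assert k12 == pytest.approx(0.0800, abs=1e-4)
        assert k21 == pytest.approx(0.5862, abs=1e-4)

    def test_micro_rates_no_peripheral_exchange(self):
        p = StructuralParams(CL_R=0, CL_NR=5, Vc=10, CLd=0, Vp=1)
        _, k12, k21 = micro_rates(p)
        assert k12 == 0 and k21 == 0

    def test_micro_rates_identity_case(self):
        p = StructuralParams(CL_R=0, CL_NR=1, Vc=1, CLd=1, Vp=1)
        assert micro_rates(p) == (1.0, 1.0, 1.0)

    def test_macro_constants_typical(self, typical_mero):
        mc = macro_constants(typical_mero)
        assert mc.lambda1 == pytest.approx(0.8303, abs=2e-4)
        assert mc.lambda2 == pytest.approx(0.3939, abs=2e-4)
        assert mc.t_half_alpha == pytest.approx(0.835, abs=2e-3)
        assert mc.t_half_beta == pytest.approx(1.760, abs=2e-3)

    def test_macro_constants_quadratic_roots(self, rng):
        # eigenvalues must solve lam^2 - (k10+k12+k21) lam + k10 k21 = 0
        for p in random_params(rng, 50):
            if p.CLd == 0:
                continue
            k10, k12, k21 = micro_rates(p)
            mc = macro_constants(p)
            assert mc.lambda1 + mc.lambda2 == pytest.approx(
                k10 + k12 + k21, rel=1e-9)
            assert mc.lambda1 * mc.lambda2 == pytest.approx(
                k10 * k21, rel=1e-6)
            assert mc.lambda1 >= mc.lambda2 > 0

    def test_one_compartment_limit(self):
        p = StructuralParams(CL_R=0, CL_NR=5.0, Vc=20.0, CLd=0, Vp=1.0)
        mc = macro_constants(p)
        assert mc.lambda1 == pytest.approx(0.25)
        assert mc.t_half_beta == pytest.approx(np.log(2) * 20 / 5)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            StructuralParams(CL_R=1, CL_NR=1, Vc=-1, CLd=1, Vp=1)
        with pytest.raises(InvalidParameterError):
            StructuralParams(CL_R=-0.1, CL_NR=1, Vc=1, CLd=1, Vp=1)
        with pytest.raises(InvalidParameterError):
            DoseEvent(0.0, 1000.0, 0.0)


class TestConcentration:
    def test_zero_before_first_dose(self, typical_mero):
        d = [DoseEvent(2.0, 2000.0, 3.0)]
        assert concentration(typical_mero, d, 1.5) == 0.0

    def test_no_elimination_mass_balance(self):
        # with negligible elimination and no distribution, the end-of-infusion
        # concentration is dose/Vc
        p = StructuralParams(CL_R=0, CL_NR=1e-9, Vc=17.0, CLd=0, Vp=1.0)
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        assert concentration(p, d, 3.0) == pytest.approx(2000 / 17.0, rel=1e-6)

    def test_matches_ode_oracle(self, rng):
        doses = [DoseEvent(0.0, 2000.0, 3.0), DoseEvent(8.0, 1000.0, 3.0)]
        times = np.linspace(0.5, 16.0, 20)
        for p in random_params(rng, 10):
            ref = ode_concentration(p, doses, times)
            got = concentration(p, doses, times)
            assert np.allclose(got, ref, rtol=1e-6, atol=1e-10)

    def test_continuous_at_infusion_end(self, typical_mero):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        left = concentration(typical_mero, d, 3.0 - 1e-9)
        right = concentration(typical_mero, d, 3.0 + 1e-9)
        assert left == pytest.approx(right, rel=1e-6)

    def test_linearity_in_dose(self, rng):
        times = np.linspace(0.5, 24.0, 15)
        for p in random_params(rng, 10):
            c1 = concentration(p, [DoseEvent(0.0, 500.0, 3.0)], times)
            c2 = concentration(p, [DoseEvent(0.0, 1500.0, 3.0)], times)
            assert np.allclose(3.0 * c1, c2, rtol=1e-10)

    def test_superposition(self, rng):
        times = np.linspace(0.5, 30.0, 15)
        d1 = [DoseEvent(0.0, 2000.0, 3.0)]
        d2 = [DoseEvent(8.0, 1000.0, 3.0)]
        for p in random_params(rng, 10):
            combined = concentration(p, d1 + d2, times)
            parts = concentration(p, d1, times) + concentration(p, d2, times)
            assert np.allclose(combined, parts, rtol=1e-10, atol=1e-300)

    def test_near_repeated_root_stays_close_to_ode(self):
        # parameters contrived so the two eigenvalues nearly coincide
        # (disc ~ 0): k10 = k21 and k12 -> 0
        p = StructuralParams(CL_R=0, CL_NR=5.0, Vc=10.0, CLd=0.5000001,
                             Vp=1.0000002)
        doses = [DoseEvent(0.0, 1000.0, 2.0)]
        times = np.linspace(0.5, 12, 10)
        ref = ode_concentration(p, doses, times)
        assert np.allclose(concentration(p, doses, times), ref, rtol=1e-5)


class TestAuc:
    def test_single_dose_total_auc_is_dose_over_cl(self, rng):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        for p in random_params(rng, 10):
            assert auc(p, d, 0.0, np.inf) == pytest.approx(
                2000.0 / p.CL, rel=1e-9)

    def test_quadrature_oracle(self, rng, typical_mero):
        doses = [DoseEvent(0.0, 2000.0, 3.0), DoseEvent(8.0, 2000.0, 3.0)]
        for p in random_params(rng, 5) + [typical_mero]:
            ref, _ = quad(lambda t: concentration(p, doses, t), 0.0, 20.0,
                          points=[3.0, 8.0, 11.0], limit=200,
                          epsabs=1e-12, epsrel=1e-12)
            assert auc(p, doses, 0.0, 20.0) == pytest.approx(ref, rel=1e-8)

    def test_steady_state_interval_auc(self, typical_mero):
        # after >= 20 q8h doses the interval AUC approaches dose/CL
        doses = [DoseEvent(8.0 * i, 2000.0, 3.0) for i in range(24)]
        a = auc(typical_mero, doses, 8.0 * 22, 8.0 * 23)
        assert a == pytest.approx(2000.0 / typical_mero.CL, rel=1e-4)
        # and the daily steady-state AUC is 3 doses' worth: 6000/CL
        assert 3 * a == pytest.approx(6000.0 / 9.486, rel=1e-3)

    def test_bad_interval_raises(self, typical_mero):
        with pytest.raises(ValueError):
            auc(typical_mero, [DoseEvent(0, 100, 1)], 2.0, 2.0)


class TestUrine:
    def test_zero_renal_clearance(self, rng):
        p = StructuralParams(CL_R=0.0, CL_NR=5.0, Vc=15.0, CLd=1.0, Vp=2.0)
        assert urine_amount(p, [DoseEvent(0, 1000, 3)], 0, 24) == 0.0

    def test_total_excretion_is_renal_fraction(self, rng):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        for p in random_params(rng, 10):
            total = urine_amount(p, d, 0.0, np.inf)
            assert total == pytest.approx(2000.0 * p.CL_R / p.CL, rel=1e-9)

    def test_cumulative_bounded_and_increasing(self, typical_mero):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        bound = 2000.0 * typical_mero.CL_R / typical_mero.CL
        prev = 0.0
        for t in (4.0, 8.0, 24.0, 48.0):
            amt = urine_amount(typical_mero, d, 0.0, t)
            assert prev <= amt <= bound * (1 + 1e-12)
            prev = amt
        assert prev == pytest.approx(bound, rel=1e-4)

    def test_typical_24h_excretion_vs_quadrature(self, typical_mero):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        ref, _ = quad(lambda t: concentration(typical_mero, d, t), 0, 24,
                      points=[3.0], limit=200)
        got = urine_amount(typical_mero, d, 0.0, 24.0)
        assert got == pytest.approx(typical_mero.CL_R * ref, rel=1e-6)
        # ~59.4% of the dose eventually appears in urine at eGFR 100
        assert got / 2000.0 == pytest.approx(0.594, abs=0.005)


class TestCmax:
    def test_no_elimination_peak_at_infusion_end(self):
        p = StructuralParams(CL_R=0, CL_NR=1e-9, Vc=17.0, CLd=0, Vp=1.0)
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        assert cmax_first_interval(p, d, 8.0) == pytest.approx(
            concentration(p, d, 3.0), rel=1e-9)

    def test_grid_oracle(self, rng):
        d = [DoseEvent(0.0, 2000.0, 3.0)]
        fine = np.arange(0.0, 8.0001, 0.001)
        for p in random_params(rng, 10):
            ref = float(np.max(concentration(p, d, fine)))
            got = cmax_first_interval(p, d, 8.0)
            assert got == pytest.approx(ref, rel=1e-3)
            assert got >= ref - 1e-9  # refinement can only beat the grid

    def test_dose_proportionality(self, typical_mero):
        c1 = cmax_first_interval(typical_mero, [DoseEvent(0, 1000, 3)], 8.0)
        c2 = cmax_first_interval(typical_mero, [DoseEvent(0, 2000, 3)], 8.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-9)
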