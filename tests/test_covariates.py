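"""Demographic equations and covariate-to-parameter relationships."""

import numpy as np
import pytest

from mvpk import (
    CovariateRecord,
    RenalFunctionModel,
    dubois_bsa,
    bmi,
    fraction_renal,
    mdrd_egfr,
    renal_clearance,
    typical_params_meropenem,
    typical_params_vaborbactam,
)


class TestMdrd:
    def test_creatinine_cap(self):
        # creatinine is floored at 0.5 mg/dl before evaluation
        assert mdrd_egfr(0.3, 50, "M", "other") == mdrd_egfr(
            0.5, 50, "M", "other")

    def test_reference_male(self):
        expected = 175.0 * 50.0 ** -0.203
        assert mdrd_egfr(1.0, 50, "M", "other") == pytest.approx(expected)
        assert expected == pytest.approx(79.1, abs=0.1)

    def test_sex_and_race_multipliers(self):
        m = mdrd_egfr(1.2, 60, "M", "other")
        assert mdrd_egfr(1.2, 60, "F", "other") / m == pytest.approx(0.742)
        assert mdrd_egfr(1.2, 60, "M", "black") / m == pytest.approx(1.212)

    def test_monotone_and_continuous_at_cap(self):
        scr = np.linspace(0.2, 4.0, 200)
        out = mdrd_egfr(scr, 55, "F", "other")
        assert np.all(np.diff(out) <= 1e-12)
        lo = mdrd_egfr(0.5 - 1e-9, 55, "F", "other")
        hi = mdrd_egfr(0.5 + 1e-9, 55, "F", "other")
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_alternative_coefficient(self):
        ratio = mdrd_egfr(1.0, 50, "M", "other", coefficient=186.0) \
            / mdrd_egfr(1.0, 50, "M", "other")
        assert ratio == pytest.approx(186.0 / 175.0)


class TestBodySize:
    def test_bsa_reference_subject(self):
        # pooled medians 75 kg / 168 cm give the published median BSA 1.84
        assert dubois_bsa(75.0, 168.0) == pytest.approx(1.85, abs=0.02)

    def test_bsa_weight_power(self):
        assert dubois_bsa(150.0, 168.0) / dubois_bsa(75.0, 168.0) \
            == pytest.approx(2 ** 0.425)

    def test_bmi(self):
        assert bmi(75.0, 168.0) == pytest.approx(75 / 1.68 ** 2, rel=1e-12)
        assert bmi(75.0, 168.0) == pytest.approx(26.6, abs=0.05)


class TestRenalClearance:
    def test_meropenem_at_egfr_100(self):
        rf = RenalFunctionModel(form="hill", clr_max=6.58, egfr50=40.0,
                                hill=1.95)
        expected = 6.58 * 100 ** 1.95 / (40 ** 1.95 + 100 ** 1.95)
        assert renal_clearance(rf, 100.0) == pytest.approx(expected)
        assert expected == pytest.approx(5.636, abs=2e-3)

    @pytest.mark.parametrize("clr_max,egfr50,hill", [
        (6.58, 40.0, 1.95),   # meropenem
        (8.86, 49.7, 2.25),   # vaborbactam
    ])
    def test_half_maximal_identity(self, clr_max, egfr50, hill):
        rf = RenalFunctionModel(form="hill", clr_max=clr_max, egfr50=egfr50,
                                hill=hill)
        assert renal_clearance(rf, egfr50) == pytest.approx(
            clr_max / 2.0, rel=1e-12)

    def test_zero_and_monotone_bounded(self):
        rf = RenalFunctionModel(form="hill", clr_max=6.58, egfr50=40.0,
                                hill=1.95)
        assert renal_clearance(rf, 0.0) == 0.0
        grid = renal_clearance(rf, np.linspace(0, 338, 500))
        assert np.all(np.diff(grid) > 0)
        assert np.all(grid < 6.58)

    def test_linear_and_power_forms(self):
        lin = RenalFunctionModel(form="linear", slope=0.05)
        assert renal_clearance(lin, 80.0) == pytest.approx(4.0)
        pw = RenalFunctionModel(form="power", a=0.2, b=0.8)
        assert renal_clearance(pw, 50.0) == pytest.approx(0.2 * 50 ** 0.8)

    def test_negative_egfr_rejected(self):
        rf = RenalFunctionModel(form="hill", clr_max=1, egfr50=1, hill=1)
        with pytest.raises(ValueError):
            renal_clearance(rf, -1.0)


class TestTypicalValues:
    def test_meropenem_reference_subject(self, mero_model):
        cov = CovariateRecord(age=53, weight=75, height=168, egfr=100.0)
        p = typical_params_meropenem(cov, mero_model.theta)
        assert p.CL == pytest.approx(9.486, abs=5e-3)
        assert fraction_renal(p) == pytest.approx(0.594, abs=2e-3)
        assert p.Vc == pytest.approx(17.0)
        assert p.CLd == pytest.approx(1.36)
        assert p.Vp == pytest.approx(2.32)

    def test_meropenem_egfr_40(self, mero_model):
        cov = CovariateRecord(age=53, weight=75, height=168, egfr=40.0)
        p = typical_params_meropenem(cov, mero_model.theta)
        assert p.CL == pytest.approx(3.85 + 3.29, abs=5e-3)

    def test_meropenem_renal_group_shift(self, mero_model):
        cov = CovariateRecord(age=53, weight=75, height=168, egfr=25.0)
        p = typical_params_meropenem(cov, mero_model.theta)
        assert p.CL_NR == pytest.approx(3.85 * 0.35, rel=1e-9)

    def test_meropenem_allometric_and_age_scaling(self, mero_model):
        ref = typical_params_meropenem(
            CovariateRecord(age=53, weight=75, height=168, egfr=100.0),
            mero_model.theta)
        heavy = typical_params_meropenem(
            CovariateRecord(age=53, weight=150, height=168, egfr=100.0),
            mero_model.theta)
        assert heavy.CL / ref.CL == pytest.approx(2 ** 0.75)
        assert heavy.Vc / ref.Vc == pytest.approx(2.0)
        old = typical_params_meropenem(
            CovariateRecord(age=106, weight=75, height=168, egfr=100.0),
            mero_model.theta)
        assert old.CL / ref.CL == pytest.approx(2 ** -0.526)
        assert old.Vc == pytest.approx(ref.Vc)

    def test_vaborbactam_half_max(self, vab_model):
        cov = CovariateRecord(age=53, weight=75, height=168, egfr=49.7,
                              phase=3)
        p = typical_params_vaborbactam(cov, vab_model.theta)
        assert p.CL == pytest.approx(0.157 + 8.86 / 2, abs=2e-3)

    def test_vaborbactam_phase_shifts(self, vab_model):
        kw = dict(age=53, weight=75, height=168, egfr=90.0)
        p3 = typical_params_vaborbactam(CovariateRecord(phase=3, **kw),
                                        vab_model.theta)
        p1 = typical_params_vaborbactam(CovariateRecord(phase=1, **kw),
                                        vab_model.theta)
        assert p1.CL / p3.CL == pytest.approx(1.517)
        assert p1.Vp / p3.Vp == pytest.approx(2.28)
        assert p1.Vc / p3.Vc == pytest.approx(1 - 0.215)

    def test_vaborbactam_saturation_asymptote(self, vab_model):
        cov = CovariateRecord(age=53, weight=75, height=168, egfr=1e9,
                              phase=3)
        p = typical_params_vaborbactam(cov, vab_model.theta)
        assert p.CL == pytest.approx(0.157 + 8.86, rel=1e-4)

    def test_renal_fraction_size_age_invariant(self, mero_model):
        # the weight and age effects multiply total CL, so CL_R/CL is fixed
        fr = None
        for wt in (45.0, 75.0, 150.0):
            for age in (20.0, 53.0, 90.0):
                cov = CovariateRecord(age=age, weight=wt, height=168,
                                      egfr=100.0)
                p = typical_params_meropenem(cov, mero_model.theta)
                if fr is None:
                    fr = fraction_renal(p)
                assert fraction_renal(p) == pytest.approx(fr, rel=1e-12)

    def test_all_parameters_positive_over_observed_ranges(self, mero_model,
                                                          vab_model):
        rng = np.random.default_rng(0)
        for _ in range(200):
            cov = CovariateRecord(
                age=float(rng.uniform(18, 92)),
                weight=float(rng.uniform(40, 177)),
                height=float(rng.uniform(145, 193)),
                egfr=float(rng.uniform(4.5, 338)),
                phase=int(rng.choice([1, 3])),
            )
            for p in (typical_params_meropenem(cov, mero_model.theta),
                      typical_params_vaborbactam(cov, vab_model.theta)):
                assert p.CL > 0 and p.Vc > 0 and p.CLd > 0 and p.Vp > 0

    def test_record_derivations_and_validation(self):
        cov = CovariateRecord(age=50, weight=80, height=170, sex="F",
                              race="black", scr=2.0)
        assert cov.egfr == pytest.approx(
            mdrd_egfr(2.0, 50, "F", "black"))
        assert cov.bsa == pytest.approx(dubois_bsa(80, 170))
        assert cov.renal_group is False
        with pytest.raises(ValueError):
            CovariateRecord(age=17, weight=70, height=170)
        with pytest.raises(ValueError):
            CovariateRecord(age=30, weight=70, height=170, phase=2)
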