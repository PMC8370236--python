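"""Laplace marginal likelihood, M3 censoring, post hoc estimates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from mvpk import (
    DoseEvent,
    PKData,
    StructuralParams,
    aic,
    concentration,
    fit,
    marginal_ofv,
    posthoc,
    simulate_study,
    study_design,
    subject_loglik,
)
from mvpk.estimation import (
    DataError,
    flag_aberrant,
    marginal_loglik_agh,
)

from conftest import plain_model, single_subject_frame

_LOG2PI = math.log(2 * math.pi)


def _toy_model(**kw):
    kw.setdefault("cl", 6.0)
    kw.setdefault("vc", 15.0)
    kw.setdefault("cld", 0.0)
    kw.setdefault("vp", 1.0)
    kw.setdefault("cv_cl", 30.0)
    kw.setdefault("sigma", (0.04, 0.01))
    return plain_model(**kw)


def _toy_pred(model, t):
    th = model.theta
    p = StructuralParams(CL_R=0.0, CL_NR=th["cl"], Vc=th["vc"],
                         CLd=th["cld"], Vp=th["vp"])
    return concentration(p, [DoseEvent(0.0, 1000.0, 1.0)], t)


class TestSubjectLoglik:
    def test_blq_at_prediction_equal_to_loq(self):
        # censoring point exactly at the prediction: the row contributes
        # log(1/2) on top of the eta prior
        model = _toy_model()
        t = 4.0
        pred = _toy_pred(model, t)
        frame = single_subject_frame([t], blq=[True], lloq=pred)
        got = subject_loglik(model, frame, np.zeros(1))
        prior = -0.5 * (_LOG2PI + math.log(model.omega[0, 0]))
        assert got == pytest.approx(prior + math.log(0.5), abs=1e-10)

    def test_no_observations_prior_only(self):
        model = _toy_model()
        frame = single_subject_frame([])
        got = subject_loglik(model, frame, np.array([0.3]))
        w2 = model.omega[0, 0]
        prior = -0.5 * (_LOG2PI + math.log(w2) + 0.3 ** 2 / w2)
        assert got == pytest.approx(prior, abs=1e-10)

    def test_quantified_row_matches_normal_density(self):
        model = _toy_model()
        t, dv = 2.0, 10.0
        pred = _toy_pred(model, t)
        sd = math.sqrt(pred ** 2 * 0.04 + 0.01)
        frame = single_subject_frame([t], dv=[dv])
        got = subject_loglik(model, frame, np.zeros(1))
        prior = -0.5 * (_LOG2PI + math.log(model.omega[0, 0]))
        assert got == pytest.approx(
            prior + norm.logpdf(dv, pred, sd), abs=1e-10)

    def test_eta_dimension_checked(self):
        model = _toy_model()
        frame = single_subject_frame([2.0], dv=[5.0])
        with pytest.raises(DataError):
            subject_loglik(model, frame, np.zeros(2))


class TestMarginal:
    def _one_obs_subject(self, model, t=3.0, dv=6.0):
        return single_subject_frame([t], dv=[dv])

    def test_censored_term_matches_density_integral(self):
        # the M3 contribution is the normal mass below the limit; compare
        # with brute-force quadrature of the residual density
        model = _toy_model()
        t, lloq = 5.0, 3.0
        pred = _toy_pred(model, t)
        sd = math.sqrt(pred ** 2 * 0.04 + 0.01)
        frame = single_subject_frame([t], blq=[True], lloq=lloq)
        got = subject_loglik(model, frame, np.zeros(1))
        prior = -0.5 * (_LOG2PI + math.log(model.omega[0, 0]))
        ref, _ = quad(lambda y: norm.pdf(y, pred, sd), -np.inf, lloq,
                      epsabs=1e-14)
        assert got - prior == pytest.approx(math.log(ref), abs=1e-8)

    def test_agh_and_laplace_vs_quadrature(self):
        # direct numerical integration of the (censored) joint density
        model = _toy_model()
        frame = single_subject_frame([3.0, 6.0], dv=[8.0, None],
                                     blq=[False, True], lloq=2.0)

        def integrand(e):
            return math.exp(subject_loglik(model, frame, np.array([e])))

        ref, err = quad(integrand, -4, 4, limit=200, epsabs=1e-13)
        agh = marginal_loglik_agh(model, frame, n_nodes=41)
        assert agh == pytest.approx(math.log(ref), abs=1e-5)
        lap = -0.5 * marginal_ofv(model, frame)
        assert lap == pytest.approx(math.log(ref), abs=0.3)

    def test_laplace_close_to_agh_on_toys(self):
        # Laplace OFV within 0.1 units of 21-node adaptive Gauss-Hermite on
        # informative toy subjects
        model = _toy_model()
        for fac in (0.7, 1.0, 1.6):
            times = [1.0, 2.0, 4.0, 6.0, 8.0]
            shifted = model.with_theta(cl=model.theta["cl"] * fac)
            dv = [float(_toy_pred(shifted, t)) for t in times]
            frame = single_subject_frame(times, dv=dv)
            agh = marginal_loglik_agh(model, frame, n_nodes=21)
            lap = -0.5 * marginal_ofv(model, frame)
            assert abs(-2 * lap - (-2 * agh)) < 0.1

    def test_omega_zero_limit(self):
        # degenerate prior: the marginal collapses to the eta=0 likelihood
        model = _toy_model(cv_cl=0.0)
        t, dv = 2.0, 9.0
        frame = single_subject_frame([t], dv=[dv])
        pred = _toy_pred(model, t)
        sd = math.sqrt(pred ** 2 * 0.04 + 0.01)
        assert marginal_ofv(model, frame) == pytest.approx(
            -2 * norm.logpdf(dv, pred, sd), abs=1e-8)

    def test_duplicated_subject_doubles_ofv(self):
        model = _toy_model()
        f1 = single_subject_frame([1.0, 4.0], dv=[14.0, 4.0])
        f2 = f1.copy()
        f2["ID"] = 2
        both = pd.concat([f1, f2], ignore_index=True)
        assert marginal_ofv(model, both) == pytest.approx(
            2 * marginal_ofv(model, f1), rel=1e-9)


class TestFit:
    def test_noise_free_recovery(self):
        # omega ~ 0, sigma ~ 0, rich sampling: thetas recovered to < 1%
        truth = _toy_model(cl=6.0, vc=15.0, cld=1.2, vp=3.0, cv_cl=0.0,
                           sigma=(1e-8, 1e-8))
        d = study_design("504", n_subjects=4)
        d = d.__class__(**{**d.__dict__, "urine_intervals": (),
                           "covariates": d.covariates})
        tab = simulate_study(d, truth, 5)
        start = truth.with_theta(cl=4.0, vc=20.0, cld=0.8, vp=2.0)
        res = fit(start, tab, free_theta=["cl", "vc", "cld", "vp"],
                  estimate_omega=False, estimate_sigma=False, maxiter=300)
        for name in ("cl", "vc", "cld", "vp"):
            assert res.model.theta[name] == pytest.approx(
                truth.theta[name], rel=0.01), name

    def test_ofv_history_non_increasing(self):
        truth = _toy_model()
        tab = simulate_study(study_design("505", n_subjects=20), truth, 8)
        res = fit(truth.with_theta(cl=9.0), tab, free_theta=["cl"],
                  estimate_omega=True, estimate_sigma=False, maxiter=25)
        hist = np.array(res.ofv_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-6)

    def test_perturbed_starts_reach_same_optimum(self):
        truth = _toy_model(sigma=(0.02, 1e-4))
        tab = simulate_study(study_design("505", n_subjects=25), truth, 4)
        kw = dict(free_theta=["cl", "vc"], estimate_omega=True,
                  estimate_sigma=False, maxiter=200)
        a = fit(truth, tab, **kw)
        b = fit(truth.with_theta(cl=truth.theta["cl"] * 2,
                                 vc=truth.theta["vc"] * 2), tab, **kw)
        assert abs(a.ofv - b.ofv) < 1.0

    def test_fixed_thetas_honored(self, mero_model):
        tab = simulate_study(study_design("505", n_subjects=10),
                             mero_model, 3)
        res = fit(mero_model, tab, free_theta=["clr_max"],
                  estimate_omega=False, estimate_sigma=False, maxiter=5)
        assert res.model.theta["wt_cl"] == 0.75
        assert res.model.theta["vc"] == 17.0

    def test_standard_errors_scale(self):
        truth = _toy_model(sigma=(0.02, 1e-4))
        tab = simulate_study(study_design("505", n_subjects=30), truth, 10)
        res = fit(truth, tab, free_theta=["cl"], estimate_omega=True,
                  estimate_sigma=False, maxiter=100, compute_se=True)
        se = res.se["cl"]
        # ~30% IIV over 30 subjects: SE of CL around cl*0.3/sqrt(30)
        rough = res.model.theta["cl"] * 0.30 / math.sqrt(30)
        assert 0.3 * rough < se < 3 * rough


class TestPosthoc:
    def test_no_observations_gives_prior_mode(self):
        model = _toy_model()
        f1 = single_subject_frame([1.0, 4.0], dv=[14.0, 4.0])
        f2 = single_subject_frame([])
        f2["ID"] = 2
        both = pd.concat([f1, f2], ignore_index=True)
        ph = posthoc(model, both)
        assert ph.loc[ph.ID == 2, "eta_CL"].iloc[0] == pytest.approx(
            0.0, abs=1e-9)

    def test_rich_data_recovers_individual_cl(self, mero_model):
        d = study_design("504", n_subjects=24)
        tab = simulate_study(d, mero_model, 13)
        data = PKData(tab)
        # regenerate the true etas with the same stream
        from mvpk.synthdata import sample_covariates, _design_skeleton, \
            _draw_etas
        rng = np.random.default_rng(13)
        covs = sample_covariates(d.covariates, 24, rng)
        _design_skeleton(d, covs, rng)
        etas_true = _draw_etas(mero_model, 24, rng)
        ph = posthoc(mero_model, data)
        rel = np.abs(ph["eta_CL"].to_numpy() - etas_true[:, 0])
        assert np.median(np.exp(rel) - 1) < 0.05

    def test_shrinkage_rises_with_sparser_sampling(self):
        truth = _toy_model(sigma=(0.02, 1e-4))
        rich = study_design("504", n_subjects=40)
        rich = rich.__class__(**{**rich.__dict__, "urine_intervals": ()})
        sparse = rich.__class__(**{**rich.__dict__,
                                   "plasma_times": (1.0, 5.0)})
        kw = dict(free_theta=[], estimate_omega=False, estimate_sigma=False,
                  maxiter=0)
        sh = {}
        for name, design in [("rich", rich), ("sparse", sparse)]:
            tab = simulate_study(design, truth, 17)
            res = fit(truth, tab, **kw)
            sh[name] = res.shrinkage["CL"]
        assert sh["sparse"] > sh["rich"]


class TestInformationCriteria:
    def test_aic_definition(self):
        truth = _toy_model()
        tab = simulate_study(study_design("505", n_subjects=10), truth, 2)
        res = fit(truth, tab, free_theta=["cl"], estimate_omega=False,
                  estimate_sigma=False, maxiter=5)
        assert aic(res) == pytest.approx(res.ofv + 2 * res.n_free)
        assert res.n_free == 1


class TestOutlierScreen:
    def test_flags_injected_outliers_only(self, mero_model):
        from mvpk.synthdata import inject_outliers

        tab = simulate_study(study_design("504", n_subjects=20),
                             mero_model, 6)
        rng = np.random.default_rng(1)
        bad = inject_outliers(tab, 0.02, 2.0, rng)
        report = flag_aberrant(mero_model, bad, threshold=6.0)
        clean_report = flag_aberrant(mero_model, tab, threshold=6.0)
        n_injected_plasma = int(
            ((bad.OUTLIER == 1) & (bad.CMT == 1)).sum())
        assert len(report) >= max(1, n_injected_plasma // 2)
        assert len(clean_report) <= 2


class TestDataValidation:
    def test_unsorted_times_rejected(self):
        frame = single_subject_frame([4.0, 1.0], dv=[1.0, 2.0])
        frame = frame.iloc[[0, 2, 1]].reset_index(drop=True)
        with pytest.raises(DataError):
            PKData(frame)

    def test_blq_without_lloq_rejected(self):
        frame = single_subject_frame([2.0], blq=[True], lloq=0.0)
        with pytest.raises(DataError):
            PKData(frame)

    def test_urine_needs_volume(self):
        frame = single_subject_frame([2.0], dv=[5.0],
                                     urine=[(4.0, 3.0, np.nan)])
        with pytest.raises(DataError):
            PKData(frame)
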