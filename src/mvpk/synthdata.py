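"""Synthetic clinical-study generator.

Emulates the four studies behind the meropenem-vaborbactam population PK
analysis so that every downstream stage (estimation, covariate selection,
VPC, exposure derivation) is exercisable without any external data:

* study 501 — phase 1, noninfected subjects, single rich-sampled dose
  followed by a week of q8h dosing with a rich steady-state day and urine
  collection (dose arms 1 g / 2 g, 3-h infusions);
* study 504 — phase 1 renal study: one 1-g dose, rich plasma and urine
  sampling, subjects stratified across normal / mild / moderate / severe /
  ESRD eGFR bands;
* studies 505 and 506 — phase 3 infected patients, 2 g q8h as 3-h
  infusions with sparse sampling (two day-1 samples after the end of
  infusion, one on day 3, one near the end of i.v. therapy) and
  protocol-style dose halving below an eGFR cutoff.

Covariates are drawn from truncated distributions whose per-study medians
and ranges mirror the published demographics; eGFR is never sampled
directly but derived from sampled creatinine through the MDRD equation, so
the age-renal-function correlation arises mechanically.  All observations
below the assay's lower calibration bound (0.02 mg/L) are flagged BLQ and
carry the limit, not a value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import mdrd_egfr, dubois_bsa, bmi as bmi_fn, RENAL_GROUP_EGFR
from .estimation import PKData
from .popmodel import PopulationModel

__all__ = [
    "CovariateSpec",
    "StudyDesign",
    "study_design",
    "sample_covariates",
    "simulate_study",
    "apply_renal_dose_adjustment",
    "inject_outliers",
    "resimulate_plasma",
]

#: assay lower calibration bound (mg/L), default BLQ limit for both drugs
DEFAULT_LLOQ = 0.02

#: default rich sampling times (h after the start of an intensive-day dose)
RICH_TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 3.25, 3.5, 4.0, 5.0, 6.0, 8.0)

#: default urine collection intervals (h after the intensive-day dose start)
URINE_INTERVALS = ((0.0, 4.0), (4.0, 8.0), (8.0, 24.0))

_EGFR_BANDS = (
    ("normal", 90.0, 140.0),
    ("mild", 60.0, 90.0),
    ("moderate", 30.0, 60.0),
    ("severe", 15.0, 30.0),
    ("esrd", 5.0, 15.0),
)


@dataclass(frozen=True)
class CovariateSpec:
    """Target distributions for one study's covariates.

    ``*_med`` are target medians; ``*_range`` hard truncation bounds.
    ``age_sd`` is a normal sd (years); ``weight_sigma``/``height_sigma`` are
    log-scale sds.  ``egfr_med`` steers the creatinine distribution unless
    ``renal_strata`` is set, in which case subjects are allocated evenly
    across the eGFR bands.  Setting every dispersion to zero makes the
    draw degenerate at the medians.
    """

    age_med: float = 53.0
    age_range: tuple[float, float] = (18.0, 92.0)
    age_sd: float = 12.0
    weight_med: float = 75.0
    weight_range: tuple[float, float] = (40.0, 177.0)
    weight_sigma: float = 0.20
    height_med: float = 168.0
    height_range: tuple[float, float] = (145.0, 193.0)
    height_sigma: float = 0.04
    female_frac: float = 0.5
    black_frac: float = 0.12
    egfr_med: float = 90.0
    egfr_range: tuple[float, float] = (4.5, 338.0)
    egfr_sigma: float = 0.35
    renal_strata: bool = False
    phase: int = 3

    def __post_init__(self) -> None:
        for med, (lo, hi) in (
            (self.age_med, self.age_range),
            (self.weight_med, self.weight_range),
            (self.height_med, self.height_range),
        ):
            if not lo <= med <= hi:
                raise ValueError("median outside its truncation range")


@dataclass(frozen=True)
class StudyDesign:
    """Dosing and sampling layout of one (possibly custom) study.

    ``dose_starts`` are infusion start times (h); every administration is
    ``amount`` mg over ``infusion_duration`` h (halved below
    ``renal_cutoff`` when ``renal_adjust``).  ``plasma_times`` and
    ``urine_intervals`` are shared by all subjects.
    """

    name: str
    n_subjects: int
    covariates: CovariateSpec
    amount: float = 2000.0
    dose_starts: tuple[float, ...] = (0.0,)
    infusion_duration: float = 3.0
    tau: float = 8.0
    plasma_times: tuple[float, ...] = RICH_TIMES
    urine_intervals: tuple[tuple[float, float], ...] = ()
    lloq: float = DEFAULT_LLOQ
    renal_adjust: bool = False
    renal_cutoff: float = RENAL_GROUP_EGFR
    #: alternate full-dose arms (e.g. the 1 g / 2 g arms of study 501)
    dose_arms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        horizon = max(self.dose_starts) + 3.0 * self.tau
        times = list(self.plasma_times) + [t for iv in self.urine_intervals
                                           for t in iv]
        if any(t < 0 or t > horizon for t in times):
            raise ValueError("sampling times outside the dosing horizon")


def _q8h(n: int, tau: float = 8.0) -> tuple[float, ...]:
    return tuple(tau * i for i in range(n))


_SPECS = {
    "501": CovariateSpec(
        age_med=24.0, age_range=(18.0, 50.0), age_sd=6.0,
        weight_med=74.6, weight_range=(56.0, 94.7), weight_sigma=0.10,
        height_med=175.0, height_range=(159.0, 193.0), height_sigma=0.03,
        female_frac=0.26, egfr_med=117.0, egfr_range=(81.1, 203.0),
        egfr_sigma=0.15, phase=1,
    ),
    "504": CovariateSpec(
        age_med=56.5, age_range=(44.0, 73.0), age_sd=7.0,
        weight_med=92.8, weight_range=(58.2, 143.0), weight_sigma=0.18,
        height_med=174.0, height_range=(156.0, 190.0), height_sigma=0.03,
        female_frac=0.37, egfr_med=46.4, egfr_range=(4.8, 142.0),
        renal_strata=True, phase=1,
    ),
    "505": CovariateSpec(
        age_med=58.0, age_range=(18.0, 92.0), age_sd=15.0,
        weight_med=73.8, weight_range=(43.8, 150.0), weight_sigma=0.20,
        height_med=165.0, height_range=(148.0, 192.0), height_sigma=0.04,
        female_frac=0.67, egfr_med=86.9, egfr_range=(12.6, 241.0),
        egfr_sigma=0.35, phase=3,
    ),
    "506": CovariateSpec(
        age_med=64.0, age_range=(29.0, 88.0), age_sd=13.0,
        weight_med=74.8, weight_range=(40.0, 177.0), weight_sigma=0.22,
        height_med=168.0, height_range=(145.0, 188.0), height_sigma=0.04,
        female_frac=0.50, egfr_med=72.1, egfr_range=(4.5, 338.0),
        egfr_sigma=0.45, phase=3,
    ),
}

_DAY = 24.0


def study_design(name: str, n_subjects: int | None = None) -> StudyDesign:
    """Bundled design for study "501", "504", "505" or "506"."""
    if name == "501":
        # single rich dose on day 1, q8h from day 8 with a rich day-14 block
        ss_start = 7 * _DAY
        n_ss = 19  # q8h through day 14
        last = ss_start + 8.0 * (n_ss - 1)
        return StudyDesign(
            name="501", n_subjects=70 if n_subjects is None else n_subjects, covariates=_SPECS["501"],
            amount=2000.0, dose_arms=(1000.0, 2000.0),
            dose_starts=(0.0,) + tuple(ss_start + 8.0 * i for i in range(n_ss)),
            plasma_times=RICH_TIMES[1:] + tuple(last + t for t in RICH_TIMES[1:]),
            urine_intervals=URINE_INTERVALS
            + tuple((last + a, last + b) for a, b in URINE_INTERVALS[:2]),
        )
    if name == "504":
        return StudyDesign(
            name="504", n_subjects=40 if n_subjects is None else n_subjects, covariates=_SPECS["504"],
            amount=1000.0, dose_starts=(0.0,),
            plasma_times=RICH_TIMES[1:] + (12.0, 24.0),
            urine_intervals=URINE_INTERVALS,
        )
    if name in ("505", "506"):
        n_doses = 21 if name == "505" else 15
        last_day = 6 if name == "505" else 4
        default_n = 272 if name == "505" else 50
        return StudyDesign(
            name=name,
            n_subjects=default_n if n_subjects is None else n_subjects,
            covariates=_SPECS[name], amount=2000.0,
            dose_starts=_q8h(n_doses),
            # day 1: 0.5 h and 2.5 h after the end of the 3-h infusion;
            # day 3 and the last treatment day: 0.5 h after an infusion end
            plasma_times=(3.5, 5.5, 2 * _DAY + 3.5, last_day * _DAY + 3.5),
            renal_adjust=True,
        )
    raise ValueError(f"unknown study {name!r}")


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------

def _trunc_normal(rng, med, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, med)
    out = rng.normal(med, sd, size=2 * n + 16)
    out = out[(out >= lo) & (out <= hi)]
    while len(out) < n:
        more = rng.normal(med, sd, size=2 * n)
        out = np.concatenate([out, more[(more >= lo) & (more <= hi)]])
    return out[:n]


def _trunc_lognormal(rng, med, sigma, lo, hi, n):
    if sigma == 0:
        return np.full(n, med)
    mu = math.log(med)
    out = rng.lognormal(mu, sigma, size=2 * n + 16)
    out = out[(out >= lo) & (out <= hi)]
    while len(out) < n:
        more = rng.lognormal(mu, sigma, size=2 * n)
        out = np.concatenate([out, more[(more >= lo) & (more <= hi)]])
    return out[:n]


def _scr_for_egfr(egfr, age, female, black):
    """Creatinine giving the target MDRD eGFR (inverse of the equation)."""
    mult = np.where(female, 0.742, 1.0) * np.where(black, 1.212, 1.0)
    base = 175.0 * np.asarray(age, float) ** -0.203 * mult
    return (np.asarray(egfr, float) / base) ** (-1.0 / 1.154)


def sample_covariates(spec: CovariateSpec, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` subjects' covariates matching the study's demography.

    Weight, height and age are truncated draws around the published medians;
    creatinine is chosen so the derived MDRD eGFR tracks the study's renal
    profile (stratified across eGFR bands for a renal-impairment study).
    Returns AGE, WTKG, HTCM, SEX (0 male / 1 female), RACE (0 other /
    1 black), SCR, EGFR, BSA, BMI, PHASE, RENAL.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    age = _trunc_normal(rng, spec.age_med, spec.age_sd, *spec.age_range, n)
    wt = _trunc_lognormal(
        rng, spec.weight_med, spec.weight_sigma, *spec.weight_range, n
    )
    ht = _trunc_lognormal(
        rng, spec.height_med, spec.height_sigma, *spec.height_range, n
    )
    female = rng.random(n) < spec.female_frac
    black = rng.random(n) < spec.black_frac
    if spec.renal_strata:
        bands = np.arange(n) % len(_EGFR_BANDS)
        lo = np.array([_EGFR_BANDS[b][1] for b in bands])
        hi = np.array([_EGFR_BANDS[b][2] for b in bands])
        target = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    else:
        lo, hi = spec.egfr_range
        if spec.egfr_sigma == 0:
            target = np.full(n, spec.egfr_med)
        else:
            target = _trunc_lognormal(
                rng, spec.egfr_med, spec.egfr_sigma, lo, hi, n
            )
    scr = np.maximum(_scr_for_egfr(target, age, female, black), 0.5)
    egfr = mdrd_egfr(scr, age, female, black)
    out = pd.DataFrame({
        "AGE": age,
        "WTKG": wt,
        "HTCM": ht,
        "SEX": female.astype(int),
        "RACE": black.astype(int),
        "SCR": scr,
        "EGFR": egfr,
        "BSA": dubois_bsa(wt, ht),
        "BMI": bmi_fn(wt, ht),
        "PHASE": spec.phase,
    })
    out["RENAL"] = (out["EGFR"] <= RENAL_GROUP_EGFR).astype(int)
    return out


def apply_renal_dose_adjustment(design: StudyDesign, egfr) -> np.ndarray:
    """Per-subject dose amount: halved below the eGFR cutoff when enabled."""
    egfr = np.atleast_1d(np.asarray(egfr, dtype=float))
    amt = np.full(egfr.shape, design.amount)
    if design.renal_adjust:
        amt = np.where(egfr < design.renal_cutoff, design.amount / 2.0, amt)
    return amt


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "BLQ", "LLOQ", "MDV",
    "URINEVOL", "AGE", "WTKG", "HTCM", "SEX", "RACE", "SCR", "EGFR", "BSA",
    "PHASE",
]


def _design_skeleton(design: StudyDesign, covs: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Event rows (doses + observation placeholders) for every subject."""
    n = design.n_subjects
    amounts = apply_renal_dose_adjustment(design, covs["EGFR"].to_numpy())
    if design.dose_arms:
        arm = np.arange(n) % len(design.dose_arms)
        full = np.array(design.dose_arms)[arm]
        scale = amounts / design.amount
        amounts = full * scale
    rows = []
    for i in range(n):
        sid = i + 1
        for t0 in design.dose_starts:
            rows.append((sid, t0, amounts[i], amounts[i] / design.infusion_duration,
                         1, 1, np.nan, 0, design.lloq, 1, np.nan))
        for t in design.plasma_times:
            rows.append((sid, t, np.nan, np.nan, 0, 1, np.nan, 0,
                         design.lloq, 0, np.nan))
        for (t1, t2) in design.urine_intervals:
            vol = float(rng.lognormal(math.log(400.0), 0.385)) * (t2 - t1) / 4.0
            rows.append((sid, t2, np.nan, np.nan, 0, 2, np.nan, 0,
                         design.lloq, 0, vol))
    df = pd.DataFrame(rows, columns=_COLUMNS[:11])
    # doses sort before observations at coincident times
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable")
    df = df.reset_index(drop=True)
    for c in ("AGE", "WTKG", "HTCM", "SEX", "RACE", "SCR", "EGFR", "BSA",
              "PHASE"):
        df[c] = covs[c].to_numpy()[df["ID"].to_numpy() - 1]
    return df


def _draw_etas(model: PopulationModel, n: int,
               rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(model.omega + 1e-300 * np.eye(model.n_eta))
    return rng.standard_normal((n, model.n_eta)) @ L.T


def _individual_arrays(model: PopulationModel, data: PKData,
                       etas: np.ndarray):
    cl_r, cl_nr, vc, cld, vp = (
        np.array(a, dtype=float) for a in model.typical_arrays(data.covs)
    )
    for i, nm in enumerate(model.eta_names):
        f = np.exp(etas[:, i])
        if nm == "CL":
            cl_r, cl_nr = cl_r * f, cl_nr * f
        elif nm == "Vc":
            vc = vc * f
        elif nm == "CLd":
            cld = cld * f
        else:
            vp = vp * f
    return cl_r, cl_nr, vc, cld, vp


def simulate_study(design: StudyDesign, model: PopulationModel,
                   seed: int | np.random.Generator) -> pd.DataFrame:
    """Simulate a complete study: covariates, etas, observations, BLQ flags.

    Deterministic given the seed.  Plasma values below the quantitation
    limit are flagged ``BLQ = 1`` with ``DV`` blanked (the row carries the
    limit in ``LLOQ``).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    covs = sample_covariates(design.covariates, design.n_subjects, rng)
    df = _design_skeleton(design, covs, rng)
    data = PKData(df)
    etas = _draw_etas(model, data.n_sub, rng)
    plasma, urine = data.predict(*_individual_arrays(model, data, etas))

    s2p, s2a = model.sigma["plasma"]
    eps = rng.standard_normal(data.n_obs)
    dv_plasma = plasma * (1.0 + math.sqrt(s2p) * eps) \
        + math.sqrt(s2a) * rng.standard_normal(data.n_obs)
    if data.n_uobs:
        s2pu, s2au = model.sigma.get("urine", (0.0, 0.0))
        dv_urine = urine * (1.0 + math.sqrt(s2pu)
                            * rng.standard_normal(data.n_uobs)) \
            + math.sqrt(s2au) * rng.standard_normal(data.n_uobs)
    obs_mask = (df["EVID"] == 0) & (df["CMT"] == 1)
    uobs_mask = (df["EVID"] == 0) & (df["CMT"] == 2)
    df.loc[obs_mask, "DV"] = dv_plasma
    if data.n_uobs:
        df.loc[uobs_mask, "DV"] = dv_urine
    blq = df["DV"].to_numpy() < df["LLOQ"].to_numpy()
    blq &= obs_mask.to_numpy()
    df.loc[blq, "BLQ"] = 1
    df.loc[blq, "DV"] = np.nan
    return df


def resimulate_plasma(data: PKData, model: PopulationModel,
                      rng: np.random.Generator):
    """One replicate of the plasma observations on an existing design.

    Redraws etas and residual errors while keeping doses, times and
    covariates fixed; used by the visual predictive check.  Returns
    ``(dv, blq_mask)`` aligned with ``data``'s plasma observation rows.
    """
    etas = _draw_etas(model, data.n_sub, rng)
    plasma, _ = data.predict(*_individual_arrays(model, data, etas))
    s2p, s2a = model.sigma["plasma"]
    dv = plasma * (1.0 + math.sqrt(s2p) * rng.standard_normal(data.n_obs)) \
        + math.sqrt(s2a) * rng.standard_normal(data.n_obs)
    blq = dv < data.o_lloq
    return dv, blq


def inject_outliers(table: pd.DataFrame, rate: float, magnitude: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Corrupt a fraction of quantified observations by 10^±magnitude.

    Ground truth is recorded in an ``OUTLIER`` column (0/1) so screening
    experiments can score recovery.  ``rate`` must be below 5%.
    """
    if not 0.0 <= rate < 0.05:
        raise ValueError("rate must be in [0, 0.05)")
    out = table.copy()
    out["OUTLIER"] = 0
    eligible = np.nonzero(
        ((out["EVID"] == 0) & (out["BLQ"] != 1)
         & (out["DV"] > 0)).to_numpy()
    )[0]
    hit = eligible[rng.random(len(eligible)) < rate]
    sign = np.where(rng.random(len(hit)) < 0.5, -1.0, 1.0)
    out.iloc[hit, out.columns.get_loc("DV")] *= 10.0 ** (sign * magnitude)
    out.iloc[hit, out.columns.get_loc("OUTLIER")] = 1
    return out
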