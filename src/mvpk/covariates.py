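"""Demographic derivations and covariate-to-parameter equations.

Renal function is the dominant covariate for both meropenem and vaborbactam:
renal clearance rises with eGFR following a sigmoidal Emax (Hill) curve,

    CL_R(eGFR) = CLR_max · eGFR^h / (eGFR50^h + eGFR^h),

with a nonrenal intercept CL_NR.  Linear and power alternatives are provided
for base-model comparison.  eGFR comes from the 4-variable MDRD creatinine
equation (creatinine floored at 0.5 mg/dl), body surface area from DuBois &
DuBois, BMI as weight/height².

Typical-value equations:

* meropenem — allometric weight scaling on all parameters (0.75 on
  clearances, 1.0 on volumes), a power age effect on CL, and a proportional
  reduction of CL_NR for subjects with eGFR <= 30 ml/min/1.73 m²;
* vaborbactam — a power height effect on CL, a power BSA effect on Vc, and
  proportional phase-1/phase-3 shifts on CL, Vc and Vp (phase 3 is the
  reference population).

Reference covariate values are the pooled study medians: weight 75 kg,
age 53 y, height 168 cm, BSA 1.84 m².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .pkcore import StructuralParams

__all__ = [
    "CovariateRecord",
    "RenalFunctionModel",
    "mdrd_egfr",
    "dubois_bsa",
    "bmi",
    "renal_clearance",
    "typical_params_meropenem",
    "typical_params_vaborbactam",
    "fraction_renal",
    "REFERENCE",
]

#: reference covariate values (pooled medians) used to normalize covariate effects
REFERENCE: dict[str, float] = {
    "weight": 75.0,   # kg
    "age": 53.0,      # years
    "height": 168.0,  # cm
    "bsa": 1.84,      # m^2
}

#: eGFR threshold (ml/min/1.73 m^2) defining the impaired renal group
RENAL_GROUP_EGFR = 30.0

_SCR_FLOOR = 0.5  # mg/dl, lower cap applied before the MDRD equation


def _is_female(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "UO":
        return np.char.upper(s.astype(str).ravel()).reshape(s.shape) != "M"
    return s.astype(bool)


def _is_black(race) -> np.ndarray:
    r = np.asarray(race)
    if r.dtype.kind in "UO":
        return np.char.lower(r.astype(str).ravel()).reshape(r.shape) == "black"
    return r.astype(bool)


def mdrd_egfr(scr, age, sex, race, coefficient: float = 175.0):
    """MDRD estimated glomerular filtration rate (ml/min/1.73 m²).

    4-variable equation: ``coefficient × scr^-1.154 × age^-0.203``, times
    0.742 for females and 1.212 for black subjects.  Serum creatinine is
    floored at 0.5 mg/dl before evaluation.  ``coefficient`` defaults to the
    IDMS-traceable 175; the older 186 variant is selectable.

    ``sex`` accepts "M"/"F" (or truthy = female); ``race`` accepts
    "black"/"other" (or truthy = black).  All inputs broadcast.
    """
    scr = np.maximum(np.asarray(scr, dtype=float), _SCR_FLOOR)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age < 18):
        raise ValueError("scr must be > 0 and age >= 18")
    out = coefficient * scr ** -1.154 * age ** -0.203
    out = out * np.where(_is_female(sex), 0.742, 1.0)
    out = out * np.where(_is_black(race), 1.212, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def dubois_bsa(weight, height):
    """DuBois & DuBois body surface area (m²): 0.007184·W^0.425·H^0.725."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be > 0")
    out = 0.007184 * weight ** 0.425 * height ** 0.725
    return float(out) if out.ndim == 0 else out


def bmi(weight, height):
    """Body mass index (kg/m²); height in cm."""
    weight = np.asarray(weight, dtype=float)
    h_m = np.asarray(height, dtype=float) / 100.0
    out = weight / (h_m * h_m)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CovariateRecord:
    """One subject's covariates; derived fields are filled in when omitted.

    ``egfr`` defaults to the MDRD value from ``scr``/``age``/``sex``/``race``;
    ``bsa`` to DuBois; ``bmi`` to weight/height².  ``phase`` is 1 (noninfected
    rich-sampling studies) or 3 (infected sparse-sampling studies).
    """

    age: float
    weight: float
    height: float
    sex: str = "M"
    race: str = "other"
    scr: float = 1.0
    phase: int = 3
    egfr: float | None = None
    bsa: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("adult studies: age must be >= 18")
        if self.weight <= 0 or self.height <= 0 or self.scr <= 0:
            raise ValueError("weight, height and scr must be > 0")
        if self.phase not in (1, 3):
            raise ValueError("phase must be 1 or 3")
        if self.egfr is None:
            object.__setattr__(
                self, "egfr", mdrd_egfr(self.scr, self.age, self.sex, self.race)
            )
        if self.bsa is None:
            object.__setattr__(self, "bsa", dubois_bsa(self.weight, self.height))
        if self.bmi is None:
            object.__setattr__(self, "bmi", bmi(self.weight, self.height))

    @property
    def renal_group(self) -> bool:
        """True for the impaired group (eGFR <= 30 ml/min/1.73 m²)."""
        return bool(self.egfr <= RENAL_GROUP_EGFR)


@dataclass(frozen=True)
class RenalFunctionModel:
    """Functional relationship between eGFR and renal clearance.

    ``hill``: CL_R = clr_max·eGFR^h/(egfr50^h + eGFR^h);
    ``linear``: CL_R = slope·eGFR; ``power``: CL_R = a·eGFR^b.
    The linear and power forms exist for base-model comparison runs.
    """

    form: Literal["hill", "linear", "power"] = "hill"
    clr_max: float = 0.0
    egfr50: float = 0.0
    hill: float = 1.0
    slope: float = 0.0
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.form == "hill" and (
            self.clr_max <= 0 or self.egfr50 <= 0 or self.hill <= 0
        ):
            raise ValueError("hill form requires clr_max, egfr50, hill > 0")


def renal_clearance(model: RenalFunctionModel, egfr):
    """Renal clearance (L/h) at the given eGFR; nondecreasing in eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr < 0):
        raise ValueError("egfr must be >= 0")
    if model.form == "hill":
        with np.errstate(over="ignore", invalid="ignore"):
            eh = egfr ** np.float64(model.hill)
            e50h = np.float64(model.egfr50) ** np.float64(model.hill)
            out = np.where(
                np.isfinite(eh) & np.isfinite(e50h),
                model.clr_max * eh / (e50h + eh),
                # saturation limits when either power overflows
                np.where(egfr > model.egfr50, model.clr_max, 0.0),
            )
    elif model.form == "linear":
        out = model.slope * egfr
    elif model.form == "power":
        out = model.a * egfr ** model.b
    else:  # pragma: no cover - dataclass restricts the literal
        raise ValueError(f"unknown form {model.form!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# typical-value equations (vectorized cores + scalar wrappers)
# ---------------------------------------------------------------------------

def typical_meropenem_arrays(theta: Mapping[str, float], age, weight, egfr,
                             renal_group=None):
    """Vectorized meropenem typical values.

    Returns ``(cl_r, cl_nr, vc, cld, vp)`` arrays.  The age and allometric
    weight factors multiply total clearance, i.e. both the renal and nonrenal
    parts jointly, so the renal fraction is size/age-invariant; the renal
    group shift applies to CL_NR only.
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if renal_group is None:
        renal_group = egfr <= RENAL_GROUP_EGFR
    renal_group = np.asarray(renal_group, dtype=bool)
    rf = RenalFunctionModel(
        form="hill", clr_max=theta["clr_max"], egfr50=theta["egfr50"],
        hill=theta["hill"],
    )
    wt_n = weight / REFERENCE["weight"]
    cl_scale = wt_n ** theta["wt_cl"] * (age / REFERENCE["age"]) ** theta["age_cl"]
    cl_nr = theta["cl_nr"] * (1.0 + theta["renal_cl_nr"] * renal_group) * cl_scale
    cl_r = renal_clearance(rf, egfr) * cl_scale
    vc = theta["vc"] * wt_n ** theta["wt_vc"] * np.ones_like(cl_scale)
    cld = theta["cld"] * wt_n ** theta["wt_cld"] * np.ones_like(cl_scale)
    vp = theta["vp"] * wt_n ** theta["wt_vp"] * np.ones_like(cl_scale)
    return cl_r, cl_nr, vc, cld, vp


def typical_vaborbactam_arrays(theta: Mapping[str, float], height, bsa, egfr,
                               phase):
    """Vectorized vaborbactam typical values.

    Returns ``(cl_r, cl_nr, vc, cld, vp)`` arrays.  Height and phase factors
    multiply total clearance; BSA and phase act on Vc; phase acts on Vp.
    Phase 3 is the reference (shifts apply to phase-1 subjects).
    """
    height = np.asarray(height, dtype=float)
    bsa = np.asarray(bsa, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    phase1 = np.asarray(phase) == 1
    rf = RenalFunctionModel(
        form="hill", clr_max=theta["clr_max"], egfr50=theta["egfr50"],
        hill=theta["hill"],
    )
    cl_scale = (height / REFERENCE["height"]) ** theta["ht_cl"] * (
        1.0 + theta["phase_cl"] * phase1
    )
    cl_nr = theta["cl_nr"] * cl_scale
    cl_r = renal_clearance(rf, egfr) * cl_scale
    vc = (
        theta["vc"]
        * (bsa / REFERENCE["bsa"]) ** theta["bsa_vc"]
        * (1.0 + theta["phase_vc"] * phase1)
    )
    cld = theta["cld"] * np.ones_like(cl_scale)
    vp = theta["vp"] * (1.0 + theta["phase_vp"] * phase1) * np.ones_like(cl_scale)
    return cl_r, cl_nr, vc, cld, vp


def _as_params(parts) -> StructuralParams:
    cl_r, cl_nr, vc, cld, vp = (float(np.asarray(x)) for x in parts)
    return StructuralParams(CL_R=cl_r, CL_NR=cl_nr, Vc=vc, CLd=cld, Vp=vp)


def typical_params_meropenem(
    cov: CovariateRecord, theta: Mapping[str, float]
) -> StructuralParams:
    """Typical meropenem parameters for one subject's covariates."""
    return _as_params(
        typical_meropenem_arrays(
            theta, cov.age, cov.weight, cov.egfr, cov.renal_group
        )
    )


def typical_params_vaborbactam(
    cov: CovariateRecord, theta: Mapping[str, float]
) -> StructuralParams:
    """Typical vaborbactam parameters for one subject's covariates."""
    return _as_params(
        typical_vaborbactam_arrays(theta, cov.height, cov.bsa, cov.egfr, cov.phase)
    )


def fraction_renal(p: StructuralParams) -> float:
    """Fraction of total clearance that is renal, CL_R/(CL_R + CL_NR)."""
    return p.CL_R / p.CL
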