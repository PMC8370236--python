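"""Population model assembly: fixed effects, IIV, residual error.

A :class:`PopulationModel` bundles the typical-value (covariate) equations of
one drug with log-normal interindividual variability (IIV) on {CL, Vc, CLd,
Vp} and combined additive-plus-proportional residual error for plasma and
urine.  Individual parameters are realized as ``P_i = TV(cov) · exp(eta_P)``;
the eta on CL multiplies renal and nonrenal clearance jointly.

Two bundled definitions transcribe the final meropenem and vaborbactam
models (``load_model("meropenem"/"vaborbactam")``).  A third kind,
``drug="plain"``, has constant typical values with no built-in covariate
equations and is the substrate for covariate-selection and censoring
experiments, where effects are planted explicitly.

Residual-error magnitudes in model files are variances by convention
(``residual_scale: variance``); a ``sd`` switch reinterprets them.
IIV magnitudes are exchanged with the conventional %CV of a log-normal via
``omega² = ln(1 + (cv/100)²)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from . import covariates as cov_mod
from .covariates import CovariateRecord
from .pkcore import StructuralParams

__all__ = [
    "ETA_ORDER",
    "PopulationModel",
    "IndividualParams",
    "CovariateEffect",
    "load_model",
    "realize_individual",
    "residual_observe",
    "cv_percent_to_omega",
    "omega_to_cv_percent",
]

#: canonical order of the random-effect dimensions
ETA_ORDER: tuple[str, ...] = ("CL", "Vc", "CLd", "Vp")


def cv_percent_to_omega(cv) -> float | np.ndarray:
    """Log-normal variance omega² from a coefficient of variation in percent."""
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be >= 0")
    out = np.log1p((cv / 100.0) ** 2)
    return float(out) if out.ndim == 0 else out


def omega_to_cv_percent(var) -> float | np.ndarray:
    """Inverse of :func:`cv_percent_to_omega`; exact round-trip."""
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be >= 0")
    out = 100.0 * np.sqrt(np.expm1(var))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CovariateEffect:
    """One extra parameter-covariate relationship applied multiplicatively.

    ``power``: TV ×= (cov/ref)^theta;  ``shift``: TV ×= (1 + theta·I[cov]).
    ``parameter`` is one of ETA_ORDER (an effect on CL scales CL_R and CL_NR
    jointly).  ``theta_name`` keys the coefficient in ``model.theta``.
    """

    parameter: str
    covariate: str
    form: str  # "power" | "shift"
    theta_name: str
    ref: float = 1.0

    def __post_init__(self) -> None:
        if self.parameter not in ETA_ORDER:
            raise ValueError(f"parameter must be one of {ETA_ORDER}")
        if self.form not in ("power", "shift"):
            raise ValueError("form must be 'power' or 'shift'")
        if self.form == "power" and self.ref <= 0:
            raise ValueError("power form needs a positive reference value")


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, IIV covariance and residual error for one drug.

    Attributes
    ----------
    drug : str
        "meropenem", "vaborbactam" or "plain".
    theta : dict
        Named fixed effects (typical values and covariate coefficients).
    fixed : frozenset
        Theta names never updated by estimation (e.g. allometric exponents).
    omega : ndarray
        IIV covariance on the log scale over ``eta_names`` (symmetric PSD).
    sigma : dict
        ``{"plasma": (prop_var, add_var), "urine": (prop_var, add_var)}``.
    eta_names : tuple
        Subset of ETA_ORDER carrying random effects.
    effects : tuple of CovariateEffect
        Extra relations on top of the drug's built-in equations.
    """

    drug: str
    theta: Mapping[str, float]
    omega: np.ndarray
    sigma: Mapping[str, tuple[float, float]]
    fixed: frozenset = frozenset()
    eta_names: tuple[str, ...] = ETA_ORDER
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        om = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if om.shape[0] != om.shape[1] or om.shape[0] != len(self.eta_names):
            raise ValueError("omega must be square and match eta_names")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(om) < -1e-10):
            raise ValueError("omega must be positive semidefinite")
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "fixed", frozenset(self.fixed))
        for name in self.fixed:
            if name not in self.theta:
                raise ValueError(f"fixed name {name!r} not in theta")

    # -- typical values ----------------------------------------------------
    def typical_arrays(self, covs: Mapping[str, np.ndarray]):
        """Vectorized typical values ``(cl_r, cl_nr, vc, cld, vp)``.

        ``covs`` maps lower-case covariate names (age, weight, height, bsa,
        egfr, phase, ...) to aligned arrays.
        """
        th = self.theta
        if self.drug == "meropenem":
            parts = cov_mod.typical_meropenem_arrays(
                th, covs["age"], covs["weight"], covs["egfr"],
                covs.get("renal_group"),
            )
        elif self.drug == "vaborbactam":
            parts = cov_mod.typical_vaborbactam_arrays(
                th, covs["height"], covs["bsa"], covs["egfr"], covs["phase"]
            )
        elif self.drug == "plain":
            n = np.broadcast(*[np.asarray(v) for v in covs.values()]).shape \
                if covs else ()
            one = np.ones(n if n else ())
            fr = th.get("fraction_renal", 0.0)
            cl = th["cl"] * one
            parts = (cl * fr, cl * (1.0 - fr), th["vc"] * one,
                     th["cld"] * one, th["vp"] * one)
        else:
            raise ValueError(f"unknown drug kind {self.drug!r}")
        cl_r, cl_nr, vc, cld, vp = (np.asarray(x, dtype=float) for x in parts)
        for eff in self.effects:
            x = np.asarray(covs[eff.covariate], dtype=float)
            coef = self.theta[eff.theta_name]
            if eff.form == "power":
                fac = (x / eff.ref) ** coef
            else:
                fac = 1.0 + coef * x
            if eff.parameter == "CL":
                cl_r, cl_nr = cl_r * fac, cl_nr * fac
            elif eff.parameter == "Vc":
                vc = vc * fac
            elif eff.parameter == "CLd":
                cld = cld * fac
            else:
                vp = vp * fac
        return cl_r, cl_nr, vc, cld, vp

    def typical(self, cov: CovariateRecord) -> StructuralParams:
        """Typical-value parameters for one subject."""
        parts = self.typical_arrays(_record_to_covs(cov))
        cl_r, cl_nr, vc, cld, vp = (float(np.asarray(x)) for x in parts)
        return StructuralParams(CL_R=cl_r, CL_NR=cl_nr, Vc=vc, CLd=cld, Vp=vp)

    # -- IIV ----------------------------------------------------------------
    @property
    def n_eta(self) -> int:
        return len(self.eta_names)

    def omega_cv(self) -> dict[str, float]:
        """Diagonal IIV expressed as %CV per eta dimension."""
        return {
            name: omega_to_cv_percent(self.omega[i, i])
            for i, name in enumerate(self.eta_names)
        }

    def update(self, **changes) -> "PopulationModel":
        """Return a copy with replaced fields (dataclasses.replace wrapper)."""
        return replace(self, **changes)

    def with_theta(self, **theta_updates) -> "PopulationModel":
        th = dict(self.theta)
        th.update(theta_updates)
        return replace(self, theta=th)


@dataclass(frozen=True)
class IndividualParams:
    """Per-subject random effects and the realized structural parameters."""

    eta: np.ndarray
    params: StructuralParams


def _record_to_covs(cov: CovariateRecord) -> dict:
    return {
        "age": cov.age,
        "weight": cov.weight,
        "height": cov.height,
        "bsa": cov.bsa,
        "bmi": cov.bmi,
        "egfr": cov.egfr,
        "phase": cov.phase,
        "renal_group": cov.renal_group,
        "sex": 1.0 if cov.sex.upper() != "M" else 0.0,
        "race": 1.0 if cov.race.lower() == "black" else 0.0,
        "scr": cov.scr,
    }


def eta_factors(model: PopulationModel, eta: np.ndarray) -> dict[str, np.ndarray]:
    """Map an eta vector/matrix to multiplicative factors per parameter."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape[-1] != model.n_eta:
        raise ValueError(
            f"eta has {eta.shape[-1]} dims, model expects {model.n_eta}"
        )
    fac = {name: np.ones(eta.shape[:-1]) for name in ETA_ORDER}
    for i, name in enumerate(model.eta_names):
        fac[name] = np.exp(eta[..., i])
    return fac


def realize_individual(
    model: PopulationModel, cov: CovariateRecord, eta: np.ndarray
) -> IndividualParams:
    """Individual parameters ``P_i = TV(cov) × exp(eta_P)`` (log-normal IIV)."""
    tv = model.typical(cov)
    fac = eta_factors(model, np.asarray(eta, dtype=float))
    p = StructuralParams(
        CL_R=tv.CL_R * float(fac["CL"]),
        CL_NR=tv.CL_NR * float(fac["CL"]),
        Vc=tv.Vc * float(fac["Vc"]),
        CLd=tv.CLd * float(fac["CLd"]),
        Vp=tv.Vp * float(fac["Vp"]),
    )
    return IndividualParams(eta=np.asarray(eta, dtype=float), params=p)


def residual_observe(pred, sigma_pair, rng: np.random.Generator):
    """Observe with combined error: ``y = pred·(1+eps_p) + eps_a``.

    ``sigma_pair`` holds (proportional, additive) variances, so
    Var(y|pred) = pred²·sigma_p² + sigma_a².
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("pred must be >= 0")
    s2p, s2a = sigma_pair
    eps_p = rng.normal(0.0, np.sqrt(s2p), size=pred.shape)
    eps_a = rng.normal(0.0, np.sqrt(s2a), size=pred.shape)
    out = pred * (1.0 + eps_p) + eps_a
    return float(out) if out.ndim == 0 else out


def load_model(name: str, residual_scale: str | None = None,
               **theta_overrides) -> PopulationModel:
    """Load a bundled model definition ("meropenem" or "vaborbactam").

    ``theta_overrides`` replace individual fixed effects (e.g. the
    alternative vaborbactam phase shifts ``phase_cl=0.264, phase_vp=1.78``).
    ``residual_scale="sd"`` reinterprets the bundled residual magnitudes as
    standard deviations rather than variances.
    """
    ref = importlib.resources.files("mvpk.models").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"no bundled model named {name!r}") from None
    return model_from_dict(yaml.safe_load(text), residual_scale=residual_scale,
                           **theta_overrides)


def model_from_dict(cfg: Mapping, residual_scale: str | None = None,
                    **theta_overrides) -> PopulationModel:
    """Build a :class:`PopulationModel` from a parsed definition mapping."""
    theta = dict(cfg["theta"])
    theta.update(theta_overrides)
    scale = residual_scale or cfg.get("residual_scale", "variance")
    sigma = {}
    for matrix, pair in cfg["sigma"].items():
        prop, add = float(pair[0]), float(pair[1])
        if scale == "sd":
            prop, add = prop * prop, add * add
        elif scale != "variance":
            raise ValueError("residual_scale must be 'variance' or 'sd'")
        sigma[matrix] = (prop, add)
    eta_names = tuple(cfg.get("eta_names", ETA_ORDER))
    if "omega_cv" in cfg:
        omega = np.diag(cv_percent_to_omega(np.asarray(cfg["omega_cv"], float)))
    else:
        omega = np.asarray(cfg["omega"], dtype=float)
    effects = tuple(
        CovariateEffect(**eff) for eff in cfg.get("effects", ())
    )
    return PopulationModel(
        drug=cfg["drug"],
        theta=theta,
        omega=omega,
        sigma=sigma,
        fixed=frozenset(cfg.get("fixed", ())),
        eta_names=eta_names,
        effects=effects,
    )


def model_to_dict(model: PopulationModel) -> dict:
    """Serializable definition mapping (inverse of :func:`model_from_dict`)."""
    return {
        "drug": model.drug,
        "theta": dict(model.theta),
        "fixed": sorted(model.fixed),
        "eta_names": list(model.eta_names),
        "omega": model.omega.tolist(),
        "sigma": {k: list(v) for k, v in model.sigma.items()},
        "residual_scale": "variance",
        "effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "form": e.form,
                "theta_name": e.theta_name,
                "ref": e.ref,
            }
            for e in model.effects
        ],
    }
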