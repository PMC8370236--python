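"""Closed-form two-compartment disposition with zero-order (infusion) input.

The disposition model is the standard mammillary two-compartment system with
first-order elimination from the central compartment and a constant-rate
(zero-order) infusion.  All production computations — concentration-time
profiles, AUC, urinary excretion, Cmax — use the analytic biexponential
solution and multiple-dose superposition; numerical ODE integration exists
only as an independent oracle in the test suite.

Parameterization is by clearances and volumes: total clearance ``CL``
(split into renal ``CL_R`` and nonrenal ``CL_NR``), central volume ``Vc``,
distributional clearance ``CLd`` and peripheral volume ``Vp``.  Units are
fixed throughout the package: mg, L, h, mg/L (equivalently ug/ml).

The one-compartment model is available as the ``CLd = 0`` limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "MacroConstants",
    "micro_rates",
    "macro_constants",
    "concentration",
    "auc",
    "urine_amount",
    "cmax_first_interval",
]

#: minimum relative separation enforced between the two disposition
#: eigenvalues; below this the pair is symmetrically widened, which is a
#: second-order-accurate evaluation of the repeated-root limit.
_MIN_EIG_SEP = 1e-7


class InvalidParameterError(ValueError):
    """Raised when structural parameters violate their constraints."""


@dataclass(frozen=True)
class StructuralParams:
    """Individual two-compartment parameters (clearance/volume form).

    Attributes
    ----------
    CL_R : float
        Renal clearance (L/h), >= 0.
    CL_NR : float
        Nonrenal clearance (L/h), >= 0.  ``CL_R + CL_NR`` must be > 0.
    Vc : float
        Central volume of distribution (L), > 0.
    CLd : float
        Distributional (inter-compartmental) clearance (L/h), >= 0;
        ``CLd = 0`` collapses to a one-compartment model.
    Vp : float
        Peripheral volume of distribution (L), > 0.
    """

    CL_R: float
    CL_NR: float
    Vc: float
    CLd: float
    Vp: float

    def __post_init__(self) -> None:
        if self.CL_R < 0 or self.CL_NR < 0:
            raise InvalidParameterError("clearance components must be >= 0")
        if self.CL_R + self.CL_NR <= 0:
            raise InvalidParameterError("total clearance must be > 0")
        if self.Vc <= 0 or self.Vp <= 0:
            raise InvalidParameterError("volumes must be > 0")
        if self.CLd < 0:
            raise InvalidParameterError("distributional clearance must be >= 0")

    @property
    def CL(self) -> float:
        """Total clearance, renal plus nonrenal (L/h)."""
        return self.CL_R + self.CL_NR

    @classmethod
    def from_total(
        cls, CL: float, Vc: float, CLd: float, Vp: float, fraction_renal: float = 0.0
    ) -> "StructuralParams":
        """Build from total clearance and a renal fraction in [0, 1]."""
        if not 0.0 <= fraction_renal <= 1.0:
            raise InvalidParameterError("fraction_renal must be in [0, 1]")
        return cls(
            CL_R=CL * fraction_renal,
            CL_NR=CL * (1.0 - fraction_renal),
            Vc=Vc,
            CLd=CLd,
            Vp=Vp,
        )


@dataclass(frozen=True)
class DoseEvent:
    """A constant-rate infusion: ``amount`` mg over ``duration`` h from ``start_time``."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidParameterError("dose amount must be > 0")
        if self.duration <= 0:
            raise InvalidParameterError("infusion duration must be > 0")

    @property
    def rate(self) -> float:
        """Zero-order input rate (mg/h)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class MacroConstants:
    """Disposition eigenvalues and the corresponding half-lives.

    ``lambda1 >= lambda2 > 0`` are the fast (alpha) and slow (beta)
    disposition rate constants; ``t_half = ln 2 / lambda``.
    """

    lambda1: float
    lambda2: float

    @property
    def t_half_alpha(self) -> float:
        return math.log(2.0) / self.lambda1

    @property
    def t_half_beta(self) -> float:
        return math.log(2.0) / self.lambda2


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def micro_rates(p: StructuralParams) -> tuple[float, float, float]:
    """Micro rate constants ``(k10, k12, k21)`` in 1/h.

    k10 = CL/Vc, k12 = CLd/Vc, k21 = CLd/Vp.
    """
    return p.CL / p.Vc, p.CLd / p.Vc, p.CLd / p.Vp


def macro_constants(p: StructuralParams) -> MacroConstants:
    """Disposition eigenvalues, the roots of λ² − (k10+k12+k21)λ + k10·k21.

    For ``CLd = 0`` the slow root is k10 and the system is mono-exponential;
    ``lambda2`` is then reported equal to k10 and ``lambda1`` is k10 as well
    only in the true one-compartment sense (the zero root carries no weight).
    """
    k10, k12, k21 = micro_rates(p)
    if p.CLd == 0.0:
        return MacroConstants(lambda1=k10, lambda2=k10)
    lam1, lam2 = _eigenvalues(np.asarray(k10), np.asarray(k12), np.asarray(k21))
    return MacroConstants(lambda1=float(lam1), lambda2=float(lam2))


def concentration(
    p: StructuralParams, doses: Sequence[DoseEvent], t: float | np.ndarray
) -> float | np.ndarray:
    """Plasma concentration (mg/L) at time(s) ``t`` under superposition."""
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(t_arr).shape or (1,))
    cl, vc = p.CL, p.Vc
    k10, k12, k21 = micro_rates(p)
    lam1, lam2 = _eigenvalues(np.asarray(k10), np.asarray(k12), np.asarray(k21))
    for d in doses:
        dt = t_arr - d.start_time
        out = out + conc_contrib(dt, d.rate, d.duration, vc, k21, lam1, lam2)
    if np.ndim(t) == 0:
        return float(np.squeeze(out))
    return out


def auc(
    p: StructuralParams, doses: Sequence[DoseEvent], t1: float, t2: float
) -> float:
    """Analytic area under the plasma curve over [t1, t2] (mg·h/L).

    ``t2 = inf`` is allowed; AUC(0, inf) of a single dose equals amount/CL.
    """
    if not t2 > t1:
        raise ValueError("t2 must exceed t1")
    k10, k12, k21 = micro_rates(p)
    lam1, lam2 = _eigenvalues(np.asarray(k10), np.asarray(k12), np.asarray(k21))
    total = 0.0
    for d in doses:
        if np.isinf(t2):
            a2 = d.amount / p.CL
        else:
            a2 = float(cum_auc_contrib(np.asarray(t2 - d.start_time), d.rate,
                                       d.duration, p.Vc, k21, lam1, lam2))
        a1 = float(cum_auc_contrib(np.asarray(t1 - d.start_time), d.rate,
                                   d.duration, p.Vc, k21, lam1, lam2))
        total += a2 - a1
    return total


def urine_amount(
    p: StructuralParams, doses: Sequence[DoseEvent], t1: float, t2: float
) -> float:
    """Amount (mg) excreted in urine over [t1, t2]: CL_R × AUC(t1, t2)."""
    return p.CL_R * auc(p, doses, t1, t2)


def cmax_first_interval(
    p: StructuralParams, doses: Sequence[DoseEvent], tau: float
) -> float:
    """Peak plasma concentration over the first dosing interval [0, tau].

    A 0.05 h grid (always including infusion start/end times) brackets the
    maximum, which is then refined by bounded scalar optimization.
    """
    if not doses:
        raise ValueError("at least one dose required")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    grid = np.arange(0.0, tau + 1e-12, 0.05)
    extra = []
    for d in doses:
        for knot in (d.start_time, d.start_time + d.duration):
            if 0.0 <= knot <= tau:
                extra.append(knot)
    grid = np.unique(np.concatenate([grid, [tau], np.asarray(extra)]))
    vals = concentration(p, doses, grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(vals[i])
    res = minimize_scalar(
        lambda t: -concentration(p, doses, float(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(max(vals[i], -res.fun))


# ---------------------------------------------------------------------------
# vectorized kernels (shared with the estimation engine)
# ---------------------------------------------------------------------------

def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, series-protected near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = -np.expm1(-xs) / xs
    series = 1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0
    return np.where(small, series, out)


def _phi2(x: np.ndarray) -> np.ndarray:
    """(x - 1 + exp(-x)) / x², series-protected near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)
    out = (xs - 1.0 + np.exp(-xs)) / (xs * xs)
    series = 0.5 - x / 6.0 + x * x / 24.0 - x * x * x / 120.0
    return np.where(small, series, out)


def _pexp(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """∫0^t exp(-λ s) ds = (1 - exp(-λ t))/λ = t·φ1(λt)."""
    return t * _phi1(lam * t)


def _ipexp(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """∫0^t (1 - exp(-λ s))/λ ds = t²·φ2(λt)."""
    return t * t * _phi2(lam * t)


def _eigenvalues(k10: np.ndarray, k12: np.ndarray, k21: np.ndarray):
    """Fast/slow disposition eigenvalues with a minimum relative separation.

    Near-repeated roots are symmetrically widened to a relative gap of
    ``_MIN_EIG_SEP`` about their mean, which evaluates the limiting
    (repeated-root) solution with O(sep²) error.
    """
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    half_gap = 0.5 * np.sqrt(np.maximum(disc, 0.0))
    mean = 0.5 * s
    half_gap = np.maximum(half_gap, 0.5 * _MIN_EIG_SEP * mean)
    return mean + half_gap, mean - half_gap


def conc_contrib(
    dt: np.ndarray,
    rate: np.ndarray,
    dur: np.ndarray,
    vc: np.ndarray,
    k21: np.ndarray,
    lam1: np.ndarray,
    lam2: np.ndarray,
) -> np.ndarray:
    """Central concentration due to one infusion, ``dt`` h after its start.

    Zero for ``dt <= 0``.  Arrays broadcast; all inputs are per-(observation,
    dose) pair in the vectorized estimation path.
    """
    dt = np.asarray(dt, dtype=float)
    active = dt > 0.0
    te = np.clip(dt, 0.0, dur)          # time infused
    post = np.maximum(dt - dur, 0.0)    # time since end of infusion
    delta = lam1 - lam2
    c1 = (lam1 - k21) / delta
    c2 = (k21 - lam2) / delta
    g1 = _pexp(lam1, te) * np.exp(-lam1 * post)
    g2 = _pexp(lam2, te) * np.exp(-lam2 * post)
    out = rate / vc * (c1 * g1 + c2 * g2)
    return np.where(active, out, 0.0)


def cum_auc_contrib(
    dt: np.ndarray,
    rate: np.ndarray,
    dur: np.ndarray,
    vc: np.ndarray,
    k21: np.ndarray,
    lam1: np.ndarray,
    lam2: np.ndarray,
) -> np.ndarray:
    """Cumulative AUC of one infusion's contribution from its start to ``dt``."""
    dt = np.asarray(dt, dtype=float)
    active = dt > 0.0
    te = np.clip(dt, 0.0, dur)
    post = np.maximum(dt - dur, 0.0)
    delta = lam1 - lam2
    c1 = (lam1 - k21) / delta
    c2 = (k21 - lam2) / delta
    a1 = _ipexp(lam1, te) + _pexp(lam1, dur) * _pexp(lam1, post)
    a2 = _ipexp(lam2, te) + _pexp(lam2, dur) * _pexp(lam2, post)
    out = rate / vc * (c1 * a1 + c2 * a2)
    return np.where(active, out, 0.0)
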