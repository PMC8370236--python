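"""Mixed-effects estimation: Laplace marginal likelihood with M3 censoring.

The population model is a nonlinear mixed-effects model with log-normal
random effects eta ~ N(0, Omega) on the structural parameters and combined
additive-plus-proportional residual error.  The marginal likelihood of each
subject,

    L_i = ∫ p(y_i | eta) p(eta) d eta,

is approximated by the Laplace method at the posterior mode of eta, with the
residual variance evaluated at the eta-dependent prediction (the interaction
retained, as in FOCE-I).  The objective function value (OFV, "MVOF" at the
optimum) is -2 Σ_i log L_i including all 2π constants, so only OFV
differences are comparable across implementations.

Observations below the limit of quantitation enter the likelihood by the
Beal M3 method: a BLQ record contributes the left-censored probability
Φ((LLOQ - pred)/sd) instead of a density, so a BLQ value is treated as a
normally distributed value somewhere below the quantitation limit.

Plasma and urine records share the subject's etas but use matrix-specific
residual variances; urine concentration predictions are interval excretion
(CL_R × AUC over the collection interval) divided by the voided volume.

Implementation notes: all subjects are advanced simultaneously -- the inner
(posterior-mode) Newton iterations operate on an (n_subjects, n_eta) matrix
with derivatives by batched finite differences, and structural predictions
are evaluated over flat (observation, dose) pair arrays.  The outer problem
optimizes transformed parameters (log for positive thetas and variances,
log1p for proportional-shift coefficients bounded below by -1, identity for
power coefficients; log-Cholesky for a full Omega) with L-BFGS-B.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr
from numpy.polynomial.hermite import hermgauss

from .pkcore import conc_contrib, cum_auc_contrib, _eigenvalues
from .covariates import mdrd_egfr, dubois_bsa, bmi as bmi_fn, RENAL_GROUP_EGFR
from .popmodel import ETA_ORDER, PopulationModel

__all__ = [
    "PKData",
    "FitResult",
    "fit",
    "marginal_ofv",
    "subject_loglik",
    "posthoc",
    "aic",
    "marginal_loglik_agh",
    "flag_aberrant",
]

_LOG2PI = math.log(2.0 * math.pi)

#: thetas that are strictly positive and optimized on the log scale
_POSITIVE_THETAS = {
    "cl_nr", "clr_max", "egfr50", "hill", "vc", "cld", "vp", "cl",
}
#: thetas bounded below by -1 (proportional shifts), optimized as log1p
_SHIFT_THETAS = {"renal_cl_nr", "phase_cl", "phase_vc", "phase_vp"}


class DataError(ValueError):
    """Raised for malformed analysis datasets."""


# ---------------------------------------------------------------------------
# vectorized dataset view
# ---------------------------------------------------------------------------

class PKData:
    """Flat, index-based view of an event table for vectorized evaluation.

    Built once per dataset; every likelihood evaluation is then pure array
    arithmetic over precomputed (observation, dose) pair indices.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.reset_index(drop=True)
        required = {"ID", "TIME", "EVID", "CMT"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"dataset lacks required columns: {sorted(missing)}")

        ids, first_rows = np.unique(df["ID"].to_numpy(), return_index=True)
        order = np.argsort(first_rows)
        self.ids = ids[order]
        self.n_sub = len(self.ids)
        sub_of_row = pd.Series(
            np.arange(self.n_sub), index=self.ids
        )[df["ID"]].to_numpy()

        t = df["TIME"].to_numpy(dtype=float)
        for s in range(self.n_sub):
            ts = t[sub_of_row == s]
            if np.any(np.diff(ts) < 0):
                raise DataError(f"times not sorted for subject {self.ids[s]!r}")

        # doses
        dose = df["EVID"].to_numpy() == 1
        self.d_sub = sub_of_row[dose]
        self.d_start = t[dose]
        amt = df.loc[dose, "AMT"].to_numpy(dtype=float)
        rate = df.loc[dose, "RATE"].to_numpy(dtype=float)
        if np.any(amt <= 0) or np.any(rate <= 0):
            raise DataError("dose rows need AMT > 0 and RATE > 0")
        self.d_rate = rate
        self.d_dur = amt / rate
        self.d_amt = amt

        # plasma observations
        obs = (df["EVID"].to_numpy() == 0) & (df["CMT"].to_numpy() == 1)
        self.o_sub = sub_of_row[obs]
        self.o_t = t[obs]
        blq = (
            df.loc[obs, "BLQ"].to_numpy(dtype=float)
            if "BLQ" in df else np.zeros(obs.sum())
        )
        self.o_blq = np.nan_to_num(blq) > 0
        dv = (
            df.loc[obs, "DV"].to_numpy(dtype=float)
            if "DV" in df else np.full(obs.sum(), np.nan)
        )
        self.o_dv = dv
        lloq = (
            df.loc[obs, "LLOQ"].to_numpy(dtype=float)
            if "LLOQ" in df else np.zeros(obs.sum())
        )
        self.o_lloq = np.nan_to_num(lloq)
        if np.any(self.o_blq & ~(self.o_lloq > 0)):
            raise DataError("BLQ rows must carry a positive LLOQ")
        bad = ~self.o_blq & ~np.isfinite(dv)
        if np.any(bad) and np.any(np.isfinite(dv)):
            raise DataError("quantified plasma rows must carry a DV")

        # urine observations: a row at TIME t covers the interval from the
        # subject's previous urine row (or 0) up to t
        uobs = (df["EVID"].to_numpy() == 0) & (df["CMT"].to_numpy() == 2)
        self.u_sub = sub_of_row[uobs]
        self.u_t2 = t[uobs]
        self.u_t1 = np.zeros_like(self.u_t2)
        for s in range(self.n_sub):
            m = self.u_sub == s
            tt = self.u_t2[m]
            self.u_t1[m] = np.concatenate([[0.0], tt[:-1]])
        if "URINEVOL" in df:
            vol = df.loc[uobs, "URINEVOL"].to_numpy(dtype=float)
        else:
            vol = np.full(uobs.sum(), np.nan)
        if np.any(~np.isfinite(vol) | (vol <= 0)) and uobs.sum():
            raise DataError("urine rows must carry a positive URINEVOL")
        self.u_vol = vol            # ml, as recorded
        self.u_vol_l = vol / 1000.0  # L, for mg/L concentrations
        self.u_dv = (
            df.loc[uobs, "DV"].to_numpy(dtype=float)
            if "DV" in df else np.full(uobs.sum(), np.nan)
        )

        # covariates from each subject's first row
        self.covs = self._baseline_covariates(df, sub_of_row)

        # (observation, dose) pair expansion
        self.po_idx, self.pd_idx = self._pairs(self.o_sub, self.o_t)
        self.uo_idx, self.ud_idx = self._pairs(self.u_sub, self.u_t2)

        self.n_obs = len(self.o_t)
        self.n_uobs = len(self.u_t2)

    def _baseline_covariates(self, df, sub_of_row) -> dict[str, np.ndarray]:
        first = np.zeros(self.n_sub, dtype=int)
        seen = set()
        for i, s in enumerate(sub_of_row):
            if s not in seen:
                first[s] = i
                seen.add(s)
        row = df.iloc[first]

        def col(name, default=np.nan):
            if name in df.columns:
                return row[name].to_numpy(dtype=float)
            return np.full(self.n_sub, default)

        covs: dict[str, np.ndarray] = {
            "age": col("AGE"),
            "weight": col("WTKG"),
            "height": col("HTCM"),
            "sex": col("SEX", 0.0),      # 0 male, 1 female
            "race": col("RACE", 0.0),    # 0 other, 1 black
            "scr": col("SCR"),
            "phase": col("PHASE", 3.0),
        }
        egfr = col("EGFR")
        need = ~np.isfinite(egfr)
        if np.any(need):
            ok = np.isfinite(covs["scr"]) & np.isfinite(covs["age"])
            if np.any(need & ~ok):
                raise DataError("EGFR absent and SCR/AGE incomplete")
            egfr = np.where(
                need,
                mdrd_egfr(
                    np.where(ok, covs["scr"], 1.0),
                    np.where(ok, covs["age"], 50.0),
                    covs["sex"] > 0, covs["race"] > 0,
                ),
                egfr,
            )
        covs["egfr"] = egfr
        bsa = col("BSA")
        need = ~np.isfinite(bsa)
        if np.any(need) and np.all(
            np.isfinite(covs["weight"]) & np.isfinite(covs["height"])
        ):
            bsa = np.where(need, dubois_bsa(covs["weight"], covs["height"]), bsa)
        covs["bsa"] = bsa
        with np.errstate(invalid="ignore"):
            covs["bmi"] = bmi_fn(
                np.where(np.isfinite(covs["weight"]), covs["weight"], 1.0),
                np.where(np.isfinite(covs["height"]), covs["height"], 1.0),
            )
        covs["renal_group"] = (egfr <= RENAL_GROUP_EGFR).astype(float)
        return covs

    def _pairs(self, o_sub, o_t):
        """Indices of (observation, dose) pairs with dose start < obs time."""
        oi, di = [], []
        for s in range(self.n_sub):
            dmask = np.nonzero(self.d_sub == s)[0]
            omask = np.nonzero(o_sub == s)[0]
            if len(dmask) == 0 or len(omask) == 0:
                continue
            starts = self.d_start[dmask]
            for o in omask:
                active = dmask[starts < o_t[o]]
                oi.append(np.full(len(active), o))
                di.append(active)
        if not oi:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        return np.concatenate(oi), np.concatenate(di)

    # -- structural predictions --------------------------------------------
    def predict(self, cl_r, cl_nr, vc, cld, vp):
        """Plasma and urine-concentration predictions from per-subject params."""
        cl = cl_r + cl_nr
        k10 = cl / vc
        k12 = cld / vc
        k21 = cld / vp
        lam1, lam2 = _eigenvalues(k10, k12, k21)

        if len(self.po_idx):
            ds = self.d_sub[self.pd_idx]
            dt = self.o_t[self.po_idx] - self.d_start[self.pd_idx]
            contrib = conc_contrib(
                dt, self.d_rate[self.pd_idx], self.d_dur[self.pd_idx],
                vc[ds], k21[ds], lam1[ds], lam2[ds],
            )
            plasma = np.bincount(self.po_idx, contrib, minlength=self.n_obs)
        else:
            plasma = np.zeros(self.n_obs)

        if len(self.uo_idx):
            ds = self.d_sub[self.ud_idx]
            start = self.d_start[self.ud_idx]
            a2 = cum_auc_contrib(
                self.u_t2[self.uo_idx] - start,
                self.d_rate[self.ud_idx], self.d_dur[self.ud_idx],
                vc[ds], k21[ds], lam1[ds], lam2[ds],
            )
            a1 = cum_auc_contrib(
                self.u_t1[self.uo_idx] - start,
                self.d_rate[self.ud_idx], self.d_dur[self.ud_idx],
                vc[ds], k21[ds], lam1[ds], lam2[ds],
            )
            amt = cl_r[self.u_sub[self.uo_idx]] * (a2 - a1)
            amount = np.bincount(self.uo_idx, amt, minlength=self.n_uobs)
            urine = amount / self.u_vol_l
        else:
            urine = np.zeros(self.n_uobs)
        return plasma, urine


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _data_loglik(data: PKData, plasma_pred, urine_pred, sigma) -> np.ndarray:
    """Per-subject data log-likelihood (M3 for BLQ plasma rows)."""
    out = np.zeros(data.n_sub)
    if data.n_obs:
        s2p, s2a = sigma["plasma"]
        var = plasma_pred * plasma_pred * s2p + s2a
        var = np.maximum(var, 1e-300)
        sd = np.sqrt(var)
        terms = np.empty(data.n_obs)
        q = ~data.o_blq
        r = data.o_dv[q] - plasma_pred[q]
        terms[q] = -0.5 * (_LOG2PI + np.log(var[q]) + r * r / var[q])
        if np.any(data.o_blq):
            b = data.o_blq
            terms[b] = log_ndtr((data.o_lloq[b] - plasma_pred[b]) / sd[b])
        out += np.bincount(data.o_sub, terms, minlength=data.n_sub)
    if data.n_uobs:
        s2p, s2a = sigma.get("urine", (0.0, 0.0))
        var = np.maximum(urine_pred * urine_pred * s2p + s2a, 1e-300)
        r = data.u_dv - urine_pred
        terms = -0.5 * (_LOG2PI + np.log(var) + r * r / var)
        out += np.bincount(data.u_sub, terms, minlength=data.n_sub)
    return out


def _transform_for(name: str, model: PopulationModel) -> str:
    if name in _POSITIVE_THETAS:
        return "log"
    if name in _SHIFT_THETAS:
        return "log1p"
    for eff in model.effects:
        if eff.theta_name == name:
            return "log1p" if eff.form == "shift" else "id"
    return "id"


@dataclass
class FitResult:
    """Estimation output: updated model, OFV, uncertainties, post hocs."""

    model: PopulationModel
    ofv: float
    etas: np.ndarray
    ids: np.ndarray
    se: dict[str, float] = field(default_factory=dict)
    shrinkage: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    n_obs: int = 0
    n_subjects: int = 0
    free_names: tuple[str, ...] = ()
    ofv_history: tuple[float, ...] = ()
    message: str = ""

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def eta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.etas, index=pd.Index(self.ids, name="ID"),
            columns=[f"eta_{n}" for n in self.model.eta_names],
        )


class LaplaceFitter:
    """Shared machinery for OFV evaluation, posterior modes and fitting."""

    def __init__(
        self,
        data: PKData,
        model: PopulationModel,
        free_theta: Sequence[str] | None = None,
        estimate_omega: bool = True,
        estimate_sigma: bool = True,
        omega_structure: str = "diagonal",
    ):
        self.data = data
        self.model = model
        self.k = model.n_eta
        self._no_iiv = bool(np.all(np.diag(model.omega) < 1e-12))
        if free_theta is None:
            free_theta = [t for t in model.theta if t not in model.fixed]
        self.free_theta = list(free_theta)
        self.estimate_omega = estimate_omega and not self._no_iiv
        self.estimate_sigma = estimate_sigma
        if omega_structure not in ("diagonal", "full"):
            raise ValueError("omega_structure must be 'diagonal' or 'full'")
        self.omega_structure = omega_structure
        self._sigma_keys = [
            m for m in ("plasma", "urine")
            if m in model.sigma
            and (m == "plasma" and data.n_obs or m == "urine" and data.n_uobs)
        ]
        self._eta_cache = np.zeros((data.n_sub, self.k))
        self._build_layout()
        n_free = len(self.free_names)
        if data.n_obs + data.n_uobs < 5 * len(self.free_theta):
            warnings.warn(
                "fewer than 5 observations per free theta; "
                "the design may not be identifiable",
                stacklevel=2,
            )

    # -- parameter packing ---------------------------------------------------
    def _build_layout(self):
        names: list[str] = []
        self._kinds: list[tuple] = []
        for t in self.free_theta:
            names.append(t)
            self._kinds.append(("theta", t, _transform_for(t, self.model)))
        if self.estimate_omega:
            if self.omega_structure == "diagonal":
                for i, nm in enumerate(self.model.eta_names):
                    names.append(f"omega_{nm}")
                    self._kinds.append(("omega_diag", i, "log_sd"))
            else:
                for i in range(self.k):
                    for j in range(i + 1):
                        names.append(
                            f"omega_chol_{self.model.eta_names[i]}"
                            f"_{self.model.eta_names[j]}"
                        )
                        self._kinds.append(("omega_chol", (i, j), None))
        if self.estimate_sigma:
            for m in self._sigma_keys:
                for j, part in enumerate(("prop", "add")):
                    names.append(f"sigma_{m}_{part}")
                    self._kinds.append(("sigma", (m, j), "log"))
        self.free_names = tuple(names)

    def pack(self) -> np.ndarray:
        x = []
        L = None
        if self.estimate_omega and self.omega_structure == "full":
            om = self.model.omega + 1e-10 * np.eye(self.k)
            L = np.linalg.cholesky(om)
        for kind, key, tr in self._kinds:
            if kind == "theta":
                v = self.model.theta[key]
                x.append(
                    math.log(v) if tr == "log"
                    else math.log1p(v) if tr == "log1p" else v
                )
            elif kind == "omega_diag":
                x.append(0.5 * math.log(max(self.model.omega[key, key], 1e-12)))
            elif kind == "omega_chol":
                i, j = key
                x.append(math.log(max(L[i, i], 1e-8)) if i == j else L[i, j])
            else:
                m, j = key
                x.append(math.log(max(self.model.sigma[m][j], 1e-10)))
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray):
        theta = dict(self.model.theta)
        omega = self.model.omega.copy()
        sigma = {m: list(v) for m, v in self.model.sigma.items()}
        L = np.zeros((self.k, self.k))
        use_chol = False
        for val, (kind, key, tr) in zip(x, self._kinds):
            val = float(np.clip(val, -40.0, 40.0))
            if kind == "theta":
                theta[key] = (
                    math.exp(val) if tr == "log"
                    else math.expm1(val) if tr == "log1p" else val
                )
            elif kind == "omega_diag":
                omega[key, key] = math.exp(2.0 * val)
            elif kind == "omega_chol":
                use_chol = True
                i, j = key
                L[i, j] = math.exp(val) if i == j else val
            else:
                m, j = key
                sigma[m][j] = math.exp(val)
        if use_chol:
            omega = L @ L.T
        sigma = {m: tuple(v) for m, v in sigma.items()}
        return theta, omega, sigma

    # -- likelihood ----------------------------------------------------------
    def _typical(self, theta):
        model = self.model.with_theta(**theta)
        return model.typical_arrays(self.data.covs)

    def _eta_param_cols(self):
        # column index of each eta dimension's target within ETA_ORDER
        return [ETA_ORDER.index(nm) for nm in self.model.eta_names]

    def _penll(self, tv, etas, omega_inv, logdet_omega, sigma) -> np.ndarray:
        """Per-subject penalized log-likelihood (data + eta prior).

        Non-finite values (overflowing trial etas during optimization)
        propagate as NaN and are rejected by the line searches.
        """
        cl_r, cl_nr, vc, cld, vp = (
            np.broadcast_to(np.asarray(a, dtype=float),
                            (self.data.n_sub,)).copy() for a in tv
        )
        with np.errstate(all="ignore"):
            for i, nm in enumerate(self.model.eta_names):
                f = np.exp(etas[:, i])
                if nm == "CL":
                    cl_r, cl_nr = cl_r * f, cl_nr * f
                elif nm == "Vc":
                    vc = vc * f
                elif nm == "CLd":
                    cld = cld * f
                else:
                    vp = vp * f
            plasma, urine = self.data.predict(cl_r, cl_nr, vc, cld, vp)
            ll = _data_loglik(self.data, plasma, urine, sigma)
            if not self._no_iiv:
                quad = np.einsum("ni,ij,nj->n", etas, omega_inv, etas)
                ll = ll - 0.5 * (self.k * _LOG2PI + logdet_omega + quad)
        return ll

    @staticmethod
    def _derivs(f, etas, f0, h):
        """Batched central-difference gradient and Hessian of f at etas."""
        n, k = etas.shape
        grad = np.zeros((n, k))
        hess = np.zeros((n, k, k))
        fp = np.zeros((n, k))
        fm = np.zeros((n, k))
        for j in range(k):
            e = etas.copy(); e[:, j] += h
            fp[:, j] = f(e)
            e = etas.copy(); e[:, j] -= h
            fm[:, j] = f(e)
            grad[:, j] = (fp[:, j] - fm[:, j]) / (2 * h)
            hess[:, j, j] = (fp[:, j] + fm[:, j] - 2 * f0) / (h * h)
        for i in range(k):
            for j in range(i):
                e = etas.copy(); e[:, i] += h; e[:, j] += h
                fpp = f(e)
                e = etas.copy(); e[:, i] -= h; e[:, j] -= h
                fmm = f(e)
                hij = (
                    fpp + fmm + 2 * f0
                    - fp[:, i] - fm[:, i] - fp[:, j] - fm[:, j]
                ) / (2 * h * h)
                hess[:, i, j] = hess[:, j, i] = hij
        grad = np.where(np.isfinite(grad), grad, 0.0)
        broken = ~np.isfinite(hess).all(axis=(1, 2))
        if np.any(broken):
            hess[broken] = -np.eye(k)
        return grad, hess

    def _simplex_rescue(self, f, etas, f0, bad, tol):
        """Per-subject derivative-free polish for non-converged subjects.

        Rarely triggered (extreme residual weighting can trap the batched
        Newton in a curved valley); Nelder-Mead restarted from the current
        point and from the prior mode.
        """
        from scipy.optimize import minimize as _minimize

        for s in np.nonzero(bad)[0]:
            def nll(e, s=s):
                trial = etas.copy()
                trial[s] = e
                v = f(trial)[s]
                return -v if np.isfinite(v) else 1e300

            best_x, best_v = etas[s], -f0[s]
            for x0 in (etas[s], np.zeros(self.k)):
                r = _minimize(nll, x0, method="Nelder-Mead",
                              options={"maxiter": 200 * self.k,
                                       "fatol": 1e-9, "xatol": 1e-7})
                if r.fun < best_v:
                    best_x, best_v = r.x, r.fun
            etas[s] = best_x
            f0[s] = -best_v
        return etas, f0

    def _inner(self, tv, omega_inv, logdet_omega, sigma, etas0,
               tol: float = 1e-7, max_iter: int = 30):
        """Batched Newton ascent to the per-subject posterior mode."""
        n, k = self.data.n_sub, self.k
        etas = etas0.copy()
        h = 1e-4

        def f(e):
            return self._penll(tv, e, omega_inv, logdet_omega, sigma)

        f0 = f(etas)
        bad = ~np.isfinite(f0)
        if np.any(bad):  # stale warm starts from a rejected outer step
            etas[bad] = 0.0
            f0 = f(etas)
        hess = np.zeros((n, k, k))
        fresh = False  # do grad/hess correspond to the current etas?
        for _ in range(max_iter):
            grad, hess = self._derivs(f, etas, f0, h)
            fresh = True
            if np.max(np.abs(grad)) < tol:
                break
            a = -hess  # should be PD near the mode
            # per-subject ridge until positive definite
            eig = np.linalg.eigvalsh(a)
            ridge = np.maximum(1e-8 - eig[:, 0], 0.0)
            a = a + ridge[:, None, None] * np.eye(k)
            try:
                step = np.linalg.solve(a, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = (np.linalg.pinv(a) @ grad[..., None])[..., 0]
            # cap the step on the log scale to stay in the finite region
            norm = np.max(np.abs(step), axis=1)
            step *= np.where(norm > 2.0, 2.0 / np.maximum(norm, 1e-300),
                             1.0)[:, None]
            # backtracking on subjects whose objective worsens (NaN counts
            # as worse)
            scale = np.ones(n)
            for _bt in range(12):
                trial = etas + scale[:, None] * step
                ft = f(trial)
                ok = ft >= f0 - 1e-12
                if np.all(ok):
                    break
                scale[~ok] *= 0.5
            improved = np.isfinite(ft) & (ft >= f0)
            etas = np.where(improved[:, None], trial, etas)
            stuck = ~improved & (np.max(np.abs(grad), axis=1) > tol)
            if np.any(stuck):
                # Newton direction rejected (indefinite curvature far from
                # the mode): steepest-ascent rescue with a step-halving
                # search along the normalized gradient
                gn = np.max(np.abs(grad), axis=1, keepdims=True)
                dirn = grad / np.maximum(gn, 1e-300)
                ft = np.where(improved, ft, f0)
                for expo in range(13):
                    trial2 = etas + np.where(stuck[:, None],
                                             dirn * (0.5 ** expo), 0.0)
                    ft2 = f(trial2)
                    better = stuck & np.isfinite(ft2) & (ft2 > ft)
                    if np.any(better):
                        etas = np.where(better[:, None], trial2, etas)
                        ft = np.where(better, ft2, ft)
                        improved = improved | better
                        stuck = stuck & ~better
                    if not np.any(stuck):
                        break
            if np.any(improved):
                fresh = False
            f_new = np.where(improved, ft, f0)
            if np.max(np.abs(f_new - f0)) < 1e-10:
                f0 = f_new
                break
            f0 = f_new
        if not fresh:
            grad, hess = self._derivs(f, etas, f0, h)
        # relative non-convergence check: residual gradient large compared
        # with the local curvature scale
        curv = np.maximum(np.abs(hess).max(axis=(1, 2)), 1.0)
        bad = np.abs(grad).max(axis=1) > 1e-3 * np.sqrt(curv)
        if np.any(bad):
            etas, f0 = self._simplex_rescue(f, etas, f0, bad, tol)
            _, hess = self._derivs(f, etas, f0, h)
        return etas, hess, f0

    def ofv_x(self, x: np.ndarray) -> float:
        theta, omega, sigma = self.unpack(x)
        return self._ofv(theta, omega, sigma)

    def _ofv(self, theta, omega, sigma) -> float:
        tv = self._typical(theta)
        if self._no_iiv:
            ll = self._penll(tv, np.zeros((self.data.n_sub, self.k)),
                             None, 0.0, sigma)
            return float(-2.0 * ll.sum())
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            return 1e12
        omega_inv = np.linalg.inv(omega)
        etas, hess, penll = self._inner(
            tv, omega_inv, logdet, sigma, self._eta_cache
        )
        self._eta_cache = etas
        a = -hess
        eig = np.linalg.eigvalsh(a)
        if np.any(eig[:, 0] <= 0):
            warnings.warn(
                "non-positive-definite curvature at a posterior mode; "
                "regularized", stacklevel=2,
            )
            ridge = np.maximum(1e-8 - eig[:, 0], 0.0)
            a = a + ridge[:, None, None] * np.eye(self.k)
        logdet_a = np.linalg.slogdet(a)[1]
        marg = penll + 0.5 * self.k * _LOG2PI - 0.5 * logdet_a
        total = -2.0 * marg.sum()
        if not np.isfinite(total):
            self._eta_cache = np.zeros_like(self._eta_cache)
            return 1e12
        return float(total)

    # -- public high-level ops ------------------------------------------------
    def posthoc(self, theta=None, omega=None, sigma=None):
        theta = theta or dict(self.model.theta)
        omega = self.model.omega if omega is None else omega
        sigma = sigma or self.model.sigma
        tv = self._typical(theta)
        if self._no_iiv:
            return np.zeros((self.data.n_sub, self.k))
        omega_inv = np.linalg.inv(omega)
        logdet = np.linalg.slogdet(omega)[1]
        etas, _, _ = self._inner(tv, omega_inv, logdet, sigma, self._eta_cache)
        return etas

    def fit(self, maxiter: int = 200, compute_se: bool = False,
            gtol: float = 0.05) -> FitResult:
        x0 = self.pack()
        history: list[float] = []

        def cb(xk):
            history.append(self._last_f)

        def fun(x):
            v = self.ofv_x(x)
            self._last_f = v
            return v

        res = minimize(
            fun, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "eps": 1e-5, "ftol": 1e-12,
                     "gtol": gtol},
            callback=cb,
        )
        theta, omega, sigma = self.unpack(res.x)
        fitted = self.model.update(
            theta=theta, omega=omega, sigma=sigma
        )
        etas = self.posthoc(theta, omega, sigma)
        shrink = {}
        if not self._no_iiv:
            for i, nm in enumerate(self.model.eta_names):
                w = math.sqrt(max(omega[i, i], 1e-300))
                shrink[nm] = 100.0 * (1.0 - float(np.std(etas[:, i], ddof=1)) / w)
        se: dict[str, float] = {}
        if compute_se:
            se = self._standard_errors(res.x)
        return FitResult(
            model=fitted,
            ofv=float(res.fun),
            etas=etas,
            ids=self.data.ids,
            se=se,
            shrinkage=shrink,
            converged=bool(res.success),
            n_iter=int(res.nit),
            n_obs=self.data.n_obs + self.data.n_uobs,
            n_subjects=self.data.n_sub,
            free_names=self.free_names,
            ofv_history=tuple(history),
            message=str(res.message),
        )

    def _standard_errors(self, x_opt: np.ndarray) -> dict[str, float]:
        """Wald SEs from a central finite-difference Hessian of the OFV."""
        p = len(x_opt)
        h = 1e-3
        hess = np.zeros((p, p))
        f0 = self.ofv_x(x_opt)
        fp = np.zeros(p); fm = np.zeros(p)
        for i in range(p):
            e = x_opt.copy(); e[i] += h
            fp[i] = self.ofv_x(e)
            e = x_opt.copy(); e[i] -= h
            fm[i] = self.ofv_x(e)
            hess[i, i] = (fp[i] + fm[i] - 2 * f0) / (h * h)
        for i in range(p):
            for j in range(i):
                e = x_opt.copy(); e[i] += h; e[j] += h
                fpp = self.ofv_x(e)
                e = x_opt.copy(); e[i] -= h; e[j] -= h
                fmm = self.ofv_x(e)
                hess[i, j] = hess[j, i] = (
                    fpp + fmm + 2 * f0 - fp[i] - fm[i] - fp[j] - fm[j]
                ) / (2 * h * h)
        try:
            cov_x = 2.0 * np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            warnings.warn("OFV Hessian singular; SEs unavailable", stacklevel=2)
            return {}
        var_x = np.clip(np.diag(cov_x), 0.0, None)
        se = {}
        theta, omega, sigma = self.unpack(x_opt)
        for v, sx, (kind, key, tr) in zip(x_opt, np.sqrt(var_x), self._kinds):
            name = self.free_names[len(se)]
            if kind == "theta":
                scale = (
                    abs(theta[key]) if tr == "log"
                    else abs(1.0 + theta[key]) if tr == "log1p" else 1.0
                )
            elif kind == "omega_diag":
                scale = 2.0 * omega[key, key]
            elif kind == "omega_chol":
                scale = 1.0
            else:
                m, j = key
                scale = sigma[m][j]
            se[name] = float(sx * scale)
        return se


# ---------------------------------------------------------------------------
# module-level convenience API
# ---------------------------------------------------------------------------

def _as_data(table) -> PKData:
    return table if isinstance(table, PKData) else PKData(table)


def marginal_ofv(model: PopulationModel, table) -> float:
    """-2 log marginal likelihood of ``table`` at the model's current values."""
    data = _as_data(table)
    fitter = LaplaceFitter(data, model, free_theta=[])
    theta = dict(model.theta)
    return fitter._ofv(theta, model.omega, model.sigma)


def fit(model0: PopulationModel, table, *, free_theta=None,
        estimate_omega=True, estimate_sigma=True,
        omega_structure="diagonal", maxiter=200,
        compute_se=False) -> FitResult:
    """Maximum (Laplace-approximate marginal) likelihood fit."""
    data = _as_data(table)
    fitter = LaplaceFitter(
        data, model0, free_theta=free_theta, estimate_omega=estimate_omega,
        estimate_sigma=estimate_sigma, omega_structure=omega_structure,
    )
    return fitter.fit(maxiter=maxiter, compute_se=compute_se)


def posthoc(model: PopulationModel, table) -> pd.DataFrame:
    """Posterior-mode (empirical Bayes) etas and individual parameters."""
    data = _as_data(table)
    fitter = LaplaceFitter(data, model, free_theta=[])
    etas = fitter.posthoc()
    tv = model.typical_arrays(data.covs)
    cl_r, cl_nr, vc, cld, vp = (np.array(a, dtype=float) for a in tv)
    fac = {nm: np.exp(etas[:, i]) for i, nm in enumerate(model.eta_names)}
    out = pd.DataFrame({"ID": data.ids})
    out["CL"] = (cl_r + cl_nr) * fac.get("CL", 1.0)
    out["CL_R"] = cl_r * fac.get("CL", 1.0)
    out["CL_NR"] = cl_nr * fac.get("CL", 1.0)
    out["Vc"] = vc * fac.get("Vc", 1.0)
    out["CLd"] = cld * fac.get("CLd", 1.0)
    out["Vp"] = vp * fac.get("Vp", 1.0)
    for i, nm in enumerate(model.eta_names):
        out[f"eta_{nm}"] = etas[:, i]
    return out


def subject_loglik(model: PopulationModel, events: pd.DataFrame,
                   eta: np.ndarray) -> float:
    """Penalized log-likelihood of one subject's events at a given eta.

    Sum of the observation log-densities (M3 censored terms for BLQ rows)
    and the log prior density of eta under Omega.
    """
    data = PKData(events)
    if data.n_sub != 1:
        raise DataError("subject_loglik expects a single subject")
    fitter = LaplaceFitter(data, model, free_theta=[])
    eta = np.asarray(eta, dtype=float).reshape(1, -1)
    if eta.shape[1] != model.n_eta:
        raise DataError("eta dimension does not match the model")
    tv = fitter._typical(dict(model.theta))
    if fitter._no_iiv:
        return float(fitter._penll(tv, eta, None, 0.0, model.sigma)[0])
    omega_inv = np.linalg.inv(model.omega)
    logdet = np.linalg.slogdet(model.omega)[1]
    return float(fitter._penll(tv, eta, omega_inv, logdet, model.sigma)[0])


def marginal_loglik_agh(model: PopulationModel, events: pd.DataFrame,
                        n_nodes: int = 21) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (1-D eta oracle).

    Exactness reference for the Laplace approximation on toy subjects with a
    single random-effect dimension; raises for higher dimensions.
    """
    if model.n_eta != 1:
        raise NotImplementedError("AGH oracle supports a single eta dimension")
    data = PKData(events)
    if data.n_sub != 1:
        raise DataError("marginal_loglik_agh expects a single subject")
    fitter = LaplaceFitter(data, model, free_theta=[])
    tv = fitter._typical(dict(model.theta))
    omega_inv = np.linalg.inv(model.omega)
    logdet = np.linalg.slogdet(model.omega)[1]

    def l(e):
        return fitter._penll(
            tv, np.asarray(e, float).reshape(1, 1), omega_inv, logdet,
            model.sigma,
        )[0]

    etas, hess, _ = fitter._inner(
        tv, omega_inv, logdet, model.sigma, np.zeros((1, 1))
    )
    mode = float(etas[0, 0])
    a = max(-float(hess[0, 0, 0]), 1e-8)
    sd = 1.0 / math.sqrt(a)
    x, w = hermgauss(n_nodes)
    pts = mode + math.sqrt(2.0) * sd * x
    vals = np.array([l(p) for p in pts])
    logterms = vals + x * x + np.log(w)
    m = logterms.max()
    return float(
        m + math.log(np.exp(logterms - m).sum()) + math.log(math.sqrt(2.0) * sd)
    )


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion: OFV + 2 × (number of free parameters)."""
    return fit_result.ofv + 2.0 * fit_result.n_free


def flag_aberrant(model: PopulationModel, table, threshold: float = 6.0
                  ) -> pd.DataFrame:
    """Report (never delete) plasma rows with extreme weighted residuals.

    The individual weighted residual (observed minus post hoc individual
    prediction, scaled by the residual sd at that prediction) is compared to
    ``threshold``; flagged rows are returned for review.
    """
    data = _as_data(table)
    fitter = LaplaceFitter(data, model, free_theta=[])
    etas = fitter.posthoc()
    tv = model.typical_arrays(data.covs)
    cl_r, cl_nr, vc, cld, vp = (np.array(a, dtype=float) for a in tv)
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
    plasma, _ = data.predict(cl_r, cl_nr, vc, cld, vp)
    s2p, s2a = model.sigma["plasma"]
    sd = np.sqrt(plasma * plasma * s2p + s2a)
    q = ~data.o_blq
    wres = np.zeros(data.n_obs)
    wres[q] = (data.o_dv[q] - plasma[q]) / np.maximum(sd[q], 1e-12)
    mask = np.abs(wres) > threshold
    return pd.DataFrame({
        "ID": data.ids[data.o_sub[mask]],
        "TIME": data.o_t[mask],
        "DV": data.o_dv[mask],
        "IPRED": plasma[mask],
        "WRES": wres[mask],
    })
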