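"""Model/Results interface over the estimation engine.

:class:`PopPK` is constructed from an analysis dataset (the rectangular
event-table format) plus a :class:`~mvpk.popmodel.PopulationModel` whose
current values serve as starting estimates; :meth:`PopPK.fit` returns a
:class:`PopPKResults` carrying the estimated model, the objective function
value, standard errors, empirical-Bayes individual estimates and shrinkage,
with a parameter table via :meth:`PopPKResults.summary`.  Simulation,
goodness of fit, the prediction-corrected VPC and secondary exposure
derivation hang off these two objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimation as est
from . import exposures as expo
from .estimation import FitResult, PKData
from .popmodel import PopulationModel, load_model, omega_to_cv_percent

__all__ = ["PopPK", "PopPKResults"]


class PopPK:
    """Population PK model bound to a dataset.

    Parameters
    ----------
    data : DataFrame or PKData
        Event table (columns ID, TIME, AMT, RATE, EVID, CMT, DV, BLQ, LLOQ,
        MDV, URINEVOL plus covariates).
    base : PopulationModel
        Structural/covariate model whose values are the starting estimates.
    free_theta, estimate_omega, estimate_sigma, omega_structure :
        Which components :meth:`fit` updates; defaults free every theta not
        flagged fixed, a diagonal Omega, and the residual variances of the
        matrices present in the data.
    """

    def __init__(self, data, base: PopulationModel, *, free_theta=None,
                 estimate_omega: bool = True, estimate_sigma: bool = True,
                 omega_structure: str = "diagonal"):
        self.data = data if isinstance(data, PKData) else PKData(data)
        self.base = base
        self._opts = dict(
            free_theta=free_theta,
            estimate_omega=estimate_omega,
            estimate_sigma=estimate_sigma,
            omega_structure=omega_structure,
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, drug: str = "meropenem",
                       **kwargs) -> "PopPK":
        """Build with the bundled final model of ``drug`` as the base."""
        return cls(frame, load_model(drug), **kwargs)

    def _fitter(self, model=None) -> est.LaplaceFitter:
        return est.LaplaceFitter(self.data, model or self.base, **self._opts)

    def ofv(self, model: PopulationModel | None = None) -> float:
        """Objective function value at the base (or a given) model."""
        return est.marginal_ofv(model or self.base, self.data)

    def fit(self, maxiter: int = 200, compute_se: bool = False,
            gtol: float = 0.05) -> "PopPKResults":
        """Estimate free parameters by Laplace marginal likelihood."""
        raw = self._fitter().fit(maxiter=maxiter, compute_se=compute_se,
                                 gtol=gtol)
        return PopPKResults(self, raw)

    def simulate(self, seed, model: PopulationModel | None = None):
        """One replicate of plasma observations on this design.

        Returns ``(dv, blq_mask)`` aligned with the plasma observation rows.
        """
        from .synthdata import resimulate_plasma

        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        return resimulate_plasma(self.data, model or self.base, rng)


class PopPKResults:
    """Fit output: estimates, uncertainties, diagnostics, derived exposures."""

    def __init__(self, model: PopPK, raw: FitResult):
        self.model = model
        self.raw = raw
        self.fitted: PopulationModel = raw.model

    # -- scalar summaries ---------------------------------------------------
    @property
    def ofv(self) -> float:
        """Minimum value of the objective function (-2 log marginal L)."""
        return self.raw.ofv

    @property
    def aic(self) -> float:
        return est.aic(self.raw)

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def params(self) -> pd.Series:
        th = self.fitted.theta
        vals = {n: th[n] for n in self.raw.free_names if n in th}
        for n in self.raw.free_names:
            if n.startswith("omega_") and not n.startswith("omega_chol"):
                nm = n.split("_", 1)[1]
                i = self.fitted.eta_names.index(nm)
                vals[n] = self.fitted.omega[i, i]
            elif n.startswith("sigma_"):
                _, m, part = n.split("_")
                vals[n] = self.fitted.sigma[m][0 if part == "prop" else 1]
        return pd.Series(vals)

    @property
    def bse(self) -> pd.Series:
        """Asymptotic standard errors (empty unless fit(compute_se=True))."""
        return pd.Series(self.raw.se)

    @property
    def shrinkage(self) -> pd.Series:
        """Eta shrinkage (%) per random-effect dimension."""
        return pd.Series(self.raw.shrinkage)

    def omega_cv(self) -> pd.Series:
        """Estimated IIV as %CV per eta dimension."""
        return pd.Series(self.fitted.omega_cv())

    # -- individuals --------------------------------------------------------
    def posthoc(self) -> pd.DataFrame:
        """Empirical-Bayes individual parameters (CL, Vc, CLd, Vp, etas)."""
        return est.posthoc(self.fitted, self.model.data)

    # -- diagnostics ---------------------------------------------------------
    def gof(self) -> dict:
        """Goodness-of-fit tables and the observed-vs-fitted r²."""
        from .diagnostics import gof_summary

        return gof_summary(self.fitted, self.model.data, etas=self.raw.etas)

    def vpc(self, n_reps: int = 500, seed: int = 0, n_bins: int = 8):
        """Prediction-corrected visual predictive check."""
        from .diagnostics import pc_vpc

        return pc_vpc(self.fitted, self.model.data, n_reps=n_reps, seed=seed,
                      n_bins=n_bins)

    # -- exposures ----------------------------------------------------------
    def exposures(self, tau: float = 8.0) -> pd.DataFrame:
        """Secondary exposure metrics from the post hoc parameters."""
        data = self.model.data
        doses = pd.DataFrame({
            "ID": data.ids[data.d_sub],
            "TIME": data.d_start,
            "AMT": data.d_amt,
            "DUR": data.d_dur,
        })
        return expo.derive_exposures(self.posthoc(), doses, tau=tau)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        """Parameter table: estimate, %SEM, IIV %CV, shrinkage %."""
        th = self.fitted.theta
        se = self.raw.se
        cv = self.fitted.omega_cv()
        lines = [
            f"Population PK fit ({self.fitted.drug}) — "
            f"{self.raw.n_subjects} subjects, {self.raw.n_obs} observations",
            f"OFV {self.ofv:.3f}   AIC {self.aic:.3f}   "
            f"converged: {self.converged}",
            "",
            f"{'Parameter':<24}{'Estimate':>12}{'%SEM':>9}",
            "-" * 45,
        ]

        def sem(name, value):
            if name in se and value:
                return f"{100.0 * se[name] / abs(value):.3g}"
            return "fixed" if name in self.fitted.fixed else "-"

        for name in th:
            mark = " (fixed)" if name in self.fitted.fixed else ""
            lines.append(
                f"{name + mark:<24}{th[name]:>12.4g}{sem(name, th[name]):>9}"
            )
        lines.append("")
        lines.append(f"{'IIV':<24}{'%CV':>12}{'shrink%':>9}")
        lines.append("-" * 45)
        for nm in self.fitted.eta_names:
            sh = self.raw.shrinkage.get(nm)
            lines.append(
                f"eta_{nm:<20}{cv[nm]:>12.1f}"
                f"{(f'{sh:.1f}' if sh is not None else '-'):>9}"
            )
        lines.append("")
        lines.append(f"{'Residual error':<24}{'prop var':>12}{'add var':>9}")
        lines.append("-" * 45)
        for m, (p, a) in self.fitted.sigma.items():
            lines.append(f"{m:<24}{p:>12.4g}{a:>9.4g}")
        return "\n".join(lines)

    def parameter_table(self) -> pd.DataFrame:
        """Machine-readable version of :meth:`summary`."""
        th = self.fitted.theta
        se = self.raw.se
        rows = []
        for name, val in th.items():
            rows.append({
                "parameter": name,
                "estimate": val,
                "pct_sem": 100.0 * se[name] / abs(val)
                if name in se and val else np.nan,
                "fixed": name in self.fitted.fixed,
            })
        for i, nm in enumerate(self.fitted.eta_names):
            rows.append({
                "parameter": f"iiv_cv_{nm}",
                "estimate": omega_to_cv_percent(self.fitted.omega[i, i]),
                "pct_sem": np.nan,
                "fixed": False,
                "shrinkage_pct": self.raw.shrinkage.get(nm, np.nan),
            })
        for m, (p, a) in self.fitted.sigma.items():
            rows.append({"parameter": f"sigma_{m}_prop", "estimate": p})
            rows.append({"parameter": f"sigma_{m}_add", "estimate": a})
        return pd.DataFrame(rows)
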