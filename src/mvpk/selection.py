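"""Covariate screening and stepwise forward-selection / backward-elimination.

Candidate parameter-covariate relationships (power functions normalized to
reference values for continuous covariates, proportional ``1 + θ·I`` shifts
for indicators) are screened by associating individual post hoc deviations
with covariates, then included or dropped on likelihood-ratio grounds: a
candidate enters if it reduces the objective function by at least 3.85
units (α = 0.05, 1 df; only the most significant candidate per step) and
survives backward elimination if its removal raises the objective by at
least 6.635 units (χ² 0.99, 1 df).  Screening is advisory only; inclusion
decisions rest solely on the objective-function change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, mannwhitneyu

from . import estimation as est
from .estimation import PKData
from .popmodel import CovariateEffect, PopulationModel

__all__ = [
    "FORWARD_DELTA",
    "BACKWARD_DELTA",
    "CandidateRelation",
    "screen",
    "forward_step",
    "backward_step",
    "stepwise",
]

#: minimum OFV reduction for forward inclusion (α = 0.05, 1 df)
FORWARD_DELTA = 3.85
#: minimum OFV increase on removal for backward retention (χ²_{0.99,1})
BACKWARD_DELTA = 6.635


@dataclass(frozen=True)
class CandidateRelation:
    """A candidate effect plus its selection status and OFV bookkeeping."""

    effect: CovariateEffect
    status: str = "candidate"  # candidate | included | eliminated
    delta_ofv: float = float("nan")

    @property
    def name(self) -> str:
        e = self.effect
        return f"{e.covariate}->{e.parameter}({e.form})"


def _eta_matrix(fit: est.FitResult) -> tuple[np.ndarray, list[str]]:
    return fit.etas, list(fit.model.eta_names)


def screen(fit: est.FitResult, covariates: pd.DataFrame,
           covariate_names=None) -> pd.DataFrame:
    """Rank (parameter, covariate) pairs by post hoc deviation association.

    Individual deviations (the post hoc etas, i.e. log individual minus log
    typical parameter) are associated with each covariate: Spearman rank
    correlation for continuous covariates, a rank-biserial location shift
    for binary ones.  Returns a frame sorted by |score| descending.
    """
    etas, pnames = _eta_matrix(fit)
    if etas.shape[0] < 2:
        raise ValueError("screening needs at least two subjects")
    names = covariate_names or [
        c for c in covariates.columns
        if covariates[c].dtype.kind in "fi" and c not in ("ID",)
    ]
    rows = []
    for cname in names:
        x = covariates[cname].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            rows.append({"covariate": cname, "parameter": None,
                         "score": np.nan, "note": "constant; skipped"})
            continue
        binary = np.unique(x).size == 2
        for j, p in enumerate(pnames):
            y = etas[:, j]
            if binary:
                lo, hi = np.unique(x)
                a, b = y[x == lo], y[x == hi]
                if len(a) == 0 or len(b) == 0:
                    score = np.nan
                else:
                    u = mannwhitneyu(a, b).statistic
                    score = 2.0 * u / (len(a) * len(b)) - 1.0  # rank-biserial
            else:
                score = spearmanr(x, y).statistic
            rows.append({"covariate": cname, "parameter": p,
                         "score": score, "note": ""})
    out = pd.DataFrame(rows)
    return out.reindex(
        out["score"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def _with_candidate(model: PopulationModel, cand: CandidateRelation,
                    init: float = 0.0) -> PopulationModel:
    th = dict(model.theta)
    th.setdefault(cand.effect.theta_name, init)
    return replace(model, theta=th, effects=model.effects + (cand.effect,))


def _without_effect(model: PopulationModel,
                    eff: CovariateEffect) -> PopulationModel:
    th = {k: v for k, v in model.theta.items() if k != eff.theta_name}
    effects = tuple(e for e in model.effects if e is not eff)
    return replace(model, theta=th, effects=effects)


def _try_fit(model, data, fit_kwargs):
    try:
        return est.fit(model, data, **fit_kwargs)
    except Exception as exc:  # non-convergent candidate: skip, log
        warnings.warn(f"candidate fit failed ({exc}); skipped", stacklevel=2)
        return None


def forward_step(model: PopulationModel, table,
                 candidates: list[CandidateRelation],
                 base_ofv: float | None = None,
                 **fit_kwargs):
    """Try each candidate singly; return (best updated model or None, record).

    The best candidate is included only if its OFV drop is >= 3.85.
    ``record`` maps candidate names to their OFV drops.
    """
    data = table if isinstance(table, PKData) else PKData(table)
    if base_ofv is None:
        base = est.fit(model, data, **fit_kwargs)
        base_ofv = base.ofv
    drops: dict[str, float] = {}
    best = None
    for cand in candidates:
        trial = _with_candidate(model, cand)
        res = _try_fit(trial, data, fit_kwargs)
        if res is None:
            continue
        drop = base_ofv - res.ofv
        drops[cand.name] = drop
        if drop >= FORWARD_DELTA and (best is None or drop > drops[best[0].name]):
            best = (cand, res)
    if best is None:
        return None, drops
    cand, res = best
    included = replace(cand, status="included", delta_ofv=drops[cand.name])
    return (res.model, included, res.ofv), drops


def backward_step(model: PopulationModel, table,
                  removable: tuple[CovariateEffect, ...] | None = None,
                  base_ofv: float | None = None,
                  **fit_kwargs):
    """Try removing each relation singly; eliminate the least supported.

    The relation whose removal increases the OFV least is eliminated if
    that increase is below 6.635; otherwise all are retained and
    ``(None, record)`` is returned.
    """
    data = table if isinstance(table, PKData) else PKData(table)
    removable = model.effects if removable is None else removable
    if not removable:
        return None, {}
    if base_ofv is None:
        base = est.fit(model, data, **fit_kwargs)
        base_ofv = base.ofv
    rises: dict[str, float] = {}
    best = None
    for eff in removable:
        trial = _without_effect(model, eff)
        res = _try_fit(trial, data, fit_kwargs)
        if res is None:
            continue
        rise = res.ofv - base_ofv
        key = f"{eff.covariate}->{eff.parameter}({eff.form})"
        rises[key] = rise
        if rise < BACKWARD_DELTA and (best is None or rise < best[2]):
            best = (eff, res, rise)
    if best is None:
        return None, rises
    eff, res, rise = best
    return (res.model, eff, res.ofv), rises


def stepwise(model0: PopulationModel, table,
             candidates: list[CandidateRelation],
             max_steps: int = 20, **fit_kwargs):
    """Full forward selection followed by backward elimination.

    Returns ``(final_model, audit)`` where ``audit`` is a DataFrame with one
    row per evaluated step (action, relation, delta OFV, decision).  Halts
    with a report if a relation cycles (added then removed then re-added).
    """
    data = table if isinstance(table, PKData) else PKData(table)
    base = est.fit(model0, data, **fit_kwargs)
    model, ofv = base.model, base.ofv
    pool = list(candidates)
    audit: list[dict] = []
    seen_actions: set[tuple[str, str]] = set()

    for _ in range(max_steps):
        if not pool:
            break
        step, drops = forward_step(model, data, pool, base_ofv=ofv,
                                   **fit_kwargs)
        for nm, d in drops.items():
            audit.append({"phase": "forward", "relation": nm,
                          "delta_ofv": d, "decision": "evaluated"})
        if step is None:
            break
        model, included, ofv = step
        key = ("add", included.name)
        if key in seen_actions:
            audit.append({"phase": "forward", "relation": included.name,
                          "delta_ofv": included.delta_ofv,
                          "decision": "cycle detected; halted"})
            break
        seen_actions.add(key)
        audit.append({"phase": "forward", "relation": included.name,
                      "delta_ofv": included.delta_ofv, "decision": "included"})
        pool = [c for c in pool if c.name != included.name]

    added = tuple(e for e in model.effects if e not in model0.effects)
    for _ in range(max_steps):
        if not added:
            break
        step, rises = backward_step(model, data, removable=added,
                                    base_ofv=ofv, **fit_kwargs)
        for nm, r in rises.items():
            audit.append({"phase": "backward", "relation": nm,
                          "delta_ofv": r, "decision": "evaluated"})
        if step is None:
            for nm in rises:
                audit.append({"phase": "backward", "relation": nm,
                              "delta_ofv": rises[nm], "decision": "retained"})
            break
        model, eliminated, ofv = step
        nm = f"{eliminated.covariate}->{eliminated.parameter}({eliminated.form})"
        audit.append({"phase": "backward", "relation": nm,
                      "delta_ofv": rises[nm], "decision": "eliminated"})
        added = tuple(e for e in added if e is not eliminated)

    return model, pd.DataFrame(audit)
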