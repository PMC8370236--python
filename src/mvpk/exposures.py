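"""Secondary exposure metrics from post hoc parameters.

For each subject the individual concentration-time profile implied by the
empirical-Bayes parameters and the actual dosing history yields: Cmax over
the first dosing interval, the day-1 AUC over 0-24 h, the steady-state
AUC over 0-24 h (3 × dose/CL for q8h dosing, reported only for subjects
who received at least three doses), and the alpha/beta half-lives from the
disposition eigenvalues.  Population summaries are geometric mean with
geometric %CV; implausible terminal half-lives above a cap are excluded
from summaries but always reported.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .pkcore import (
    DoseEvent,
    StructuralParams,
    auc,
    cmax_first_interval,
    macro_constants,
)

__all__ = [
    "derive_exposures",
    "geo_summary",
    "exclusion_screen",
    "summarize_exposures",
    "exposures_by_group",
]


def derive_exposures(params: pd.DataFrame, doses: pd.DataFrame,
                     tau: float = 8.0) -> pd.DataFrame:
    """Per-subject exposure metrics.

    Parameters
    ----------
    params : DataFrame
        Post hoc parameters with columns ID, CL, Vc, CLd, Vp and optionally
        CL_R/CL_NR (as produced by the fit results' ``posthoc()``).
    doses : DataFrame
        Dosing history with columns ID, TIME (infusion start, h), AMT (mg)
        and DUR (h).
    tau : float
        Dosing interval (h) defining the first-interval Cmax window and the
        steady-state accumulation factor (24/tau doses per day).

    Returns one row per subject: cmax, auc24_day1, auc24_ss (NaN when fewer
    than three doses were received), t_half_alpha, t_half_beta, CL, n_doses.
    """
    per_day = 24.0 / tau
    rows = []
    for sid, g in doses.groupby("ID", sort=False):
        prow = params.loc[params["ID"] == sid]
        if prow.empty:
            continue
        prow = prow.iloc[0]
        cl = float(prow["CL"])
        cl_r = float(prow["CL_R"]) if "CL_R" in prow else 0.0
        p = StructuralParams(
            CL_R=cl_r, CL_NR=cl - cl_r, Vc=float(prow["Vc"]),
            CLd=float(prow["CLd"]), Vp=float(prow["Vp"]),
        )
        evs = [
            DoseEvent(start_time=float(r.TIME), amount=float(r.AMT),
                      duration=float(r.DUR))
            for r in g.itertuples()
        ]
        n_doses = len(evs)
        amt = float(np.median([e.amount for e in evs]))
        mc = macro_constants(p)
        rows.append({
            "ID": sid,
            "cmax": cmax_first_interval(p, evs, tau),
            "auc24_day1": auc(p, evs, 0.0, 24.0),
            "auc24_ss": per_day * amt / cl if n_doses >= 3 else np.nan,
            "t_half_alpha": mc.t_half_alpha,
            "t_half_beta": mc.t_half_beta,
            "CL": cl,
            "n_doses": n_doses,
        })
    return pd.DataFrame(rows)


def geo_summary(values) -> tuple[float, float]:
    """Geometric mean and geometric %CV (sample variance, n-1).

    Nonpositive values are excluded (they have no logarithm) and reported
    via a warning-free count drop; gm = exp(mean ln x),
    g%CV = 100·sqrt(exp(var ln x) − 1).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = x[x > 0]
    if x.size == 0:
        return float("nan"), float("nan")
    lx = np.log(x)
    gm = float(np.exp(lx.mean()))
    if x.size == 1:
        return gm, 0.0
    gcv = float(100.0 * math.sqrt(math.expm1(lx.var(ddof=1))))
    return gm, gcv


def exclusion_screen(records: pd.DataFrame, t_half_cap: float = 24.0):
    """Flag terminal half-lives above ``t_half_cap`` hours.

    Returns ``(filtered, report)``: the filtered frame has the offending
    ``t_half_beta`` blanked (never a silently dropped row); the report
    lists every excluded value.
    """
    if not t_half_cap > 0:
        raise ValueError("t_half_cap must be > 0")
    out = records.copy()
    mask = out["t_half_beta"] > t_half_cap
    report = out.loc[mask, ["ID", "t_half_beta"]].copy()
    report["reason"] = f"t_half_beta > {t_half_cap} h"
    out.loc[mask, "t_half_beta"] = np.nan
    return out, report


_METRICS = ("cmax", "auc24_day1", "auc24_ss", "CL", "t_half_alpha",
            "t_half_beta")


def summarize_exposures(records: pd.DataFrame, by=None) -> pd.DataFrame:
    """Geometric mean (g%CV) per metric, optionally per group column."""
    groups = [("pooled", records)] if by is None else list(records.groupby(by))
    rows = []
    for name, g in groups:
        row: dict = {"group": name, "n": len(g)}
        for m in _METRICS:
            if m in g:
                gm, gcv = geo_summary(g[m])
                row[m] = gm
                row[f"{m}_gcv"] = gcv
        rows.append(row)
    return pd.DataFrame(rows)


def exposures_by_group(records: pd.DataFrame,
                       covariates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive exposure summaries across covariate groups.

    Groups: eGFR band, weight quartile, age decade, sex, race — a tabular
    stand-in for covariate-vs-exposure review plots.
    """
    df = records.merge(covariates, on="ID", how="left")
    out = {}
    if "EGFR" in df:
        df["egfr_band"] = pd.cut(
            df["EGFR"], [0, 15, 30, 60, 90, np.inf],
            labels=["<15", "15-30", "30-60", "60-90", ">90"],
        )
        out["egfr_band"] = summarize_exposures(df, "egfr_band")
    if "WTKG" in df:
        df["weight_q"] = pd.qcut(df["WTKG"], 4, duplicates="drop")
        out["weight_quartile"] = summarize_exposures(df, "weight_q")
    if "AGE" in df:
        df["age_decade"] = (df["AGE"] // 10 * 10).astype(int)
        out["age_decade"] = summarize_exposures(df, "age_decade")
    for c in ("SEX", "RACE"):
        if c in df:
            out[c.lower()] = summarize_exposures(df, c)
    return out
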