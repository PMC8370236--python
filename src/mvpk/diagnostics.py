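"""Goodness-of-fit summaries and the prediction-corrected VPC.

The visual predictive check simulates many replicate datasets on the
original design and compares the observed 5th/50th/95th percentile curves
of plasma concentration with the 90% prediction intervals of the same
percentiles across replicates.  Because dosing and covariates are
heterogeneous, observed and simulated values are first prediction-corrected:
each value is rescaled by the ratio of the bin's median population
prediction to the record's own population prediction, which collapses the
data onto one plot.  Binning is quantile-based on time after the most
recent dose.  BLQ records are excluded from the percentile curves and
reported as a per-bin BLQ fraction instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import PKData, LaplaceFitter
from .popmodel import PopulationModel

__all__ = ["VpcResult", "gof_summary", "pc_vpc", "bin_times"]

_PCTS = (5.0, 50.0, 95.0)


def _as_data(table) -> PKData:
    return table if isinstance(table, PKData) else PKData(table)


def _population_pred(model: PopulationModel, data: PKData) -> np.ndarray:
    cl_r, cl_nr, vc, cld, vp = (
        np.asarray(a, dtype=float) * np.ones(data.n_sub)
        for a in model.typical_arrays(data.covs)
    )
    plasma, _ = data.predict(cl_r, cl_nr, vc, cld, vp)
    return plasma


def _individual_pred(model: PopulationModel, data: PKData,
                     etas: np.ndarray) -> np.ndarray:
    cl_r, cl_nr, vc, cld, vp = (
        np.asarray(a, dtype=float) * np.ones(data.n_sub)
        for a in model.typical_arrays(data.covs)
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
    plasma, _ = data.predict(cl_r, cl_nr, vc, cld, vp)
    return plasma


def time_after_last_dose(data: PKData) -> np.ndarray:
    """Time from each plasma observation to its most recent dose start."""
    last = np.full(data.n_obs, -np.inf)
    if len(data.po_idx):
        np.maximum.at(last, data.po_idx, data.d_start[data.pd_idx])
    return data.o_t - last  # inf where no prior dose exists


def bin_times(times, n_bins: int = 8) -> np.ndarray:
    """Quantile-based bin edges over observation times.

    Returns at most ``n_bins`` bins; fewer when there are fewer distinct
    times.  Edges are unique and span the data.
    """
    times = np.asarray(times, dtype=float)
    times = times[np.isfinite(times)]
    if times.size == 0:
        raise ValueError("need at least one observation time")
    uniq = np.unique(times)
    n_bins = min(n_bins, len(uniq))
    if n_bins <= 1:
        lo, hi = uniq[0], uniq[-1]
        return np.array([lo - 1e-9, hi + 1e-9])
    edges = np.quantile(times, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def gof_summary(model: PopulationModel, table, etas=None) -> dict:
    """Residual tables and the r² of observed vs individual-fitted values.

    Returns a dict with ``table`` (per-observation DV, PRED, IPRED,
    residuals, weighted residuals, time after dose) and ``r2``.
    """
    data = _as_data(table)
    if etas is None:
        etas = LaplaceFitter(data, model).posthoc()
    pred = _population_pred(model, data)
    ipred = _individual_pred(model, data, etas)
    s2p, s2a = model.sigma["plasma"]
    sd = np.sqrt(ipred * ipred * s2p + s2a)
    q = ~data.o_blq & np.isfinite(data.o_dv)
    frame = pd.DataFrame({
        "ID": data.ids[data.o_sub],
        "TIME": data.o_t,
        "TALD": time_after_last_dose(data),
        "DV": data.o_dv,
        "PRED": pred,
        "IPRED": ipred,
        "RES": data.o_dv - pred,
        "IRES": data.o_dv - ipred,
        "IWRES": (data.o_dv - ipred) / np.maximum(sd, 1e-12),
        "BLQ": data.o_blq.astype(int),
    })
    dv, ip = data.o_dv[q], ipred[q]
    if dv.size >= 2 and np.std(dv) > 0 and np.std(ip) > 0:
        r2 = float(np.corrcoef(dv, ip)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return {"table": frame, "r2": r2}


@dataclass
class VpcResult:
    """Prediction-corrected VPC curves and simulation bands.

    ``obs`` holds the observed prediction-corrected percentile per bin
    (rows: 5th/50th/95th); ``band_lo``/``band_hi`` the 90% prediction
    interval of each percentile across replicates; ``sim_med`` the median
    of each simulated percentile.
    """

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    obs: np.ndarray        # (3, n_bins)
    band_lo: np.ndarray    # (3, n_bins)
    band_hi: np.ndarray    # (3, n_bins)
    sim_med: np.ndarray    # (3, n_bins)
    blq_frac: np.ndarray   # (n_bins,)
    n_reps: int
    seed: int

    @property
    def percentiles(self) -> tuple[float, ...]:
        return _PCTS

    def coverage(self) -> float:
        """Fraction of (percentile, bin) cells with the observed curve
        inside its 90% simulation band."""
        inside = (self.obs >= self.band_lo) & (self.obs <= self.band_hi)
        return float(inside.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(_PCTS):
            for b in range(len(self.bin_mid)):
                rows.append({
                    "percentile": p, "bin_mid": self.bin_mid[b],
                    "bin_lo": self.bin_edges[b],
                    "bin_hi": self.bin_edges[b + 1],
                    "n_obs": self.n_per_bin[b],
                    "observed": self.obs[i, b],
                    "band_lo": self.band_lo[i, b],
                    "band_hi": self.band_hi[i, b],
                    "simulated_median": self.sim_med[i, b],
                    "blq_frac": self.blq_frac[b],
                })
        return pd.DataFrame(rows)

    def plot(self, path=None, ax=None):
        """Observed percentile curves over the simulated 90% bands."""
        import matplotlib
        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(7, 4.5))
        else:
            fig = ax.figure
        colors = ["tab:blue", "tab:red", "tab:blue"]
        styles = ["--", "-", "--"]
        for i, p in enumerate(_PCTS):
            ax.fill_between(self.bin_mid, self.band_lo[i], self.band_hi[i],
                            color=colors[i], alpha=0.25, linewidth=0)
            ax.plot(self.bin_mid, self.sim_med[i], color=colors[i],
                    linewidth=1)
            ax.plot(self.bin_mid, self.obs[i], styles[i], color="black",
                    label=f"observed {p:g}th")
        ax.set_xlabel("time after last dose (h)")
        ax.set_ylabel("prediction-corrected concentration (mg/L)")
        ax.set_yscale("log")
        ax.legend(frameon=False, fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax


def _binned_percentiles(values, bins, n_bins) -> np.ndarray:
    out = np.full((len(_PCTS), n_bins), np.nan)
    for b in range(n_bins):
        v = values[bins == b]
        if v.size:
            out[:, b] = np.percentile(v, _PCTS)
    return out


def pc_vpc(model: PopulationModel, table, n_reps: int = 500, seed: int = 0,
           n_bins: int = 8) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Deterministic given ``(model, table, n_reps, seed)``.  Bins with no
    quantified observations are merged into their left neighbour.
    """
    from .synthdata import resimulate_plasma

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for stable bands")
    data = _as_data(table)
    pred = _population_pred(model, data)
    tald = time_after_last_dose(data)
    usable = np.isfinite(tald) & (pred > 1e-12)
    q_obs = usable & ~data.o_blq & np.isfinite(data.o_dv)

    edges = bin_times(tald[usable], n_bins)
    bins_all = np.clip(np.searchsorted(edges, tald, side="right") - 1,
                       0, len(edges) - 2)
    # merge bins that contain no quantified observations
    keep = []
    for b in range(len(edges) - 1):
        if np.any(q_obs & (bins_all == b)) or not keep:
            keep.append(b)
    if len(keep) < len(edges) - 1:
        mapping = np.zeros(len(edges) - 1, dtype=int)
        for b in range(len(edges) - 1):
            mapping[b] = max(i for i, kb in enumerate(keep) if kb <= b)
        bins_all = mapping[bins_all]
        edges = np.concatenate([[edges[0]], [edges[k + 1] for k in
                                             range(len(edges) - 1)
                                             if k in keep]])
    nb = len(edges) - 1

    # per-bin median population prediction over usable records
    med_pred = np.ones(nb)
    for b in range(nb):
        m = usable & (bins_all == b)
        if np.any(m):
            med_pred[b] = np.median(pred[m])
    corr = np.where(usable, med_pred[bins_all] / np.maximum(pred, 1e-12), 1.0)

    obs = _binned_percentiles((data.o_dv * corr)[q_obs], bins_all[q_obs], nb)
    n_per_bin = np.array([(q_obs & (bins_all == b)).sum() for b in range(nb)])
    blq_frac = np.array([
        float(np.mean(data.o_blq[usable & (bins_all == b)]))
        if np.any(usable & (bins_all == b)) else np.nan
        for b in range(nb)
    ])

    rng = np.random.default_rng(seed)
    sim = np.full((n_reps, len(_PCTS), nb), np.nan)
    for r in range(n_reps):
        dv, blq = resimulate_plasma(data, model, rng)
        m = usable & ~blq
        sim[r] = _binned_percentiles((dv * corr)[m], bins_all[m], nb)
    band_lo = np.nanpercentile(sim, 5.0, axis=0)
    band_hi = np.nanpercentile(sim, 95.0, axis=0)
    sim_med = np.nanpercentile(sim, 50.0, axis=0)

    mids = 0.5 * (edges[:-1] + edges[1:])
    return VpcResult(
        bin_edges=edges, bin_mid=mids, n_per_bin=n_per_bin, obs=obs,
        band_lo=band_lo, band_hi=band_hi, sim_med=sim_med,
        blq_frac=blq_frac, n_reps=n_reps, seed=int(seed),
    )
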