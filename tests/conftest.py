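import numpy as np
import pandas as pd
import pytest

from mvpk import StructuralParams, load_model
from mvpk.popmodel import PopulationModel


@pytest.fixture(scope="session")
def mero_model():
    return load_model("meropenem")


@pytest.fixture(scope="session")
def vab_model():
    return load_model("vaborbactam")


@pytest.fixture(scope="session")
def typical_mero():
    """Typical meropenem parameters at eGFR 100, reference body size/age."""
    return StructuralParams(CL_R=5.636, CL_NR=3.85, Vc=17.0, CLd=1.36, Vp=2.32)


@pytest.fixture
def rng():
    return np.random.default_rng(20260131)


def random_params(rng, n):
    """Random but physiologic two-compartment parameter draws."""
    out = []
    for _ in range(n):
        out.append(StructuralParams(
            CL_R=float(rng.uniform(0.0, 12.0)),
            CL_NR=float(rng.uniform(0.2, 6.0)),
            Vc=float(rng.uniform(5.0, 40.0)),
            CLd=float(rng.uniform(0.0, 6.0)),
            Vp=float(rng.uniform(0.5, 20.0)),
        ))
    return out


def single_subject_frame(times, dv=None, blq=None, lloq=0.02, dose_amt=1000.0,
                         dose_dur=1.0, dose_times=(0.0,), urine=None,
                         **covs) -> pd.DataFrame:
    """Minimal one-subject event table for toy likelihood problems."""
    rows = []
    base = {"AGE": covs.get("age", 50.0), "WTKG": covs.get("weight", 75.0),
            "HTCM": covs.get("height", 168.0), "SEX": covs.get("sex", 0),
            "RACE": covs.get("race", 0), "SCR": covs.get("scr", 1.0),
            "PHASE": covs.get("phase", 3)}
    for t0 in dose_times:
        rows.append({"ID": 1, "TIME": t0, "AMT": dose_amt,
                     "RATE": dose_amt / dose_dur, "EVID": 1, "CMT": 1,
                     "DV": np.nan, "BLQ": 0, "LLOQ": lloq, "MDV": 1,
                     "URINEVOL": np.nan, **base})
    for i, t in enumerate(times):
        is_blq = bool(blq[i]) if blq is not None else False
        rows.append({"ID": 1, "TIME": t, "AMT": np.nan, "RATE": np.nan,
                     "EVID": 0, "CMT": 1,
                     "DV": np.nan if is_blq or dv is None else dv[i],
                     "BLQ": int(is_blq), "LLOQ": lloq, "MDV": 0,
                     "URINEVOL": np.nan, **base})
    if urine:
        for t, dvu, vol in urine:
            rows.append({"ID": 1, "TIME": t, "AMT": np.nan, "RATE": np.nan,
                         "EVID": 0, "CMT": 2, "DV": dvu, "BLQ": 0,
                         "LLOQ": lloq, "MDV": 0, "URINEVOL": vol, **base})
    df = pd.DataFrame(rows).sort_values(["TIME", "EVID"],
                                        ascending=[True, False])
    return df.reset_index(drop=True)


def plain_model(cl=8.0, vc=20.0, cld=0.0, vp=1.0, cv_cl=30.0,
                sigma=(0.02, 1e-4), eta_names=("CL",),
                effects=(), extra_theta=None) -> PopulationModel:
    """Covariate-free population model for toy experiments."""
    from mvpk.popmodel import cv_percent_to_omega

    theta = {"cl": cl, "vc": vc, "cld": cld, "vp": vp}
    if extra_theta:
        theta.update(extra_theta)
    k = len(eta_names)
    omega = np.eye(k) * cv_percent_to_omega(cv_cl)
    return PopulationModel(
        drug="plain", theta=theta, omega=omega,
        sigma={"plasma": tuple(sigma)}, eta_names=tuple(eta_names),
        effects=tuple(effects),
    )
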