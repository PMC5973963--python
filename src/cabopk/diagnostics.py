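"""Goodness-of-fit summaries, eta-by-covariate summaries, and the posterior
predictive check (smoothed parametric bootstrap).

The PPC draws replicate population-parameter vectors from the multivariate
normal sampling distribution of the estimates (on the transformed scale),
simulates a replicate dataset per draw that preserves the study design,
sample size and covariates of the observed data, computes the median and
10th/90th percentile of concentration at each nominal time, and summarises
each statistic's simulated distribution by its 5th/95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, _SubjectModel, prepare_subjects
from .population_model import _as_rng
from .synthetic_data import PKDataset, resimulate

__all__ = ["GofTable", "PpcResult", "gof_summary", "eta_by_covariate",
           "posterior_predictive_check"]


@dataclass
class GofTable:
    """Per-observation predictions and per-group geometric means.

    ``records``: DV, PRED (eta = 0), IPRED (MAP eta) and IWRES per non-BLQ
    observation.  ``group_summary``: geometric means of DV, PRED and IPRED
    per study and nominal time.
    """

    records: pd.DataFrame
    group_summary: pd.DataFrame


def gof_summary(fit: FitResult, ds: PKDataset) -> GofTable:
    """Standard goodness-of-fit table: typical (PRED) and individual (IPRED)
    predictions with individual weighted residuals on the log scale."""
    subjects = prepare_subjects(ds)
    sigma = np.sqrt(max(fit.residual.sigma2, 1e-12))
    rows = []
    for subj in subjects:
        if subj.sid not in fit.map_etas:
            raise KeyError(f"subject {subj.sid} absent from the fit's MAP etas")
        model = _SubjectModel(subj, fit.theta)
        pred = model.predict(np.zeros(4))
        ipred = model.predict(np.asarray(fit.map_etas[subj.sid]))
        dv = np.exp(subj.log_dv)
        with np.errstate(divide="ignore"):
            iwres = (subj.log_dv - np.log(ipred)) / sigma
        for t, d, p, ip, iw in zip(subj.obs_times, dv, pred, ipred, iwres):
            rows.append({"ID": subj.sid, "STUDY": None, "TIME": t, "DV": d,
                         "PRED": p, "IPRED": ip, "IWRES": iw})
    records = pd.DataFrame(rows)
    study_map = (
        ds.df[ds.df["EVID"] == 0].groupby("ID")["STUDY"].first().to_dict()
    )
    records["STUDY"] = records["ID"].map(study_map)

    def gmean(x):
        x = np.asarray(x, dtype=float)
        x = x[x > 0]
        return float(np.exp(np.mean(np.log(x)))) if len(x) else np.nan

    group_summary = (
        records.groupby(["STUDY", "TIME"])
        .agg(n=("DV", "size"), dv_gmean=("DV", gmean),
             pred_gmean=("PRED", gmean), ipred_gmean=("IPRED", gmean))
        .reset_index()
    )
    return GofTable(records=records, group_summary=group_summary)


def eta_by_covariate(fit: FitResult, ds: PKDataset, covariate: str,
                     eta: str = "cl") -> pd.DataFrame:
    """Summaries of MAP eta per covariate level (median, quartiles, 5th/95th
    percentiles).  A continuous covariate is binned by quartiles and the bin
    edges are reported in the level labels."""
    from .population_model import ETA_LABELS

    obs = ds.df[ds.df["EVID"] == 0]
    if covariate not in obs.columns:
        raise KeyError(f"covariate {covariate!r} not in dataset")
    per_subject = obs.groupby("ID").first()
    j = ETA_LABELS.index(eta)
    etas = {sid: vec[j] for sid, vec in fit.map_etas.items()}
    tbl = per_subject[[covariate]].copy()
    tbl["eta"] = [etas.get(sid, np.nan) for sid in per_subject.index]
    tbl = tbl.dropna(subset=["eta"])

    values = tbl[covariate]
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 8:
        binned = pd.qcut(values, q=4, duplicates="drop")
        tbl["level"] = binned.astype(str)
    else:
        tbl["level"] = values.astype(str)

    def q(p):
        return lambda x: float(np.percentile(x, p))

    out = (
        tbl.groupby("level")["eta"]
        .agg(n="size", median="median", q25=q(25), q75=q(75), p5=q(5), p95=q(95))
        .reset_index()
    )
    return out


@dataclass
class PpcResult:
    """Observed PPC statistics per nominal time with their simulated 90%
    prediction intervals (5th/95th percentiles across replicates)."""

    table: pd.DataFrame
    n_rep: int
    n_rejected: int

    def coverage(self, stat: str = "median") -> float:
        """Fraction of nominal times where the observed statistic lies
        inside its 90% prediction interval."""
        t = self.table.dropna(subset=[f"{stat}_lo", f"{stat}_hi"])
        inside = (t[f"obs_{stat}"] >= t[f"{stat}_lo"]) & (
            t[f"obs_{stat}"] <= t[f"{stat}_hi"]
        )
        return float(inside.mean())


_STATS = ("median", "p10", "p90")


def _group_stats(ds: PKDataset) -> pd.DataFrame:
    obs = ds.estimation_view()
    return (
        obs.groupby(["STUDY", "TIME"])["DV"]
        .agg(median="median",
             p10=lambda x: np.percentile(x, 10),
             p90=lambda x: np.percentile(x, 90))
        .reset_index()
    )


def posterior_predictive_check(
    fit: FitResult,
    data: PKDataset,
    n_rep: int = 500,
    seed=None,
) -> PpcResult:
    """Smoothed parametric bootstrap predictive check.

    For each of ``n_rep`` replicates a population parameter vector is drawn
    from the estimate's sampling distribution (requires the fit to carry a
    parameter covariance), the observed dataset's design and covariates are
    re-simulated, and the median/10th/90th percentile of concentration per
    study and nominal time are recorded.  Draws violating parameter
    invariants are rejected and redrawn (count reported).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if fit.cov is None:
        raise ValueError(
            "fit carries no parameter covariance; refit with compute_cov=True"
        )
    rng = _as_rng(seed)
    observed = _group_stats(data).set_index(["STUDY", "TIME"])
    sims = {s: [] for s in _STATS}
    n_rejected = 0
    for _ in range(n_rep):
        th, om, rm, rej = fit.draw_parameters(rng)
        n_rejected += rej
        rep = resimulate(data, th, om, rm, rng)
        stats_r = _group_stats(rep).set_index(["STUDY", "TIME"])
        stats_r = stats_r.reindex(observed.index)
        for s in _STATS:
            sims[s].append(stats_r[s].to_numpy())

    out = observed.rename(columns={s: f"obs_{s}" for s in _STATS}).reset_index()
    for s in _STATS:
        arr = np.vstack(sims[s])
        with np.errstate(invalid="ignore"):
            out[f"{s}_lo"] = np.nanpercentile(arr, 5, axis=0)
            out[f"{s}_hi"] = np.nanpercentile(arr, 95, axis=0)
    return PpcResult(table=out, n_rep=n_rep, n_rejected=n_rejected)
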