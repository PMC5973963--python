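"""Virtual pooled multi-study PK datasets.

Generates NONMEM-style long-format datasets that emulate the pooled
nine-study cabozantinib design: per-study sample sizes, doses, formulations
and planned PK sampling schedules, and per-study demographic distributions
(sex and race proportions, truncated-normal age and weight).  Observations
are simulated from the full model — covariates -> typical parameters ->
log-normal IIV -> concentration profile -> log-additive residual error —
with values below the 0.5 ng/mL LLOQ flagged BLQ and excluded from the
estimation view (but retained in the file).

Notes on the shipped suite: the crossover bioequivalence study is encoded as
a tablet dose at t = 0 and a capsule dose after a 672-h washout; the
randomized-discontinuation arm samples pre-dose at even weeks 14-24; the
renal-cell study samples ~12 h after the preceding daily dose on days 29 and
57.  Race proportions are renormalized over the four known levels where the
source tables carry a not-available category.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariate_model import CovariateSet, ThetaVector, typical_absorption, typical_disposition
from .population_model import (
    OmegaMatrix,
    ResidualModel,
    apply_iiv,
    draw_etas,
    individual_model_params,
    _as_rng,
)
from .structural_pk import DoseEvent, Regimen, conc_profile

__all__ = [
    "LLOQ",
    "DemographicSpec",
    "Arm",
    "StudySpec",
    "PKDataset",
    "DatasetValidationError",
    "default_study_suite",
    "build_virtual_population",
    "simulate_dataset",
    "resimulate",
    "read_dataset",
    "write_dataset",
]

#: lower limit of quantification, ng/mL
LLOQ = 0.5

DATASET_COLUMNS = [
    "ID", "STUDY", "TIME", "AMT", "EVID", "DV", "MDV", "BLQ",
    "AGE", "WT", "SEX", "RACE", "POP", "FORM", "DOSE",
]

_RACES = ("White", "Black", "Asian", "Other")


class DatasetValidationError(ValueError):
    """A PKDataset violates a structural invariant."""


@dataclass(frozen=True)
class DemographicSpec:
    """Sex/race proportions and truncated-normal age and weight settings."""

    male_prop: float
    race_props: tuple[float, float, float, float]  # White, Black, Asian, Other
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    wt_mean: float
    wt_sd: float
    wt_min: float
    wt_max: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_prop <= 1.0:
            raise ValueError("male_prop must be in [0,1]")
        if abs(sum(self.race_props) - 1.0) > 1e-9:
            raise ValueError("race proportions must sum to 1")
        for lo, hi, mean, name in (
            (self.age_min, self.age_max, self.age_mean, "age"),
            (self.wt_min, self.wt_max, self.wt_mean, "weight"),
        ):
            if not lo < hi:
                raise ValueError(f"{name} range must satisfy min < max")
            if not lo <= mean <= hi:
                raise ValueError(f"{name} mean {mean} outside range [{lo}, {hi}]")


@dataclass(frozen=True)
class Arm:
    """One dosing arm: explicit dose events and planned observation times."""

    label: str
    n: int
    dose: float
    formulation: str
    dose_events: tuple[tuple[float, float, str], ...]  # (time, amount, formulation)
    obs_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("arm n must be positive")
        if any(t < 0 for t in self.obs_times):
            raise ValueError("observation times must be >= 0")

    @classmethod
    def qd(cls, label: str, n: int, dose: float, formulation: str,
           obs_times: Sequence[float]) -> "Arm":
        """Once-daily dosing from t = 0 through the last observation day."""
        last = max(obs_times)
        n_doses = int(last // 24) + 1
        events = tuple((24.0 * i, dose, formulation) for i in range(n_doses))
        return cls(label, n, dose, formulation, events, tuple(obs_times))

    @classmethod
    def single(cls, label: str, n: int, dose: float, formulation: str,
               obs_times: Sequence[float]) -> "Arm":
        return cls(label, n, dose, formulation, ((0.0, dose, formulation),),
                   tuple(obs_times))


@dataclass(frozen=True)
class StudySpec:
    """One clinical study: population label, demographics and dosing arms."""

    study_id: str
    population: str
    demographics: DemographicSpec
    arms: tuple[Arm, ...]

    @property
    def n(self) -> int:
        return sum(a.n for a in self.arms)


# ---------------------------------------------------------------------------
# the default nine-study suite

_RICH_SINGLE = (0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12, 14,
                24, 48, 72, 120, 168, 240, 288, 336, 408, 504)


def _demo(male, races, age, wt) -> DemographicSpec:
    counts = np.asarray(races, dtype=float)
    props = tuple(counts / counts.sum())
    return DemographicSpec(
        male_prop=male, race_props=props,
        age_mean=age[0], age_sd=age[1], age_min=age[2], age_max=age[3],
        wt_mean=wt[0], wt_sd=wt[1], wt_min=wt[2], wt_max=wt[3],
    )


def default_study_suite() -> list[StudySpec]:
    """The nine-study pooled design (1534 subjects in total)."""
    d1 = (0.5, 1, 2, 4, 8, 24.0)
    d19 = tuple(432.0 + t for t in (0.0, 0.5, 1, 2, 4, 8, 24))
    s001 = StudySpec(
        "001", "OTH",
        _demo(31 / 40, (35, 2, 1, 2), (56.0, 11.0, 23, 71), (82.8, 15.9, 53.4, 116)),
        (
            Arm.qd("140qd", 35, 140.0, "capsule", d1 + (96.0, 100.0, 336.0) + d19 + (672.0,)),
            Arm.qd("200qd", 5, 200.0, "capsule", d1 + (96.0, 100.0, 336.0) + d19 + (672.0,)),
        ),
    )
    crossover = tuple(_RICH_SINGLE) + tuple(672.0 + t for t in _RICH_SINGLE)
    s010 = StudySpec(
        "010", "HV",
        _demo(32 / 77, (74, 2, 0, 1), (39.3, 9.7, 18, 55), (71.9, 11.5, 46.1, 106)),
        (
            Arm("xover", 77, 140.0, "tablet",
                ((0.0, 140.0, "tablet"), (672.0, 140.0, "capsule")), crossover),
        ),
    )
    s020 = StudySpec(
        "020", "HV",
        _demo(33 / 63, (62, 1, 0, 0), (36.9, 8.6, 19, 54), (76.4, 11.8, 58.1, 113.5)),
        tuple(
            Arm.single(f"{d:g}mg", 21, float(d), "tablet", _RICH_SINGLE)
            for d in (20, 40, 60)
        ),
    )
    s201 = StudySpec(
        "201", "GB",
        _demo(26 / 39, (33, 3, 1, 1), (48.6, 13.5, 20, 67), (81.4, 18.3, 52, 125.3)),
        (
            Arm.qd("140qd", 39, 140.0, "capsule",
                   (4.0, 336.0, 340.0, 672.0, 676.0, 1008.0, 1012.0, 1344.0)),
        ),
    )
    rdt_obs = tuple(168.0 * w for w in (14, 16, 18, 20, 22, 24))
    nre_obs = (504.0, 1008.0, 2016.0, 3024.0, 4032.0)
    s203 = StudySpec(
        "203", "CRPC",
        _demo(1.0, (246, 15, 14, 9), (66.3, 8.8, 43, 87), (90.2, 18.6, 50.3, 182.9)),
        (
            Arm.qd("rdt100", 200, 100.0, "capsule", rdt_obs),
            Arm.qd("nre40", 42, 40.0, "capsule", nre_obs),
            Arm.qd("nre100", 42, 100.0, "capsule", nre_obs),
        ),
    )
    s301 = StudySpec(
        "301", "MTC",
        _demo(146 / 210, (188, 1, 9, 5), (54.7, 13.3, 20, 86), (72.9, 18.0, 30.4, 137.9)),
        (
            Arm.qd("140qd", 210, 140.0, "capsule",
                   (2.0, 4.0, 6.0, 672.0, 674.0, 676.0, 678.0)),
        ),
    )
    s306 = StudySpec(
        "306", "CRPC",
        _demo(1.0, (34, 4, 1, 2), (64.8, 6.4, 48, 79), (89.3, 23.1, 57.5, 190.7)),
        (Arm.qd("60qd", 41, 60.0, "tablet", (504.0, 1008.0, 2016.0)),),
    )
    s307 = StudySpec(
        "307", "CRPC",
        _demo(1.0, (380, 9, 1, 3), (68.7, 7.6, 35, 87), (83.3, 14.0, 49.7, 140)),
        (Arm.qd("60qd", 498, 60.0, "tablet", (504.0, 2016.0)),),
    )
    s308 = StudySpec(
        "308", "RCC",
        _demo(222 / 282, (231, 5, 19, 16), (61.6, 9.5, 32, 86), (81.9, 17.0, 48.1, 155.7)),
        (Arm.qd("60qd", 282, 60.0, "tablet", (684.0, 1356.0)),),
    )
    return [s001, s010, s020, s201, s203, s301, s306, s307, s308]


# ---------------------------------------------------------------------------
# population generation


def _arm_assignment(spec: StudySpec) -> list[Arm]:
    """Deterministic subject-to-arm assignment: arms filled in order."""
    out: list[Arm] = []
    for arm in spec.arms:
        out.extend([arm] * arm.n)
    return out


def _truncnorm(rng, mean, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def build_virtual_population(spec: StudySpec, seed) -> list[CovariateSet]:
    """Draw covariates for every subject of one study.

    Sex and race are multinomial with the spec proportions; age and weight
    are truncated normal clipped to the observed ranges.  Dose, formulation
    and population come from the (deterministic) arm assignment.
    """
    rng = _as_rng(seed)
    n = spec.n
    d = spec.demographics
    sexes = np.where(rng.random(n) < d.male_prop, "male", "female")
    races = rng.choice(_RACES, size=n, p=d.race_props)
    ages = _truncnorm(rng, d.age_mean, d.age_sd, d.age_min, d.age_max, n)
    wts = _truncnorm(rng, d.wt_mean, d.wt_sd, d.wt_min, d.wt_max, n)
    arms = _arm_assignment(spec)
    return [
        CovariateSet(
            age=float(ages[i]), weight=float(wts[i]), sex=str(sexes[i]),
            race=str(races[i]), population=spec.population,
            formulation=arms[i].formulation, dose=arms[i].dose,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# dataset container


class PKDataset:
    """Long-format dosing/observation records for a pooled population.

    Thin wrapper over a DataFrame with the NONMEM-style column dialect:
    ID, STUDY, TIME (h), AMT (mg; dose records), EVID, DV (ng/mL;
    observation records), MDV, BLQ, and covariate columns AGE, WT, SEX,
    RACE, POP, FORM, DOSE.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetValidationError(f"missing mandatory column(s): {missing}")
        for sid, g in self.df.groupby("ID", sort=False):
            doses = g[g["EVID"] == 1]
            if doses.empty:
                raise DatasetValidationError(f"subject {sid} has no dose record")
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise DatasetValidationError(
                    f"subject {sid} has non-monotone record times"
                )
            obs = g[g["EVID"] == 0]
            if not obs.empty and obs["TIME"].min() < doses["TIME"].min():
                raise DatasetValidationError(
                    f"subject {sid} has an observation before the first dose"
                )
            bad = obs[(obs["DV"] < LLOQ) & (obs["BLQ"] != 1)]
            if not bad.empty:
                raise DatasetValidationError(
                    f"subject {sid} has sub-LLOQ DV without the BLQ flag"
                )

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def estimation_view(self) -> pd.DataFrame:
        """Observation records usable in the likelihood (BLQ excluded)."""
        return self.df[(self.df["EVID"] == 0) & (self.df["MDV"] == 0)]

    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def __eq__(self, other) -> bool:  # convenience for round-trip tests
        return isinstance(other, PKDataset) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# simulation


def _simulate_subject(rows, sid, study_id, cov, events, obs_times, th, eta, rm, rng,
                      time_jitter=0.0, dropout_time=None):
    dp_t = typical_disposition(cov, th)
    aps_t = [
        typical_absorption(replace(cov, dose=amt, formulation=form), th)
        for (_, amt, form) in events
    ]
    ip = apply_iiv(aps_t[0], dp_t, eta)
    aps_i = []
    for ap_t in aps_t:
        ap_i, dp_i = individual_model_params(ap_t, dp_t, ip)
        # dose/formulation effects on ka scale the individual value too
        aps_i.append(replace(ap_i, ka=ap_t.ka * ip.ka / aps_t[0].ka))
    _, dp_i = individual_model_params(aps_t[0], dp_t, ip)

    times = np.asarray(obs_times, dtype=float)
    if time_jitter:
        times = times * (1.0 + rng.uniform(-time_jitter, time_jitter, size=len(times)))
        times = np.maximum(times, 0.0)
    if dropout_time is not None:
        times = times[times <= dropout_time]
    reg = Regimen(tuple(DoseEvent(t, a, f) for (t, a, f) in events))
    conc = conc_profile(reg, aps_i, dp_i, times).concentrations
    # log-additive residual error; structurally-zero predictions stay 0 (BLQ)
    dv = conc.copy()
    if rm.sigma2 > 0:
        pos = conc > 0
        eps = rng.normal(0.0, float(np.sqrt(rm.sigma2)), size=int(pos.sum()))
        dv[pos] = conc[pos] * np.exp(eps)

    base = {
        "ID": sid, "STUDY": study_id, "AGE": cov.age, "WT": cov.weight,
        "SEX": cov.sex, "RACE": cov.race, "POP": cov.population,
    }
    for (t, amt, form) in events:
        rows.append({**base, "TIME": t, "AMT": amt, "EVID": 1, "DV": 0.0,
                     "MDV": 1, "BLQ": 0, "FORM": form, "DOSE": amt})
    for t, y in zip(times, dv):
        blq = int(y < LLOQ)
        rows.append({**base, "TIME": float(t), "AMT": 0.0, "EVID": 0,
                     "DV": float(y), "MDV": blq, "BLQ": blq,
                     "FORM": cov.formulation, "DOSE": cov.dose})


def simulate_dataset(
    specs: Sequence[StudySpec],
    th: ThetaVector,
    omega: OmegaMatrix,
    rm: ResidualModel,
    seed,
    time_jitter: float = 0.0,
    dropout_hazard_per_day: float = 0.0,
) -> PKDataset:
    """Simulate a pooled dataset under the full model for the given studies.

    ``time_jitter`` (off by default) perturbs each planned sampling time by a
    uniform relative deviation; ``dropout_hazard_per_day`` (off by default)
    censors each subject's observations at an exponentially distributed
    dropout time.  Deterministic and byte-stable given ``seed``.
    """
    rng = _as_rng(seed)
    rows: list[dict] = []
    sid = 0
    for spec in specs:
        covs = build_virtual_population(spec, rng)
        arms = _arm_assignment(spec)
        etas = draw_etas(spec.n, omega, rng)
        for i, (cov, arm) in enumerate(zip(covs, arms)):
            sid += 1
            dropout = None
            if dropout_hazard_per_day > 0:
                dropout = rng.exponential(24.0 / dropout_hazard_per_day)
            _simulate_subject(
                rows, sid, spec.study_id, cov, arm.dose_events, arm.obs_times,
                th, etas[i], rm, rng, time_jitter=time_jitter,
                dropout_time=dropout,
            )
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return PKDataset(df)


def resimulate(ds: PKDataset, th: ThetaVector, omega: OmegaMatrix,
               rm: ResidualModel, seed) -> PKDataset:
    """Redraw random effects and residuals keeping the dataset's design and
    covariates fixed (used by the posterior predictive check)."""
    rng = _as_rng(seed)
    rows: list[dict] = []
    ids = ds.df["ID"].unique()
    etas = draw_etas(len(ids), omega, rng)
    for i, sid in enumerate(ids):
        g = ds.df[ds.df["ID"] == sid]
        obs = g[g["EVID"] == 0]
        doses = g[g["EVID"] == 1]
        ref = obs.iloc[0] if not obs.empty else g.iloc[0]
        cov = CovariateSet(
            age=float(ref["AGE"]), weight=float(ref["WT"]), sex=str(ref["SEX"]),
            race=str(ref["RACE"]), population=str(ref["POP"]),
            formulation=str(ref["FORM"]), dose=float(ref["DOSE"]),
        )
        events = tuple(
            (float(r["TIME"]), float(r["AMT"]), str(r["FORM"]))
            for _, r in doses.iterrows()
        )
        _simulate_subject(rows, int(sid), str(ref["STUDY"]), cov, events,
                          tuple(obs["TIME"].astype(float)), th, etas[i], rm, rng)
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return PKDataset(df)


# ---------------------------------------------------------------------------
# i/o


def write_dataset(ds: PKDataset, path) -> None:
    """Write as CSV (full float precision, '.' decimal, header row)."""
    ds.df.to_csv(path, index=False)


def read_dataset(path) -> PKDataset:
    """Read and validate a dataset CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing mandatory column(s): {missing}")
    return PKDataset(df)
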