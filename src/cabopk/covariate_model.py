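"""Covariate model: map a subject's demographics, cancer population, dose and
formulation to typical PK parameter values.

Continuous covariates (age, weight on CL/F and Vc/F; dose on Ka) act through
power models, ``theta = theta_ref * (x / x_ref) ** exponent``.  Categorical
covariates (sex, race, cancer population on CL/F and Vc/F; capsule on Ka and
overall bioavailability) act multiplicatively, ``theta = theta_ref *
exp(theta_x * I)``, where ``theta_x`` is the log of the fractional change
from the reference level — so a printed fractional change ``fc`` corresponds
to the multiplier ``1 + fc``.

Reference subject: White male healthy volunteer, 80 kg, 60 years, tablet.
Three built-in presets carry the published fixed-effect sets of the final
integrated model (``FM``), the variant without cancer-type effects
(``FMECT``) and the covariate-free base structure (``BASE``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

from .structural_pk import AbsorptionParams, DispositionParams

__all__ = [
    "CovariateSet",
    "ThetaVector",
    "REFERENCE_SUBJECT",
    "fractional_change_to_theta",
    "theta_to_fractional_change",
    "typical_disposition",
    "typical_absorption",
    "covariate_impact_table",
    "figure_scenarios",
    "load_preset",
    "PRESETS",
]

SEXES = ("male", "female")
RACES = ("White", "Black", "Asian", "Other")
POPULATIONS = ("HV", "RCC", "CRPC", "MTC", "GB", "OTH")
FORMULATIONS = ("tablet", "capsule")


@dataclass(frozen=True)
class CovariateSet:
    """One subject's covariates plus the dose/formulation they receive."""

    age: float
    weight: float
    sex: str
    race: str
    population: str
    formulation: str
    dose: float

    def __post_init__(self) -> None:
        if not (self.age > 0 and self.weight > 0 and self.dose > 0):
            raise ValueError("age, weight and dose must be positive")
        for val, allowed, name in (
            (self.sex, SEXES, "sex"),
            (self.race, RACES, "race"),
            (self.population, POPULATIONS, "population"),
            (self.formulation, FORMULATIONS, "formulation"),
        ):
            if val not in allowed:
                raise ValueError(f"unknown {name} level {val!r}; expected one of {allowed}")


#: White, male, 80 kg, 60-year-old healthy volunteer on a 60-mg tablet.
REFERENCE_SUBJECT = CovariateSet(
    age=60.0, weight=80.0, sex="male", race="White",
    population="HV", formulation="tablet", dose=60.0,
)


def fractional_change_to_theta(fc: float) -> float:
    """log of the fractional-change multiplier: theta_x = ln(1 + fc)."""
    if fc <= -1.0:
        raise ValueError(
            f"fractional change must exceed -1 (got {fc}); the implied "
            "multiplier would be non-positive"
        )
    return math.log1p(fc)


def theta_to_fractional_change(theta_x: float) -> float:
    """Inverse transform: fc = exp(theta_x) - 1."""
    return math.expm1(theta_x)


def _freeze(d: Mapping[str, float]) -> Mapping[str, float]:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects: structural reference values plus covariate coefficients.

    Structural references apply to the reference subject.  Categorical
    coefficients are stored as printed fractional changes (``*_fc``, i.e.
    ``exp(theta_x) - 1``); continuous coefficients are power-model exponents.
    Absent keys in the categorical maps mean "no effect estimated" and act as
    coefficient 0.
    """

    ka_ref: float
    d2: float
    cl_ref: float
    vc_ref: float
    q: float
    vp: float
    alag1: float
    f1_ref: float  # natural (anti-logit) scale, in (0,1)
    ka_dose_exp: float
    capsule_ka_fc: float
    capsule_f_fc: float
    cl_age_exp: float = 0.0
    cl_wt_exp: float = 0.0
    cl_female_fc: float = 0.0
    cl_race_fc: Mapping[str, float] = field(default_factory=dict)
    cl_pop_fc: Mapping[str, float] = field(default_factory=dict)
    vc_age_exp: float = 0.0
    vc_wt_exp: float = 0.0
    vc_female_fc: float = 0.0
    vc_race_fc: Mapping[str, float] = field(default_factory=dict)
    vc_pop_fc: Mapping[str, float] = field(default_factory=dict)
    age_ref: float = 60.0
    weight_ref: float = 80.0
    dose_ref: float = 60.0

    def __post_init__(self) -> None:
        for name in ("ka_ref", "d2", "cl_ref", "vc_ref", "q", "vp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive (got {getattr(self, name)})")
        if self.alag1 < 0:
            raise ValueError(f"alag1 must be >= 0 (got {self.alag1})")
        if not 0.0 < self.f1_ref < 1.0:
            raise ValueError(f"f1_ref must be in (0,1) (got {self.f1_ref})")
        for fc_map in (self.cl_race_fc, self.cl_pop_fc, self.vc_race_fc, self.vc_pop_fc):
            for level, fc in fc_map.items():
                if fc <= -1.0:
                    raise ValueError(f"fractional change for {level!r} must exceed -1")
        object.__setattr__(self, "cl_race_fc", _freeze(self.cl_race_fc))
        object.__setattr__(self, "cl_pop_fc", _freeze(self.cl_pop_fc))
        object.__setattr__(self, "vc_race_fc", _freeze(self.vc_race_fc))
        object.__setattr__(self, "vc_pop_fc", _freeze(self.vc_pop_fc))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        from dataclasses import fields

        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = dict(v) if isinstance(v, MappingProxyType) else v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThetaVector":
        return cls(**d)

    def replace(self, **kwargs) -> "ThetaVector":
        return replace(self, **kwargs)


def _categorical_multiplier(cov: CovariateSet, female_fc: float,
                            race_fc: Mapping[str, float],
                            pop_fc: Mapping[str, float]) -> float:
    mult = 1.0
    if cov.sex == "female":
        mult *= 1.0 + female_fc
    if cov.race != "White":
        if cov.race in race_fc:
            mult *= 1.0 + race_fc[cov.race]
    if cov.population != "HV":
        if cov.population in pop_fc:
            mult *= 1.0 + pop_fc[cov.population]
    return mult


def typical_disposition(cov: CovariateSet, th: ThetaVector) -> DispositionParams:
    """Typical (eta = 0) disposition parameters for a subject."""
    cl = (
        th.cl_ref
        * (cov.age / th.age_ref) ** th.cl_age_exp
        * (cov.weight / th.weight_ref) ** th.cl_wt_exp
        * _categorical_multiplier(cov, th.cl_female_fc, th.cl_race_fc, th.cl_pop_fc)
    )
    vc = (
        th.vc_ref
        * (cov.age / th.age_ref) ** th.vc_age_exp
        * (cov.weight / th.weight_ref) ** th.vc_wt_exp
        * _categorical_multiplier(cov, th.vc_female_fc, th.vc_race_fc, th.vc_pop_fc)
    )
    return DispositionParams(cl=cl, vc=vc, q=th.q, vp=th.vp)


def typical_absorption(cov: CovariateSet, th: ThetaVector) -> AbsorptionParams:
    """Typical absorption parameters; ka is dose-dependent (power model) and
    capsule formulation scales both ka and overall bioavailability."""
    ka = th.ka_ref * (cov.dose / th.dose_ref) ** th.ka_dose_exp
    frel = 1.0
    if cov.formulation == "capsule":
        ka *= 1.0 + th.capsule_ka_fc
        frel *= 1.0 + th.capsule_f_fc
    return AbsorptionParams(ka=ka, alag1=th.alag1, d2=th.d2, f1=th.f1_ref, frel=frel)


def figure_scenarios() -> list[tuple[str, CovariateSet]]:
    """Single-covariate contrast scenarios against the reference subject:
    low/high weight (56/112 kg), low/high age (36/79 y), female, each
    non-reference race, each cancer population."""
    ref = REFERENCE_SUBJECT
    out = [("REF", ref)]
    out.append(("LWT", replace(ref, weight=56.0)))
    out.append(("HWT", replace(ref, weight=112.0)))
    out.append(("LAGE", replace(ref, age=36.0)))
    out.append(("HAGE", replace(ref, age=79.0)))
    out.append(("FEMALE", replace(ref, sex="female")))
    for race in ("Black", "Asian", "Other"):
        out.append((race.upper(), replace(ref, race=race)))
    for pop in ("RCC", "CRPC", "MTC", "GB", "OTH"):
        out.append((pop, replace(ref, population=pop)))
    return out


def covariate_impact_table(th: ThetaVector, scenarios=None, dose: float = 60.0,
                           tau: float = 24.0):
    """Ratios of typical CL/F, Cmax,ss and Cmin,ss versus the reference
    subject for each scenario (no IIV, no residual error).

    Returns a DataFrame with columns scenario, cl_ratio, cmax_ss_ratio,
    cmin_ss_ratio.
    """
    import pandas as pd

    from .structural_pk import steady_state_metrics

    if scenarios is None:
        scenarios = figure_scenarios()

    def metrics(cov: CovariateSet):
        cov = replace(cov, dose=dose)
        dp = typical_disposition(cov, th)
        ap = typical_absorption(cov, th)
        cmax, cmin, _, _ = steady_state_metrics(ap, dp, dose, tau)
        return dp.cl, cmax, cmin

    cl0, cmax0, cmin0 = metrics(REFERENCE_SUBJECT)
    rows = []
    for label, cov in scenarios:
        cl, cmax, cmin = metrics(cov)
        rows.append(
            {
                "scenario": label,
                "cl_ratio": cl / cl0,
                "cmax_ss_ratio": cmax / cmax0,
                "cmin_ss_ratio": cmin / cmin0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published fixed-effect presets

_FM = ThetaVector(
    ka_ref=0.979, d2=2.4, cl_ref=2.478, vc_ref=187.0, q=31.213, vp=195.1,
    alag1=0.784, f1_ref=0.854, ka_dose_exp=0.677,
    capsule_ka_fc=-0.579, capsule_f_fc=-0.144,
    cl_age_exp=-0.162, cl_wt_exp=-0.028, cl_female_fc=-0.230,
    cl_race_fc={"Black": 0.301, "Asian": -0.078, "Other": -0.007},
    cl_pop_fc={"RCC": -0.129, "CRPC": -0.009, "MTC": 0.928, "GB": 0.216, "OTH": 0.178},
    vc_age_exp=-0.012, vc_wt_exp=1.019, vc_female_fc=0.11,
    vc_race_fc={"Black": -0.022, "Asian": 0.05, "Other": -0.059},
    vc_pop_fc={"RCC": -0.63, "CRPC": -0.241, "MTC": -0.07, "GB": -0.569, "OTH": -0.186},
)

_FMECT = ThetaVector(
    ka_ref=0.846, d2=2.441, cl_ref=2.553, vc_ref=146.713, q=30.118, vp=193.605,
    alag1=0.777, f1_ref=0.840, ka_dose_exp=0.585,
    capsule_ka_fc=-0.300, capsule_f_fc=-0.183,
    cl_age_exp=-0.273, cl_wt_exp=-0.248, cl_female_fc=-0.233,
    cl_race_fc={"Black": 0.249, "Asian": -0.118, "Other": -0.029},
    vc_age_exp=-0.277, vc_wt_exp=0.798, vc_female_fc=0.165,
    vc_race_fc={"Black": -0.065, "Asian": 0.125, "Other": -0.018},
)

_BASE = ThetaVector(
    ka_ref=0.804, d2=2.435, cl_ref=2.457, vc_ref=157.178, q=30.154, vp=188.666,
    alag1=0.789, f1_ref=0.847, ka_dose_exp=0.566,
    capsule_ka_fc=-0.211, capsule_f_fc=-0.189,
)

PRESETS: Mapping[str, ThetaVector] = MappingProxyType(
    {"FM": _FM, "FMECT": _FMECT, "BASE": _BASE}
)


def load_preset(name: str) -> ThetaVector:
    """Return one of the built-in fixed-effect presets: FM, FMECT or BASE."""
    try:
        return PRESETS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {tuple(PRESETS)}") from None
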