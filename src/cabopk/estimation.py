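"""Marginal-likelihood estimation and nested-model comparison.

The marginal likelihood of a nonlinear mixed-effects model has no closed
form; this module maximises a Laplace approximation.  For each subject the
joint -2 log density of the observations and the random effects is minimised
over eta (the MAP step), and the integral over eta is approximated by the
curvature at the mode:

    OFV_i = nll_i(eta_hat) + log det( H_i / (4 pi) ),

where ``nll_i`` is -2 log of the joint density and ``H_i`` its Hessian at
the MAP (equivalently, the Hessian of the negative log joint divided by
2 pi).  The total objective function value (OFV) is the sum over subjects;
nested covariate structures are compared by the chi-square likelihood-ratio
logic on OFV differences.

The outer problem optimises transformed parameters (log scale for positive
structural values and variances, logit scale for the depot fraction F1,
log-fractional-change scale for categorical covariate coefficients) with a
derivative-free simplex search, warm-starting each subject's inner MAP
problem from the previous outer iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .covariate_model import (
    CovariateSet,
    ThetaVector,
    load_preset,
    typical_absorption,
    typical_disposition,
)
from .population_model import (
    ETA_LABELS,
    OmegaMatrix,
    ResidualModel,
    expit,
    logit,
)
from .synthetic_data import PKDataset

__all__ = [
    "ModelConfig",
    "FitResult",
    "BASE_CONFIG",
    "FMECT_CONFIG",
    "FM_CONFIG",
    "prepare_subjects",
    "individual_joint_nll",
    "laplace_ofv",
    "fit_model",
    "estimate_covariance",
    "compare_nested",
]

_PENALTY = 1e10
_LOG_4PI = math.log(4.0 * math.pi)


# ---------------------------------------------------------------------------
# model configuration


@dataclass(frozen=True)
class ModelConfig:
    """Covariate structure plus the set of parameters to estimate.

    ``demographics``/``populations`` toggle the age/weight/sex/race and
    cancer-population covariate blocks on CL/F and Vc/F (dose on Ka and the
    capsule effects are structural and always retained).  ``estimate`` lists
    the parameter names optimised by :func:`fit_model`; everything else is
    fixed at its initial value.  ``random_effects`` lists the eta labels
    carrying IIV.
    """

    name: str
    demographics: bool
    populations: bool
    estimate: tuple[str, ...]
    random_effects: tuple[str, ...] = ("ka", "cl", "vc", "f1")
    preset: str = "FM"

    def __post_init__(self) -> None:
        for lab in self.random_effects:
            if lab not in ETA_LABELS:
                raise ValueError(f"unknown random effect {lab!r}")

    def apply_structure(self, th: ThetaVector) -> ThetaVector:
        """Zero the covariate blocks excluded by this configuration."""
        if not self.demographics:
            th = th.replace(
                cl_age_exp=0.0, cl_wt_exp=0.0, cl_female_fc=0.0, cl_race_fc={},
                vc_age_exp=0.0, vc_wt_exp=0.0, vc_female_fc=0.0, vc_race_fc={},
            )
        if not self.populations:
            th = th.replace(cl_pop_fc={}, vc_pop_fc={})
        return th

    def is_nested_in(self, other: "ModelConfig") -> bool:
        return (
            set(self.estimate) <= set(other.estimate)
            and (other.demographics or not self.demographics)
            and (other.populations or not self.populations)
        )


BASE_CONFIG = ModelConfig("BASE", demographics=False, populations=False,
                          estimate=("cl", "vc"), preset="BASE")
FMECT_CONFIG = ModelConfig("FMECT", demographics=True, populations=False,
                           estimate=("cl", "vc"), preset="FMECT")
FM_CONFIG = ModelConfig("FM", demographics=True, populations=True,
                        estimate=("cl", "vc"), preset="FM")


# ---------------------------------------------------------------------------
# parameter transforms


def _fc_transform(fc: float) -> float:
    return math.log1p(fc)


def _fc_back(t: float) -> float:
    return math.expm1(t)


class Parameterization:
    """Maps between named model parameters and a flat transformed vector."""

    def __init__(self, names: Sequence[str], theta: ThetaVector,
                 omega: OmegaMatrix, rm: ResidualModel):
        self.names = tuple(names)
        self.base_theta = theta
        self.base_omega = omega
        self.base_rm = rm
        for n in self.names:
            self._check_name(n)

    _LOG_FIELDS = {
        "cl": "cl_ref", "vc": "vc_ref", "ka": "ka_ref", "q": "q", "vp": "vp",
        "d2": "d2", "alag1": "alag1",
    }
    _IDENT_FIELDS = {
        "ka_dose_exp": "ka_dose_exp", "cl_age_exp": "cl_age_exp",
        "cl_wt_exp": "cl_wt_exp", "vc_age_exp": "vc_age_exp",
        "vc_wt_exp": "vc_wt_exp",
    }
    _FC_FIELDS = {
        "cl_female_fc": "cl_female_fc", "vc_female_fc": "vc_female_fc",
        "capsule_ka_fc": "capsule_ka_fc", "capsule_f_fc": "capsule_f_fc",
    }

    def _check_name(self, n: str) -> None:
        if n in self._LOG_FIELDS or n in self._IDENT_FIELDS or n in self._FC_FIELDS:
            return
        if n == "f1" or n == "sigma2":
            return
        if n.startswith("omega_") and n[6:] in ETA_LABELS:
            return
        for prefix in ("cl_race_", "cl_pop_", "vc_race_", "vc_pop_"):
            if n.startswith(prefix):
                return
        raise ValueError(f"unknown parameter name {n!r}")

    def _get(self, n: str) -> float:
        th, om, rm = self.base_theta, self.base_omega, self.base_rm
        if n in self._LOG_FIELDS:
            return math.log(getattr(th, self._LOG_FIELDS[n]))
        if n in self._IDENT_FIELDS:
            return getattr(th, self._IDENT_FIELDS[n])
        if n in self._FC_FIELDS:
            return _fc_transform(getattr(th, self._FC_FIELDS[n]))
        if n == "f1":
            return logit(th.f1_ref)
        if n == "sigma2":
            return math.log(max(rm.sigma2, 1e-12))
        if n.startswith("omega_"):
            return math.log(max(om.variance(n[6:]), 1e-12))
        for prefix, attr in (("cl_race_", "cl_race_fc"), ("cl_pop_", "cl_pop_fc"),
                             ("vc_race_", "vc_race_fc"), ("vc_pop_", "vc_pop_fc")):
            if n.startswith(prefix):
                level = n[len(prefix):]
                return _fc_transform(getattr(th, attr).get(level, 0.0))
        raise AssertionError(n)

    def pack(self) -> np.ndarray:
        return np.array([self._get(n) for n in self.names])

    def unpack(self, x) -> tuple[ThetaVector, OmegaMatrix, ResidualModel]:
        th, om, rm = self.base_theta, self.base_omega, self.base_rm
        updates: dict = {}
        omega_m = om.matrix.copy()
        sigma2 = rm.sigma2
        maps: dict[str, dict] = {}
        for n, v in zip(self.names, np.asarray(x, dtype=float)):
            if n in self._LOG_FIELDS:
                updates[self._LOG_FIELDS[n]] = math.exp(v)
            elif n in self._IDENT_FIELDS:
                updates[self._IDENT_FIELDS[n]] = v
            elif n in self._FC_FIELDS:
                updates[self._FC_FIELDS[n]] = _fc_back(v)
            elif n == "f1":
                updates["f1_ref"] = expit(v)
            elif n == "sigma2":
                sigma2 = math.exp(v)
            elif n.startswith("omega_"):
                i = ETA_LABELS.index(n[6:])
                omega_m[i, i] = math.exp(v)
            else:
                for prefix, attr in (("cl_race_", "cl_race_fc"),
                                     ("cl_pop_", "cl_pop_fc"),
                                     ("vc_race_", "vc_race_fc"),
                                     ("vc_pop_", "vc_pop_fc")):
                    if n.startswith(prefix):
                        m = maps.setdefault(attr, dict(getattr(th, attr)))
                        m[n[len(prefix):]] = _fc_back(v)
                        break
        for attr, m in maps.items():
            updates[attr] = m
        th2 = th.replace(**updates) if updates else th
        return th2, OmegaMatrix(omega_m), ResidualModel(sigma2)


# ---------------------------------------------------------------------------
# subject preparation and prediction


@dataclass
class SubjectData:
    """Precomputed per-subject data for likelihood evaluation."""

    sid: int
    cov: CovariateSet
    dose_groups: tuple[tuple[float, str, np.ndarray], ...]  # (amount, form, times)
    obs_times: np.ndarray
    log_dv: np.ndarray


def prepare_subjects(ds: PKDataset) -> list[SubjectData]:
    """Extract dosing and usable (non-BLQ) observations per subject."""
    out: list[SubjectData] = []
    df = ds.df
    for sid, g in df.groupby("ID", sort=True):
        doses = g[g["EVID"] == 1]
        obs = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
        if obs.empty:
            continue
        ref = obs.iloc[0]
        cov = CovariateSet(
            age=float(ref["AGE"]), weight=float(ref["WT"]), sex=str(ref["SEX"]),
            race=str(ref["RACE"]), population=str(ref["POP"]),
            formulation=str(ref["FORM"]), dose=float(ref["DOSE"]),
        )
        groups: dict[tuple[float, str], list[float]] = {}
        for t, a, f in zip(doses["TIME"], doses["AMT"], doses["FORM"]):
            groups.setdefault((float(a), str(f)), []).append(float(t))
        dose_groups = tuple(
            (a, f, np.asarray(ts)) for (a, f), ts in groups.items()
        )
        out.append(
            SubjectData(
                sid=int(sid), cov=cov, dose_groups=dose_groups,
                obs_times=obs["TIME"].to_numpy(dtype=float),
                log_dv=np.log(obs["DV"].to_numpy(dtype=float)),
            )
        )
    return out


class _SubjectModel:
    """Caches theta-dependent quantities so inner eta evaluations are cheap.

    The prediction path is inlined (no parameter-object construction) because
    it sits inside the per-subject MAP optimisation inside the outer
    parameter search.
    """

    def __init__(self, subj: SubjectData, th: ThetaVector):
        self.subj = subj
        dp = typical_disposition(subj.cov, th)
        self.cl_t, self.vc_t = dp.cl, dp.vc
        self.q, self.vp = dp.q, dp.vp
        self.groups = []
        for amount, form, times in subj.dose_groups:
            ap = typical_absorption(
                replace(subj.cov, dose=amount, formulation=form), th
            )
            u = subj.obs_times[None, :] - times[:, None]
            # masks depend only on the (fixed) lag and zero-order duration
            w = u - ap.alag1
            fo_mask = w > 0
            zo_during = (u > 0) & (u <= ap.d2)
            zo_post = u > ap.d2
            self.groups.append({
                "amt": ap.frel * amount, "ka_t": ap.ka, "d2": ap.d2,
                "w": np.maximum(w, 0.0), "fo_mask": fo_mask,
                "u": np.maximum(u, 0.0), "zo_during": zo_during,
                "zo_post": zo_post,
            })
        self.logit_f1 = logit(ap.f1)

    def predict(self, eta) -> np.ndarray:
        """Predicted concentrations at the subject's observation times for a
        full eta 4-vector (order ka, cl, vc, f1)."""
        cl = self.cl_t * math.exp(eta[1])
        vc = self.vc_t * math.exp(eta[2])
        f1 = expit(self.logit_f1 + eta[3])
        k10 = cl / vc
        k12 = self.q / vc
        k21 = self.q / self.vp
        s = k10 + k12 + k21
        p = k10 * k21
        alpha = 0.5 * (s + math.sqrt(max(s * s - 4.0 * p, 0.0)))
        beta = p / alpha
        a_co = (alpha - k21) / (alpha - beta)
        b_co = (k21 - beta) / (alpha - beta)
        c = np.zeros_like(self.subj.obs_times)
        for g in self.groups:
            ka = g["ka_t"] * math.exp(eta[0])
            for lam in (alpha, beta):
                if abs(ka - lam) < 1e-8 * lam:
                    ka *= 1.0 + 1e-7
            amt = g["amt"]
            # lagged first-order route
            pref = f1 * amt * ka / vc
            ca = pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
            cb = pref * (k21 - beta) / ((ka - beta) * (alpha - beta))
            ck = pref * (k21 - ka) / ((alpha - ka) * (beta - ka))
            w = g["w"]
            fo = ca * np.exp(-alpha * w) + cb * np.exp(-beta * w) + ck * np.exp(-ka * w)
            c += np.sum(fo * g["fo_mask"], axis=0)
            # zero-order route
            r0v = (1.0 - f1) * amt / g["d2"] / vc
            u = g["u"]
            fa = a_co / alpha
            fb = b_co / beta
            during = r0v * (fa * (1.0 - np.exp(-alpha * u))
                            + fb * (1.0 - np.exp(-beta * u)))
            c += np.sum(during * g["zo_during"], axis=0)
            if g["zo_post"].any():
                d2 = g["d2"]
                post = r0v * (
                    fa * (1.0 - math.exp(-alpha * d2)) * np.exp(-alpha * np.maximum(u - d2, 0.0))
                    + fb * (1.0 - math.exp(-beta * d2)) * np.exp(-beta * np.maximum(u - d2, 0.0))
                )
                c += np.sum(post * g["zo_post"], axis=0)
        return c * 1000.0

    def residual_nll(self, eta, sigma2: float) -> float:
        sigma2 = max(sigma2, 1e-12)  # degenerate error model floor
        c = self.predict(eta)
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            eta = np.asarray(eta, dtype=float)
            return _PENALTY * (1.0 + float(np.dot(eta, eta)))
        r = self.subj.log_dv - np.log(c)
        n = len(r)
        return float(np.dot(r, r) / sigma2 + n * math.log(2.0 * math.pi * sigma2))

    def log_pred_jacobian(self, eta: np.ndarray, active: list[int],
                          h: float = 1e-5):
        """(log C, d log C / d eta_active) by forward differences."""
        c0 = self.predict(eta)
        ok = np.all(np.isfinite(c0)) and np.all(c0 > 0)
        if not ok:
            return None, None
        logc0 = np.log(c0)
        jac = np.empty((len(active), len(c0)))
        for k, i in enumerate(active):
            e = eta.copy()
            e[i] += h
            ci = self.predict(e)
            jac[k] = (np.log(ci) - logc0) / h
        return logc0, jac


def individual_joint_nll(eta, subj: SubjectData, th: ThetaVector,
                         omega: OmegaMatrix, rm: ResidualModel) -> float:
    """-2 log joint density of one subject's observations and eta.

    Composes the log-additive residual likelihood with the N(0, Omega) prior
    on eta.  A semidefinite Omega is ridged by 1e-8 on the diagonal.
    """
    eta = np.asarray(eta, dtype=float)
    model = _SubjectModel(subj, th)
    m = omega.matrix + 1e-8 * np.eye(4)
    sign, logdet = np.linalg.slogdet(m)
    quad = float(eta @ np.linalg.solve(m, eta))
    prior = quad + logdet + 4.0 * math.log(2.0 * math.pi)
    return model.residual_nll(eta, rm.sigma2) + prior


# ---------------------------------------------------------------------------
# Laplace objective


def _active_indices(omega: OmegaMatrix, labels=None) -> list[int]:
    idx = [i for i in range(4) if omega.matrix[i, i] > 0]
    if labels is not None:
        allowed = {ETA_LABELS.index(l) for l in labels}
        idx = [i for i in idx if i in allowed]
    return idx


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                     h: float = 1e-4) -> np.ndarray:
    d = len(x)
    hess = np.zeros((d, d))
    f0 = f(x)
    steps = h * (1.0 + np.abs(x))
    for i in range(d):
        ei = np.zeros(d); ei[i] = steps[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = steps[j]
            fij = f(x + ei + ej)
            fi = fpp
            fj = f(x + ej)
            fji = f(x - ei - ej)
            fmi = fmm
            fmj = f(x - ej)
            hess[i, j] = hess[j, i] = (
                (fij - fi - fj + 2.0 * f0 - fmi - fmj + fji)
                / (2.0 * steps[i] * steps[j])
            )
    return hess


_JITTER = np.array([[0.3, -0.3, 0.3, -0.3], [-0.5, 0.5, -0.5, 0.5],
                    [0.8, 0.8, -0.8, -0.8]])


def laplace_ofv(
    th: ThetaVector,
    omega: OmegaMatrix,
    rm: ResidualModel,
    ds: PKDataset | Sequence[SubjectData],
    random_effects: Sequence[str] | None = None,
    eta_warm: dict | None = None,
) -> tuple[float, dict]:
    """Laplace-approximate OFV (-2 log marginal likelihood) and MAP etas.

    Each subject's joint nll is minimised over the active random effects
    (those with positive Omega variance, optionally restricted to
    ``random_effects``) starting from eta = 0 or the warm start; the inner
    Hessian is taken by central finite differences.  Deterministic given the
    data.  Returns ``(ofv, {subject id: MAP eta 4-vector})``.
    """
    subjects = ds if not isinstance(ds, PKDataset) else prepare_subjects(ds)
    active = _active_indices(omega, random_effects)
    d = len(active)
    if d:
        sub = omega.matrix[np.ix_(active, active)]
        eig = np.linalg.eigvalsh(sub)
        if eig.min() <= 1e-12 * max(eig.max(), 1.0):
            sub = sub + 1e-8 * np.eye(d)
        sub_inv = np.linalg.inv(sub)
        _, sub_logdet = np.linalg.slogdet(sub)
        prior_const = sub_logdet + d * math.log(2.0 * math.pi)

    ofv = 0.0
    map_etas: dict = {}
    for subj in subjects:
        model = _SubjectModel(subj, th)
        if d == 0:
            ofv += model.residual_nll(np.zeros(4), rm.sigma2)
            map_etas[subj.sid] = np.zeros(4)
            continue
        x0 = np.zeros(d)
        if eta_warm and subj.sid in eta_warm:
            x0 = np.asarray(eta_warm[subj.sid])[active]
        eta_hat, nll_hat, hess = _map_eta(
            model, rm.sigma2, active, sub_inv, prior_const, x0
        )
        if hess is None:
            for row in _JITTER:
                eta_hat, nll_hat, hess = _map_eta(
                    model, rm.sigma2, active, sub_inv, prior_const,
                    x0 + row[:d],
                )
                if hess is not None:
                    break
        if hess is None:  # subject flagged: contribute the penalty value
            ofv += nll_hat
            map_etas[subj.sid] = np.zeros(4)
            continue
        sign, logdet = np.linalg.slogdet(hess)
        ofv += nll_hat + logdet - d * _LOG_4PI
        full = np.zeros(4)
        full[active] = eta_hat
        map_etas[subj.sid] = full
    return float(ofv), map_etas


def _map_eta(model: _SubjectModel, sigma2: float, active: list[int],
             sub_inv: np.ndarray, prior_const: float, x0: np.ndarray,
             max_iter: int = 50, tol: float = 1e-8):
    """Damped Gauss-Newton minimisation of one subject's joint nll over the
    active etas.

    The Gauss-Newton curvature 2 J'J / sigma2 + 2 Omega^-1 (J the Jacobian
    of log-predictions) is used both for the Newton steps and as the
    interaction-style expected Hessian in the Laplace determinant.  Returns
    (eta_active_hat, nll_at_map, hessian) or (x0, penalty, None) when no
    valid linearisation exists at the starting point.
    """
    d = len(active)

    def nll(ea):
        eta = np.zeros(4)
        eta[active] = ea
        return (model.residual_nll(eta, sigma2)
                + float(ea @ sub_inv @ ea) + prior_const)

    x = np.asarray(x0, dtype=float)
    fx = nll(x)
    if fx >= _PENALTY:
        # fall back from an infeasible warm start
        x = np.zeros(d)
        fx = nll(x)
        if fx >= _PENALTY:
            return x, fx, None
    lam = 0.0
    hess = None
    for _ in range(max_iter):
        eta = np.zeros(4)
        eta[active] = x
        logc, jac = model.log_pred_jacobian(eta, active)
        if logc is None:
            return x, fx, None
        r = model.subj.log_dv - logc
        grad = -2.0 * jac @ r / sigma2 + 2.0 * sub_inv @ x
        hess = 2.0 * jac @ jac.T / sigma2 + 2.0 * sub_inv
        if np.max(np.abs(grad)) < 1e-7 * (1.0 + abs(fx)):
            break
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(hess + lam * np.eye(d), -grad)
            except np.linalg.LinAlgError:
                lam = max(10.0 * lam, 1e-6)
                continue
            fn = nll(x + step)
            if fn < fx:
                x = x + step
                improved = fx - fn
                fx = fn
                lam = lam / 10.0 if lam > 1e-10 else 0.0
                break
            lam = max(10.0 * lam, 1e-6)
        else:
            break
        if improved < tol * (1.0 + abs(fx)):
            break
    return x, fx, hess


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Estimates, OFV, per-subject MAP etas and (optionally) the parameter
    covariance on the transformed scale."""

    theta: ThetaVector
    omega: OmegaMatrix
    residual: ResidualModel
    ofv: float
    map_etas: dict
    converged: bool
    config: ModelConfig
    param_names: tuple[str, ...]
    x: np.ndarray
    cov: np.ndarray | None = None
    n_outer_evals: int = 0

    def draw_parameters(self, rng, max_tries: int = 1000):
        """Draw one population parameter set from the multivariate-normal
        sampling distribution of the estimates (transformed scale), rejecting
        draws that violate parameter invariants.

        Returns ``(theta, omega, rm, n_rejected)``.
        """
        if self.cov is None:
            raise ValueError(
                "FitResult has no parameter covariance; refit with "
                "compute_cov=True (or call estimate_covariance)"
            )
        packer = Parameterization(self.param_names, self.theta, self.omega,
                                  self.residual)
        rejected = 0
        for _ in range(max_tries):
            x = rng.multivariate_normal(self.x, self.cov, method="svd")
            try:
                th, om, rm = packer.unpack(x)
            except ValueError:
                rejected += 1
                continue
            return th, om, rm, rejected
        raise RuntimeError(f"no valid parameter draw in {max_tries} attempts")


def fit_model(
    cfg: ModelConfig,
    ds: PKDataset,
    theta_init: ThetaVector | str | None = None,
    omega_init: OmegaMatrix | None = None,
    rm_init: ResidualModel | None = None,
    compute_cov: bool = False,
    maxfev: int = 400,
    xatol: float = 1e-4,
    fatol: float = 0.05,
) -> FitResult:
    """Maximise the Laplace marginal likelihood over ``cfg.estimate``.

    ``theta_init`` may be a ThetaVector, a preset name, or None (the config's
    preset).  Parameters not listed in ``cfg.estimate`` stay fixed at their
    initial values.  Deterministic given the data and initial values.
    """
    if theta_init is None:
        theta_init = cfg.preset
    if isinstance(theta_init, str):
        theta_init = load_preset(theta_init)
    theta_init = cfg.apply_structure(theta_init)
    if omega_init is None:
        from .population_model import default_omega

        omega_init = default_omega(0.0)
    if rm_init is None:
        from .population_model import default_residual

        rm_init = default_residual()

    # zero out IIV not carried by this config
    m = omega_init.matrix.copy()
    for i, lab in enumerate(ETA_LABELS):
        if lab not in cfg.random_effects:
            m[i, :] = 0.0
            m[:, i] = 0.0
    omega_init = OmegaMatrix(m)

    subjects = prepare_subjects(ds)
    packer = Parameterization(cfg.estimate, theta_init, omega_init, rm_init)
    x0 = packer.pack()
    warm: dict = {}
    n_eval = [0]

    def objective(x: np.ndarray) -> float:
        n_eval[0] += 1
        try:
            th, om, rm = packer.unpack(x)
        except ValueError:
            return _PENALTY
        ofv, etas = laplace_ofv(th, om, rm, subjects,
                                random_effects=cfg.random_effects,
                                eta_warm=warm)
        warm.update(etas)
        return ofv

    if len(x0):
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev,
                     "adaptive": len(x0) > 2},
        )
        x_opt = res.x
        converged = bool(res.success)
    else:
        x_opt = x0
        converged = True
    theta, omega, rm = packer.unpack(x_opt)
    ofv, map_etas = laplace_ofv(theta, omega, rm, subjects,
                                random_effects=cfg.random_effects,
                                eta_warm=warm)
    fit = FitResult(
        theta=theta, omega=omega, residual=rm, ofv=ofv, map_etas=map_etas,
        converged=converged, config=cfg, param_names=tuple(cfg.estimate),
        x=np.asarray(x_opt, dtype=float), n_outer_evals=n_eval[0],
    )
    if compute_cov:
        estimate_covariance(fit, subjects)
    return fit


def estimate_covariance(fit: FitResult, ds, step: float = 1e-3) -> np.ndarray:
    """Parameter covariance = 2 * inverse numeric Hessian of the OFV on the
    transformed scale (OFV = -2 log L, so the information matrix is H/2).
    Stores and returns the covariance."""
    subjects = ds if not isinstance(ds, PKDataset) else prepare_subjects(ds)
    packer = Parameterization(fit.param_names, fit.theta, fit.omega, fit.residual)
    warm = dict(fit.map_etas)

    def f(x: np.ndarray) -> float:
        th, om, rm = packer.unpack(x)
        ofv, etas = laplace_ofv(th, om, rm, subjects,
                                random_effects=fit.config.random_effects,
                                eta_warm=warm)
        warm.update(etas)
        return ofv

    hess = _numeric_hessian(f, fit.x, h=step)
    # guard: symmetrise and ridge to positive definiteness if needed
    hess = 0.5 * (hess + hess.T)
    eig = np.linalg.eigvalsh(hess)
    if eig.min() <= 0:
        hess = hess + (abs(eig.min()) + 1e-6) * np.eye(len(fit.x))
    fit.cov = 2.0 * np.linalg.inv(hess)
    return fit.cov


def compare_nested(fit_reduced: FitResult, fit_full: FitResult):
    """Likelihood-ratio comparison of nested fits.

    Returns ``(delta_ofv, df, p)`` with ``delta_ofv = OFV_reduced -
    OFV_full`` and ``p`` from the chi-square upper tail with df equal to the
    difference in estimated-parameter counts.
    """
    if not fit_reduced.config.is_nested_in(fit_full.config):
        raise ValueError(
            f"config {fit_reduced.config.name!r} is not nested in "
            f"{fit_full.config.name!r}"
        )
    df = len(fit_full.param_names) - len(fit_reduced.param_names)
    delta = fit_reduced.ofv - fit_full.ofv
    if df == 0:
        p = 1.0 if delta <= 0 else 0.0
        return delta, df, p
    p = float(stats.chi2.sf(max(delta, 0.0), df))
    return delta, df, p
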