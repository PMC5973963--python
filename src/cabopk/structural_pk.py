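"""Closed-form concentration-time computation for the two-compartment
disposition model with dual (lagged first-order + zero-order) absorption.

The structural model is linear: drug enters the central compartment through
two parallel routes — a fraction ``f1`` of the bioavailable dose is absorbed
first-order (rate constant ``ka``) after a lag ``alag1``, and the complement
``1 - f1`` enters at a constant (zero-order) rate over a duration ``d2``
starting at the dose time.  Disposition is the standard two-compartment model
with first-order elimination from the central compartment, parameterised by
apparent clearance CL/F, central volume Vc/F, inter-compartmental flow Q/F
and peripheral volume Vp/F.

Units are fixed throughout the package: dose in mg (free-base equivalents),
volumes in L, time in h, concentrations in ng/mL (hence the factor 1000 when
converting mg/L to ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DispositionParams",
    "AbsorptionParams",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "hybrid_disposition_constants",
    "conc_single_dose",
    "conc_profile",
    "steady_state_metrics",
    "terminal_half_life",
]

#: ng/mL per mg/L
_UNIT_SCALE = 1000.0

#: relative window within which ka is considered degenerate with alpha/beta
_KA_DEGENERACY_TOL = 1e-8
#: relative perturbation applied to a degenerate ka
_KA_PERTURB = 1e-7


class InvalidParameterError(ValueError):
    """A PK parameter violates its positivity/range invariant."""


@dataclass(frozen=True)
class DispositionParams:
    """Two-compartment disposition parameters (apparent, i.e. /F).

    cl : CL/F, L/h; vc : Vc/F, L; q : Q/F, L/h; vp : Vp/F, L.
    ``q`` may be exactly 0 for the one-compartment reduction (``vp`` ignored).
    """

    cl: float
    vc: float
    q: float
    vp: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.vc > 0):
            raise InvalidParameterError(
                f"cl and vc must be positive (got cl={self.cl}, vc={self.vc})"
            )
        if self.q < 0:
            raise InvalidParameterError(f"q must be non-negative (got {self.q})")
        if self.q > 0 and not self.vp > 0:
            raise InvalidParameterError(
                f"vp must be positive when q > 0 (got vp={self.vp})"
            )


@dataclass(frozen=True)
class AbsorptionParams:
    """Dual-absorption parameters.

    ka : first-order rate constant, 1/h; alag1 : lag on the first-order
    depot, h; d2 : duration of the zero-order input, h; f1 : fraction of the
    bioavailable dose routed to the first-order depot, in (0, 1); frel :
    overall relative bioavailability multiplier (tablet reference = 1).
    """

    ka: float
    alag1: float
    d2: float
    f1: float
    frel: float = 1.0

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise InvalidParameterError(f"ka must be positive (got {self.ka})")
        if self.alag1 < 0:
            raise InvalidParameterError(f"alag1 must be >= 0 (got {self.alag1})")
        if not self.d2 > 0:
            raise InvalidParameterError(f"d2 must be positive (got {self.d2})")
        if not 0.0 < self.f1 < 1.0:
            raise InvalidParameterError(f"f1 must be in (0,1) (got {self.f1})")
        if not self.frel > 0:
            raise InvalidParameterError(f"frel must be positive (got {self.frel})")


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose: time (h since first dose), amount (mg FBE), formulation."""

    time: float
    amount: float
    formulation: str = "tablet"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError(f"dose time must be >= 0 (got {self.time})")
        if not self.amount > 0:
            raise InvalidParameterError(f"dose amount must be > 0 (got {self.amount})")
        if self.formulation not in ("tablet", "capsule"):
            raise InvalidParameterError(
                f"formulation must be tablet|capsule (got {self.formulation!r})"
            )


@dataclass(frozen=True)
class Regimen:
    """Ordered sequence of dose events (times non-decreasing)."""

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("dose times must be non-decreasing")

    @classmethod
    def qd(cls, dose: float, n_days: int, formulation: str = "tablet") -> "Regimen":
        """Once-daily regimen: ``n_days`` doses at 0, 24, ..., 24*(n_days-1) h."""
        return cls(tuple(DoseEvent(24.0 * i, dose, formulation) for i in range(n_days)))


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment plasma concentrations (ng/mL) at given times (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise InvalidParameterError("times and concentrations must match in length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "conc": self.concentrations})


# ---------------------------------------------------------------------------
# disposition constants


def hybrid_disposition_constants(dp: DispositionParams):
    """Return (alpha, beta, k10, k12, k21) for two-compartment disposition.

    alpha and beta are the fast and slow hybrid rate constants, i.e. the
    negated eigenvalues of the linear disposition system; they satisfy
    alpha + beta = k10 + k12 + k21 and alpha * beta = k10 * k21.
    """
    k10 = dp.cl / dp.vc
    k12 = dp.q / dp.vc
    k21 = dp.q / dp.vp if dp.q > 0 else 0.0
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    # computed via the product to avoid cancellation when alpha >> beta
    beta = p / alpha if alpha > 0 else 0.0
    return alpha, beta, k10, k12, k21


def terminal_half_life(dp: DispositionParams) -> float:
    """Terminal half-life (h): ln2/beta, or ln2*vc/cl in the one-compartment
    reduction (q == 0)."""
    if dp.q == 0:
        return math.log(2.0) * dp.vc / dp.cl
    _, beta, *_ = hybrid_disposition_constants(dp)
    return math.log(2.0) / beta


def _resolve_ka(ka: float, alpha: float, beta: float) -> float:
    """Deterministically perturb ka away from alpha/beta degeneracy.

    If |ka - lambda| < 1e-8 * lambda for either hybrid constant, ka is moved
    by 1e-7 relative; this clears the degeneracy window without a separate
    limit formula and changes predictions far below any fitting tolerance.
    """
    for lam in (alpha, beta):
        if abs(ka - lam) < _KA_DEGENERACY_TOL * lam:
            ka = ka * (1.0 + _KA_PERTURB)
    return ka


# ---------------------------------------------------------------------------
# single-dose closed form


def _bolus_coeffs(dp: DispositionParams):
    """Unit-bolus-to-central response coefficients A, B with
    C(t) = (X0/vc) * (A e^{-alpha t} + B e^{-beta t})."""
    if dp.q == 0:
        raise InvalidParameterError(
            "concentration formulas require q > 0 (q = 0 is supported only "
            "for the one-compartment terminal_half_life reduction)"
        )
    alpha, beta, _, _, k21 = hybrid_disposition_constants(dp)
    denom = alpha - beta
    a = (alpha - k21) / denom
    b = (k21 - beta) / denom
    return alpha, beta, a, b


def conc_single_dose(
    dose_amount: float,
    ap: AbsorptionParams,
    dp: DispositionParams,
    t,
) -> np.ndarray | float:
    """Plasma concentration (ng/mL) at time(s) ``t`` (h) after a single dose.

    The bioavailable dose ``frel * dose_amount`` is split: ``f1`` to a lagged
    first-order depot, ``1 - f1`` to a zero-order input of duration ``d2``
    starting at the dose time.  Vectorised over ``t``; negative times give 0.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)

    alpha, beta, a, b = _bolus_coeffs(dp)
    ka = _resolve_ka(ap.ka, alpha, beta)
    amt = ap.frel * dose_amount
    c = np.zeros_like(t_arr)

    # first-order route, lagged
    d_fo = ap.f1 * amt
    u = t_arr - ap.alag1
    m = u > 0
    if np.any(m):
        pref = d_fo * ka / dp.vc
        ca = pref * ( (_k21(dp) - alpha) / ((ka - alpha) * (beta - alpha)) )
        cb = pref * ( (_k21(dp) - beta) / ((ka - beta) * (alpha - beta)) )
        ck = pref * ( (_k21(dp) - ka) / ((alpha - ka) * (beta - ka)) )
        um = u[m]
        c[m] += ca * np.exp(-alpha * um) + cb * np.exp(-beta * um) + ck * np.exp(-ka * um)

    # zero-order route, no lag
    d_zo = (1.0 - ap.f1) * amt
    if d_zo > 0:
        r0 = d_zo / ap.d2
        fa = a / alpha
        fb = b / beta
        m1 = (t_arr > 0) & (t_arr <= ap.d2)
        if np.any(m1):
            tt = t_arr[m1]
            c[m1] += (r0 / dp.vc) * (
                fa * (1.0 - np.exp(-alpha * tt)) + fb * (1.0 - np.exp(-beta * tt))
            )
        m2 = t_arr > ap.d2
        if np.any(m2):
            tt = t_arr[m2]
            c[m2] += (r0 / dp.vc) * (
                fa * (1.0 - math.exp(-alpha * ap.d2)) * np.exp(-alpha * (tt - ap.d2))
                + fb * (1.0 - math.exp(-beta * ap.d2)) * np.exp(-beta * (tt - ap.d2))
            )

    c *= _UNIT_SCALE
    return float(c[0]) if scalar else c


def _k21(dp: DispositionParams) -> float:
    return dp.q / dp.vp if dp.q > 0 else 0.0


def conc_profile(
    reg: Regimen,
    ap_per_dose: AbsorptionParams | Sequence[AbsorptionParams],
    dp: DispositionParams,
    times,
) -> ConcentrationProfile:
    """Multi-dose profile by superposition (linear kinetics).

    ``ap_per_dose`` is either one AbsorptionParams shared by every dose or a
    sequence with one entry per dose (dose-dependent ka / formulation effects
    may differ per dose).  Times before 0 raise; an empty regimen returns an
    all-zero profile.
    """
    t_arr = np.asarray(times, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("observation times must be >= 0")
    if isinstance(ap_per_dose, AbsorptionParams):
        aps = [ap_per_dose] * len(reg.doses)
    else:
        aps = list(ap_per_dose)
        if len(aps) != len(reg.doses):
            raise InvalidParameterError(
                f"need one AbsorptionParams per dose ({len(reg.doses)}), got {len(aps)}"
            )
    c = np.zeros_like(t_arr)
    for dose, ap in zip(reg.doses, aps):
        c += conc_single_dose(dose.amount, ap, dp, t_arr - dose.time)
    return ConcentrationProfile(t_arr, c)


# ---------------------------------------------------------------------------
# steady state


def _tail_exp_coeffs(dose: float, ap: AbsorptionParams, dp: DispositionParams):
    """Exponential-sum representation of the single-dose profile, valid for
    t >= max(alag1, d2): C(t) = 1000 * sum_k coeff_k * exp(-lam_k * t)."""
    alpha, beta, a, b = _bolus_coeffs(dp)
    ka = _resolve_ka(ap.ka, alpha, beta)
    k21 = _k21(dp)
    amt = ap.frel * dose

    lams = np.array([alpha, beta, ka])
    coeffs = np.zeros(3)

    d_fo = ap.f1 * amt
    pref = d_fo * ka / dp.vc
    coeffs[0] += pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha)) * math.exp(alpha * ap.alag1)
    coeffs[1] += pref * (k21 - beta) / ((ka - beta) * (alpha - beta)) * math.exp(beta * ap.alag1)
    coeffs[2] += pref * (k21 - ka) / ((alpha - ka) * (beta - ka)) * math.exp(ka * ap.alag1)

    d_zo = (1.0 - ap.f1) * amt
    if d_zo > 0:
        r0 = d_zo / ap.d2
        coeffs[0] += (r0 / dp.vc) * (a / alpha) * (math.exp(alpha * ap.d2) - 1.0)
        coeffs[1] += (r0 / dp.vc) * (b / beta) * (math.exp(beta * ap.d2) - 1.0)

    return lams, coeffs


def conc_steady_state(
    ap: AbsorptionParams, dp: DispositionParams, dose: float, tau: float, t
) -> np.ndarray | float:
    """Steady-state concentration within a dosing interval.

    ``t`` is time since the most recent dose, in [0, tau]; values are the
    limit of the finite superposition after infinitely many tau-spaced doses.
    The first few intervals (while the lag / zero-order input is still
    piecewise) are summed explicitly; the remaining geometric tail of each
    exponential term is summed in closed form (division by 1 - e^{-lam tau}).
    """
    if not tau > 0:
        raise InvalidParameterError(f"tau must be positive (got {tau})")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.asarray(t).ndim == 0

    t_star = max(ap.alag1, ap.d2)
    n_explicit = int(math.ceil(t_star / tau)) + 1
    c = np.zeros_like(t_arr)
    for n in range(n_explicit):
        c += conc_single_dose(dose, ap, dp, t_arr + n * tau)
    lams, coeffs = _tail_exp_coeffs(dose, ap, dp)
    shift = t_arr + n_explicit * tau
    for lam, coef in zip(lams, coeffs):
        c += _UNIT_SCALE * coef * np.exp(-lam * shift) / (1.0 - math.exp(-lam * tau))
    return float(c[0]) if scalar else c


def steady_state_metrics(
    ap: AbsorptionParams, dp: DispositionParams, dose: float, tau: float
):
    """Steady-state exposure metrics for ``dose`` mg every ``tau`` h.

    Returns (cmax_ss, cmin_ss, auc_tau_ss, tmax_ss).  cmin_ss is the trough
    (pre-dose) concentration; cmax_ss is located by a 0.05-h grid search over
    one interval refined by bounded scalar minimisation; auc_tau_ss is the
    exact mass-balance value 1000 * frel * dose / cl.
    """
    from scipy.optimize import minimize_scalar

    grid = np.arange(0.0, tau + 1e-9, 0.05)
    cs = conc_steady_state(ap, dp, dose, tau, grid)
    i = int(np.argmax(cs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda x: -conc_steady_state(ap, dp, dose, tau, float(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        tmax = float(res.x)
        cmax = float(-res.fun)
    else:  # pragma: no cover - degenerate single-point grid
        tmax, cmax = float(grid[i]), float(cs[i])
    cmin = float(conc_steady_state(ap, dp, dose, tau, tau))
    auc = _UNIT_SCALE * ap.frel * dose / dp.cl
    return cmax, cmin, auc, tmax
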