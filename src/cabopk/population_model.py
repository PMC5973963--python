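"""Between-subject and residual variability.

Inter-individual variability (IIV) is log-normal: an individual's parameter
is the typical value times ``exp(eta)``, with ``eta`` drawn from a
multivariate normal with mean zero and covariance ``Omega`` over
(Ka, CL/F, Vc/F, F1).  F1 is bounded in (0,1), so its random effect is
applied on the logit scale instead of the exp scale.  Residual variability
is additive on the log-concentration scale: ``ln Y = ln C + eps`` with
``eps ~ N(0, sigma2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structural_pk import AbsorptionParams, DispositionParams

__all__ = [
    "ETA_LABELS",
    "OmegaMatrix",
    "ResidualModel",
    "IndividualParams",
    "draw_etas",
    "apply_iiv",
    "individual_model_params",
    "add_residual_error",
    "default_omega",
    "default_residual",
    "PRINTED_CL_VC_TERM",
]

log = logging.getLogger(__name__)

ETA_LABELS = ("ka", "cl", "vc", "f1")

#: published variances of the final-model random effects, in ETA_LABELS order
_FM_OMEGA_DIAG = (2.063, 0.202, 0.233, 0.466)
#: published residual variance on the log scale
_FM_SIGMA2 = 0.118
#: The published CL/F:Vc/F omega term, 2.475, exceeds the Cauchy-Schwarz bound
#: sqrt(0.202 * 0.233) ~ 0.217 and therefore cannot be the CL-Vc covariance of
#: a valid matrix; it is kept here as metadata only and never enters a
#: simulation.  ``default_omega`` uses a configurable CL-Vc correlation.
PRINTED_CL_VC_TERM = 2.475


class OmegaError(ValueError):
    """The IIV covariance matrix violates an invariant."""


@dataclass(frozen=True)
class OmegaMatrix:
    """4x4 variance-covariance matrix of the IIV random effects over
    (Ka, CL/F, Vc/F, F1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise OmegaError(f"Omega must be 4x4 (got shape {m.shape})")
        if not np.allclose(m, m.T, atol=1e-12):
            raise OmegaError("Omega must be symmetric")
        if np.any(np.diag(m) < 0):
            raise OmegaError("Omega diagonal must be non-negative")
        sd = np.sqrt(np.diag(m))
        bound = np.outer(sd, sd)
        off = ~np.eye(4, dtype=bool)
        if np.any(np.abs(m[off]) > bound[off] + 1e-12):
            raise OmegaError(
                "an off-diagonal Omega element exceeds the Cauchy-Schwarz bound "
                "sqrt(omega_ii * omega_jj)"
            )
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise OmegaError("Omega must be positive semidefinite")
        object.__setattr__(self, "matrix", m)
        self.matrix.setflags(write=False)

    @classmethod
    def diagonal(cls, ka: float, cl: float, vc: float, f1: float) -> "OmegaMatrix":
        return cls(np.diag([ka, cl, vc, f1]))

    @classmethod
    def zero(cls) -> "OmegaMatrix":
        return cls(np.zeros((4, 4)))

    def variance(self, label: str) -> float:
        return float(self.matrix[ETA_LABELS.index(label), ETA_LABELS.index(label)])

    def with_variance(self, label: str, value: float) -> "OmegaMatrix":
        m = self.matrix.copy()
        i = ETA_LABELS.index(label)
        m[i, i] = value
        return OmegaMatrix(m)


def default_omega(cl_vc_corr: float = 0.5) -> OmegaMatrix:
    """Final-model IIV variances on the diagonal plus a CL-Vc correlation
    (default 0.5; see ``PRINTED_CL_VC_TERM`` for why the printed off-diagonal
    term is unusable)."""
    m = np.diag(_FM_OMEGA_DIAG).astype(float)
    cov = cl_vc_corr * math.sqrt(_FM_OMEGA_DIAG[1] * _FM_OMEGA_DIAG[2])
    m[1, 2] = m[2, 1] = cov
    return OmegaMatrix(m)


@dataclass(frozen=True)
class ResidualModel:
    """Log-additive residual error with variance sigma2."""

    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0 (got {self.sigma2})")


def default_residual() -> ResidualModel:
    return ResidualModel(_FM_SIGMA2)


@dataclass(frozen=True)
class IndividualParams:
    """Realized subject-level Ka, CL/F, Vc/F and F1 (other parameters stay
    at their typical values)."""

    ka: float
    cl: float
    vc: float
    f1: float

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.cl > 0 and self.vc > 0):
            raise ValueError("ka, cl and vc must be positive")
        if not 0.0 < self.f1 < 1.0:
            raise ValueError(f"f1 must be in (0,1) (got {self.f1})")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_etas(n: int, omega: OmegaMatrix, seed) -> np.ndarray:
    """Draw ``n`` IIV vectors eta ~ N(0, Omega); rows in ETA_LABELS order.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    return rng.multivariate_normal(
        np.zeros(4), omega.matrix, size=n, method="svd"
    )


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def apply_iiv(ap: AbsorptionParams, dp: DispositionParams, eta) -> IndividualParams:
    """Realize one subject's parameters from typical values and an eta
    4-vector (order ka, cl, vc, f1).  Ka, CL and Vc are multiplied by
    ``exp(eta)``; F1 is perturbed on the logit scale."""
    eta = np.asarray(eta, dtype=float)
    return IndividualParams(
        ka=ap.ka * math.exp(eta[0]),
        cl=dp.cl * math.exp(eta[1]),
        vc=dp.vc * math.exp(eta[2]),
        f1=expit(logit(ap.f1) + eta[3]),
    )


def individual_model_params(
    ap: AbsorptionParams, dp: DispositionParams, ip: IndividualParams
) -> tuple[AbsorptionParams, DispositionParams]:
    """Merge realized individual values into full parameter objects."""
    from dataclasses import replace

    return (
        replace(ap, ka=ip.ka, f1=ip.f1),
        replace(dp, cl=ip.cl, vc=ip.vc),
    )


def add_residual_error(conc, rm: ResidualModel, seed) -> np.ndarray:
    """Observed concentrations Y = C * exp(eps), eps ~ N(0, sigma2).

    Non-positive predicted concentrations cannot carry a log-scale error;
    they are returned as 0 with a logged warning.
    """
    rng = _as_rng(seed)
    c = np.atleast_1d(np.asarray(conc, dtype=float))
    y = np.zeros_like(c)
    pos = c > 0
    n_bad = int((~pos).sum())
    if n_bad:
        log.warning(
            "add_residual_error: %d non-positive predicted concentration(s) "
            "skipped (log-scale residual undefined at 0)", n_bad,
        )
    eps = rng.normal(0.0, math.sqrt(rm.sigma2), size=int(pos.sum()))
    y[pos] = c[pos] * np.exp(eps)
    return y
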