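"""YAML serialization of model configurations (fixed effects, Omega, sigma2)."""

from __future__ import annotations

import numpy as np
import yaml

from .covariate_model import ThetaVector
from .population_model import OmegaMatrix, ResidualModel

__all__ = ["save_model", "load_model"]


def save_model(path, theta: ThetaVector, omega: OmegaMatrix,
               rm: ResidualModel) -> None:
    """Write a model configuration as a flat YAML map."""
    doc = {
        "theta": theta.to_dict(),
        "omega": [[float(v) for v in row] for row in omega.matrix],
        "sigma2": float(rm.sigma2),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model(path):
    """Read a model configuration; returns (ThetaVector, OmegaMatrix,
    ResidualModel)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    theta = ThetaVector.from_dict(doc["theta"])
    omega = OmegaMatrix(np.asarray(doc["omega"], dtype=float))
    rm = ResidualModel(float(doc["sigma2"]))
    return theta, omega, rm
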