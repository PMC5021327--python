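"""Similarity coefficients between two force curves.

``fit_co`` is a percent point-wise agreement score,
``100 * (1 - sqrt(mean(delta_i**2)))`` where ``delta_i`` is the per-sample
difference normalized to the common (joint) maximum of the two curves; 100
means a perfect match.  ``area_co`` is the ratio of the areas under the
reference and model curves (trapezoid rule); 1 means equal total impulse,
values above 1 mean the reference develops more force than the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ValidationError
from .trace import ForceTrace

__all__ = ["SimilarityReport", "fit_co", "area_co", "compare"]


@dataclass(frozen=True)
class SimilarityReport:
    fit_co: float
    area_co: float


def _check_grids(reference: ForceTrace, model: ForceTrace) -> None:
    if not reference.same_grid(model):
        raise GridMismatchError(
            "traces are sampled on different grids: "
            f"(t0={reference.t0}, dt={reference.dt}, n={reference.n}) vs "
            f"(t0={model.t0}, dt={model.dt}, n={model.n})"
        )


def fit_co(reference: ForceTrace, model: ForceTrace) -> float:
    """Percent fit coefficient between two traces on the same grid."""
    _check_grids(reference, model)
    common_max = max(float(np.max(reference.force)), float(np.max(model.force)))
    if common_max <= 0:
        raise ValidationError("fit coefficient undefined: both traces are non-positive")
    delta = (reference.force - model.force) / common_max
    return 100.0 * (1.0 - float(np.sqrt(np.mean(delta**2))))


def area_co(reference: ForceTrace, model: ForceTrace) -> float:
    """Ratio of the areas under the reference and the model curves."""
    _check_grids(reference, model)
    area_mod = float(np.trapezoid(model.force, dx=model.dt))
    if area_mod <= 0:
        raise ValidationError("area coefficient undefined: model curve has no positive area")
    area_ref = float(np.trapezoid(reference.force, dx=reference.dt))
    return area_ref / area_mod


def compare(reference: ForceTrace, model: ForceTrace) -> SimilarityReport:
    """Both similarity coefficients in one report."""
    return SimilarityReport(fit_co(reference, model), area_co(reference, model))
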