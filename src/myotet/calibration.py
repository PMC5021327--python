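"""Calibration of the angle power law and the time-prolongation lines.

``sensitivity_scan`` searches a grid of angles around a starting value for
the angle whose full prediction best matches a reference recording — the
procedure that turns the per-unit model angles into empirically optimal
ones.  ``fit_power_model`` then refits ``alpha = a * ratio**b`` to a corpus
of (force ratio, optimal angle) points, and ``fit_time_param_lines``
refits the linear prolongation of the contraction and half-relaxation
times against the normalized starting force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import ValidationError
from .metrics import SimilarityReport, compare
from .prediction import MotorUnit, PredictionConfig, StimulationPattern, full_predict
from .trace import ForceTrace

__all__ = [
    "ScanResult",
    "PowerFit",
    "LineFit",
    "sensitivity_scan",
    "fit_power_model",
    "fit_time_param_lines",
]


@dataclass(frozen=True)
class ScanResult:
    """Outcome of an angle sensitivity scan for one motor unit."""

    alpha: float
    report: SimilarityReport
    alphas: np.ndarray
    fit_cos: np.ndarray
    area_cos: np.ndarray


@dataclass(frozen=True)
class PowerFit:
    """Fitted power law y = a * x**b and its root-mean-square error."""

    a: float
    b: float
    rmse: float

    def __call__(self, x):
        return self.a * np.asarray(x, dtype=float) ** self.b


@dataclass(frozen=True)
class LineFit:
    """Fitted line y = intercept + slope * x with the Pearson correlation.

    ``r`` is NaN (and ``degenerate`` True) when the response is constant.
    """

    intercept: float
    slope: float
    r: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.r)


#: FitCo ties closer than this are broken by the area coefficient.
FITCO_TIE = 0.01


def sensitivity_scan(
    mu: MotorUnit,
    pattern: StimulationPattern,
    reference: ForceTrace,
    alpha1: float,
    half_width: float = 20.0,
    step: float = 0.1,
    cfg: PredictionConfig | None = None,
) -> ScanResult:
    """Grid-search the angle giving the full prediction closest to ``reference``.

    The grid spans the integer value of ``alpha1`` +/- ``half_width`` in
    ``step``-degree increments (a zero-width scan evaluates ``alpha1``
    itself).  The best angle maximizes the fit coefficient; ties within
    :data:`FITCO_TIE` percent are broken by the area coefficient closest
    to 1.
    """
    cfg = cfg or PredictionConfig()
    if half_width < 0 or step <= 0:
        raise ValidationError("scan half_width must be >= 0 and step > 0")
    if half_width == 0:
        alphas = np.array([alpha1])
    else:
        center = float(round(alpha1))
        n_steps = int(round(half_width / step))
        alphas = center + step * np.arange(-n_steps, n_steps + 1)
        alphas = alphas[(alphas > 0.0) & (alphas < 180.0)]
    if alphas.size == 0:
        raise ValidationError("sensitivity scan grid is empty")
    fit_cos = np.empty(alphas.size)
    area_cos = np.empty(alphas.size)
    for k, alpha in enumerate(alphas):
        trace, _ = full_predict(mu, pattern, replace(cfg, alpha=float(alpha)), grid=reference)
        rep = compare(reference, trace)
        fit_cos[k] = rep.fit_co
        area_cos[k] = rep.area_co
    best_fit = float(np.max(fit_cos))
    tied = np.flatnonzero(fit_cos >= best_fit - FITCO_TIE)
    winner = tied[int(np.argmin(np.abs(area_cos[tied] - 1.0)))]
    return ScanResult(
        float(alphas[winner]),
        SimilarityReport(float(fit_cos[winner]), float(area_cos[winner])),
        alphas,
        fit_cos,
        area_cos,
    )


def fit_power_model(points) -> PowerFit:
    """Least-squares fit of y = a * x**b to (x, y) pairs, in linear space.

    The fit minimizes the RMSE of y directly (not log-log least squares);
    a log-log line only provides the starting values.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValidationError("fit_power_model needs at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("power-model fitting requires positive x and y")
    if np.ptp(x) == 0:
        raise ValidationError("power-model fit is degenerate: all x values are equal")
    b0, log_a0 = np.polyfit(np.log(x), np.log(y), 1)
    if pts.shape[0] == 2:
        # exactly determined: the log-log line interpolates both points
        a, b = float(np.exp(log_a0)), float(b0)
    else:
        (a, b), _ = curve_fit(
            lambda xx, aa, bb: aa * xx**bb, x, y, p0=(np.exp(log_a0), b0), maxfev=10000
        )
    rmse = float(np.sqrt(np.mean((a * x**b - y) ** 2)))
    return PowerFit(float(a), float(b), rmse)


def fit_time_param_lines(points) -> tuple[LineFit, LineFit]:
    """Fit the two time-prolongation lines from decomposition data.

    ``points`` are triples ``(x, tc_ratio, thr_ratio)`` where ``x`` is the
    starting force normalized to the first-twitch amplitude and the ratios
    normalize T_c(i) and T_hr(i) to T_c(1).  Returns the contraction-time
    and half-relaxation-time line fits with their Pearson correlations.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("fit_time_param_lines needs at least two (x, y1, y2) points")
    x = pts[:, 0]
    if np.ptp(x) == 0:
        raise ValidationError("line fit is degenerate: all x values are equal")

    def fit_one(y: np.ndarray) -> LineFit:
        if np.ptp(y) == 0:
            return LineFit(float(y[0]), 0.0, float("nan"))
        res = linregress(x, y)
        return LineFit(float(res.intercept), float(res.slope), float(res.rvalue))

    return fit_one(pts[:, 1]), fit_one(pts[:, 2])
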