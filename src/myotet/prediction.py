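"""Prediction of unfused tetanic force from single-twitch parameters.

The model rests on an empirical regularity of decomposed motor-unit (MU)
tetani: the amplitude of each successive twitch-like contraction, normalized
to the first twitch, is a linear function of the force level ``F_tetmin`` at
which that contraction starts, and the slope of that line — expressed as the
angle ``alpha`` between the line and the ordinate — is specific to the MU.
``alpha`` itself is predicted from the ratio of the maximal fused-tetanus
force to the single-twitch amplitude by a power law; contraction and
half-relaxation times lengthen linearly with the normalized starting force.

Given only the six first-twitch parameters, the fused-tetanus maximum
``F_mftf`` and a pulse train, the "full prediction" loop models contraction
``n`` from the force level reached by the sum of the ``n - 1`` previously
modeled contractions at the time of pulse ``n``, then superimposes all
modeled twitches into the tetanic force curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .trace import ForceTrace
from .twitch import TwitchCurve, TwitchParams, build_twitch

__all__ = [
    "MotorUnit",
    "StimulationPattern",
    "PredictionConfig",
    "ContractionTrain",
    "ALPHA_MODELS",
    "compute_alpha",
    "cot_degrees",
    "predict_contraction",
    "full_predict",
    "predict_with_observed_minima",
    "sum_equal_twitches",
]

logger = logging.getLogger(__name__)

MU_TYPES = ("S", "FR", "FF")

#: Power-law coefficients (a, b) of alpha = a * (F_mftf / F_max(1)) ** b, degrees.
#: "base" is the law fitted to the angles of the decomposed training MUs;
#: "refined" is the law refitted to the sensitivity-analysis optimal angles.
ALPHA_MODELS: dict[str, tuple[float, float]] = {
    "base": (108.8, -0.2603),
    "refined": (117.2, -0.3144),
}


@dataclass(frozen=True)
class MotorUnit:
    """A motor unit: identity, physiological type, first twitch and F_mftf.

    ``f_mftf`` is the maximal force of the fused tetanus (150 Hz
    stimulation), in mN.  The twitch-to-tetanus ratio
    ``p = first_twitch.f_max / f_mftf`` must lie in (0, 1].
    """

    mu_id: str
    mu_type: str
    first_twitch: TwitchParams
    f_mftf: float

    def __post_init__(self) -> None:
        if self.mu_type not in MU_TYPES:
            raise ValidationError(f"mu_type must be one of {MU_TYPES}, got {self.mu_type!r}")
        if not (self.f_mftf > 0 and np.isfinite(self.f_mftf)):
            raise ValidationError(f"f_mftf must be positive, got {self.f_mftf}")
        if self.first_twitch.f_max <= 0:
            raise ValidationError("the first twitch must have positive amplitude")
        if self.first_twitch.f_max > self.f_mftf:
            raise ValidationError(
                "twitch-to-tetanus ratio out of range: "
                f"f_max(1)={self.first_twitch.f_max} exceeds f_mftf={self.f_mftf}"
            )

    @property
    def p(self) -> float:
        """Twitch-to-tetanus force ratio."""
        return self.first_twitch.f_max / self.f_mftf

    @property
    def tetanus_twitch_ratio(self) -> float:
        """F_mftf / F_max(1) = 1 / p; the predictor of the angle alpha."""
        return self.f_mftf / self.first_twitch.f_max


@dataclass(frozen=True)
class StimulationPattern:
    """An ordered train of stimulus times (ms); first pulse at t = 0."""

    pulse_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", times)
        if times.ndim != 1 or times.size < 1:
            raise ValidationError("a stimulation pattern needs at least one pulse")
        if not np.all(np.isfinite(times)):
            raise ValidationError("pulse times must be finite")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValidationError("interpulse intervals must all be positive")

    @classmethod
    def from_ipis(cls, ipis: Sequence[float]) -> "StimulationPattern":
        """Build from a list of interpulse intervals (ms); n IPIs give n+1 pulses."""
        ipis = np.asarray(ipis, dtype=float)
        if ipis.size and np.any(ipis <= 0):
            bad = int(np.argmax(ipis <= 0))
            raise ValidationError(f"interpulse interval {bad + 1} is not positive: {ipis[bad]}")
        return cls(np.concatenate([[0.0], np.cumsum(ipis)]))

    @classmethod
    def constant(cls, freq_hz: float, n_pulses: int) -> "StimulationPattern":
        """Constant-frequency train of ``n_pulses`` pulses."""
        if freq_hz <= 0:
            raise ValidationError("stimulation frequency must be positive")
        return cls(np.arange(n_pulses) * (1000.0 / freq_hz))

    @classmethod
    def unchecked(cls, pulse_times: Sequence[float]) -> "StimulationPattern":
        """Bypass the increasing-times check (degenerate patterns for testing)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "pulse_times", np.asarray(pulse_times, dtype=float))
        return obj

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    @property
    def ipis(self) -> np.ndarray:
        return np.diff(self.pulse_times)


@dataclass(frozen=True)
class PredictionConfig:
    """Tunable constants of the prediction algorithm.

    ``alpha_model`` selects the power law for the angle ("base" or
    "refined"); an explicit ``alpha`` (degrees) overrides it.  ``tc_coeffs``
    and ``thr_coeffs`` are the (intercept, slope) of the linear prolongation
    of the contraction and half-relaxation times with the normalized
    starting force; both lines multiply the first contraction time T_c(1).
    ``lead_offset_in_sampling`` shifts the force-level read-out of the full
    prediction from the pulse time to pulse time + T_lead(1).  ``step`` is
    the sampling step of synthesized traces (ms).
    """

    alpha_model: str = "base"
    alpha: float | None = None
    tc_coeffs: tuple[float, float] = (1.04, 0.274)
    thr_coeffs: tuple[float, float] = (2.397, 0.3509)
    lead_offset_in_sampling: bool = False
    step: float = 0.1
    clamp_negative_amplitude: bool = True

    def __post_init__(self) -> None:
        if self.alpha is None and self.alpha_model not in ALPHA_MODELS:
            raise ValidationError(
                f"alpha_model must be one of {tuple(ALPHA_MODELS)}, got {self.alpha_model!r}"
            )
        if self.alpha is not None and not (0.0 < self.alpha < 180.0):
            raise ValidationError(f"alpha must lie in (0, 180) degrees, got {self.alpha}")
        for name, pair in (("tc_coeffs", self.tc_coeffs), ("thr_coeffs", self.thr_coeffs)):
            if len(pair) != 2 or not np.all(np.isfinite(pair)):
                raise ValidationError(f"{name} must be two finite numbers, got {pair}")
        if not (self.step > 0 and np.isfinite(self.step)):
            raise ValidationError(f"sampling step must be positive, got {self.step}")


@dataclass(frozen=True)
class ContractionTrain:
    """Per-stimulus modeled contractions of one tetanus.

    For each pulse: the stimulus time, the fitted/predicted twitch
    parameters, and the force level ``f_tetmin`` at which the contraction
    started.
    """

    stim_times: np.ndarray
    contractions: tuple[TwitchParams, ...]
    f_tetmin: np.ndarray
    alpha: float | None = field(default=None)

    def __post_init__(self) -> None:
        stim = np.asarray(self.stim_times, dtype=float)
        ftm = np.asarray(self.f_tetmin, dtype=float)
        object.__setattr__(self, "stim_times", stim)
        object.__setattr__(self, "f_tetmin", ftm)
        object.__setattr__(self, "contractions", tuple(self.contractions))
        if not (stim.size == len(self.contractions) == ftm.size):
            raise ValidationError("train fields must have one entry per stimulus")

    def __len__(self) -> int:
        return len(self.contractions)

    def __iter__(self) -> Iterator[tuple[float, TwitchParams, float]]:
        return iter(zip(self.stim_times, self.contractions, self.f_tetmin))

    @property
    def end_time(self) -> float:
        """Time at which the last modeled contraction has fully relaxed."""
        return max(t + p.end_time for t, p in zip(self.stim_times, self.contractions))

    def curves(self) -> list[TwitchCurve]:
        return [build_twitch(p) for p in self.contractions]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus_time": t,
                "f_tetmin": f,
                "f_max": p.f_max,
                "t_lead": p.t_lead,
                "t_hc": p.t_hc,
                "t_c": p.t_c,
                "t_hr": p.t_hr,
                "t_tw": p.t_tw,
            }
            for t, p, f in self
        ]
        return pd.DataFrame(rows)


def compute_alpha(ratio: float, model: str = "refined") -> float:
    """Angle alpha (degrees) from the fused-tetanus-to-twitch force ratio.

    ``alpha = a * ratio ** b`` with (a, b) taken from :data:`ALPHA_MODELS`.
    The ratio must be >= 1 because a twitch cannot exceed the fused tetanus.
    """
    if model not in ALPHA_MODELS:
        raise ValidationError(f"unknown alpha model {model!r}; choose from {tuple(ALPHA_MODELS)}")
    if not (ratio >= 1.0 and np.isfinite(ratio)):
        raise ValidationError(f"F_mftf/F_max(1) ratio must be >= 1, got {ratio}")
    a, b = ALPHA_MODELS[model]
    return a * ratio**b


def cot_degrees(alpha_deg: float) -> float:
    """Cotangent of an angle in degrees; exactly 0 at 90 degrees."""
    if alpha_deg == 90.0:
        return 0.0
    rad = math.radians(alpha_deg)
    return math.cos(rad) / math.sin(rad)


def predict_contraction(
    mu: MotorUnit,
    f_tetmin: float,
    alpha: float,
    cfg: PredictionConfig | None = None,
) -> TwitchParams:
    """Parameters of a contraction starting from force level ``f_tetmin``.

    A contraction starting from a fully relaxed unit (``f_tetmin == 0``)
    reproduces the first twitch unchanged.  Otherwise, with
    ``x = f_tetmin / f_max(1)``::

        f_max(i) = (1 + cot(alpha) * x) * f_max(1)     (clamped at 0)
        t_c(i)   = (p1 + p2 * x) * t_c(1)
        t_hr(i)  = (q1 + q2 * x) * t_c(1)
        t_hc(i)  = t_hc(1) * t_c(i) / t_c(1)
        t_tw(i)  = t_tw(1) * t_hr(i) / t_hr(1)
        t_lead(i)= t_lead(1)

    Both time lines multiply the *contraction* time of the first twitch.
    """
    cfg = cfg or PredictionConfig()
    if not (f_tetmin >= 0 and np.isfinite(f_tetmin)):
        raise ValidationError(f"f_tetmin must be non-negative, got {f_tetmin}")
    if not 0.0 < alpha < 180.0:
        raise ValidationError(f"alpha must lie in (0, 180) degrees, got {alpha}")
    first = mu.first_twitch
    if f_tetmin == 0.0:
        return first
    x = f_tetmin / first.f_max
    amplitude = (1.0 + cot_degrees(alpha) * x) * first.f_max
    if amplitude < 0:
        if cfg.clamp_negative_amplitude:
            amplitude = 0.0
        else:
            raise NumericalError(
                f"predicted amplitude is negative ({amplitude:.4g} mN) at "
                f"f_tetmin={f_tetmin:.4g}, alpha={alpha:.4g}"
            )
    p1, p2 = cfg.tc_coeffs
    q1, q2 = cfg.thr_coeffs
    t_c = (p1 + p2 * x) * first.t_c
    t_hr = (q1 + q2 * x) * first.t_c
    if not t_c < t_hr:
        raise NumericalError(
            f"predicted time ordering t_c < t_hr violated (t_c={t_c:.4g}, t_hr={t_hr:.4g}); "
            f"check tc_coeffs={cfg.tc_coeffs} and thr_coeffs={cfg.thr_coeffs}"
        )
    t_hc = first.t_hc * t_c / first.t_c
    t_tw = first.t_tw * t_hr / first.t_hr
    if not t_hr < t_tw:
        raise NumericalError(
            f"predicted time ordering t_hr < t_tw violated (t_hr={t_hr:.4g}, t_tw={t_tw:.4g}); "
            "the first twitch's t_tw/t_hr ratio is too small for these coefficients"
        )
    return TwitchParams(amplitude, first.t_lead, t_hc, t_c, t_hr, t_tw)


def _resolve_alpha(mu: MotorUnit, cfg: PredictionConfig) -> float:
    if cfg.alpha is not None:
        return cfg.alpha
    return compute_alpha(mu.tetanus_twitch_ratio, cfg.alpha_model)


def _evaluate_prior_sum(curves: list[TwitchCurve], stim_times: np.ndarray, t: float) -> float:
    """Force of all already-modeled contractions at absolute time ``t``."""
    total = 0.0
    for stim, curve in zip(stim_times, curves):
        rel = t - stim
        if 0.0 < rel <= curve.params.end_time:
            total += curve(rel)
    return total


def synthesize_trace(
    train: ContractionTrain,
    step: float,
    t0: float = 0.0,
    grid: ForceTrace | None = None,
    t_end: float | None = None,
) -> ForceTrace:
    """Superimpose the train's twitch curves on a uniform grid.

    ``grid`` reuses another trace's sampling exactly; otherwise the grid
    spans ``[t0, t_end]`` (default: until the last contraction relaxes).
    Each curve is evaluated only over its own support for speed.
    """
    if grid is not None:
        t0, step, n = grid.t0, grid.dt, grid.n
    else:
        if t_end is None:
            t_end = train.end_time if len(train) else t0 + step
        n = max(2, int(math.ceil((t_end - t0) / step)) + 1)
    force = np.zeros(n)
    for stim, params in zip(train.stim_times, train.contractions):
        if params.f_max == 0:
            continue
        curve = build_twitch(params)
        a = stim + params.t_lead
        b = stim + params.end_time
        i0 = max(0, int(math.ceil((a - t0) / step)))
        i1 = min(n - 1, int(math.floor((b - t0) / step)))
        if i1 < i0:
            continue
        ts = t0 + step * np.arange(i0, i1 + 1)
        force[i0 : i1 + 1] += curve(ts - stim)
    return ForceTrace(t0, step, force)


def _predict_train(
    mu: MotorUnit,
    pattern: StimulationPattern,
    cfg: PredictionConfig,
    observed_f_tetmin: np.ndarray | None,
) -> ContractionTrain:
    alpha = _resolve_alpha(mu, cfg)
    curves: list[TwitchCurve] = []
    contractions: list[TwitchParams] = []
    f_tetmins: list[float] = []
    lead = mu.first_twitch.t_lead if cfg.lead_offset_in_sampling else 0.0
    for n, t_pulse in enumerate(pattern.pulse_times):
        if observed_f_tetmin is not None:
            f_tetmin = float(observed_f_tetmin[n])
        elif n == 0:
            f_tetmin = 0.0
        else:
            f_tetmin = _evaluate_prior_sum(curves, pattern.pulse_times, t_pulse + lead)
        params = predict_contraction(mu, f_tetmin, alpha, cfg)
        logger.info(
            "contraction %d: t=%.2f ms, f_tetmin=%.4f mN, f_max=%.4f mN, "
            "t_c=%.3f ms, t_hr=%.3f ms",
            n + 1, t_pulse, f_tetmin, params.f_max, params.t_c, params.t_hr,
        )
        contractions.append(params)
        curves.append(build_twitch(params))
        f_tetmins.append(f_tetmin)
    return ContractionTrain(pattern.pulse_times.copy(), tuple(contractions), np.array(f_tetmins), alpha)


def full_predict(
    mu: MotorUnit,
    pattern: StimulationPattern,
    cfg: PredictionConfig | None = None,
    grid: ForceTrace | None = None,
) -> tuple[ForceTrace, ContractionTrain]:
    """Predict an unfused tetanus from the first twitch, F_mftf and a pattern.

    The starting force level of every contraction after the first is read
    from the running sum of the previously predicted contractions at the
    pulse time; no recorded force is consulted.  Returns the synthesized
    trace and the train of per-contraction parameters.
    """
    cfg = cfg or PredictionConfig()
    train = _predict_train(mu, pattern, cfg, None)
    return synthesize_trace(train, cfg.step, grid=grid), train


def predict_with_observed_minima(
    mu: MotorUnit,
    pattern: StimulationPattern,
    observed_f_tetmin: Sequence[float],
    cfg: PredictionConfig | None = None,
    grid: ForceTrace | None = None,
) -> tuple[ForceTrace, ContractionTrain]:
    """Predict a tetanus with starting force levels taken from a recording.

    ``observed_f_tetmin`` holds one local-minimum force per pulse (the
    first entry must be 0: the first contraction starts at rest).
    """
    cfg = cfg or PredictionConfig()
    observed = np.asarray(observed_f_tetmin, dtype=float)
    if observed.size != pattern.n_pulses:
        raise ValidationError(
            f"need one observed force level per pulse: got {observed.size}, "
            f"expected {pattern.n_pulses}"
        )
    if np.any(observed < 0):
        raise ValidationError("observed force levels must be non-negative")
    if observed[0] != 0.0:
        raise ValidationError("the first contraction must start from zero force")
    train = _predict_train(mu, pattern, cfg, observed)
    return synthesize_trace(train, cfg.step, grid=grid), train


def sum_equal_twitches(
    mu: MotorUnit,
    pattern: StimulationPattern,
    cfg: PredictionConfig | None = None,
    grid: ForceTrace | None = None,
) -> ForceTrace:
    """Baseline model: superimpose identical first twitches at every pulse."""
    cfg = cfg or PredictionConfig()
    n = pattern.n_pulses
    train = ContractionTrain(
        pattern.pulse_times.copy(), tuple([mu.first_twitch] * n), np.zeros(n), None
    )
    return synthesize_trace(train, cfg.step, grid=grid)
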