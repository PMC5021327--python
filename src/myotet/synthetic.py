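"""Synthetic motor units, stimulation patterns and noisy recordings.

The generator emulates the statistical structure of a rat medial
gastrocnemius MU sample: twitch-to-tetanus ratios of 0.13 +/- 0.05,
0.19 +/- 0.06 and 0.28 +/- 0.08 for S, FR and FF units, firing at
10-16.6 Hz (S) or 25-40 Hz (fast), with 41-pulse trains whose interpulse
intervals are jittered uniformly within 50-150% of the mean interval.
Twitch time parameters are drawn from type-specific contraction-time ranges
and completed by fixed shape proportions; these proportions are synthetic
conventions — only their ordering matters to the algorithms under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .prediction import (
    ContractionTrain,
    MotorUnit,
    PredictionConfig,
    StimulationPattern,
    full_predict,
)
from .trace import ForceTrace
from .twitch import TwitchParams

__all__ = [
    "SyntheticSpec",
    "RATIO_STATS",
    "FREQ_RANGES",
    "generate_motor_unit",
    "generate_pattern",
    "default_frequency",
    "synth_recording",
    "make_recording",
]

#: Twitch-to-tetanus ratio mean and SD per MU type.
RATIO_STATS: dict[str, tuple[float, float]] = {
    "S": (0.13, 0.05),
    "FR": (0.19, 0.06),
    "FF": (0.28, 0.08),
}

#: Physiological firing-frequency ranges (Hz) per MU type.
FREQ_RANGES: dict[str, tuple[float, float]] = {
    "S": (10.0, 16.6),
    "FR": (25.0, 40.0),
    "FF": (25.0, 40.0),
}

#: Contraction-time ranges (ms) per MU type (slow units are slower).
TC_RANGES: dict[str, tuple[float, float]] = {
    "S": (30.0, 70.0),
    "FR": (12.0, 25.0),
    "FF": (12.0, 25.0),
}

#: First-twitch amplitude ranges (mN) per MU type.
FMAX_RANGES: dict[str, tuple[float, float]] = {
    "S": (5.0, 40.0),
    "FR": (20.0, 100.0),
    "FF": (30.0, 150.0),
}

# fixed twitch-shape proportions relative to the contraction time
_THC_OVER_TC = 0.55
_THR_OVER_TC = 2.2
_TTW_OVER_TC = 8.0

#: Truncation bounds of the twitch-to-tetanus ratio.
P_BOUNDS = (0.05, 1.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic MU recording."""

    mu_type: str = "S"
    mean_freq: float | None = None  # Hz; None draws from the type's range
    jitter: tuple[float, float] = (0.5, 1.5)
    n_pulses: int = 41
    noise_sd: float = 0.0  # fraction of f_mftf
    seed: int = 0
    #: accepted range of peak tetanic force relative to f_mftf; the study
    #: conditions are moderately fused tetani reaching 30-70% of the
    #: fused-tetanus maximum.  None disables the check.
    fusion_band: tuple[float, float] | None = (0.3, 0.7)

    def __post_init__(self) -> None:
        if self.mu_type not in RATIO_STATS:
            raise ValidationError(f"unknown MU type {self.mu_type!r}")
        lo, hi = self.jitter
        if not (0 < lo <= hi < 2):
            raise ValidationError(f"jitter bounds must lie within (0, 2), got {self.jitter}")
        if self.n_pulses < 1:
            raise ValidationError("need at least one pulse")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be non-negative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_motor_unit(mu_type: str, seed=0) -> MotorUnit:
    """Draw one motor unit of the given physiological type.

    The twitch-to-tetanus ratio is drawn from the type's normal
    distribution truncated to (0.05, 1); twitch times follow the type's
    contraction-time range and fixed shape proportions.
    """
    if mu_type not in RATIO_STATS:
        raise ValidationError(f"unknown MU type {mu_type!r}")
    rng = _rng(seed)
    mean, sd = RATIO_STATS[mu_type]
    p = rng.normal(mean, sd)
    while not (P_BOUNDS[0] < p < P_BOUNDS[1]):
        p = rng.normal(mean, sd)
    t_c = rng.uniform(*TC_RANGES[mu_type])
    f_max1 = rng.uniform(*FMAX_RANGES[mu_type])
    t_lead = rng.uniform(1.0, 3.0)
    twitch = TwitchParams(
        f_max1, t_lead, _THC_OVER_TC * t_c, t_c, _THR_OVER_TC * t_c, _TTW_OVER_TC * t_c
    )
    return MotorUnit(f"{mu_type}-synth", mu_type, twitch, f_max1 / p)


def default_frequency(mu_type: str, seed=0) -> float:
    """Draw a physiological mean firing frequency (Hz) for the type."""
    if mu_type not in FREQ_RANGES:
        raise ValidationError(f"unknown MU type {mu_type!r}")
    return float(_rng(seed).uniform(*FREQ_RANGES[mu_type]))


def generate_pattern(
    mean_freq: float,
    jitter: tuple[float, float] = (0.5, 1.5),
    n: int = 41,
    seed=0,
) -> StimulationPattern:
    """Pulse train with IPIs i.i.d. uniform on ``jitter`` times the mean IPI."""
    if mean_freq <= 0:
        raise ValidationError("mean frequency must be positive")
    if n < 1:
        raise ValidationError("need at least one pulse")
    rng = _rng(seed)
    mean_ipi = 1000.0 / mean_freq
    ipis = rng.uniform(jitter[0] * mean_ipi, jitter[1] * mean_ipi, size=n - 1)
    return StimulationPattern.from_ipis(ipis)


def synth_recording(
    mu: MotorUnit,
    pattern: StimulationPattern,
    noise_sd: float = 0.0,
    seed=0,
    cfg: PredictionConfig | None = None,
) -> ForceTrace:
    """Forward-simulated tetanus plus Gaussian measurement noise, clipped at 0.

    ``noise_sd`` is a fraction of the unit's fused-tetanus force; 0 returns
    the noiseless full-prediction trace.
    """
    if noise_sd < 0:
        raise ValidationError("noise SD must be non-negative")
    trace, _ = full_predict(mu, pattern, cfg)
    if noise_sd == 0:
        return trace
    rng = _rng(seed)
    noisy = trace.force + rng.normal(0.0, noise_sd * mu.f_mftf, size=trace.n)
    return trace.with_force(np.clip(noisy, 0.0, None))


def make_recording(
    spec: SyntheticSpec, cfg: PredictionConfig | None = None, max_tries: int = 500
) -> tuple[MotorUnit, StimulationPattern, ForceTrace, ContractionTrain]:
    """Generate a complete synthetic dataset from one spec.

    Motor unit, mean frequency and pulse train are redrawn until the
    simulated tetanus peaks inside ``spec.fusion_band`` relative to the
    unit's fused-tetanus force — the counterpart of an experimenter picking
    stimulation rates that evoke a moderately fused tetanus.  All
    randomness derives from ``spec.seed``; the same spec reproduces the
    same unit, pattern and noise.
    """
    from .errors import NumericalError

    rng = _rng(spec.seed)
    for _ in range(max_tries):
        mu = generate_motor_unit(spec.mu_type, rng)
        freq = spec.mean_freq if spec.mean_freq is not None else default_frequency(spec.mu_type, rng)
        pattern = generate_pattern(freq, spec.jitter, spec.n_pulses, rng)
        trace, train = full_predict(mu, pattern, cfg)
        if spec.fusion_band is None:
            break
        rel_peak = float(np.max(trace.force)) / mu.f_mftf
        if spec.fusion_band[0] <= rel_peak <= spec.fusion_band[1]:
            break
    else:
        raise NumericalError(
            f"no {spec.mu_type} unit/pattern combination reached a relative peak force "
            f"inside {spec.fusion_band} after {max_tries} draws"
        )
    if spec.noise_sd > 0:
        noisy = trace.force + rng.normal(0.0, spec.noise_sd * mu.f_mftf, size=trace.n)
        trace = trace.with_force(np.clip(noisy, 0.0, None))
    return mu, pattern, trace, train
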