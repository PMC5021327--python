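"""The six-parameter analytical twitch curve.

A single motor-unit contraction is represented by a bell-shaped force
transient pinned to six measured quantities: the peak force ``f_max`` and
five characteristic times counted from the contraction onset — the
half-contraction time ``t_hc`` (force reaches f_max/2 while rising), the
contraction time ``t_c`` (force peaks), the half-relaxation time ``t_hr``
(force falls back to f_max/2) and the total duration ``t_tw`` at which the
force has decayed to 0.01% of the peak.  ``t_lead`` is the latency between
the stimulus and the contraction onset.

The curve is built from the bell kernel ``g(u) = u * exp(1 - u)`` on
normalized time ``u = (t - t_lead) / t_c``.  ``g`` rises from 0 to
``g(1) = 1`` and decays for ``u > 1``, so a power ``g(u)**k`` keeps the
peak at ``t_c`` while the exponent shapes the flanks.  Three exponents are
solved in closed form so that the curve passes exactly through the four
force anchors (f_max/2 rising, f_max at peak, f_max/2 falling, 1e-4*f_max
at ``t_tw``); the relaxation piece is rescaled to keep the curve continuous
at ``t_hr``.  Beyond ``t_tw`` the force is truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["TwitchParams", "TwitchCurve", "build_twitch", "evaluate_on_grid", "TAIL_FRACTION"]

#: Relative force level defining the end of the twitch: f(t_tw) = TAIL_FRACTION * f_max.
TAIL_FRACTION = 1e-4


@dataclass(frozen=True)
class TwitchParams:
    """Parameters of one twitch-like contraction (ms and mN).

    ``f_max`` may be zero, denoting a silenced contraction (an amplitude
    clamped at zero); negative amplitudes are rejected.  The time anchors
    must satisfy ``0 < t_hc < t_c < t_hr < t_tw`` and ``t_lead >= 0``.
    """

    f_max: float
    t_lead: float
    t_hc: float
    t_c: float
    t_hr: float
    t_tw: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.f_max, self.t_lead, self.t_hc, self.t_c, self.t_hr, self.t_tw]).all():
            raise ParameterError("twitch parameters must be finite")
        if self.f_max < 0:
            raise ParameterError(f"f_max must be non-negative, got {self.f_max}")
        if self.t_lead < 0:
            raise ParameterError(f"t_lead must be non-negative, got {self.t_lead}")
        if not 0 < self.t_hc:
            raise ParameterError(f"time ordering violated: 0 < t_hc fails (t_hc={self.t_hc})")
        if not self.t_hc < self.t_c:
            raise ParameterError(
                f"time ordering violated: t_hc < t_c fails (t_hc={self.t_hc}, t_c={self.t_c})"
            )
        if not self.t_c < self.t_hr:
            raise ParameterError(
                f"time ordering violated: t_c < t_hr fails (t_c={self.t_c}, t_hr={self.t_hr})"
            )
        if not self.t_hr < self.t_tw:
            raise ParameterError(
                f"time ordering violated: t_hr < t_tw fails (t_hr={self.t_hr}, t_tw={self.t_tw})"
            )

    def scaled(self, c: float) -> "TwitchParams":
        """Amplitude-scaled copy (time parameters unchanged)."""
        return replace(self, f_max=self.f_max * c)

    @property
    def end_time(self) -> float:
        """Time since the stimulus at which the force support ends."""
        return self.t_lead + self.t_tw


def _log_g(u: np.ndarray | float):
    # log of the bell kernel g(u) = u * exp(1 - u); valid for u > 0
    return np.log(u) + 1.0 - u


class TwitchCurve:
    """Callable force curve ``f(t)`` with ``t`` the time since the stimulus."""

    def __init__(self, params: TwitchParams):
        self.params = params
        p = params
        u_hc = p.t_hc / p.t_c
        u_hr = p.t_hr / p.t_c
        u_tw = p.t_tw / p.t_c
        # Exponents solved exactly from the half-force and tail anchors.
        self._k1 = np.log(0.5) / _log_g(u_hc)
        self._k2 = np.log(0.5) / _log_g(u_hr)
        self._lg_hr = _log_g(u_hr)
        self._k3 = np.log(2.0 * TAIL_FRACTION) / (_log_g(u_tw) - self._lg_hr)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        out = np.zeros_like(t_arr)
        p = self.params
        if p.f_max > 0:
            tau = t_arr - p.t_lead
            with np.errstate(divide="ignore", invalid="ignore"):
                u = tau / p.t_c
                m1 = (tau > 0) & (tau <= p.t_c)
                m2 = (tau > p.t_c) & (tau <= p.t_hr)
                m3 = (tau > p.t_hr) & (tau <= p.t_tw)
                out[m1] = p.f_max * np.exp(self._k1 * _log_g(u[m1]))
                out[m2] = p.f_max * np.exp(self._k2 * _log_g(u[m2]))
                out[m3] = 0.5 * p.f_max * np.exp(self._k3 * (_log_g(u[m3]) - self._lg_hr))
        return float(out[0]) if scalar else out


def build_twitch(params: TwitchParams) -> TwitchCurve:
    """Construct the analytical twitch curve for ``params``.

    The returned callable maps time since the stimulus (ms) to force (mN);
    it is zero before ``t_lead`` and beyond ``t_lead + t_tw``.
    """
    return TwitchCurve(params)


def evaluate_on_grid(curve: TwitchCurve, times: np.ndarray) -> np.ndarray:
    """Sample ``curve`` on a strictly increasing uniform time grid (ms)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("evaluation grid must be a non-empty 1-D array")
    if times.size > 1:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValidationError("evaluation grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValidationError("evaluation grid must be uniform")
    return curve(times)
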