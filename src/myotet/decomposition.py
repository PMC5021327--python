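"""Decomposition of an unfused tetanus into twitch-like contractions.

The recorded (or simulated) tetanic curve is peeled apart sequentially: for
contraction ``i`` the models of all previous contractions are subtracted
from the trace and a six-parameter twitch is least-squares fitted to the
residual in a window after pulse ``i``.  Because the first, causal pass can
only see each contraction up to the onset of the next one, optional
refinement passes revisit every contraction against the residual formed by
all *other* current models over the contraction's full support, which pins
down the relaxation-phase parameters.

Fitting works on a reparameterized vector (f_max, t_lead, t_hc, and the
three positive increments t_c - t_hc, t_hr - t_c, t_tw - t_hr) so that the
time ordering invariant holds for every candidate the optimizer visits.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitError, FitConvergenceError, ValidationError
from .metrics import SimilarityReport, compare
from .prediction import ContractionTrain, StimulationPattern, synthesize_trace
from .trace import ForceTrace
from .twitch import TwitchCurve, TwitchParams, build_twitch

__all__ = [
    "reconstruct",
    "fit_twitch_segment",
    "decompose_tetanus",
    "local_minima",
    "decomposition_report",
]

#: Fit window length, as a multiple of the reference twitch duration.
#: Decomposed contractions can be several-fold longer than the single twitch.
WINDOW_FACTOR = 3.0

#: Least-squares bounds, as multiples of the reference twitch's parameters.
BOUND_FACTORS = (0.2, 8.0)


def reconstruct(
    train: ContractionTrain,
    step: float = 0.1,
    t0: float = 0.0,
    t_end: float | None = None,
    grid: ForceTrace | None = None,
) -> ForceTrace:
    """Sum of the train's twitch models on a uniform grid.

    An empty train yields a zero trace over ``[t0, t_end]``.
    """
    if len(train) == 0:
        if grid is not None:
            return grid.with_force(np.zeros(grid.n))
        t_end = t_end if t_end is not None else t0 + step
        n = max(2, int(math.ceil((t_end - t0) / step)) + 1)
        return ForceTrace(t0, step, np.zeros(n))
    return synthesize_trace(train, step, t0=t0, grid=grid, t_end=t_end)


def _theta_from_params(p: TwitchParams) -> np.ndarray:
    return np.array([p.f_max, p.t_lead, p.t_hc, p.t_c - p.t_hc, p.t_hr - p.t_c, p.t_tw - p.t_hr])


def _params_from_theta(theta: np.ndarray) -> TwitchParams:
    f_max, t_lead, t_hc, d1, d2, d3 = theta
    return TwitchParams(f_max, t_lead, t_hc, t_hc + d1, t_hc + d1 + d2, t_hc + d1 + d2 + d3)


def _fit_bounds(reference: TwitchParams) -> tuple[np.ndarray, np.ndarray]:
    ref = _theta_from_params(reference)
    lo = BOUND_FACTORS[0] * ref
    hi = BOUND_FACTORS[1] * ref
    # the lead time may legitimately be (near) zero
    lo[1] = 0.0
    hi[1] = max(hi[1], 2.0)
    return lo, hi


def fit_twitch_segment(
    residual: ForceTrace,
    stimulus_time: float,
    initial: TwitchParams,
    reference: TwitchParams | None = None,
    window: float | None = None,
    on_flat: str = "raise",
    free: Sequence[int] | None = None,
) -> TwitchParams:
    """Least-squares twitch fit to a residual segment after one stimulus.

    The fit uses the samples in ``[stimulus_time, stimulus_time + window]``
    (to the end of the trace when ``window`` is None).  ``reference``
    centers the box bounds (defaults to ``initial``).  ``free`` selects
    which components of the internal parameter vector (f_max, t_lead, t_hc,
    and the three time increments) are optimized; the rest stay at the
    initial guess — used for short windows that do not constrain the
    relaxation phase.  A residual without signal either raises
    :class:`DegenerateFitError` or, with ``on_flat="zero"``, returns a
    zero-amplitude copy of the initial guess.
    """
    reference = reference or initial
    t_hi = residual.t_end if window is None else stimulus_time + window
    times = residual.times
    mask = (times >= stimulus_time) & (times <= t_hi)
    if not np.any(mask):
        raise ValidationError(
            f"empty fit window [{stimulus_time}, {t_hi}] for trace ending at {residual.t_end}"
        )
    ts = times[mask] - stimulus_time
    ys = residual.force[mask]
    if float(np.max(np.abs(ys))) < 1e-9 * max(reference.f_max, 1e-12):
        if on_flat == "zero":
            return replace(initial, f_max=0.0)
        raise DegenerateFitError(
            f"residual after stimulus at {stimulus_time} ms carries no signal"
        )
    lo, hi = _fit_bounds(reference)
    theta_full = np.clip(_theta_from_params(initial), lo + 1e-12, hi - 1e-12)
    free_idx = np.arange(theta_full.size) if free is None else np.asarray(free, dtype=int)

    def cost(theta: np.ndarray) -> np.ndarray:
        full = theta_full.copy()
        full[free_idx] = theta
        return TwitchCurve(_params_from_theta(full))(ts) - ys

    result = least_squares(
        cost,
        theta_full[free_idx],
        bounds=(lo[free_idx], hi[free_idx]),
        method="trf",
        x_scale=np.maximum(np.abs(theta_full[free_idx]), 1e-3),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=400 * free_idx.size,
    )
    if not result.success:
        raise FitConvergenceError(
            f"twitch fit after stimulus at {stimulus_time} ms failed: {result.message}"
        )
    full = theta_full.copy()
    full[free_idx] = result.x
    return _params_from_theta(full)


def _add_support(acc: np.ndarray, trace: ForceTrace, curve_params: TwitchParams,
                 stim: float, sign: float = 1.0) -> tuple[int, int]:
    """Add (or subtract) one twitch model over its support slice of ``acc``."""
    if curve_params.f_max == 0:
        return 0, -1
    a = stim + curve_params.t_lead
    b = stim + curve_params.end_time
    i0 = max(0, int(math.ceil((a - trace.t0) / trace.dt)))
    i1 = min(trace.n - 1, int(math.floor((b - trace.t0) / trace.dt)))
    if i1 < i0:
        return 0, -1
    ts = trace.t0 + trace.dt * np.arange(i0, i1 + 1)
    acc[i0 : i1 + 1] += sign * build_twitch(curve_params)(ts - stim)
    return i0, i1


def _heuristic_seed(trace: ForceTrace, pattern: StimulationPattern) -> TwitchParams:
    """Rough first-twitch guess from the rising phase after the first pulse.

    Peak position and height are read from the segment before the second
    pulse; the remaining times follow generic twitch-shape proportions.
    """
    p0 = pattern.pulse_times[0]
    t_hi = pattern.pulse_times[1] if pattern.n_pulses > 1 else trace.t_end
    times = trace.times
    mask = (times >= p0) & (times <= t_hi)
    seg = trace.force[mask]
    if seg.size == 0 or np.max(seg) <= 0:
        raise DegenerateFitError("cannot seed the decomposition: no force after the first pulse")
    i_peak = int(np.argmax(seg))
    t_peak = times[mask][i_peak] - p0
    t_lead = max(0.02 * t_peak, trace.dt)
    t_c = max(t_peak - t_lead, 2 * trace.dt)
    return TwitchParams(float(np.max(seg)), t_lead, 0.55 * t_c, t_c, 2.2 * t_c, 8.0 * t_c)


def decompose_tetanus(
    trace: ForceTrace,
    pattern: StimulationPattern,
    seed_twitch: TwitchParams | None = None,
    refine_passes: int = 1,
    window_factor: float = WINDOW_FACTOR,
    on_flat: str = "zero",
    polish: bool = False,
) -> ContractionTrain:
    """Decompose a tetanic force curve into per-stimulus twitch models.

    ``seed_twitch`` supplies the initial guess and bound reference for the
    first contraction (measured single-twitch parameters when available);
    without it a rising-phase heuristic is used.  Each subsequent fit starts
    from the previous contraction's solution.  ``polish`` finishes with one
    joint least-squares over all contractions at once, which resolves the
    parameter trade-offs between overlapping neighbours that the sequential
    sweeps cannot; it is accurate but considerably slower for long trains.
    """
    if pattern.pulse_times[-1] >= trace.t_end:
        raise ValidationError(
            f"trace (ending at {trace.t_end} ms) does not cover all stimuli "
            f"(last pulse at {pattern.pulse_times[-1]} ms)"
        )
    reference = seed_twitch or _heuristic_seed(trace, pattern)
    window = window_factor * reference.t_tw
    pulses = pattern.pulse_times
    n = pattern.n_pulses

    fitted: list[TwitchParams] = []
    acc = np.zeros(trace.n)  # running sum of fitted models
    for i, p in enumerate(pulses):
        initial = fitted[-1] if fitted else reference
        # causal window: the next contraction has not started before its
        # pulse time + lead, so the residual there is contraction i alone
        w_end = p + window
        if i + 1 < n:
            w_end = min(w_end, pulses[i + 1] + initial.t_lead)
        w_end = min(w_end, trace.t_end)
        # a short window cannot constrain the relaxation increments; free
        # only the parameters the data reach and leave the tail shape to
        # the initial guess and the refinement passes
        if w_end < p + initial.t_lead + initial.t_hr:
            free: tuple[int, ...] | None = (0, 1, 2, 3)
        elif w_end < p + initial.t_lead + 0.9 * initial.t_tw:
            free = (0, 1, 2, 3, 4)
        else:
            free = None
        residual = trace.with_force(trace.force - acc)
        try:
            params = fit_twitch_segment(
                residual, p, initial, reference=reference, window=w_end - p,
                on_flat=on_flat, free=free,
            )
        except (FitConvergenceError, DegenerateFitError) as exc:
            raise type(exc)(f"contraction {i + 1}: {exc}") from exc
        fitted.append(params)
        _add_support(acc, trace, params, p)

    for _ in range(refine_passes):
        for i, p in enumerate(pulses):
            _add_support(acc, trace, fitted[i], p, sign=-1.0)
            residual = trace.with_force(trace.force - acc)
            w_end = min(p + window, trace.t_end)
            try:
                params = fit_twitch_segment(
                    residual, p, fitted[i], reference=reference,
                    window=w_end - p, on_flat=on_flat,
                )
            except (FitConvergenceError, DegenerateFitError) as exc:
                raise type(exc)(f"contraction {i + 1} (refinement): {exc}") from exc
            fitted[i] = params
            _add_support(acc, trace, params, p)

    if polish:
        fitted = _joint_polish(trace, pulses, fitted, reference, window)

    f_tetmin = local_minima(trace, pattern, lead_time=fitted[0].t_lead)
    return ContractionTrain(pulses.copy(), tuple(fitted), f_tetmin, None)


def _joint_polish(
    trace: ForceTrace,
    pulses: np.ndarray,
    fitted: list[TwitchParams],
    reference: TwitchParams,
    window: float,
) -> list[TwitchParams]:
    """Joint bounded least-squares over all contractions at once.

    Every contraction only influences the samples of its own support, so
    for long trains the Jacobian is evaluated with that sparsity pattern;
    short trains use plain dense differencing, which is faster there.
    """
    from scipy.sparse import lil_matrix

    m = len(fitted)
    lo1, hi1 = _fit_bounds(reference)
    lo, hi = np.tile(lo1, m), np.tile(hi1, m)
    x0 = np.clip(np.concatenate([_theta_from_params(p) for p in fitted]), lo + 1e-12, hi - 1e-12)

    def cost(x: np.ndarray) -> np.ndarray:
        params = tuple(_params_from_theta(x[6 * i : 6 * i + 6]) for i in range(m))
        train = ContractionTrain(pulses, params, np.zeros(m))
        return synthesize_trace(train, trace.dt, grid=trace).force - trace.force

    kwargs: dict = {}
    if m > 12:
        sparsity = lil_matrix((trace.n, 6 * m))
        times = trace.times
        support = hi1[1] + hi1[2] + hi1[3] + hi1[4] + hi1[5]  # widest admissible twitch
        for i, p in enumerate(pulses):
            rows = np.flatnonzero((times > p) & (times <= p + support))
            sparsity[rows.reshape(-1, 1), np.arange(6 * i, 6 * i + 6)] = 1
        kwargs = {"jac_sparsity": sparsity, "tr_solver": "lsmr"}
    result = least_squares(
        cost, x0, bounds=(lo, hi), method="trf",
        x_scale=np.maximum(x0, 1e-3), max_nfev=300, **kwargs,
    )
    if not result.success:
        raise FitConvergenceError(f"joint polish failed: {result.message}")
    return [_params_from_theta(result.x[6 * i : 6 * i + 6]) for i in range(m)]


def local_minima(
    trace: ForceTrace, pattern: StimulationPattern, lead_time: float = 0.0
) -> np.ndarray:
    """Force level at which each contraction starts.

    For pulse ``n`` the minimum force in ``[t_pulse, t_pulse + lead_time +
    2*dt]`` is taken — the true minimum lies between the pulse and the
    contraction onset.  The first entry is 0 by definition (the first
    contraction starts from rest).
    """
    times = trace.times
    out = np.empty(pattern.n_pulses)
    for i, p in enumerate(pattern.pulse_times):
        mask = (times >= p) & (times <= p + lead_time + 2 * trace.dt)
        if not np.any(mask):
            raise ValidationError(f"empty search window for pulse {i + 1} at {p} ms")
        out[i] = float(np.min(trace.force[mask]))
    out[0] = 0.0
    return out


def decomposition_report(trace: ForceTrace, train: ContractionTrain) -> SimilarityReport:
    """Similarity between a trace and the reconstruction of its decomposition."""
    model = reconstruct(train, grid=trace)
    return compare(trace, model)
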