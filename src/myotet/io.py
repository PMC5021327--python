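"""Plain-text input/output: force traces, IPI lists, MU tables, trains.

File conventions:

* force trace — CSV with columns ``time_ms,force_mN`` on a uniform grid;
* stimulation pattern — plain text, one interpulse interval (ms) per line;
* motor units — CSV with columns ``id,type,f_max1,t_lead1,t_hc1,t_c1,
  t_hr1,t_tw1,f_mftf``;
* contraction train — CSV with the stimulus time, starting force level and
  the six twitch parameters per row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .prediction import ContractionTrain, MotorUnit, StimulationPattern
from .trace import ForceTrace
from .twitch import TwitchParams

__all__ = [
    "read_trace",
    "write_trace",
    "read_ipis",
    "write_ipis",
    "read_mus",
    "write_mus",
    "read_train",
    "write_train",
]

_MU_COLUMNS = ["id", "type", "f_max1", "t_lead1", "t_hc1", "t_c1", "t_hr1", "t_tw1", "f_mftf"]
_TRAIN_COLUMNS = ["stimulus_time", "f_tetmin", "f_max", "t_lead", "t_hc", "t_c", "t_hr", "t_tw"]


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def read_trace(path) -> ForceTrace:
    """Read a force trace CSV and validate its uniform time grid."""
    df = _read_csv(path, ["time_ms", "force_mN"])
    t = df["time_ms"].to_numpy(dtype=float)
    f = df["force_mN"].to_numpy(dtype=float)
    for name, arr in (("time_ms", t), ("force_mN", f)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValidationError(f"{path}: non-finite {name} at data row {bad[0] + 1}")
    if t.size < 2:
        raise ValidationError(f"{path}: a trace needs at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 2
        raise ValidationError(f"{path}: time not strictly increasing at data row {row}")
    dt = float(np.median(steps))
    off = np.flatnonzero(np.abs(steps - dt) > 1e-6 * dt)
    if off.size:
        raise ValidationError(f"{path}: non-uniform time step at data row {off[0] + 2}")
    return ForceTrace(float(t[0]), dt, f)


def write_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.times, "force_mN": trace.force}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_ipis(path) -> StimulationPattern:
    """Read a one-IPI-per-line text file into a stimulation pattern."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    values = []
    for k, ln in enumerate(lines, start=1):
        if not ln or ln.startswith("#"):
            continue
        try:
            values.append(float(ln))
        except ValueError as exc:
            raise ValidationError(f"{path}: line {k}: not a number: {ln!r}") from exc
    if not values:
        raise ValidationError(f"{path}: no interpulse intervals found")
    return StimulationPattern.from_ipis(values)


def write_ipis(pattern: StimulationPattern, path) -> None:
    Path(path).write_text("".join(f"{ipi:.10g}\n" for ipi in pattern.ipis))


def read_mus(path) -> list[MotorUnit]:
    """Read a motor-unit parameter table into validated domain objects."""
    df = _read_csv(path, _MU_COLUMNS)
    units = []
    for idx, row in df.iterrows():
        try:
            twitch = TwitchParams(
                float(row["f_max1"]), float(row["t_lead1"]), float(row["t_hc1"]),
                float(row["t_c1"]), float(row["t_hr1"]), float(row["t_tw1"]),
            )
            units.append(MotorUnit(str(row["id"]), str(row["type"]), twitch, float(row["f_mftf"])))
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {idx + 1}: {exc}") from exc
    return units


def write_mus(units: list[MotorUnit], path) -> None:
    rows = [
        {
            "id": mu.mu_id,
            "type": mu.mu_type,
            "f_max1": mu.first_twitch.f_max,
            "t_lead1": mu.first_twitch.t_lead,
            "t_hc1": mu.first_twitch.t_hc,
            "t_c1": mu.first_twitch.t_c,
            "t_hr1": mu.first_twitch.t_hr,
            "t_tw1": mu.first_twitch.t_tw,
            "f_mftf": mu.f_mftf,
        }
        for mu in units
    ]
    pd.DataFrame(rows, columns=_MU_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_train(path) -> ContractionTrain:
    df = _read_csv(path, _TRAIN_COLUMNS)
    contractions = tuple(
        TwitchParams(
            float(r["f_max"]), float(r["t_lead"]), float(r["t_hc"]),
            float(r["t_c"]), float(r["t_hr"]), float(r["t_tw"]),
        )
        for _, r in df.iterrows()
    )
    return ContractionTrain(
        df["stimulus_time"].to_numpy(dtype=float),
        contractions,
        df["f_tetmin"].to_numpy(dtype=float),
    )


def write_train(train: ContractionTrain, path) -> None:
    train.to_frame().to_csv(path, index=False, float_format="%.17g")
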