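"""Uniformly sampled force-versus-time curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ForceTrace"]


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled force curve (recorded, reconstructed or predicted).

    Parameters
    ----------
    t0 : float
        Time of the first sample, in ms.
    dt : float
        Sampling step, in ms; must be positive.
    force : ndarray
        Force samples in mN; at least two finite values.
    """

    t0: float
    dt: float
    force: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if not np.isfinite(self.t0):
            raise ValidationError("trace start time must be finite")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValidationError(f"sampling step must be positive, got {self.dt}")
        if force.ndim != 1 or force.size < 2:
            raise ValidationError("a force trace needs at least two samples")
        if not np.all(np.isfinite(force)):
            raise ValidationError("force samples must be finite")

    @property
    def n(self) -> int:
        return self.force.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n - 1)

    def with_force(self, force: np.ndarray) -> "ForceTrace":
        """Same grid, different samples."""
        return ForceTrace(self.t0, self.dt, np.asarray(force, dtype=float))

    def padded_to(self, n: int) -> "ForceTrace":
        """Extend with trailing zeros (or truncate) to exactly ``n`` samples."""
        if n < 2:
            raise ValidationError("cannot shrink a trace below two samples")
        if n == self.n:
            return self
        if n < self.n:
            return ForceTrace(self.t0, self.dt, self.force[:n].copy())
        out = np.zeros(n)
        out[: self.n] = self.force
        return ForceTrace(self.t0, self.dt, out)

    def same_grid(self, other: "ForceTrace", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0 - other.t0) <= rtol * max(self.dt, abs(self.t0))
        )
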