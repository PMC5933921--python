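"""Uniformly sampled time-series container used throughout the package.

A :class:`Trace` is the common currency between the simulator, the stimulus
generators and every analysis routine: a 1-D float array plus its sample
interval and a unit tag (``mV`` for membrane voltage, ``pA`` for injected
current, ``a.u.`` for fluorescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """One uniformly sampled signal.

    Parameters
    ----------
    data : ndarray
        Sample values, 1-D.
    dt : float
        Sample interval in seconds (> 0).
    unit : str
        Physical unit of the samples (``mV``, ``pA`` or ``a.u.``).
    kind : str
        Signal kind: ``V`` (voltage), ``I`` (current) or ``F`` (fluorescence).
    meta : dict
        Free-form annotations (e.g. the lead-in duration of a chirp).
    """

    data: np.ndarray
    dt: float
    unit: str = "mV"
    kind: str = "V"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Trace data must be one-dimensional")
        if not self.dt > 0:
            raise ValueError(f"Trace dt must be positive, got {self.dt}")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) * self.dt

    def slice_time(self, t0: float, t1: float | None = None) -> "Trace":
        """Return the sub-trace covering ``[t0, t1)`` (``t1=None`` = end)."""
        i0 = max(0, int(round(t0 / self.dt)))
        i1 = self.n if t1 is None else min(self.n, int(round(t1 / self.dt)))
        if i1 <= i0:
            raise ValueError(f"empty time slice [{t0}, {t1})")
        return Trace(self.data[i0:i1].copy(), self.dt, self.unit, self.kind,
                     dict(self.meta))

    def copy(self) -> "Trace":
        return Trace(self.data.copy(), self.dt, self.unit, self.kind,
                     dict(self.meta))
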