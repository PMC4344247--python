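"""In-memory containers for calcium and luminescence time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import StimulusCondition


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    return arr


@dataclass(frozen=True, eq=False)
class CalciumTrace:
    """Cytosolic free calcium versus time, stimulus at t = 0.

    ``time_s`` is a strictly increasing uniform grid in seconds relative to
    stimulus onset; ``ca_nM`` is [Ca2+]_cyt in nM and must be positive
    everywhere (resting cytosol is ~100 nM, never zero).
    """

    time_s: np.ndarray
    ca_nM: np.ndarray
    condition: StimulusCondition

    def __post_init__(self) -> None:
        t = _as_1d(self.time_s, "time_s")
        ca = _as_1d(self.ca_nM, "ca_nM")
        if t.shape != ca.shape:
            raise ValueError("time_s and ca_nM must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(ca <= 0):
            raise ValueError("ca_nM must be > 0 everywhere")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ca_nM", ca)

    @property
    def dt_s(self) -> float:
        """Sampling interval; raises on a non-uniform grid."""
        steps = np.diff(self.time_s)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform")
        return float(steps[0])


@dataclass(frozen=True, eq=False)
class LuminescenceTrace:
    """Photon counts per sampling interval plus the terminal discharge.

    ``counts[i]`` is the luminescence integrated over
    ``[time_s[i], time_s[i] + dt)``; ``discharge_counts`` is the photon yield
    of the terminal discharge (lysis), i.e. the aequorin pool left unconsumed.
    Counts are floats so that noise-free expected-count traces are
    representable; Poisson-sampled traces hold integral values.
    """

    time_s: np.ndarray
    counts: np.ndarray
    discharge_counts: float
    condition: StimulusCondition
    pool_exhausted: bool = False

    def __post_init__(self) -> None:
        t = _as_1d(self.time_s, "time_s")
        c = _as_1d(self.counts, "counts")
        if t.shape != c.shape:
            raise ValueError("time_s and counts must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        if self.discharge_counts < 0:
            raise ValueError("discharge_counts must be >= 0")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "discharge_counts", float(self.discharge_counts))

    @property
    def dt_s(self) -> float:
        steps = np.diff(self.time_s)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform")
        return float(steps[0])

    @property
    def total_counts(self) -> float:
        """Total photon yield including the discharge (the initial pool)."""
        return float(self.counts.sum() + self.discharge_counts)
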