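"""Aequorin luminescence <-> [Ca2+]_cyt calibration.

Aequorin emits photons at a rate proportional to the fraction of the
remaining (unconsumed) photoprotein pool, with a rate constant k that is a
steep function of [Ca2+].  The standard empirical calibration is linear in
log-log space::

    k_t  = counts_t / (remaining_t * dt)          [per second]
    pCa  = slope * (-log10 k) + intercept
    [Ca2+] = 10**(-pCa) M

where ``remaining_t`` is the photon yield still available at the start of
interval t — the terminal discharge plus all counts from t onward.  Because k
depends only on the *ratio* of counts to remaining pool, the calibrated
calcium is invariant to the detector's absolute photon efficiency.

The inverse map :func:`calcium_to_rate` is the forward model used by the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import CalciumTrace, LuminescenceTrace

#: Empirical calibration slope: pCa units per decade of rate constant.
DEFAULT_SLOPE = 0.332588
#: Empirical calibration intercept: pCa at k = 1 s^-1.
DEFAULT_INTERCEPT = 5.5593


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the empirical aequorin calibration.

    Parameters
    ----------
    slope, intercept
        Coefficients of ``pCa = slope * (-log10 k) + intercept``.
    rate_floor
        Rate constant substituted for intervals with zero counts (a zero
        count gives k = 0 and pCa = +inf).  ``None`` uses the per-trace
        one-count pseudo-rate ``1 / (total counts * dt)``, which is below any
        observed rate in that trace.
    pca_cap
        Upper bound on pCa, i.e. a lower bound of ``10**(9 - pca_cap)`` nM on
        reported calcium; guards against absurd values from near-empty
        intervals.
    """

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    rate_floor: float | None = None
    pca_cap: float = 8.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.rate_floor is not None and self.rate_floor <= 0:
            raise ValueError("rate_floor must be > 0")


def rate_to_calcium(k_per_s, params: CalibrationParams = CalibrationParams()):
    """Pointwise map from aequorin rate constant (s^-1) to [Ca2+]_cyt (nM)."""
    k = np.asarray(k_per_s, dtype=float)
    if np.any(k <= 0):
        raise ValueError("rate constant must be > 0")
    pca = params.slope * (-np.log10(k)) + params.intercept
    pca = np.minimum(pca, params.pca_cap)
    return 10.0 ** (9.0 - pca)


def calcium_to_rate(ca_nM, params: CalibrationParams = CalibrationParams()):
    """Pointwise inverse of :func:`rate_to_calcium` (pCa cap ignored).

    ``k = 10**(-(pCa - intercept) / slope)`` with ``pCa = 9 - log10(ca_nM)``.
    """
    ca = np.asarray(ca_nM, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca_nM must be > 0")
    pca = 9.0 - np.log10(ca)
    return 10.0 ** (-(pca - params.intercept) / params.slope)


def counts_to_calcium(
    trace: LuminescenceTrace, params: CalibrationParams = CalibrationParams()
) -> CalciumTrace:
    """Calibrate a photon-count trace into a [Ca2+]_cyt trace.

    The remaining pool at interval t includes the counts of interval t itself
    (the pool is consumed *by* the emission being normalised).  Intervals with
    zero counts are assigned the floor rate rather than dropped, so the output
    grid matches the input grid exactly.

    Raises
    ------
    ValueError
        If the trace carries no luminescence at all (cannot normalise).
    """
    counts = trace.counts
    total = counts.sum() + trace.discharge_counts
    if total <= 0 or counts.sum() <= 0:
        raise ValueError("no luminescence: trace has no positive counts")
    dt = trace.dt_s

    # remaining pool at the start of each interval: discharge + suffix sum
    remaining = trace.discharge_counts + counts[::-1].cumsum()[::-1]
    floor = params.rate_floor if params.rate_floor is not None else 1.0 / (total * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(
            (counts > 0) & (remaining > 0), counts / (remaining * dt), floor
        )
    k = np.maximum(k, floor)
    ca = rate_to_calcium(k, params)
    return CalciumTrace(time_s=trace.time_s, ca_nM=ca, condition=trace.condition)
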