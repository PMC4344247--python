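"""Windowed biphasic peak features from averaged calcium response curves.

The signature analysis reduces each averaged response curve to two numbers:
the amplitude of the first transient, read in the window (0, 30] s after
stimulus onset, and the amplitude of the second transient, read in
(30, 120] s.  An amplitude is the within-window range (local maximum minus
local minimum), so a window containing only the decaying tail of the first
transient still yields a positive "second amplitude" — this is what gives
monophasic genotypes a small but nonzero second feature.  The discriminant
operates on the log10 of the two amplitudes.

Replicates are averaged *before* feature extraction.  The order matters:
seedling-to-seedling phase variation in the second transient means the peak
of the average is generally lower than the average of the peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conditions import StimulusCondition
from .traces import CalciumTrace

logger = logging.getLogger(__name__)

#: Half-open windows (lo, hi] in seconds after stimulus onset.
WINDOW1: tuple[float, float] = (0.0, 30.0)
WINDOW2: tuple[float, float] = (30.0, 120.0)


@dataclass(frozen=True)
class PeakFeatures:
    """Two-window amplitude features of one averaged response curve."""

    condition_key: tuple[str, str, float]
    amp1_nM: float
    amp2_nM: float
    t_peak1_s: float
    t_peak2_s: float
    log_amp1: float
    log_amp2: float

    @property
    def valid(self) -> bool:
        """True when both window amplitudes are positive (log features exist)."""
        return self.amp1_nM > 0 and self.amp2_nM > 0


def average_replicates(traces: list[CalciumTrace]) -> CalciumTrace:
    """Pointwise mean of replicate traces sharing a condition and time grid.

    The replicate index of the returned condition is cleared.  Raises if the
    grids differ or the traces belong to different conditions.
    """
    if not traces:
        raise ValueError("need at least one trace to average")
    ref = traces[0]
    key = ref.condition.key
    for tr in traces[1:]:
        if tr.condition.key != key:
            raise ValueError(f"cannot average across conditions: {tr.condition.key} != {key}")
        if not np.array_equal(tr.time_s, ref.time_s):
            raise ValueError("cannot average traces with different time grids")
    # canonical replicate order so any permutation averages bit-identically
    ordered = sorted(traces, key=lambda tr: tr.condition.replicate_id or 0)
    mean_ca = np.mean([tr.ca_nM for tr in ordered], axis=0)
    return CalciumTrace(
        time_s=ref.time_s, ca_nM=mean_ca, condition=ref.condition.without_replicate()
    )


def _window_stats(t: np.ndarray, y: np.ndarray, window: tuple[float, float], onset_s: float):
    lo, hi = window
    mask = (t > onset_s + lo) & (t <= onset_s + hi)
    if not mask.any():
        raise ValueError(f"trace has no samples in window ({lo}, {hi}] s after onset")
    tw, yw = t[mask], y[mask]
    i_max = int(np.argmax(yw))  # argmax returns the earliest tie
    amp = float(yw[i_max] - yw.min())
    return amp, float(tw[i_max])


def extract_peak_features(
    trace: CalciumTrace,
    window1: tuple[float, float] = WINDOW1,
    window2: tuple[float, float] = WINDOW2,
    onset_s: float = 0.0,
) -> PeakFeatures:
    """Two-window range amplitudes and peak times of one response curve.

    The trace must cover both windows (relative to ``onset_s``).  Amplitudes
    are max - min within each half-open window; ties in the maximum break to
    the earliest time.  Zero amplitudes leave the log features as NaN and the
    result flagged invalid — they are excluded downstream, never clamped.
    """
    t, y = trace.time_s, trace.ca_nM
    if t[0] > onset_s + window1[0] or t[-1] < onset_s + window2[1]:
        raise ValueError("trace does not cover the feature windows")
    amp1, t1 = _window_stats(t, y, window1, onset_s)
    amp2, t2 = _window_stats(t, y, window2, onset_s)
    log1 = float(np.log10(amp1)) if amp1 > 0 else float("nan")
    log2 = float(np.log10(amp2)) if amp2 > 0 else float("nan")
    return PeakFeatures(
        condition_key=trace.condition.key,
        amp1_nM=amp1,
        amp2_nM=amp2,
        t_peak1_s=t1 - onset_s,
        t_peak2_s=t2 - onset_s,
        log_amp1=log1,
        log_amp2=log2,
    )


def build_feature_table(traces: list[CalciumTrace]) -> list[PeakFeatures]:
    """Group traces by condition, average replicates, extract features.

    One :class:`PeakFeatures` row per (genotype, stimulus, concentration),
    in first-appearance order.  Rows with a zero amplitude are excluded with
    a logged warning.
    """
    if not traces:
        raise ValueError("no traces supplied")
    groups: dict[tuple, list[CalciumTrace]] = {}
    for tr in traces:
        groups.setdefault(tr.condition.key, []).append(tr)
    rows: list[PeakFeatures] = []
    for key, grp in groups.items():
        feats = extract_peak_features(average_replicates(grp))
        if not feats.valid:
            logger.warning("excluding condition %s: zero window amplitude", key)
            continue
        rows.append(feats)
    return rows
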