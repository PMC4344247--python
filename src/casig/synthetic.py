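"""Synthetic aequorin luminometry: calcium signatures and photon counts.

The generator emulates whole-seedling luminometer experiments: a seedling at
rest (~100 nM [Ca2+]_cyt) receives a stimulus at t = 0 and responds with

* an immediate first transient (~20 s wide) whose amplitude saturates with
  stimulus strength — NaCl and iso-osmotic sorbitol share the curve, sorbitol
  scaled down by the genotype's ``sorbitol_scale``;
* for biphasic (col0-like) genotypes under NaCl only, a delayed second
  transient (~30 s wide) whose onset varies seedling to seedling within
  30–120 s post stimulus;
* a cold shock or a touch (base-solution) response as single transients with
  their own amplitudes.

Transients are alpha pulses ``a(x) = x * exp(1 - x)``, ``x = (t - onset)/tau``
(zero before onset, unit peak at ``x = 1``), with tau set so the width at 10%
of peak equals the profile's stated duration.  Amplitudes are jittered
multiplicatively by a truncated-at-zero Gaussian with coefficient of
variation ``amp_cv``.

The photon-count forward model inverts the calibration: per interval,
``expected counts = k([Ca2+]) * remaining_pool * dt`` with the pool consumed
by every photon emitted; the terminal discharge releases whatever remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .calibration import CalibrationParams, calcium_to_rate
from .conditions import (
    DEFAULT_CONCENTRATIONS_MM,
    DEFAULT_PROFILES,
    Genotype,
    GenotypeProfile,
    Stimulus,
    StimulusCondition,
)
from .traces import CalciumTrace, LuminescenceTrace


def _alpha_ten_percent_width() -> float:
    """Width of the unit alpha pulse at 10% of peak, in units of tau."""
    f = lambda x: x * np.exp(1.0 - x) - 0.1
    lo = brentq(f, 1e-9, 1.0)
    hi = brentq(f, 1.0, 50.0)
    return hi - lo


#: a(x) = 0.1 at x = lo and x = hi; duration-at-10% = tau * (hi - lo).
_WIDTH_FACTOR = _alpha_ten_percent_width()


def duration_to_tau(duration_s: float) -> float:
    """Alpha-pulse time constant giving the requested width at 10% of peak."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return duration_s / _WIDTH_FACTOR


def alpha_pulse(time_s: np.ndarray, onset_s: float, tau_s: float) -> np.ndarray:
    """Unit-peak alpha pulse rising at ``onset_s``; identically 0 before it."""
    x = (np.asarray(time_s, dtype=float) - onset_s) / tau_s
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.exp(1.0 - x[pos])
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated luminometry experiment.

    ``aequorin_pool`` is the expected total photon yield of a seedling
    (counts across the trace plus terminal discharge).  ``seed`` drives every
    random draw; each (genotype, stimulus, concentration, replicate) cell uses
    an independent substream so replicates are statistically independent and
    individually reproducible.
    """

    profiles: dict[Genotype, GenotypeProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    concentrations_mM: tuple[float, ...] = DEFAULT_CONCENTRATIONS_MM
    n_replicates: int = 3
    dt_s: float = 1.0
    t_start_s: float = -10.0
    t_end_s: float = 300.0
    aequorin_pool: float = 1e6
    seed: int = 0
    calibration: CalibrationParams = field(default_factory=CalibrationParams)

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.aequorin_pool <= 0:
            raise ValueError("aequorin_pool must be > 0")
        if self.t_start_s > -10 or self.t_end_s < 300:
            raise ValueError("time grid must cover at least [-10, 300] s")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end_s - self.t_start_s) / self.dt_s))
        return self.t_start_s + self.dt_s * np.arange(n + 1)


_STIM_INDEX = {s: i for i, s in enumerate(Stimulus, start=1)}
_GENO_INDEX = {g: i for i, g in enumerate(Genotype, start=1)}


def rng_for_condition(seed: int, condition: StimulusCondition) -> np.random.Generator:
    """Independent, reproducible RNG substream for one experimental cell."""
    key = (
        _GENO_INDEX[condition.genotype],
        _STIM_INDEX[condition.stimulus],
        int(round(condition.concentration_mM * 1000)),
        condition.replicate_id or 0,
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def dose_response_amplitude(
    concentration_mM: float,
    profile: GenotypeProfile,
    stimulus: Stimulus | str = Stimulus.NACL,
) -> float:
    """Mean first-transient amplitude (nM) at a given stimulus strength.

    Hyperbolic saturation ``A1(c) = A_max * c / (c + K)`` on the
    NaCl-osmolarity scale.  Sorbitol concentrations are iso-osmotic at twice
    the NaCl molarity, so they are mapped to ``c_osm = c / 2`` and scaled by
    the profile's ``sorbitol_scale`` (the purely osmotic response fraction).
    Strictly increasing in concentration; A1(0) = 0.
    """
    stimulus = Stimulus(stimulus)
    if concentration_mM < 0:
        raise ValueError("concentration must be >= 0")
    if stimulus is Stimulus.NACL:
        c, scale = float(concentration_mM), 1.0
    elif stimulus is Stimulus.SORBITOL:
        c, scale = float(concentration_mM) / 2.0, profile.sorbitol_scale
    else:
        raise ValueError(f"dose response is defined for nacl/sorbitol, not {stimulus.value}")
    return scale * profile.first_amp_max_nM * c / (c + profile.first_amp_K_mM)


def _jitter(rng: np.random.Generator, cv: float) -> float:
    # multiplicative amplitude factor, Gaussian truncated at zero
    return max(1.0 + cv * rng.standard_normal(), 0.0)


def simulate_calcium_trace(
    condition: StimulusCondition,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CalciumTrace:
    """Simulate one seedling's [Ca2+]_cyt response to a stimulus.

    NaCl and sorbitol evoke the dose-dependent first transient; NaCl
    additionally evokes the delayed second transient in biphasic genotypes.
    Cold and base-solution applications evoke single transients with the
    profile's cold and touch amplitudes (the measured amplitude of a stress
    response already includes any mechanical component of the application, so
    no separate touch pulse is stacked onto stress stimuli).
    """
    profile = config.profiles[condition.genotype]
    t = config.time_grid()
    ca = np.full_like(t, profile.baseline_nM)

    if condition.stimulus is Stimulus.BASE:
        amp = profile.touch_amp_nM * _jitter(rng, profile.amp_cv)
        ca = ca + amp * alpha_pulse(t, 0.0, duration_to_tau(profile.touch_duration_s))
    elif condition.stimulus is Stimulus.COLD:
        amp = profile.cold_amp_nM * _jitter(rng, profile.amp_cv)
        ca = ca + amp * alpha_pulse(t, 0.0, duration_to_tau(profile.first_duration_s))
    else:
        mean_amp = dose_response_amplitude(
            condition.concentration_mM, profile, condition.stimulus
        )
        amp1 = mean_amp * _jitter(rng, profile.amp_cv)
        ca = ca + amp1 * alpha_pulse(t, 0.0, duration_to_tau(profile.first_duration_s))
        if condition.stimulus is Stimulus.NACL and profile.biphasic:
            amp2 = profile.second_amp_mean_nM * _jitter(rng, profile.amp_cv)
            onset2 = rng.uniform(*profile.second_time_range_s)
            ca = ca + amp2 * alpha_pulse(t, onset2, duration_to_tau(profile.second_duration_s))

    return CalciumTrace(time_s=t, ca_nM=ca, condition=condition)


def simulate_luminescence(
    trace: CalciumTrace,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    poisson: bool = True,
) -> LuminescenceTrace:
    """Forward-model photon counts from a calcium trace.

    Per interval i the emission rate constant ``k_i = k(ca_i)`` (inverse
    calibration) applies to the remaining pool ``R_i``::

        expected counts_i = k_i * R_i * dt ;  R_{i+1} = R_i - counts_i

    With ``poisson=True`` counts are Poisson draws (shot noise) capped at the
    integer pool; otherwise the noise-free expected counts are recorded.
    Counts plus terminal discharge equal the initial pool exactly.  A pool
    that runs dry before the end of the trace is flagged, not an error.
    """
    if poisson and rng is None:
        raise ValueError("poisson sampling requires an rng")
    dt = trace.dt_s
    k = calcium_to_rate(trace.ca_nM, config.calibration)
    n = trace.time_s.size

    exhausted = False
    if poisson:
        pool = int(round(config.aequorin_pool))
        remaining = pool
        counts = np.zeros(n, dtype=float)
        for i in range(n):
            if remaining <= 0:
                exhausted = True
                break
            mu = k[i] * remaining * dt
            c = min(int(rng.poisson(mu)), remaining)
            counts[i] = c
            remaining -= c
        discharge = float(pool - counts.sum())
    else:
        pool = float(config.aequorin_pool)
        remaining = pool
        counts = np.zeros(n, dtype=float)
        for i in range(n):
            if remaining <= 0:
                exhausted = True
                break
            mu = min(k[i] * remaining * dt, remaining)
            counts[i] = mu
            remaining -= mu
        discharge = max(pool - float(counts.sum()), 0.0)

    return LuminescenceTrace(
        time_s=trace.time_s,
        counts=counts,
        discharge_counts=discharge,
        condition=trace.condition,
        pool_exhausted=exhausted,
    )


def simulate_replicates(
    config: SimulationConfig,
    genotype: Genotype | str,
    stimulus: Stimulus | str,
    concentration_mM: float,
) -> list[CalciumTrace]:
    """All replicate calcium traces for one experimental cell."""
    genotype, stimulus = Genotype(genotype), Stimulus(stimulus)
    out = []
    for rep in range(1, config.n_replicates + 1):
        cond = StimulusCondition(stimulus, concentration_mM, genotype, rep)
        out.append(simulate_calcium_trace(cond, config, rng_for_condition(config.seed, cond)))
    return out
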