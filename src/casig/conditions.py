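"""Experimental conditions and genotype response profiles.

A condition identifies one luminometer run: which stimulus was pipetted onto
the seedling at t = 0 (NaCl, iso-osmotic sorbitol, cold shock, or plain base
solution), at what concentration, on which genotype, and which biological
replicate it is.  A :class:`GenotypeProfile` collects the response parameters
of one accession — resting [Ca2+]_cyt, touch/cold/first-transient amplitudes,
the dose-response half-saturation, and whether the NaCl signature is biphasic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum


class Stimulus(str, Enum):
    """Treatment applied at stimulus onset (t = 0)."""

    NACL = "nacl"
    SORBITOL = "sorbitol"
    COLD = "cold"
    BASE = "base"


class Genotype(str, Enum):
    """Ecotype-like response class.

    ``col0_like`` mounts a biphasic NaCl signature (initial transient plus a
    delayed second transient); ``c24_like`` is monophasic.
    """

    COL0 = "col0_like"
    C24 = "c24_like"


@dataclass(frozen=True)
class StimulusCondition:
    """Metadata for a single trace.

    Parameters
    ----------
    stimulus
        Treatment type.
    concentration_mM
        Solute concentration in mM.  Must be 0 for ``cold`` and ``base``.
    genotype
        Response class of the seedling.
    replicate_id
        1-based biological replicate index, or ``None`` for a
        replicate-averaged curve.
    """

    stimulus: Stimulus
    concentration_mM: float
    genotype: Genotype
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus", Stimulus(self.stimulus))
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "concentration_mM", float(self.concentration_mM))
        if self.concentration_mM < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration_mM}")
        if self.stimulus in (Stimulus.COLD, Stimulus.BASE) and self.concentration_mM != 0:
            raise ValueError(f"{self.stimulus.value} stimulus requires concentration 0")
        if self.replicate_id is not None and self.replicate_id < 1:
            raise ValueError(f"replicate_id must be >= 1, got {self.replicate_id}")

    @property
    def key(self) -> tuple[str, str, float]:
        """Grouping key ignoring the replicate: (genotype, stimulus, concentration)."""
        return (self.genotype.value, self.stimulus.value, self.concentration_mM)

    def without_replicate(self) -> "StimulusCondition":
        return replace(self, replicate_id=None)


@dataclass(frozen=True)
class GenotypeProfile:
    """Response parameters of one genotype.

    All amplitudes are in nM [Ca2+]_cyt above the resting baseline.  The mean
    first-transient amplitude follows the saturating dose response
    ``A1(c) = first_amp_max_nM * c / (c + first_amp_K_mM)`` with ``c`` on the
    NaCl-osmolarity scale; sorbitol responses are the same curve scaled by
    ``sorbitol_scale`` (the purely osmotic fraction of the NaCl response).
    Durations are transient widths measured at 10% of peak height.
    ``amp_cv`` is the between-seedling coefficient of variation applied
    multiplicatively to every drawn amplitude.
    """

    baseline_nM: float = 100.0
    touch_amp_nM: float = 284.0
    cold_amp_nM: float = 1052.0
    first_amp_max_nM: float = 1800.0
    first_amp_K_mM: float = 250.0
    sorbitol_scale: float = 737.0 / 800.0
    second_amp_mean_nM: float = 656.0
    biphasic: bool = True
    second_time_range_s: tuple[float, float] = (35.0, 100.0)
    first_duration_s: float = 20.0
    second_duration_s: float = 30.0
    touch_duration_s: float = 10.0
    amp_cv: float = 0.08

    def __post_init__(self) -> None:
        for name in ("baseline_nM", "touch_amp_nM", "cold_amp_nM",
                     "first_amp_max_nM", "second_amp_mean_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_nM <= 0:
            raise ValueError("baseline_nM must be > 0")
        if self.first_amp_K_mM <= 0:
            raise ValueError("first_amp_K_mM must be > 0")
        if not (0 < self.sorbitol_scale <= 1):
            raise ValueError("sorbitol_scale must be in (0, 1]")
        lo, hi = self.second_time_range_s
        if not (30 < lo <= hi <= 120):
            raise ValueError("second_time_range_s must lie within (30, 120]")
        if not self.biphasic and self.second_amp_mean_nM != 0:
            raise ValueError("monophasic profile must have second_amp_mean_nM = 0")
        if self.amp_cv < 0:
            raise ValueError("amp_cv must be >= 0")
        for name in ("first_duration_s", "second_duration_s", "touch_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# Default profiles.  Dose-response maxima are fixed so that A1(200 mM NaCl)
# reproduces the observed 800 nM (col0_like) and 855 nM (c24_like) first-peak
# heights with K = 250 mM: A_max = A1(200) * (200 + K) / 200.
COL0_PROFILE = GenotypeProfile(
    touch_amp_nM=284.0,
    cold_amp_nM=1052.0,
    first_amp_max_nM=800.0 * (200.0 + 250.0) / 200.0,
    sorbitol_scale=737.0 / 800.0,
    second_amp_mean_nM=656.0,
    biphasic=True,
)

C24_PROFILE = GenotypeProfile(
    touch_amp_nM=219.0,
    cold_amp_nM=914.0,
    first_amp_max_nM=855.0 * (200.0 + 250.0) / 200.0,
    sorbitol_scale=750.0 / 855.0,
    second_amp_mean_nM=0.0,
    biphasic=False,
)

DEFAULT_PROFILES: dict[Genotype, GenotypeProfile] = {
    Genotype.COL0: COL0_PROFILE,
    Genotype.C24: C24_PROFILE,
}

#: NaCl concentration grid of the default discrimination experiment (mM).
DEFAULT_CONCENTRATIONS_MM: tuple[float, ...] = (
    20.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 500.0, 750.0, 1000.0,
)
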