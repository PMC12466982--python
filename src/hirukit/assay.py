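"""Thrombin-titration antithrombin activity model.

The quantitative assay fixes the thrombin dose at 50 U/mL x 50 uL = 2.5 U and
titrates the volume V (uL) of a test protein solution of concentration C
(mg/mL) down to the smallest volume producing a half-coagulated state (30-70%
solidified).  The specific activity then follows from

    ATU/mg = (50 * 50) / (V * C) * K,

with K a correction coefficient, 1 unless stated otherwise.

Because the half-coagulation endpoint is only observed, not modelled, in the
protocol, the simulation uses a latent logistic clot-fraction curve: the
fraction of thrombin neutralised is f = V*C*A / 2500 (A the true specific
activity), and clot_fraction(V) = logistic((d50 - f) / s) with d50 = 1 at the
half-coagulation point and s a steepness parameter.  The titration search
mirrors the protocol's coarse-to-fine volume schedule (20, 10, 2 uL steps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import mean as _mean

import numpy as np

__all__ = [
    "THROMBIN_DOSE_NUMERATOR",
    "TitrationRecord",
    "TitrationSeries",
    "CoagulationModel",
    "TitrationResult",
    "atu_per_mg",
    "invert_for_volume",
    "qualitative_assay",
    "titrate_half_coagulation",
    "replicate_summary",
    "series_from_replicates",
]

#: (50 U/mL) x (50 uL): the fixed thrombin dose term of the activity formula.
THROMBIN_DOSE_NUMERATOR = 50.0 * 50.0

#: Protocol cap on the test-solution volume, uL.
MAX_VOLUME_UL = 100.0

#: Semi-coagulated window: 30-70% solidified.
HALF_COAGULATION_WINDOW = (0.30, 0.70)

#: Clot fraction above which coagulation is called "complete".
COMPLETE_COAGULATION_THRESHOLD = 0.95

#: Protocol volume schedule: initial screen, refinement, precise step (uL).
DEFAULT_SCHEDULE = (20.0, 10.0, 2.0)


def atu_per_mg(V: float, C: float, K: float = 1.0) -> float:
    """Antithrombin activity, ATU/mg = 2500 / (V * C) * K."""
    if V <= 0:
        raise ValueError(f"volume must be positive, got {V}")
    if C <= 0:
        raise ValueError(f"concentration must be positive, got {C}")
    if K <= 0:
        raise ValueError(f"correction coefficient must be positive, got {K}")
    return THROMBIN_DOSE_NUMERATOR / (V * C) * K


def invert_for_volume(ATU: float, C: float, K: float = 1.0) -> float:
    """Half-coagulation volume implied by an activity: V = 2500*K / (ATU*C)."""
    if ATU <= 0:
        raise ValueError("no finite half-coagulation volume for ATU <= 0")
    if C <= 0:
        raise ValueError(f"concentration must be positive, got {C}")
    return THROMBIN_DOSE_NUMERATOR * K / (ATU * C)


@dataclass(frozen=True)
class TitrationRecord:
    """One titration endpoint: volume, concentration, correction, activity."""

    protein_id: str
    V: float
    C: float
    K: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.V <= MAX_VOLUME_UL:
            raise ValueError(
                f"volume {self.V} uL outside (0, {MAX_VOLUME_UL}] for "
                f"{self.protein_id!r}"
            )
        if self.C <= 0 or self.K <= 0:
            raise ValueError(f"C and K must be positive for {self.protein_id!r}")

    @property
    def ATU(self) -> float:
        return atu_per_mg(self.V, self.C, self.K)


@dataclass(frozen=True)
class TitrationSeries:
    """Replicate activities for one protein with their summary."""

    protein_id: str
    replicates: tuple[float, ...]
    mean: float
    sd: float
    active: bool

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"no replicates for {self.protein_id!r}")


@dataclass
class CoagulationModel:
    """Latent clotting response of the fibrinogen/thrombin mix.

    ``specific_activity`` is the true activity in ATU/mg, ``concentration``
    the test-solution concentration in mg/mL.  ``d50`` scales the
    half-coagulation point (1.0 = noise-free truth); per-replicate noise is
    applied by perturbing d50.  ``steepness`` is the logistic width on the
    neutralised-fraction axis.
    """

    specific_activity: float
    concentration: float
    d50: float = 1.0
    steepness: float = 0.05

    def __post_init__(self) -> None:
        if self.specific_activity < 0:
            raise ValueError("specific activity must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.d50 <= 0 or self.steepness <= 0:
            raise ValueError("d50 and steepness must be positive")

    def neutralised_fraction(self, V: float) -> float:
        """Fraction of the 2.5 U thrombin dose neutralised at volume V."""
        return V * self.concentration * self.specific_activity / THROMBIN_DOSE_NUMERATOR

    def clot_fraction(self, V: float) -> float:
        """Solidified fraction of the mix, in [0, 1], non-increasing in V."""
        if V < 0:
            raise ValueError("volume must be >= 0")
        if self.specific_activity == 0:
            return 1.0
        x = (self.d50 - self.neutralised_fraction(V)) / self.steepness
        # clamp to avoid overflow in exp
        x = max(min(x, 700.0), -700.0)
        return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class TitrationResult:
    """Outcome of the coarse-to-fine half-coagulation search."""

    active: bool
    V_min: float | None
    clot_fraction: float | None
    quantized_at_floor: bool = False
    in_window: bool = True

    def atu(self, C: float, K: float = 1.0) -> float:
        """Specific activity implied by the endpoint; 0.0 when inactive."""
        if not self.active or self.V_min is None:
            return 0.0
        return atu_per_mg(self.V_min, C, K)


def qualitative_assay(model: CoagulationModel, V: float = MAX_VOLUME_UL) -> str:
    """Qualitative call at a single volume: 'clotted' or 'not_clotted'.

    Complete coagulation (clot fraction above the completeness threshold)
    means no detectable antithrombin activity.
    """
    if model.clot_fraction(V) > COMPLETE_COAGULATION_THRESHOLD:
        return "clotted"
    return "not_clotted"


def _check_monotone(model: CoagulationModel) -> None:
    grid = np.linspace(0.0, MAX_VOLUME_UL, 26)
    values = [model.clot_fraction(v) for v in grid]
    if any(b > a + 1e-9 for a, b in zip(values, values[1:])):
        raise ValueError("clot_fraction is not non-increasing in volume")


def titrate_half_coagulation(
    model: CoagulationModel,
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
) -> TitrationResult:
    """Coarse-to-fine search for the smallest half-coagulation volume.

    Scans volumes on successively finer grids (anchored at 0, so the grids
    nest when each step divides the previous one) and returns the smallest
    volume on the final grid whose clot fraction has dropped to the
    semi-coagulated window's upper bound or below.  Volumes below the finest
    step are not searched: a true threshold smaller than the finest step
    reports V_min equal to that step with ``quantized_at_floor`` set.

    Returns an inactive result when even the maximum volume leaves the mix
    completely coagulated (or never reaches the window).
    """
    if not schedule or any(s <= 0 for s in schedule):
        raise ValueError("schedule must contain positive step sizes")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule step sizes must be strictly decreasing")
    _check_monotone(model)

    upper = HALF_COAGULATION_WINDOW[1]
    if model.clot_fraction(MAX_VOLUME_UL) > upper:
        # Even the full 100 uL never reaches the semi-coagulated window.
        return TitrationResult(active=False, V_min=None, clot_fraction=None)

    lo = 0.0  # largest volume known to clot above the window
    hi = MAX_VOLUME_UL
    for step in schedule:
        v = math.floor(lo / step) * step + step
        found = None
        while v <= hi + 1e-9:
            if model.clot_fraction(v) <= upper:
                found = v
                break
            lo = v
            v += step
        if found is not None:
            hi = found

    final_step = schedule[-1]
    v_min = max(hi, final_step)
    clot = model.clot_fraction(v_min)
    return TitrationResult(
        active=True,
        V_min=v_min,
        clot_fraction=clot,
        quantized_at_floor=hi < final_step + 1e-9 and clot < HALF_COAGULATION_WINDOW[0],
        in_window=HALF_COAGULATION_WINDOW[0] <= clot <= upper,
    )


def replicate_summary(values: list[float]) -> tuple[float, float, bool]:
    """Mean, sample SD (n-1 denominator) and activity flag for replicates.

    A single value yields SD = 0 with a degenerate-sample warning.  The
    series is inactive only when every replicate is exactly 0.
    """
    if not values:
        raise ValueError("empty replicate list")
    if any(v < 0 for v in values):
        raise ValueError("replicate activities must be >= 0")
    m = _mean(values)
    if len(values) == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))
    active = any(v != 0 for v in values)
    return m, sd, active


def series_from_replicates(protein_id: str, values: list[float]) -> TitrationSeries:
    m, sd, active = replicate_summary(values)
    return TitrationSeries(
        protein_id=protein_id,
        replicates=tuple(values),
        mean=m,
        sd=sd,
        active=active,
    )
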