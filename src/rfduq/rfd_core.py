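"""Deterministic reference-dose arithmetic.

A reference dose (RfD) is derived by dividing a point of departure (POD) —
an intake rate anchored to an observed serum concentration — by a composite
uncertainty factor (UF).  This module holds the unit-carrying dose types and
the small, exact operations that the rest of the package composes:
UF multiplication, POD division with presentation rounding, peak/window
averaging, anchored serum-to-intake scaling, and fold-change comparisons
between serum levels.

All doses carry explicit units and exposure metrics; no bare floats cross
module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Metric",
    "DoseUnit",
    "SerumConcentration",
    "IntakeRate",
    "PointOfDeparture",
    "UncertaintyFactorSpec",
    "RfdEstimate",
    "SerumIntakeAnchor",
    "round_sigfigs",
    "compose_uf",
    "derive_rfd",
    "average_peak_and_window",
    "serum_to_intake",
    "fold_change",
]


class Metric(str, Enum):
    """Exposure metric for a lipid-adjusted serum concentration."""

    TCDD = "TCDD"
    TEQ = "TEQ"


class DoseUnit(str, Enum):
    """Intake-rate unit; conversions are exact powers of ten."""

    NG_PER_KG_DAY = "ng/kg/day"
    PG_PER_KG_DAY = "pg/kg/day"


_UNIT_TO_PG = {DoseUnit.NG_PER_KG_DAY: 1000.0, DoseUnit.PG_PER_KG_DAY: 1.0}


@dataclass(frozen=True)
class SerumConcentration:
    """Lipid-adjusted serum concentration in ppt (pg analyte / g serum lipid).

    The exposure metric (TCDD-only or total TEQ) must be stated explicitly:
    the two are never interchangeable in POD arithmetic.
    """

    value: float
    metric: Metric

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"serum concentration must be positive, got {self.value}")
        if not isinstance(self.metric, Metric):
            object.__setattr__(self, "metric", Metric(self.metric))


@dataclass(frozen=True)
class IntakeRate:
    """Daily oral intake rate with explicit unit (ng/kg/day or pg/kg/day)."""

    value: float
    unit: DoseUnit

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"intake rate must be non-negative, got {self.value}")
        if not isinstance(self.unit, DoseUnit):
            object.__setattr__(self, "unit", DoseUnit(self.unit))

    @property
    def pg_per_kg_day(self) -> float:
        return self.value * _UNIT_TO_PG[self.unit]

    def to(self, unit: DoseUnit) -> "IntakeRate":
        unit = DoseUnit(unit)
        return IntakeRate(self.pg_per_kg_day / _UNIT_TO_PG[unit], unit)


class Classification(str, Enum):
    NOAEL = "NOAEL"
    LOAEL = "LOAEL"


@dataclass(frozen=True)
class PointOfDeparture:
    """A POD: an intake rate or serum concentration plus its NOAEL/LOAEL call.

    ``ci_low``/``ci_high`` optionally carry a confidence interval on the dose
    (same units), e.g. from an inverse-prediction fit; ``ci_high`` may be
    ``math.inf`` when the upper bound is unbounded.
    """

    dose: Union[IntakeRate, SerumConcentration]
    classification: Classification
    provenance: str = ""
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.classification, Classification):
            object.__setattr__(self, "classification", Classification(self.classification))


@dataclass(frozen=True)
class UncertaintyFactorSpec:
    """A named uncertainty factor, as a point value or lognormal distribution.

    ``nominal`` is the deterministic value (e.g. UF_L = 10 for LOAEL-to-NOAEL
    extrapolation, UF_H = 3 for human interindividual variability).  The
    optional ``distribution`` (a ``prob_rfd.LognormalSpec``) supports the
    probabilistic treatment.
    """

    name: str
    nominal: float
    distribution: Optional[object] = None

    def __post_init__(self) -> None:
        if self.nominal < 1:
            raise ValueError(f"UF nominal must be >= 1, got {self.nominal} ({self.name})")


@dataclass(frozen=True)
class RfdEstimate:
    """An RfD in pg/kg/day: exact value plus presentation-rounded value."""

    value: float
    rounded_value: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("RfD must be positive")


@dataclass(frozen=True)
class SerumIntakeAnchor:
    """A (serum concentration, intake rate) pair used for proportional scaling.

    Stands in for the kinetic model that maps a lipid-adjusted serum
    concentration to the daily intake producing it: intakes scale linearly
    with serum level through this anchor.
    """

    serum: SerumConcentration
    intake: IntakeRate

    def __post_init__(self) -> None:
        if not self.intake.value > 0:
            raise ValueError("anchor intake must be positive")


def round_sigfigs(x: float, sigfigs: int = 1) -> float:
    """Round ``x`` to ``sigfigs`` significant figures (half away handled by
    the underlying decimal rounding of ``round`` on the scaled mantissa)."""
    if x == 0:
        return 0.0
    if sigfigs < 1:
        raise ValueError("sigfigs must be >= 1")
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (sigfigs - 1 - exponent)
    return round(x * factor) / factor


def compose_uf(factors: Iterable[Union[UncertaintyFactorSpec, float]]) -> float:
    """Product of uncertainty-factor nominals; the empty product is 1.

    Order-independent by construction; any nominal < 1 is rejected.
    """
    total = 1.0
    for f in factors:
        nominal = f.nominal if isinstance(f, UncertaintyFactorSpec) else float(f)
        if nominal < 1:
            raise ValueError(f"uncertainty factor must be >= 1, got {nominal}")
        total *= nominal
    return total


def derive_rfd(
    pod: PointOfDeparture,
    composite_uf: float,
    sigfigs: int = 1,
) -> RfdEstimate:
    """RfD = POD (pg/kg/day) / composite UF, with presentation rounding.

    The POD must be intake-typed; serum PODs are converted first via
    :func:`serum_to_intake`.  Default presentation rounding is one
    significant figure (0.6667 -> 0.7, 6.667 -> 7).
    """
    if not isinstance(pod.dose, IntakeRate):
        raise TypeError(
            "derive_rfd requires an intake-rate POD; convert serum PODs with serum_to_intake first"
        )
    if composite_uf < 1:
        raise ValueError(f"composite UF must be >= 1, got {composite_uf}")
    if not pod.dose.value > 0:
        raise ValueError("POD intake must be positive")
    exact = pod.dose.pg_per_kg_day / composite_uf
    return RfdEstimate(
        value=exact,
        rounded_value=round_sigfigs(exact, sigfigs),
        provenance=f"{pod.provenance} / UF {composite_uf:g}".strip(" /"),
    )


def average_peak_and_window(peak: IntakeRate, window_avg: IntakeRate) -> IntakeRate:
    """Arithmetic mean of a peak intake and a critical-window average intake.

    Both operands must carry the same unit; mixed units are rejected rather
    than silently converted.
    """
    if peak.unit is not window_avg.unit:
        raise ValueError(f"mixed units: {peak.unit.value} vs {window_avg.unit.value}")
    return IntakeRate((peak.value + window_avg.value) / 2.0, peak.unit)


def serum_to_intake(
    serum: SerumConcentration,
    anchor: SerumIntakeAnchor,
    kinetic_adjustment: float = 1.0,
) -> IntakeRate:
    """Anchored proportional serum-to-intake scaling.

    intake = anchor.intake × (serum / anchor.serum) × kinetic_adjustment.

    This is an explicit linear stand-in anchored at a published
    (serum, intake) pair, not a kinetic model.  ``kinetic_adjustment``
    (default 1, i.e. off) allows an upward correction for kinetic models
    that underpredict the intake associated with low serum concentrations.
    """
    if serum.metric is not anchor.serum.metric:
        raise ValueError(
            f"metric mismatch: serum is {serum.metric.value}, anchor is {anchor.serum.metric.value}"
        )
    if kinetic_adjustment <= 0:
        raise ValueError("kinetic_adjustment must be positive")
    scale = serum.value / anchor.serum.value
    return IntakeRate(anchor.intake.value * scale * kinetic_adjustment, anchor.intake.unit)


class FoldRounding(str, Enum):
    NONE = "none"
    NEAREST_INTEGER = "nearest_integer"
    ONE_SIGFIG = "one_sigfig"


def fold_change(
    numerator: SerumConcentration,
    denominator: SerumConcentration,
    rounding: Union[FoldRounding, str] = FoldRounding.NONE,
) -> float:
    """Ratio of two serum concentrations on the same metric.

    Rounding is caller-specified because published fold statements mix
    conventions (one significant figure vs nearest integer).
    """
    if numerator.metric is not denominator.metric:
        raise ValueError("fold_change requires matching exposure metrics")
    ratio = numerator.value / denominator.value
    rounding = FoldRounding(rounding)
    if rounding is FoldRounding.NEAREST_INTEGER:
        return float(round(ratio))
    if rounding is FoldRounding.ONE_SIGFIG:
        return round_sigfigs(ratio, 1)
    return ratio
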