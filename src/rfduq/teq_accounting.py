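"""Toxic-equivalency (TEQ) accounting at the aggregate TCDD / non-TCDD level.

Dioxin-like compounds act through the same receptor as TCDD; a serum level
expressed as total TEQ (the TEF-weighted sum over congeners) is the mixture
basis on which a POD should sit when background dioxin-like exposure is
considered.  This module combines a TCDD-only concentration with the
non-TCDD dioxin-like TEQ, computes contribution fractions, and converts a
TCDD-only POD to a TEQ-basis POD.

Published modeled totals need not equal the sum of their components (they
come from separate kinetic modeling); the breakdown type therefore accepts
an authoritative supplied total that overrides additivity, warning when the
discrepancy exceeds 1%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

from .rfd_core import Metric, SerumConcentration

__all__ = ["TeqBreakdown", "fraction_non_tcdd", "teq_basis_pod"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TeqBreakdown:
    """Aggregate serum TEQ breakdown in ppt lipid-adjusted.

    ``total_teq`` may be supplied directly when the components do not sum
    (modeled totals); when omitted it defaults to ``tcdd + non_tcdd_teq``.
    """

    tcdd: float
    non_tcdd_teq: float
    total_teq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tcdd < 0 or self.non_tcdd_teq < 0:
            raise ValueError("TEQ components must be non-negative")
        if self.total_teq is None:
            object.__setattr__(self, "total_teq", self.tcdd + self.non_tcdd_teq)
        else:
            if self.total_teq < max(self.tcdd, self.non_tcdd_teq):
                raise ValueError(
                    "supplied total TEQ must be at least the largest component"
                )
            component_sum = self.tcdd + self.non_tcdd_teq
            if component_sum > 0 and abs(self.total_teq - component_sum) / self.total_teq > 0.01:
                msg = (
                    f"supplied total TEQ {self.total_teq:g} ppt differs from component sum "
                    f"{component_sum:g} ppt by more than 1%; keeping the supplied total"
                )
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)

    @property
    def fraction_tcdd(self) -> float:
        return self.tcdd / self.total_teq


def fraction_non_tcdd(b: TeqBreakdown, as_percent_rounded: bool = False) -> float:
    """Share of the total TEQ contributed by dioxin-like compounds other than
    TCDD; with ``as_percent_rounded`` the share is returned as an integer
    percentage."""
    if not b.total_teq > 0:
        raise ValueError("total TEQ must be positive")
    frac = b.non_tcdd_teq / b.total_teq
    if as_percent_rounded:
        return float(round(frac * 100))
    return frac


def teq_basis_pod(tcdd_pod: SerumConcentration, breakdown: TeqBreakdown) -> SerumConcentration:
    """Convert a TCDD-only serum POD to its TEQ-basis equivalent.

    Uses the breakdown's (possibly authoritative) total; never decreases the
    concentration.  A TEQ-metric input is rejected — it is already converted.
    """
    if tcdd_pod.metric is not Metric.TCDD:
        raise ValueError("teq_basis_pod expects a TCDD-metric concentration")
    total = breakdown.total_teq
    if total < tcdd_pod.value:
        # a breakdown whose total is below the POD cannot describe this POD
        raise ValueError(
            f"breakdown total {total:g} ppt is below the TCDD POD {tcdd_pod.value:g} ppt"
        )
    return SerumConcentration(total, Metric.TEQ)
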