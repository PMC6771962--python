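"""Log-log calibration and inverse prediction with confidence bounds.

The exposure–response relation between maternal lipid-adjusted serum dioxin
and neonatal TSH is modelled as a straight line on log-log axes:

    log(TSH) = a + b · log(serum) + ε,   ε ~ Normal(0, σ²).

Fitting is ordinary least squares on the log scale.  The POD question is the
*inverse* one: at what serum concentration does the fitted line reach a
specified TSH threshold (5 μU/mL screening, 10 μU/mL clinical recall), and
how precisely is that concentration determined?  Two interval methods are
provided:

``approx_se``
    The Massart-style first-order standard error of the estimated predictor
    value, with a t-interval on the log scale, then exponentiated.  By
    default the replicate term 1/m is omitted because the threshold is a
    fixed cutoff rather than a measured response with its own error; a
    chemCal-compatible mode (finite m, default 1) is available.

``fieller``
    The exact confidence set obtained by inverting the band
    |y0 − (â + b̂x)| ≤ t·s·√(1/m + 1/n + (x−x̄)²/Sxx).  Depending on how
    well the slope is determined this set is a finite interval, the whole
    line, or the complement of an interval; all three cases are reported
    explicitly rather than clipped.

Natural logarithms are used internally; results in ppt are invariant to the
internal log base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rfd_core import Classification, Metric, PointOfDeparture, SerumConcentration

__all__ = [
    "CohortPairs",
    "CalibrationFit",
    "InversePrediction",
    "CiKind",
    "fit_loglog",
    "inverse_predict",
    "pod_from_threshold",
]


@dataclass(frozen=True)
class CohortPairs:
    """Bivariate cohort records: maternal serum (ppt) vs neonatal TSH (μU/mL)."""

    serum: np.ndarray
    tsh: np.ndarray
    metric: Metric = Metric.TCDD

    def __post_init__(self) -> None:
        serum = np.asarray(self.serum, dtype=float)
        tsh = np.asarray(self.tsh, dtype=float)
        object.__setattr__(self, "serum", serum)
        object.__setattr__(self, "tsh", tsh)
        if not isinstance(self.metric, Metric):
            object.__setattr__(self, "metric", Metric(self.metric))
        if serum.shape != tsh.shape or serum.ndim != 1:
            raise ValueError("serum and tsh must be 1-d arrays of equal length")
        if serum.size < 3:
            raise ValueError("need at least 3 mother-infant pairs")
        for name, arr in (("serum", serum), ("tsh", tsh)):
            bad = np.flatnonzero(~(arr > 0))
            if bad.size:
                raise ValueError(
                    f"{name} values must be positive (log-transformable); "
                    f"first offending row index {int(bad[0])}"
                )

    @property
    def n(self) -> int:
        return int(self.serum.size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric: Optional[str] = None) -> "CohortPairs":
        m = metric or (df["metric"].iloc[0] if "metric" in df else Metric.TCDD)
        return cls(df["maternal_serum_ppt"].to_numpy(), df["tsh_uU_mL"].to_numpy(), Metric(m))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maternal_serum_ppt": self.serum,
                "tsh_uU_mL": self.tsh,
                "metric": self.metric.value,
            }
        )


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit state on the natural-log scale, with the sufficient statistics
    needed for inverse prediction (slope, intercept, residual SE, n, x̄, ȳ,
    Sxx of the log predictor)."""

    slope: float
    intercept: float
    residual_se: float
    n: int
    xbar_log: float
    ybar_log: float
    sxx_log: float
    metric: Metric = Metric.TCDD

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("fit requires n >= 3")
        if not self.sxx_log > 0:
            raise ValueError("zero predictor variance on the log scale")

    def predict_log(self, log_serum: float) -> float:
        return self.intercept + self.slope * log_serum

    def predict_tsh(self, serum_ppt: float) -> float:
        """Forward prediction: fitted median TSH at a serum concentration."""
        return math.exp(self.predict_log(math.log(serum_ppt)))


def fit_loglog(pairs: CohortPairs) -> CalibrationFit:
    """Ordinary least squares of log(TSH) on log(serum)."""
    x = np.log(pairs.serum)
    y = np.log(pairs.tsh)
    n = x.size
    xbar = float(x.mean())
    ybar = float(y.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx <= 0:
        raise ValueError("zero predictor variance: all serum values identical")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    residual_se = math.sqrt(max(sse, 0.0) / (n - 2)) if n > 2 else 0.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        residual_se=residual_se,
        n=int(n),
        xbar_log=xbar,
        ybar_log=ybar,
        sxx_log=sxx,
        metric=pairs.metric,
    )


class CiKind(str, Enum):
    """Shape of the inverse-prediction confidence set."""

    INTERVAL = "interval"
    WHOLE_LINE = "whole_line"
    COMPLEMENT = "complement"


@dataclass(frozen=True)
class InversePrediction:
    """Serum concentration (ppt) at which the fitted line reaches a TSH
    threshold, with its confidence set.

    For ``kind == INTERVAL`` the set is [ci_low, ci_high]; ``ci_high`` may be
    ``inf``.  For ``WHOLE_LINE`` every positive concentration is compatible.
    For ``COMPLEMENT`` (Fieller with a poorly determined slope) the set is
    everything *outside* (ci_low, ci_high).  ``cap`` is the presentation
    ceiling: bounds above it are displayed as "> cap".
    """

    point: float
    ci_low: float
    ci_high: float
    level: float
    threshold: float
    method: str
    kind: CiKind = CiKind.INTERVAL
    cap: float = 1e7

    def __post_init__(self) -> None:
        if not self.point > 0:
            raise ValueError("inverse-prediction point must be positive")
        if self.kind is CiKind.INTERVAL and not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("point estimate must lie inside its confidence interval")

    @property
    def upper_unbounded(self) -> bool:
        return self.kind is not CiKind.INTERVAL or self.ci_high > self.cap

    def display_upper(self) -> str:
        if self.kind is CiKind.WHOLE_LINE:
            return "unbounded"
        return f"> {self.cap:g}" if self.ci_high > self.cap else f"{self.ci_high:g}"

    def contains(self, serum_ppt: float) -> bool:
        """Membership of a concentration in the confidence set."""
        if self.kind is CiKind.WHOLE_LINE:
            return True
        if self.kind is CiKind.COMPLEMENT:
            return serum_ppt <= self.ci_low or serum_ppt >= self.ci_high
        return self.ci_low <= serum_ppt <= self.ci_high


def inverse_predict(
    fit: CalibrationFit,
    threshold_tsh: float,
    level: float = 0.95,
    method: str = "approx_se",
    m: Optional[int] = None,
    cap: float = 1e7,
) -> InversePrediction:
    """Serum concentration at which the calibration line reaches a TSH
    threshold, with a confidence set at ``level``.

    ``m`` is the notional number of replicate threshold measurements in the
    Massart variance term 1/m; the default ``None`` treats the threshold as
    a fixed cutoff (m → ∞).  Pass ``m=1`` for chemCal-compatible intervals.
    """
    if not threshold_tsh > 0:
        raise ValueError("TSH threshold must be positive")
    if fit.slope == 0:
        raise ZeroDivisionError("zero slope: the threshold concentration is undefined")
    y0 = math.log(threshold_tsh)
    x0 = (y0 - fit.intercept) / fit.slope
    point = math.exp(x0)
    s, b, n = fit.residual_se, fit.slope, fit.n
    inv_m = 0.0 if m is None else 1.0 / m
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 2))

    if method == "approx_se":
        se_x0 = (s / abs(b)) * math.sqrt(
            inv_m + 1.0 / n + (y0 - fit.ybar_log) ** 2 / (b**2 * fit.sxx_log)
        )
        half = tcrit * se_x0
        return InversePrediction(
            point=point,
            ci_low=math.exp(x0 - half),
            ci_high=math.exp(x0 + half),
            level=level,
            threshold=threshold_tsh,
            method=method,
            kind=CiKind.INTERVAL,
            cap=cap,
        )

    if method == "fieller":
        # invert |y0 - (a + b x)| <= t s sqrt(1/m + 1/n + (x - xbar)^2/Sxx)
        c = tcrit**2 * s**2 / fit.sxx_log
        u = fit.intercept - y0
        A = b**2 - c
        B = 2.0 * (u * b + c * fit.xbar_log)
        C = u**2 - tcrit**2 * s**2 * (inv_m + 1.0 / n) - c * fit.xbar_log**2
        disc = B**2 - 4.0 * A * C
        if A > 0:
            r = math.sqrt(max(disc, 0.0))
            lo = (-B - r) / (2.0 * A)
            hi = (-B + r) / (2.0 * A)
            return InversePrediction(
                point=point,
                ci_low=math.exp(lo),
                ci_high=math.exp(hi),
                level=level,
                threshold=threshold_tsh,
                method=method,
                kind=CiKind.INTERVAL,
                cap=cap,
            )
        # slope CI spans zero (g >= 1): unbounded set, signalled explicitly
        if disc < 0 or A == 0:
            return InversePrediction(
                point=point,
                ci_low=0.0,
                ci_high=math.inf,
                level=level,
                threshold=threshold_tsh,
                method=method,
                kind=CiKind.WHOLE_LINE,
                cap=cap,
            )
        r = math.sqrt(disc)
        lo = (-B + r) / (2.0 * A)  # A < 0: roots swap order
        hi = (-B - r) / (2.0 * A)
        return InversePrediction(
            point=point,
            ci_low=math.exp(lo),
            ci_high=math.exp(hi),
            level=level,
            threshold=threshold_tsh,
            method=method,
            kind=CiKind.COMPLEMENT,
            cap=cap,
        )

    raise ValueError(f"unknown interval method {method!r}")


#: default NOAEL/LOAEL reading of the two conventional TSH thresholds:
#: 5 μU/mL (population screening level, read as a LOAEL in the current RfD)
#: and 10 μU/mL (clinical recall threshold, read as a NOAEL).
DEFAULT_THRESHOLD_CLASSIFICATION = {
    5.0: Classification.LOAEL,
    10.0: Classification.NOAEL,
}


def pod_from_threshold(
    fit: CalibrationFit,
    threshold: float,
    level: float = 0.95,
    method: str = "approx_se",
    m: Optional[int] = None,
    cap: float = 1e7,
    classification: Optional[Classification] = None,
) -> tuple[PointOfDeparture, InversePrediction]:
    """Wrap an inverse prediction as a serum-typed POD.

    The default classification follows the conventional reading of the two
    TSH thresholds (5 → LOAEL, 10 → NOAEL) and is overridable.
    """
    pred = inverse_predict(fit, threshold, level=level, method=method, m=m, cap=cap)
    if classification is None:
        classification = DEFAULT_THRESHOLD_CLASSIFICATION.get(
            float(threshold), Classification.LOAEL
        )
    pod = PointOfDeparture(
        dose=SerumConcentration(pred.point, fit.metric),
        classification=classification,
        provenance=f"inverse prediction at TSH {threshold:g} uU/mL ({fit.metric.value})",
        ci_low=pred.ci_low if pred.kind is CiKind.INTERVAL else None,
        ci_high=pred.ci_high if pred.kind is CiKind.INTERVAL else None,
    )
    return pod, pred
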