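"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators:

* a mother–infant TSH cohort — lognormal maternal serum exposure with a
  small high tail, and TSH following a log-log linear response with
  lognormal noise — standing in for the digitized exposure–response series;
* quartiled sperm-concentration group data — raw normal draws per dose
  group plus the (mean, 95% CI) summaries computed from them — standing in
  for published quartile summary tables.

Default parameters are calibrated to the printed facts about the cohorts
they emulate (sample sizes, central exposure levels, threshold crossings,
high-tail counts); see docs/methods.md for the calibration.  Every
generator returns a "truth" sidecar carrying its generating parameters so
recovery tests consume only generated data plus the sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calibration import CohortPairs
from .group_stats import GroupSummary
from .rfd_core import Metric, SerumConcentration

__all__ = [
    "TshCohortParams",
    "QuartileSummaryParams",
    "GroupParams",
    "generate_tsh_cohort",
    "generate_quartile_summaries",
    "default_tsh_params",
    "default_quartile_params",
]

# Calibration anchors for the default TSH cohort (all printed cohort facts):
# n = 51 pairs; central maternal TCDD 18.9 ppt; 5 of 51 above 50 ppt;
# the log-log response crosses 5 uU/mL at 235 ppt and 10 uU/mL at 1513.56
# ppt; the inverse-prediction interval at 10 uU/mL spans a factor of ten
# below its point estimate.
_N_DEFAULT = 51
_MEDIAN_PPT = 18.9
_TAIL_CUTOFF_PPT = 50.0
_TAIL_COUNT = 5
_CROSS_5 = 235.0
_CROSS_10 = 1513.56

_SLOPE = math.log(10.0 / 5.0) / math.log(_CROSS_10 / _CROSS_5)
_INTERCEPT = math.log(5.0) - _SLOPE * math.log(_CROSS_5)
_EXPOSURE_LOG_MEAN = math.log(_MEDIAN_PPT)
_EXPOSURE_LOG_SD = (math.log(_TAIL_CUTOFF_PPT) - _EXPOSURE_LOG_MEAN) / float(
    stats.norm.ppf(1.0 - _TAIL_COUNT / _N_DEFAULT)
)


def _calibrated_noise_log_sd() -> float:
    """Residual log-SD such that the approx-SE inverse-prediction interval
    at the 10 uU/mL threshold spans a factor of ten below the point
    estimate, at the default design (n, exposure spread, slope)."""
    n = _N_DEFAULT
    sxx = (n - 1) * _EXPOSURE_LOG_SD**2
    ybar = _INTERCEPT + _SLOPE * _EXPOSURE_LOG_MEAN
    tcrit = float(stats.t.ppf(0.975, df=n - 2))
    geom = math.sqrt(1.0 / n + (math.log(10.0) - ybar) ** 2 / (_SLOPE**2 * sxx))
    target_half = math.log(10.0)  # point / lower bound = 10
    return target_half * abs(_SLOPE) / (tcrit * geom)


_NOISE_LOG_SD = _calibrated_noise_log_sd()


@dataclass(frozen=True)
class TshCohortParams:
    """Generating parameters of the synthetic mother–infant TSH cohort."""

    n: int = _N_DEFAULT
    exposure_log_mean: float = _EXPOSURE_LOG_MEAN
    exposure_log_sd: float = _EXPOSURE_LOG_SD
    intercept: float = _INTERCEPT
    slope: float = _SLOPE
    noise_log_sd: float = _NOISE_LOG_SD
    metric: Metric = Metric.TCDD
    seed: int = 0
    #: mixture weight of a heavier second exposure component (robustness runs)
    heavy_tail_weight: float = 0.0
    heavy_tail_log_sd_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.noise_log_sd < 0 or self.exposure_log_sd <= 0:
            raise ValueError("spreads must be positive (noise may be zero)")
        if not 0.0 <= self.heavy_tail_weight < 1.0:
            raise ValueError("heavy_tail_weight must lie in [0, 1)")

    @property
    def high_tail_count(self) -> float:
        """Expected number of exposures above the 50-ppt cutoff (lognormal
        survival function)."""
        z = (math.log(_TAIL_CUTOFF_PPT) - self.exposure_log_mean) / self.exposure_log_sd
        return self.n * float(stats.norm.sf(z))


def generate_tsh_cohort(
    params: TshCohortParams, seed: Optional[int] = None
) -> Tuple[CohortPairs, Dict[str, float]]:
    """Draw a synthetic cohort: lognormal exposures, log-log TSH response.

    TSH_i = exp(intercept + slope·log(serum_i) + Normal(0, noise_log_sd)).
    Returns the pairs and a truth sidecar with every generating parameter.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    log_sd = np.full(params.n, params.exposure_log_sd)
    if params.heavy_tail_weight > 0:
        heavy = rng.random(params.n) < params.heavy_tail_weight
        log_sd = np.where(heavy, params.exposure_log_sd * params.heavy_tail_log_sd_factor, log_sd)
    serum = np.exp(rng.normal(params.exposure_log_mean, log_sd))
    noise = rng.normal(0.0, params.noise_log_sd, size=params.n) if params.noise_log_sd > 0 else 0.0
    tsh = np.exp(params.intercept + params.slope * np.log(serum) + noise)
    truth = {k: (v.value if isinstance(v, Metric) else v) for k, v in asdict(params).items()}
    truth["expected_high_tail_count"] = params.high_tail_count
    return CohortPairs(serum=serum, tsh=tsh, metric=params.metric), truth


def default_tsh_params(metric: Metric = Metric.TCDD, teq_ratio: float = 485.0 / 235.0,
                       seed: int = 0) -> TshCohortParams:
    """Default cohort parameters; the TEQ variant scales every exposure by
    the TEQ/TCDD ratio at the POD (485/235), shifting the 5 uU/mL crossing
    from 235 ppt TCDD to 485 ppt TEQ while leaving the response unchanged."""
    metric = Metric(metric)
    if metric is Metric.TCDD:
        return TshCohortParams(metric=metric, seed=seed)
    shift = math.log(teq_ratio)
    return TshCohortParams(
        metric=metric,
        seed=seed,
        exposure_log_mean=_EXPOSURE_LOG_MEAN + shift,
        intercept=_INTERCEPT - _SLOPE * shift,
    )


def population_fit(params: TshCohortParams) -> "CalibrationFit":
    """The calibration fit implied by the generating model itself.

    Sufficient statistics are set to their expected values (slope and
    intercept at truth, residual SE at the noise SD, Sxx at (n−1)·σx²), so
    the fit represents the design of the cohort rather than one sampled
    replicate.  This is the fixed reference regression the scenario grid is
    evaluated on; per-replicate fits from :func:`generate_tsh_cohort` +
    ``fit_loglog`` are used for the sampling-variability studies.
    """
    from .calibration import CalibrationFit

    sxx = (params.n - 1) * params.exposure_log_sd**2
    ybar = params.intercept + params.slope * params.exposure_log_mean
    return CalibrationFit(
        slope=params.slope,
        intercept=params.intercept,
        residual_se=params.noise_log_sd,
        n=params.n,
        xbar_log=params.exposure_log_mean,
        ybar_log=ybar,
        sxx_log=sxx,
        metric=params.metric,
    )


@dataclass(frozen=True)
class GroupParams:
    """One dose group of the quartile generator."""

    label: str
    n: int
    mean: float
    sd: float
    dose_ppt: Optional[float] = None


def default_quartile_params(seed: int = 0, effect_pattern: str = "q4_only") -> "QuartileSummaryParams":
    return QuartileSummaryParams(seed=seed, effect_pattern=effect_pattern)


@dataclass(frozen=True)
class QuartileSummaryParams:
    """Generating parameters of the quartiled sperm-concentration data.

    Defaults emulate the sperm-endpoint cohort: control mean 72.5
    million/mL, a cohort-level depression toward 53.6 million/mL carried by
    the top quartile, quartile median doses 68/135/345/733 ppt (the second
    quartile's median is not published; 135 ppt is a synthetic geometric
    interpolation).  Group sizes are realistic choices, not published.
    """

    control: GroupParams = field(
        default_factory=lambda: GroupParams("control", 184, 72.5, 36.0)
    )
    quartiles: Tuple[GroupParams, ...] = field(
        default_factory=lambda: (
            GroupParams("Q1", 34, 71.0, 35.0, 68.0),
            GroupParams("Q2", 34, 69.0, 35.0, 135.0),
            GroupParams("Q3", 34, 67.0, 35.0, 345.0),
            GroupParams("Q4", 34, 54.0, 35.0, 733.0),
        )
    )
    effect_pattern: str = "q4_only"  # "q4_only" | "null"
    seed: int = 0

    def __post_init__(self) -> None:
        doses = [q.dose_ppt for q in self.quartiles]
        if any(d is None for d in doses) or any(
            b <= a for a, b in zip(doses, doses[1:])
        ):
            raise ValueError("quartile doses must be strictly increasing")
        if self.effect_pattern not in ("q4_only", "null"):
            raise ValueError(f"unknown effect pattern {self.effect_pattern!r}")


def generate_quartile_summaries(
    params: QuartileSummaryParams, seed: Optional[int] = None
) -> Tuple[List[GroupSummary], Dict[str, np.ndarray]]:
    """Draw raw per-group samples and summarise them as (mean, 95% CI).

    Summaries are computed *from the draws*, so summary-based tests can be
    validated against raw-data tests on the same data.  Under the "null"
    pattern every group shares the control mean.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    raw: Dict[str, np.ndarray] = {}
    summaries: List[GroupSummary] = []
    groups = [params.control, *params.quartiles]
    for g in groups:
        mean = params.control.mean if (params.effect_pattern == "null" and g.label != "control") else g.mean
        draws = rng.normal(mean, g.sd, size=g.n)
        raw[g.label] = draws
        m = float(draws.mean())
        se = float(draws.std(ddof=1)) / math.sqrt(g.n)
        half = float(stats.t.ppf(0.975, df=g.n - 1)) * se
        summaries.append(
            GroupSummary(
                label=g.label,
                n=g.n,
                mean=m,
                ci_low=m - half,
                ci_high=m + half,
                dose=SerumConcentration(g.dose_ppt, Metric.TCDD) if g.dose_ppt else None,
            )
        )
    return summaries, raw
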