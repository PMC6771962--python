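"""Induced-prior RfD distributions from lognormal uncertainty factors.

Instead of dividing a point POD by fixed UFs, the POD and each UF are
treated as lognormal random variables; the RfD they imply,

    RfD = POD / ∏ UF_i,

is then itself lognormal (logs subtract, log-variances add), giving a full
distribution of plausible reference doses — an *induced prior*, since no
data updating is involved.  The 2.5th percentile of that distribution is a
conservative lower-bound RfD; the percentile at which a fixed reference RfD
sits measures how conservative that reference is.

The closed lognormal form is carried alongside Monte Carlo samples whenever
every input is lognormal or a point mass: extreme tail placements (1e-30)
are only resolvable analytically, far below Monte Carlo resolution.

UF prior convention (``p95_nominal``, the half-log convention from the
probabilistic-UF literature): the nominal UF sits at the 95th percentile
and the median is √nominal, so log_sd = ln(√nominal)/z_0.95.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationFit, CiKind, InversePrediction, inverse_predict
from .rfd_core import (
    Classification,
    Metric,
    SerumIntakeAnchor,
    UncertaintyFactorSpec,
)

__all__ = [
    "LognormalSpec",
    "PodDistribution",
    "RfdDistribution",
    "uf_prior",
    "induced_rfd",
    "lower_bound",
    "percentile_of",
    "scenario_grid",
]

Z95 = float(stats.norm.ppf(0.95))
Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution on the natural-log scale."""

    log_mean: float
    log_sd: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError("log_sd must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.log_mean)

    def quantile(self, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ValueError("quantile level must be in (0, 1)")
        return math.exp(self.log_mean + stats.norm.ppf(p) * self.log_sd)

    def cdf(self, value: float) -> float:
        if not value > 0:
            raise ValueError("lognormal support is positive")
        return float(stats.norm.cdf((math.log(value) - self.log_mean) / self.log_sd))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.log_mean, self.log_sd, size=n))


MIN_LOG_SD = 1e-9  # degenerate-UF floor (nominal 1): numerically a point mass


def uf_prior(
    nominal: float,
    convention: str = "p95_nominal",
    log_sd: Optional[float] = None,
    log_mean: Optional[float] = None,
    min_log_sd: float = MIN_LOG_SD,
) -> LognormalSpec:
    """Lognormal prior for an uncertainty factor with the given nominal.

    ``p95_nominal`` (default): the nominal is the 95th percentile, the
    median is √nominal.  ``median_nominal``: the nominal is the median and
    ``log_sd`` must be supplied.  ``explicit``: both parameters supplied.
    """
    if nominal < 1:
        raise ValueError(f"UF nominal must be >= 1, got {nominal}")
    if convention == "p95_nominal":
        mu = 0.5 * math.log(nominal)
        sd = (math.log(nominal) - mu) / Z95
        return LognormalSpec(max(mu, 0.0), max(sd, min_log_sd), f"p95_nominal({nominal:g})")
    if convention == "median_nominal":
        if log_sd is None:
            raise ValueError("median_nominal convention requires log_sd")
        return LognormalSpec(
            math.log(nominal), max(log_sd, min_log_sd), f"median_nominal({nominal:g})"
        )
    if convention == "explicit":
        if log_mean is None or log_sd is None:
            raise ValueError("explicit convention requires log_mean and log_sd")
        return LognormalSpec(log_mean, max(log_sd, min_log_sd), "explicit")
    raise ValueError(f"unknown UF prior convention {convention!r}")


@dataclass(frozen=True)
class PodDistribution:
    """A POD as a point mass or lognormal, with its scenario coordinates.

    ``unit`` is ``"ppt"`` for a serum-based POD or ``"pg/kg/day"`` once it
    has been carried through the serum-to-intake anchor (see
    :func:`pod_to_intake`).  The lognormal median equals the deterministic
    POD point estimate.
    """

    form: str  # "point" | "lognormal"
    spec: Union[float, LognormalSpec]
    metric: Metric
    threshold: float
    classification: Classification
    unit: str = "ppt"

    def __post_init__(self) -> None:
        if self.form not in ("point", "lognormal"):
            raise ValueError(f"unknown POD form {self.form!r}")
        if self.form == "point" and not float(self.spec) > 0:
            raise ValueError("point POD must be positive")
        if self.form == "lognormal" and not isinstance(self.spec, LognormalSpec):
            raise TypeError("lognormal POD requires a LognormalSpec")

    @property
    def log_mean(self) -> float:
        return math.log(self.spec) if self.form == "point" else self.spec.log_mean

    @property
    def log_sd(self) -> float:
        return 0.0 if self.form == "point" else self.spec.log_sd

    @property
    def median(self) -> float:
        return math.exp(self.log_mean)

    @classmethod
    def from_inverse_prediction(
        cls,
        pred: InversePrediction,
        metric: Metric,
        classification: Classification,
    ) -> "PodDistribution":
        """Lognormal POD with median at the inverse-prediction point and
        log_sd from the CI half-width on the log scale divided by z_0.975.

        Requires a bounded (interval-kind) prediction; the log-symmetric
        approx-SE interval always qualifies.
        """
        if pred.kind is not CiKind.INTERVAL or not math.isfinite(pred.ci_high):
            raise ValueError(
                "POD spread needs a bounded interval; use the approx_se method"
            )
        half = 0.5 * (math.log(pred.ci_high) - math.log(pred.ci_low))
        spec = LognormalSpec(
            math.log(pred.point),
            max(half / Z975, MIN_LOG_SD),
            provenance=f"inverse prediction CI at TSH {pred.threshold:g}",
        )
        return cls(
            form="lognormal",
            spec=spec,
            metric=metric,
            threshold=pred.threshold,
            classification=classification,
        )


def pod_to_intake(pod: PodDistribution, anchor: SerumIntakeAnchor) -> PodDistribution:
    """Carry a serum-based POD distribution through the anchored linear
    serum-to-intake scaling, yielding a POD in pg/kg/day.

    The scaling is multiplicative, so on the log scale it shifts the
    location by log(intake-per-ppt) and leaves the spread unchanged.  The
    same anchor ratio is applied to either metric: the anchor defines
    intake-per-ppt of lipid-adjusted serum.
    """
    if pod.unit != "ppt":
        raise ValueError("POD is already on the intake scale")
    k = anchor.intake.pg_per_kg_day / anchor.serum.value  # pg/kg/day per ppt
    shift = math.log(k)
    if pod.form == "point":
        spec: Union[float, LognormalSpec] = float(pod.spec) * k
    else:
        spec = LognormalSpec(
            pod.spec.log_mean + shift, pod.spec.log_sd, pod.spec.provenance
        )
    return PodDistribution(
        form=pod.form,
        spec=spec,
        metric=pod.metric,
        threshold=pod.threshold,
        classification=pod.classification,
        unit="pg/kg/day",
    )


@dataclass(frozen=True)
class RfdDistribution:
    """An induced RfD distribution: Monte Carlo samples in pg/kg/day plus,
    when every input admits it, the closed lognormal form."""

    samples: np.ndarray
    closed_form: Optional[LognormalSpec]
    scenario: Mapping[str, object]
    seed: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise ValueError("empty sample array")
        if not np.all(samples > 0):
            raise ValueError("RfD samples must be positive")


def _uf_log_params(uf: UncertaintyFactorSpec) -> Tuple[float, float]:
    if uf.distribution is not None:
        d = uf.distribution
        return float(d.log_mean), float(d.log_sd)
    return math.log(uf.nominal), 0.0


def induced_rfd(
    pod: PodDistribution,
    ufs: Sequence[UncertaintyFactorSpec],
    n_samples: int = 100_000,
    seed: Optional[int] = None,
    scenario: Optional[Mapping[str, object]] = None,
) -> RfdDistribution:
    """Monte Carlo induced RfD distribution: POD / ∏ UF, in pg/kg/day.

    The POD must already be on the intake scale (see :func:`pod_to_intake`).
    A seed is mandatory — reproducibility is part of the contract.  UFs are
    drawn independently; applying them sequentially or as one composite
    product draw is equivalent because their logs add.
    """
    if seed is None:
        raise ValueError("a seed is required for induced_rfd")
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10,000")
    if pod.unit != "pg/kg/day":
        raise ValueError("convert the POD to the intake scale first (pod_to_intake)")

    log_mu = pod.log_mean
    log_var = pod.log_sd**2
    for uf in ufs:
        mu_i, sd_i = _uf_log_params(uf)
        log_mu -= mu_i
        log_var += sd_i**2
    log_sd = math.sqrt(log_var)

    rng = np.random.default_rng(seed)
    if log_sd > 0:
        samples = np.exp(rng.normal(log_mu, log_sd, size=n_samples))
        closed = LognormalSpec(log_mu, log_sd, provenance="product of lognormals")
    else:
        samples = np.full(n_samples, math.exp(log_mu))
        closed = None  # degenerate point mass: no proper lognormal form
    scen = dict(scenario) if scenario is not None else {
        "metric": pod.metric.value,
        "threshold": pod.threshold,
        "classification": pod.classification.value,
    }
    return RfdDistribution(samples=samples, closed_form=closed, scenario=scen, seed=int(seed))


def lower_bound(dist: RfdDistribution, p: float = 0.025) -> float:
    """The p-quantile of the RfD distribution — by default the 2.5th
    percentile, the conservative lower-bound RfD."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if dist.closed_form is not None:
        return dist.closed_form.quantile(p)
    return float(np.quantile(dist.samples, p))


def percentile_of(dist: RfdDistribution, value: float) -> float:
    """Percentile (0–100) at which ``value`` sits in the RfD distribution.

    Uses the closed-form lognormal CDF when available, which resolves
    extreme tail placements that no feasible Monte Carlo sample can; the
    empirical CDF fallback is censored (and warns) below 100/n_samples.
    """
    if not value > 0:
        raise ValueError("value must be positive")
    if dist.closed_form is not None:
        return 100.0 * dist.closed_form.cdf(value)
    n = dist.samples.size
    frac = float(np.mean(dist.samples <= value))
    floor = 100.0 / n
    if frac == 0.0:
        warnings.warn(
            f"value below all {n} samples; percentile censored at < {floor:g}",
            stacklevel=2,
        )
        return floor
    return 100.0 * frac


#: composite UF sets by POD classification: a NOAEL needs only the human
#: variability factor (3); a LOAEL additionally needs LOAEL-to-NOAEL
#: extrapolation (10).
DEFAULT_UF_NOMINALS: Dict[Classification, Tuple[Tuple[str, float], ...]] = {
    Classification.NOAEL: (("UF_H", 3.0),),
    Classification.LOAEL: (("UF_L", 10.0), ("UF_H", 3.0)),
}


def _ufs_for(
    classification: Classification, convention: str
) -> List[UncertaintyFactorSpec]:
    return [
        UncertaintyFactorSpec(name, nominal, uf_prior(nominal, convention))
        for name, nominal in DEFAULT_UF_NOMINALS[classification]
    ]


def scenario_grid(
    fits: Mapping[Union[Metric, str], CalibrationFit],
    anchor: SerumIntakeAnchor,
    thresholds: Sequence[float] = (5.0, 10.0),
    classifications: Sequence[Classification] = (Classification.NOAEL, Classification.LOAEL),
    uf_convention: str = "p95_nominal",
    n_samples: int = 100_000,
    seed: int = 0,
    reference_rfd: float = 0.7,
    level: float = 0.95,
) -> Tuple[List[RfdDistribution], pd.DataFrame]:
    """The 2×2×2 scenario grid of induced RfD distributions.

    One distribution per combination of exposure metric (TCDD or TEQ
    calibration fit), TSH threshold (5 or 10 μU/mL) and POD classification
    (NOAEL or LOAEL).  Each scenario reports its 2.5th-percentile lower
    bound and the percentile of the reference RfD (default 0.7 pg/kg/day).
    Per-scenario seeds are spawned deterministically from ``seed``; the
    summary table is bit-identical across runs with the same seed.
    """
    fits = {Metric(k): v for k, v in fits.items()}
    scen_keys = [
        (metric, float(th), Classification(cl))
        for metric in sorted(fits, key=lambda m: m.value)
        for th in thresholds
        for cl in classifications
    ]
    if len(set(scen_keys)) != len(scen_keys):
        raise ValueError("duplicate scenario keys in the grid")

    child_seeds = np.random.SeedSequence(seed).generate_state(len(scen_keys)) % (2**31)
    dists: List[RfdDistribution] = []
    rows = []
    for (metric, th, cl), child in zip(scen_keys, child_seeds):
        pred = inverse_predict(fits[metric], th, level=level, method="approx_se")
        pod = PodDistribution.from_inverse_prediction(pred, metric, cl)
        pod_intake = pod_to_intake(pod, anchor)
        ufs = _ufs_for(cl, uf_convention)
        scen = {
            "metric": metric.value,
            "threshold": th,
            "classification": cl.value,
            "uf_convention": uf_convention,
        }
        dist = induced_rfd(pod_intake, ufs, n_samples=n_samples, seed=int(child), scenario=scen)
        dists.append(dist)
        rows.append(
            {
                "metric": metric.value,
                "threshold_tsh_uU_mL": th,
                "classification": cl.value,
                "pod_serum_ppt": pod.median,
                "pod_intake_pg_kg_day": pod_intake.median,
                "composite_uf_nominal": float(
                    np.prod([nom for _, nom in DEFAULT_UF_NOMINALS[cl]])
                ),
                "rfd_p2.5_pg_kg_day": lower_bound(dist, 0.025),
                "rfd_p50_pg_kg_day": lower_bound(dist, 0.5),
                "rfd_p97.5_pg_kg_day": lower_bound(dist, 0.975),
                "percentile_of_reference": percentile_of(dist, reference_rfd),
                "uf_convention": uf_convention,
                "seed": int(child),
            }
        )
    table = pd.DataFrame(rows)
    return dists, table
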