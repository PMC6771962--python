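"""Significance screening from published group summaries and NOAEL/LOAEL calls.

Dose-group re-analysis frequently has to work from what a publication
prints: group sizes, means and 95% confidence intervals (or SDs).  This
module recovers standard errors from symmetric confidence intervals,
runs two-sample tests (Welch by default, pooled optionally) directly from
those summaries, and classifies an ordered series of dose groups into a
NOAEL (highest non-significant dose) and LOAEL (lowest significant dose).

Non-monotone significance patterns (a significant group below a
non-significant one) are reported, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .rfd_core import SerumConcentration

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "se_from_ci",
    "welch_test_from_summaries",
    "adjust_comparisons",
    "classify_noael_loael",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published summary for one dose group.

    Dispersion comes either from a 95% CI of the mean (``ci_low``/``ci_high``,
    assumed symmetric on the reported scale) or directly from ``sd``.
    ``dose`` is the group's median serum concentration; the control group
    may omit it.
    """

    label: str
    n: int
    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    sd: Optional[float] = None
    dose: Optional[SerumConcentration] = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.mean <= self.ci_high):
                raise ValueError(
                    f"group {self.label!r}: mean must lie inside its confidence interval"
                )
        elif self.sd is None:
            raise ValueError(
                f"group {self.label!r}: supply either a CI (ci_low, ci_high) or sd"
            )

    @property
    def se(self) -> float:
        """Standard error of the mean, recovered from the CI or SD."""
        if self.sd is not None:
            return self.sd / np.sqrt(self.n)
        return se_from_ci(self.mean, self.ci_low, self.ci_high, self.n, self.ci_level)


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing one dose group against the control."""

    group: str
    statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float
    dose: Optional[SerumConcentration] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def se_from_ci(
    mean: float, ci_low: float, ci_high: float, n: int, level: float = 0.95
) -> float:
    """Standard error implied by a symmetric t-based confidence interval.

    SE = (ci_high − ci_low) / (2 · t_{1−α/2, n−1}).  A degenerate CI
    (ci_low == ci_high) gives SE 0; an inverted CI is rejected.
    """
    if ci_low > ci_high:
        raise ValueError("inverted confidence interval")
    if n < 2:
        raise ValueError("n must be >= 2")
    halfwidth = (ci_high - ci_low) / 2.0
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return halfwidth / tcrit


def welch_test_from_summaries(
    g1: GroupSummary,
    g2: GroupSummary,
    alpha: float = 0.05,
    test: Literal["welch", "pooled"] = "welch",
) -> GroupComparison:
    """Two-sided two-sample t-test computed from group summaries.

    Welch (unequal variances, Welch–Satterthwaite df) by default; the
    pooled-variance variant is available for sensitivity.  Identical to a
    raw-data test when the summaries were computed from the raw samples.
    The returned comparison is labelled and dosed by ``g1``.
    """
    se1, se2 = g1.se, g2.se
    if se1 == 0 and se2 == 0 and g1.mean == g2.mean:
        t_stat, df, p = 0.0, float(g1.n + g2.n - 2), 1.0
    elif test == "welch":
        v1, v2 = se1**2, se2**2
        denom = np.sqrt(v1 + v2)
        t_stat = (g1.mean - g2.mean) / denom
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    elif test == "pooled":
        sd1, sd2 = se1 * np.sqrt(g1.n), se2 * np.sqrt(g2.n)
        df = float(g1.n + g2.n - 2)
        sp2 = ((g1.n - 1) * sd1**2 + (g2.n - 1) * sd2**2) / df
        t_stat = (g1.mean - g2.mean) / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    else:
        raise ValueError(f"unknown test family {test!r}")
    p = min(float(p), 1.0)
    return GroupComparison(
        group=g1.label,
        statistic=float(t_stat),
        df=float(df),
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        dose=g1.dose,
    )


def adjust_comparisons(
    comparisons: Sequence[GroupComparison],
    method: Literal["bonferroni", "holm"] = "holm",
    alpha: float = 0.05,
) -> List[GroupComparison]:
    """Multiple-testing adjustment across a family of group comparisons.

    Per-group conclusions are unadjusted by default in this package;
    Bonferroni or Holm control of the familywise error rate is applied here
    when requested.  Returns new comparisons with adjusted p-values and
    significance flags.
    """
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(
        [c.p_value for c in comparisons], alpha=alpha, method=method
    )
    return [
        GroupComparison(
            group=c.group,
            statistic=c.statistic,
            df=c.df,
            p_value=float(p),
            significant=bool(r),
            alpha=alpha,
            dose=c.dose,
        )
        for c, p, r in zip(comparisons, p_adj, reject)
    ]


@dataclass(frozen=True)
class NoaelLoael:
    """NOAEL/LOAEL classification of an ordered dose series."""

    noael: Optional[SerumConcentration]
    loael: Optional[SerumConcentration]
    monotone: bool


def classify_noael_loael(groups: Sequence[GroupComparison]) -> NoaelLoael:
    """Classify dose groups into NOAEL and LOAEL by significance.

    ``groups`` must be sorted by strictly ascending dose and each must carry
    one.  LOAEL = lowest significant dose; NOAEL = highest non-significant
    dose strictly below the LOAEL (or the top dose when nothing is
    significant).  A significant group below a non-significant one is
    flagged ``monotone=False`` in the result, not repaired.
    """
    if not groups:
        raise ValueError("no groups to classify")
    doses: List[float] = []
    for g in groups:
        if g.dose is None:
            raise ValueError(f"group {g.group!r} carries no dose")
        doses.append(g.dose.value)
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("groups must be sorted by strictly ascending dose")

    sig_flags = [g.significant for g in groups]
    loael_idx = next((i for i, s in enumerate(sig_flags) if s), None)
    if loael_idx is None:
        return NoaelLoael(noael=groups[-1].dose, loael=None, monotone=True)
    loael = groups[loael_idx].dose
    noael = groups[loael_idx - 1].dose if loael_idx > 0 else None
    # non-monotone: any non-significant group above the lowest significant one
    monotone = all(sig_flags[loael_idx:])
    return NoaelLoael(noael=noael, loael=loael, monotone=monotone)
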