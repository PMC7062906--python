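"""Method-agreement and group-comparison statistics.

Implements the study's statistical protocol for comparing two
quantification procedures and two participant groups:

* paired agreement — mean and SD of the paired differences with
  Bland–Altman limits at mean ± 2 SD, Pearson correlation, paired t-test;
* Cohen's d from group summaries with the equal-weight pooled SD
  sqrt((sd1² + sd2²)/2);
* normality-gated two-group comparison — Shapiro–Wilk on each group, then
  an equal-variance t-test if both pass, otherwise the two-sided
  Mann–Whitney test;
* a normal-approximation sample-size formula for a two-sample comparison.

The difference sign convention is first argument minus second throughout
(e.g. T1 − IDEAL).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedEffectError, ValidationError

__all__ = [
    "AgreementReport",
    "GroupComparison",
    "MethodAgreement",
    "agreement",
    "cohens_d",
    "group_compare",
    "sample_size_per_group",
]


@dataclass(frozen=True)
class AgreementReport:
    """Paired-difference summary between two methods (x − y).

    ``loa_low``/``loa_high`` are the Bland–Altman limits of agreement at
    mean_diff ∓ 2·sd_diff.  ``pearson_r`` is NaN (with a warning at
    construction time) when either input has zero variance.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pearson_p: float
    paired_t: float
    paired_p: float
    labels: tuple[str, str] = ("x", "y")

    def summary(self) -> str:
        a, b = self.labels
        return "\n".join([
            f"Method agreement: {a} vs {b}  (differences are {a} - {b})",
            "=" * 52,
            f"n pairs                  {self.n}",
            f"mean difference          {self.mean_diff: .4f}",
            f"SD of difference         {self.sd_diff: .4f}",
            f"limits of agreement      ({self.loa_low: .4f}, {self.loa_high: .4f})"
            "   [mean +/- 2 SD]",
            f"Pearson r                {self.pearson_r: .4f}   (p = {self.pearson_p:.4g})",
            f"paired t                 {self.paired_t: .4f}   (p = {self.paired_p:.4g})",
        ])

    def plot_bland_altman(self, ax=None):
        """Bland–Altman plot: per-pair mean vs difference with the mean
        difference and ± 2 SD limits as horizontal lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self._means, self._diffs, s=18, color="k")
        ax.axhline(self.mean_diff, color="k")
        ax.axhline(self.loa_low, color="k", linestyle=":")
        ax.axhline(self.loa_high, color="k", linestyle=":")
        a, b = self.labels
        ax.set_xlabel(f"mean of {a} and {b}")
        ax.set_ylabel(f"{a} - {b}")
        return ax

    # stashed by the constructor for plotting; not part of the report proper
    _means: np.ndarray = field(default=None, repr=False, compare=False)
    _diffs: np.ndarray = field(default=None, repr=False, compare=False)


class MethodAgreement:
    """Model-style wrapper around :func:`agreement`.

    >>> rep = MethodAgreement(bmfv_t1, bmfv_ideal, labels=("T1", "IDEAL")).fit()
    >>> print(rep.summary())
    """

    def __init__(self, x, y, labels: tuple[str, str] = ("x", "y")) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.labels = labels

    def fit(self) -> AgreementReport:
        return agreement(self.x, self.y, labels=self.labels)


def agreement(x, y, labels: tuple[str, str] = ("x", "y")) -> AgreementReport:
    """Paired agreement statistics between two measurement vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValidationError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")

    diffs = x - y
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))

    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in one input; Pearson r undefined",
                      stacklevel=2)
        r, rp = math.nan, math.nan
    else:
        r, rp = stats.pearsonr(x, y)

    if sd_diff == 0:
        t, tp = (math.nan, math.nan) if mean_diff == 0 else (math.inf, 0.0)
    else:
        t, tp = stats.ttest_rel(x, y)

    rep = AgreementReport(
        n=int(x.size), mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - 2.0 * sd_diff, loa_high=mean_diff + 2.0 * sd_diff,
        pearson_r=float(r), pearson_p=float(rp),
        paired_t=float(t), paired_p=float(tp), labels=labels,
    )
    object.__setattr__(rep, "_means", (x + y) / 2.0)
    object.__setattr__(rep, "_diffs", diffs)
    return rep


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d (magnitude) from group summaries.

    Uses the equal-weight pooled SD sqrt((sd1² + sd2²)/2), which coincides
    with the (n−1)-weighted pooled SD for equal group sizes.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be >= 0")
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise UndefinedEffectError("both group SDs are zero")
    return abs(mean1 - mean2) / pooled


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison with a normality-gated test choice."""

    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    d: float
    test_used: str          # "t" | "Mann-Whitney"
    statistic: float
    p: float

    def summary(self) -> str:
        return "\n".join([
            "Group comparison",
            "=" * 40,
            f"group 1   n={self.n1:<4d} mean={self.mean1:.4g} sd={self.sd1:.4g}",
            f"group 2   n={self.n2:<4d} mean={self.mean2:.4g} sd={self.sd2:.4g}",
            f"Cohen's d                {self.d:.3f}",
            f"test                     {self.test_used}",
            f"statistic                {self.statistic:.4f}",
            f"p (two-sided)            {self.p:.4g}",
        ])


def _normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        warnings.warn("constant group: normality test undefined, using "
                      "Mann-Whitney", stacklevel=3)
        return False
    return stats.shapiro(sample).pvalue > alpha


def group_compare(group1, group2, alpha_norm: float = 0.05) -> GroupComparison:
    """Compare two independent groups as the study protocol prescribes.

    Shapiro–Wilk is applied to each group at ``alpha_norm``; if both pass,
    the equal-variance two-sided t-test is used, otherwise the two-sided
    Mann–Whitney test (normal approximation with tie correction for
    n >= 8, exact otherwise).  Cohen's d is always reported from the
    sample summaries.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValidationError("each group needs at least 3 values")

    m1, s1 = float(g1.mean()), float(g1.std(ddof=1))
    m2, s2 = float(g2.mean()), float(g2.std(ddof=1))
    d = cohens_d(m1, s1, g1.size, m2, s2, g2.size) if (s1 or s2) else 0.0

    if _normal(g1, alpha_norm) and _normal(g2, alpha_norm):
        res = stats.ttest_ind(g1, g2, equal_var=True)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([g1, g2])
        if np.ptp(pooled) == 0:
            # every observation tied: no evidence of a shift by convention
            test, statistic, p = "Mann-Whitney", g1.size * g2.size / 2.0, 1.0
        else:
            method = ("asymptotic" if min(g1.size, g2.size) >= 8
                      else "auto")
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                     method=method)
            test, statistic, p = ("Mann-Whitney", float(res.statistic),
                                  float(min(res.pvalue, 1.0)))
    return GroupComparison(n1=int(g1.size), n2=int(g2.size),
                           mean1=m1, sd1=s1, mean2=m2, sd2=s2, d=d,
                           test_used=test, statistic=statistic, p=p)


def sample_size_per_group(d: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Per-group n for a two-sided two-sample comparison at effect size d.

    Normal approximation: n = ceil(2 · (z_{1−α/2} + z_{power})² / d²).
    """
    if d <= 0:
        raise ValidationError("effect size d must be > 0 (d = 0 needs infinite n)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return math.ceil(2.0 * (z_a + z_b) ** 2 / d**2)
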