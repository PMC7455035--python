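"""Group statistics for capillary and behavioral data.

The battery follows common practice in small-n in-vivo studies:

* two-group comparisons are gated by the Shapiro-Wilk normality test —
  unpaired t-test when both groups look normal, Mann-Whitney otherwise;
* per-vessel measurements (speed, diameter) are compared with a nested
  ANOVA in which vessels are nested within mice, so the group effect is
  tested against between-mouse variability rather than treating vessels
  as independent;
* associations are summarized by the Pearson product-moment correlation
  with its least-squares line;
* null results are accompanied by a post-hoc sensitivity analysis: the
  minimum detectable difference in proportions (two-proportion z
  approximation) or in means (noncentral-t power inversion) at alpha =
  0.05 and power = 0.80;
* behavioral indices: object-replacement preference score and Y-maze
  spontaneous alternation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "GroupSample",
    "GroupStatsResult",
    "CorrelationResult",
    "compare_groups",
    "nested_anova",
    "pearson_correlation",
    "min_detectable_proportion_diff",
    "min_detectable_mean_shift",
    "preference_score",
    "spontaneous_alternation",
]


@dataclass
class GroupSample:
    """One experimental group: one value per unit (mouse), with optional
    per-vessel nested measurements keyed by unit."""

    label: str
    values: np.ndarray
    units: np.ndarray | None = None  # unit (mouse) id per value, for nesting

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a group needs at least one value")
        if self.units is not None:
            self.units = np.asarray(self.units)
            if self.units.shape != self.values.shape:
                raise ValueError("units must align one-to-one with values")


@dataclass
class GroupStatsResult:
    """Outcome of a two-group comparison with full provenance."""

    test_used: str  # "t-test" | "mann-whitney" | "nested-anova"
    statistic: float
    p_value: float
    normality_p: dict = field(default_factory=dict)
    effect: float = math.nan  # group difference estimate
    effect_ci: tuple[float, float] | None = None
    min_detectable_effect: float | None = None
    alpha: float = 0.05
    power: float = 0.80
    df: tuple | None = None


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


# --------------------------------------------------------------------------
# gated two-group comparison
# --------------------------------------------------------------------------

def compare_groups(a: GroupSample, b: GroupSample, alpha: float = 0.05,
                   sensitivity: bool = True) -> GroupStatsResult:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups are tested for normality; if both pass at ``alpha`` the
    comparison is an unpaired two-sided t-test, otherwise a two-sided
    Mann-Whitney test (exact p for small samples without ties).  The
    result records the gate outcome, the mean-difference estimate with a
    95% t-interval, and the minimum detectable mean shift at (alpha,
    power=0.80) given the realized pooled variance.
    """
    x, y = a.values, b.values
    if len(x) < 3 or len(y) < 3:
        raise ValueError("normality gate requires n >= 3 per group")
    sw_a = stats.shapiro(x).pvalue
    sw_b = stats.shapiro(y).pvalue
    normal = sw_a >= alpha and sw_b >= alpha

    diff = float(x.mean() - y.mean())
    n1, n2 = len(x), len(y)
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dof
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(0.975, dof)
    ci = (diff - tcrit * se, diff + tcrit * se)

    if normal:
        res = stats.ttest_ind(x, y, equal_var=True)
        test_used = "t-test"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test_used = "mann-whitney"

    mde = None
    if sensitivity and sp2 > 0:
        mde = min_detectable_mean_shift(n1, n2, math.sqrt(sp2), alpha=alpha)
    return GroupStatsResult(
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p={a.label: float(sw_a), b.label: float(sw_b)},
        effect=diff,
        effect_ci=ci,
        min_detectable_effect=mde,
        alpha=alpha,
        df=(dof,),
    )


# --------------------------------------------------------------------------
# nested ANOVA (vessels within mice)
# --------------------------------------------------------------------------

def nested_anova(data: pd.DataFrame, value: str = "value",
                 group: str = "group", unit: str = "mouse") -> GroupStatsResult:
    """Hierarchical ANOVA with units (mice) nested within groups.

    The group effect is tested against the mouse-within-group mean square
    (F = MS_group / MS_mouse(group)), never against the per-vessel
    residual, so vessels are not treated as independent units.  In the
    balanced case with per-mouse means this reduces to the mouse-level
    t-test (F = t²).
    """
    df = data[[group, unit, value]].dropna()
    groups = df[group].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if df.loc[df[group] == g, unit].nunique() < 2:
            raise ValueError(
                f"group {g!r} has a single unit; the group effect is not "
                "separable from the unit effect"
            )
    counts = df.groupby([group, unit], observed=True)[value].count()
    if (counts < 2).any():
        warnings.warn("some units contribute a single measurement")

    grand = df[value].mean()
    g_stats = df.groupby(group, observed=True)[value].agg(["mean", "count"])
    ss_group = float((g_stats["count"] * (g_stats["mean"] - grand) ** 2).sum())
    u_stats = df.groupby([group, unit], observed=True)[value].agg(["mean", "count"])
    g_mean_of_unit = u_stats.join(g_stats["mean"].rename("gmean"), on=group)
    ss_unit = float(
        (g_mean_of_unit["count"]
         * (g_mean_of_unit["mean"] - g_mean_of_unit["gmean"]) ** 2).sum()
    )
    n_units = len(u_stats)
    df_group = len(groups) - 1
    df_unit = n_units - len(groups)
    if df_unit < 1:
        raise ValueError("no degrees of freedom for the unit-within-group stratum")
    ms_group = ss_group / df_group
    ms_unit = ss_unit / df_unit
    if ss_group <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif ms_unit <= 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = ms_group / ms_unit
        p = float(stats.f.sf(f_stat, df_group, df_unit))

    means = df.groupby(group, observed=True)[value].mean()
    effect = float(means.iloc[0] - means.iloc[1]) if len(means) == 2 else math.nan
    return GroupStatsResult(
        test_used="nested-anova",
        statistic=float(f_stat),
        p_value=float(p),
        effect=effect,
        df=(df_group, df_unit),
    )


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with its least-squares line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), r_squared=float(r) ** 2, p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept), n=x.size,
    )


# --------------------------------------------------------------------------
# post-hoc sensitivity (minimum detectable effect)
# --------------------------------------------------------------------------

def _two_proportion_power(p1: float, p0: float, n1: int, n2: int,
                          alpha: float) -> float:
    """Power of the unpooled two-proportion z-test for p1 vs p0 (two-sided,
    both rejection tails, so power -> alpha as p1 -> p0)."""
    se = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
    if se == 0:
        return 1.0
    z_a = stats.norm.ppf(1 - alpha / 2)
    delta = abs(p1 - p0) / se
    return float(stats.norm.cdf(delta - z_a) + stats.norm.cdf(-delta - z_a))


def min_detectable_proportion_diff(n1: int, n2: int, p0: float,
                                   alpha: float = 0.05,
                                   power: float = 0.80,
                                   direction: str = "any") -> float:
    """Smallest |p1 - p0| detectable by a two-proportion z-test.

    Monotone root search from the baseline ``p0``.  ``direction`` selects
    the alternative: "increase", "decrease", or "any" (the smaller
    feasible difference of the two — a decrease is detectable at a
    smaller difference because the binomial variance shrinks with p).
    For rare-event baselines the decrease direction may be infeasible.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("baseline proportion must lie strictly in (0, 1)")
    if not 0.0 < alpha < 1.0 or not alpha < power < 1.0:
        raise ValueError("need 0 < alpha < power < 1")
    if direction not in ("any", "increase", "decrease"):
        raise ValueError("direction must be 'any', 'increase' or 'decrease'")

    candidates = []
    eps = 1e-9
    bounds = {"increase": (1.0 - eps,), "decrease": (eps,),
              "any": (1.0 - eps, eps)}[direction]
    f = lambda p1: _two_proportion_power(p1, p0, n1, n2, alpha) - power
    for bound in bounds:
        if f(bound) < 0:
            continue  # power target unreachable in this direction
        a, b = (p0 + eps, bound) if bound > p0 else (bound, p0 - eps)
        root = optimize.brentq(f, a, b, xtol=1e-10)
        candidates.append(abs(root - p0))
    if not candidates:
        raise ValueError("power target unreachable at these sample sizes")
    return min(candidates)


def min_detectable_mean_shift(n1: int, n2: int, sd: float,
                              alpha: float = 0.05, power: float = 0.80,
                              ref_mean: float | None = None):
    """Smallest mean difference detectable by a two-sample t-test.

    Inversion of the noncentral-t power function at (alpha, power), scaled
    by the pooled sd.  Returns the shift in measurement units, or
    ``(shift, percent_of_reference)`` when ``ref_mean`` is given.
    """
    if sd <= 0:
        raise ValueError("sd must be strictly positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    d = TTestIndPower().solve_power(
        effect_size=None, nobs1=n1, ratio=n2 / n1, alpha=alpha, power=power,
        alternative="two-sided",
    )
    shift = float(d) * sd
    if ref_mean is not None:
        return shift, 100.0 * shift / ref_mean
    return shift


# --------------------------------------------------------------------------
# behavioral indices
# --------------------------------------------------------------------------

def preference_score(t_target: float, t_other: float) -> float:
    """Object-replacement preference: time on the displaced object over
    total exploration time.  0.5 is chance; NaN when nothing was explored."""
    if t_target < 0 or t_other < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_target + t_other
    if total == 0:
        warnings.warn("preference undefined: no exploration time")
        return math.nan
    return t_target / total


def spontaneous_alternation(triads: int, entries: int) -> float:
    """Y-maze spontaneous alternation: alternating triads / (entries - 2).

    The triad count can never exceed entries - 2 (every window of three
    consecutive entries yields at most one alternating triad).  NaN when
    fewer than 3 entries were made.
    """
    if triads < 0 or entries < 0:
        raise ValueError("counts must be non-negative")
    if entries < 3:
        warnings.warn("alternation undefined for fewer than 3 arm entries")
        return math.nan
    if triads > entries - 2:
        raise ValueError("alternating triads cannot exceed entries - 2")
    return triads / (entries - 2)
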