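"""Cohort-level statistics for the pipeline's outcome measures.

Each continuous outcome is compared between groups with an independent
two-sample t-test, falling back to the Mann-Whitney U test when either
sample deviates from normality by Shapiro-Wilk (the gate and its alpha are
configurable and recorded in the result). Associations with the EZ
normalized reflectivity use Spearman rank correlation. No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    effect_direction: int        # sign of (central tendency a - b), or rho
    n: tuple

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise StatsError("p-value outside [0, 1]")


@dataclass
class EyeRecord:
    """One eye's outcome row (the cohort CSV schema)."""

    eye_id: str
    group: str                   # "AMD" | "control"
    ez_norm_whole: float = float("nan")
    ez_norm_drusen_free: float = float("nan")
    ez_norm_drusen: float = float("nan")
    fd_percent_whole: float = float("nan")
    fd_percent_drusen_free: float = float("nan")
    fd_mean_size_whole: float = float("nan")
    fd_mean_size_drusen_free: float = float("nan")
    drusen_area_mm2: float = float("nan")
    drusen_volume_mm3: float = float("nan")


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def compare_groups(values_a, values_b,
                   alpha_normality: float = 0.05) -> StatResult:
    """Two-sided group comparison with a Shapiro-Wilk normality gate.

    If either sample rejects normality at ``alpha_normality`` a two-sided
    Mann-Whitney U test is reported; otherwise an independent-samples
    t-test. Non-finite values are dropped.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 3 or len(b) < 3:
        raise StatsError("each group needs at least 3 finite values")
    normal = True
    for sample in (a, b):
        if np.ptp(sample) == 0:       # Shapiro undefined on constant data
            normal = False
            break
        if sps.shapiro(sample).pvalue < alpha_normality:
            normal = False
            break
    direction = int(np.sign(np.mean(a) - np.mean(b)))
    if normal:
        res = sps.ttest_ind(a, b)
        name = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mannwhitneyu"
        direction = int(np.sign(np.median(a) - np.median(b)))
    return StatResult(test_name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      effect_direction=direction, n=(len(a), len(b)))


def spearman_corr(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p; ties use midranks.

    Pairs with a non-finite member are dropped pairwise; constant inputs
    leave the rank correlation undefined and are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise StatsError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult(test_name="spearman", statistic=float(rho),
                      p_value=float(p),
                      effect_direction=int(np.sign(rho)), n=(len(x),))


def power_two_sample(n_per_group: int, effect_size_d: float,
                     alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    ``effect_size_d`` is Cohen's d; both groups have ``n_per_group``
    observations. At d = 0 the power equals alpha by construction.
    """
    if n_per_group < 2:
        raise StatsError("need n >= 2 per group")
    if effect_size_d < 0:
        raise StatsError("effect size must be non-negative")
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = effect_size_d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(tcrit, df, nc)
                 + sps.nct.cdf(-tcrit, df, nc))
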