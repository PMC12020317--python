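"""Trend and group-comparison statistics for longitudinal implant data.

Chronic-stability questions ("did threshold charge drift over the months?")
are answered by comparing a fitted trend model against a constant model:
ordinary least squares with an F-test for continuous measures, binomial
logistic regression with a likelihood-ratio chi-squared test for
proportions. Group comparisons use rank-based tests (Kruskal-Wallis with a
studentized-range post hoc, Wilcoxon rank-sum / signed-rank), matching the
nonparametric treatment appropriate for small repeated clinical samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    model: str


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    pairwise_p: dict[tuple[int, int], float] = field(default_factory=dict)


def linear_trend_test(x, y) -> TrendResult:
    """OLS fit of y on x with an F-test against the intercept-only model.

    For a single regressor the model F-test is equivalent to the two-sided
    t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; trend undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 F for constant y
        p = float(fit.f_pvalue)
        r2 = float(fit.rsquared)
    if np.isnan(p):  # zero residual variance with zero slope: F = 0/0
        p = 1.0
    return TrendResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2 if not np.isnan(r2) else 0.0,
        p_value=p,
        model="linear_vs_constant",
    )


def logistic_trend_test(x, successes, totals) -> TrendResult:
    """Binomial logistic fit of proportion on time vs a constant model.

    Returns the slope in log-odds per unit time and the likelihood-ratio
    chi-squared p-value (1 df). Complete separation is flagged and handled
    with a ridge-penalized fit.
    """
    x = np.asarray(x, dtype=float)
    succ = np.asarray(successes, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if (tot <= 0).any():
        raise ValueError("totals must be positive")
    endog = np.column_stack([succ, tot - succ])
    X = sm.add_constant(x)
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((len(x), 1)), family=sm.families.Binomial()).fit()
            llf_full, llf_null = full.llf, null.llf
            slope = float(full.params[1])
            # statsmodels warns on any deviance-zero fit; only a diverging
            # slope indicates true separation needing a penalized refit
            separated = (
                any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
                and abs(slope) > 20
            )
            converged = np.isfinite(llf_full) and not separated
        except Exception:
            converged = False
    if not converged:
        warnings.warn("separation detected; using penalized fit", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(endog, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
            slope = float(full.params[1])
            mu = 1 / (1 + np.exp(-(X @ full.params)))
            llf_full = float(np.sum(succ * np.log(mu) + (tot - succ) * np.log1p(-mu)))
            p_null = succ.sum() / tot.sum()
            p_null = min(max(p_null, 1e-12), 1 - 1e-12)
            llf_null = float(np.sum(succ * np.log(p_null) + (tot - succ) * np.log1p(-p_null)))
    lr = max(2 * (llf_full - llf_null), 0.0)
    p = float(sps.chi2.sf(lr, df=1))
    phat = succ.sum() / tot.sum()
    return TrendResult(
        slope=slope,
        intercept=float(full.params[0]),
        r_squared=float(np.clip(1 - llf_full / llf_null if llf_null != 0 else 0.0, 0, 1)),
        p_value=p,
        model="logistic_vs_constant",
    )


def _nemenyi_pairwise(groups) -> dict[tuple[int, int], float]:
    """Rank-based all-pairs post hoc using the studentized range distribution."""
    all_vals = np.concatenate(groups)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    k = len(groups)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        n = len(g)
        mean_ranks.append(ranks[start : start + n].mean())
        sizes.append(n)
        start += n
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(n_total * (n_total + 1) / 12.0 * (1 / sizes[i] + 1 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            out[(i, j)] = float(sps.studentized_range.sf(q, k, np.inf))
    return out


def group_compare(
    groups, paired: bool = False, alternative: str = "two-sided"
) -> GroupComparison:
    """Rank-based comparison dispatching on design.

    Three or more unpaired groups: Kruskal-Wallis with all-pairs
    studentized-range post hoc. Two unpaired groups: Wilcoxon rank-sum.
    Paired (two equal-length samples): Wilcoxon signed-rank.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if paired:
        if len(groups) != 2 or groups[0].size != groups[1].size:
            raise ValueError("paired comparison needs two equal-length samples")
        d = groups[0] - groups[1]
        if np.all(d == 0):
            return GroupComparison(test="wilcoxon_signed_rank", statistic=0.0, p_value=1.0)
        stat, p = sps.wilcoxon(groups[0], groups[1], alternative=alternative)
        return GroupComparison(test="wilcoxon_signed_rank", statistic=float(stat), p_value=float(p))
    if len(groups) == 2:
        stat, p = sps.ranksums(groups[0], groups[1], alternative=alternative)
        return GroupComparison(test="wilcoxon_rank_sum", statistic=float(stat), p_value=float(p))
    stat, p = sps.kruskal(*groups)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        pairwise_p=_nemenyi_pairwise(groups),
    )


@dataclass
class AmulaRecord:
    """Task x repetition score grid (0-4 scale) for one test condition.

    Repetitions in which the prosthesis malfunctioned are entered as NaN and
    dropped before aggregation.
    """

    task_scores: np.ndarray
    condition: str = "no_stim"
    mdc: float = 4.4

    def __post_init__(self) -> None:
        self.task_scores = np.atleast_2d(np.asarray(self.task_scores, dtype=float))
        valid = self.task_scores[~np.isnan(self.task_scores)]
        if ((valid < 0) | (valid > 4)).any():
            raise ValueError("scores must lie in [0, 4]")


def amula_summary(record: AmulaRecord) -> float:
    """Summary score: 10 x mean over tasks of the per-task repetition mean.

    Tasks with no surviving repetitions are dropped with a warning.
    """
    scores = record.task_scores
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        task_means = np.nanmean(scores, axis=1)
    keep = ~np.isnan(task_means)
    if not keep.any():
        raise ValueError("no tasks with surviving repetitions")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} task(s) with no repetitions", stacklevel=2)
    return float(10.0 * task_means[keep].mean())


def amula_difference(a: AmulaRecord, b: AmulaRecord) -> dict:
    """Condition difference judged against the minimum detectable change."""
    da, db = amula_summary(a), amula_summary(b)
    diff = da - db
    return {
        "scores": {a.condition: da, b.condition: db},
        "difference": diff,
        "mdc": a.mdc,
        "meaningful": abs(diff) > a.mdc,
    }
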