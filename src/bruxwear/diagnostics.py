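"""Diagnostic-accuracy statistics for validating the pixel score against
the polysomnographic criterion.

The cohort is a labelled table (SB / non-SB with one pixel score per
subject).  This module provides the empirical ROC curve with the
Youden-optimal cut-off, confusion metrics and predictive values, the
pooled-SD standardized mean difference with its small-sample correction,
post-hoc power of the two-sample t-test via the noncentral t
distribution, Student-t confidence intervals for group means, group
comparisons (Shapiro–Wilk gated Welch t / Wilcoxon rank-sum with an exact
small-sample null), and Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RocResult",
    "GroupTestResult",
    "DiagnosticReport",
    "roc_analysis",
    "confusion_metrics",
    "predictive_values",
    "effect_size",
    "ttest_power",
    "mean_ci",
    "wilcoxon_rank_sum",
    "compare_groups",
    "fdr_adjust",
    "validation_report",
]


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending; score >= threshold classifies positive
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    confusion: dict[str, int]  # TP / FP / TN / FN at the Youden cut-off

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_analysis(scores, labels, positive="SB") -> RocResult:
    """Empirical ROC with higher-score-is-positive orientation.

    Thresholds run over all distinct observed scores; a score greater than
    or equal to the threshold classifies as positive, so the chosen
    cut-off value itself tests positive.  The AUC is the trapezoidal area,
    which for this construction equals the Mann–Whitney concordance
    probability with ties counted one half.  The Youden cut-off maximizes
    J = sensitivity + specificity − 1; ties are resolved toward higher
    sensitivity, then the lower cut-off — deliberately favouring detection
    of all true positives.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive for lab in labels], dtype=bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be nonempty for ROC analysis")

    thresholds = np.unique(scores)[::-1]  # descending
    tp = np.array([(y & (scores >= t)).sum() for t in thresholds])
    fp = np.array([(~y & (scores >= t)).sum() for t in thresholds])
    tpr = tp / n_pos
    fpr = fp / n_neg
    # close the curve at (0,0) for the area computation
    auc = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))

    j = tpr - fpr
    best = 0
    for i in range(1, len(thresholds)):
        better = j[i] > j[best] or (
            j[i] == j[best]
            and (tpr[i] > tpr[best] or (tpr[i] == tpr[best] and thresholds[i] < thresholds[best]))
        )
        if better:
            best = i
    cutoff = float(thresholds[best])
    confusion = {
        "TP": int(tp[best]),
        "FP": int(fp[best]),
        "TN": n_neg - int(fp[best]),
        "FN": n_pos - int(tp[best]),
    }
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        youden_cutoff=cutoff,
        youden_j=float(j[best]),
        confusion=confusion,
    )


def confusion_metrics(confusion: dict[str, int]) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and Youden J from a 2×2 table.

    Ratios with a zero denominator are reported as ``None`` (undefined)
    rather than raising.
    """
    tp, fp = confusion["TP"], confusion["FP"]
    tn, fn = confusion["TN"], confusion["FN"]
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    return {
        "sensitivity": se,
        "specificity": sp,
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "youden_j": (se + sp - 1.0) if se is not None and sp is not None else None,
    }


def predictive_values(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> dict[str, float | None]:
    """PPV and NPV at the study's class balance.

    ``ppv = Se·n⁺ / (Se·n⁺ + (1−Sp)·n⁻)``;
    ``npv = Sp·n⁻ / (Sp·n⁻ + (1−Se)·n⁺)``.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    ppv_den = sensitivity * n_pos + (1 - specificity) * n_neg
    npv_den = specificity * n_neg + (1 - sensitivity) * n_pos
    return {
        "ppv": sensitivity * n_pos / ppv_den if ppv_den > 0 else None,
        "npv": specificity * n_neg / npv_den if npv_den > 0 else None,
    }


# ---------------------------------------------------------------------------
# effect size / power / CI
# ---------------------------------------------------------------------------


def effect_size(m1, s1, n1, m2, s2, n2) -> dict[str, float]:
    """Pooled-SD standardized mean difference.

    ``cohen_d`` uses the pooled SD with n−1 weights; ``hedges_g`` applies
    the small-sample correction ``1 − 3/(4N − 9)``.  With a zero pooled SD
    and unequal means the effect is infinite (signed).
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = m1 - m2
    if pooled == 0:
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        d = diff / pooled
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return {"cohen_d": d, "hedges_g": d * correction, "pooled_sd": pooled}


def ttest_power(
    effect_d: float, n1: int, n2: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of the two-sample t-test at standardized effect ``effect_d``.

    Uses the noncentral t distribution with df = n1 + n2 − 2 and
    noncentrality ``d·sqrt(n1·n2/(n1+n2))``.  At d = 0 the power equals
    the significance level.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    ncp = effect_d * math.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp))


def mean_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for a mean from summary statistics."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    half = stats.t.ppf((1 + level) / 2, n - 1) * sd / math.sqrt(n)
    return (mean - half, mean + half)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    statistic: float
    df: float | None
    p_raw: float
    test_used: str  # welch_t | wilcoxon_exact | wilcoxon_normal
    normality_p: tuple[float | None, float | None] = (None, None)
    p_adjusted: float | None = None
    degenerate: bool = False


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, obs2: int) -> float:
    """Exact two-sided rank-sum p under the permutation null with midranks.

    ``ranks2`` are midranks doubled to integers; ``obs2`` the doubled
    observed rank sum of the first group.  Counts size-``n1`` subsets whose
    rank sum deviates from the null mean at least as much as observed, via
    dynamic programming over (subset size, rank sum).
    """
    total = int(ranks2.sum())
    n = len(ranks2)
    # table[c, s]: number of subsets of size c with doubled-rank sum s
    table = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        table[1:, r:] += table[:-1, : total + 1 - r]
    counts = table[n1]
    mean2 = n1 * (n + 1)  # doubled null mean of the rank sum
    dev = abs(obs2 - mean2)
    sums = np.arange(total + 1)
    extreme = counts[np.abs(sums - mean2) >= dev].sum()
    return float(extreme / counts.sum())


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact permutation null (tie-capable, via midranks) when both samples
    have at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie and continuity corrections.  The statistic is
    the Mann–Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return GroupTestResult(
            statistic=u, df=None, p_raw=1.0, test_used="wilcoxon_exact", degenerate=True
        )
    if n1 <= exact_max_n and n2 <= exact_max_n:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_rank_sum_p(ranks2, n1, int(round(w * 2)))
        return GroupTestResult(statistic=u, df=None, p_raw=p, test_used="wilcoxon_exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return GroupTestResult(
            statistic=u, df=None, p_raw=1.0, test_used="wilcoxon_normal", degenerate=True
        )
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(sigma2) if u != mu else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return GroupTestResult(statistic=u, df=None, p_raw=p, test_used="wilcoxon_normal")


def compare_groups(x, y, method: str = "auto") -> GroupTestResult:
    """Two-group comparison with normality-gated test choice.

    ``auto``: Shapiro–Wilk in each group at α = 0.05; if both pass, the
    Welch unequal-variance t-test (fractional Welch–Satterthwaite df),
    otherwise the Wilcoxon rank-sum test.  All p-values two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")

    normality: tuple[float | None, float | None] = (None, None)
    if method == "auto":
        if len(x) >= 3 and len(y) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            p1 = float(stats.shapiro(x).pvalue)
            p2 = float(stats.shapiro(y).pvalue)
            normality = (p1, p2)
            method = "welch_t" if (p1 > 0.05 and p2 > 0.05) else "wilcoxon"
        else:
            method = "wilcoxon"

    if method == "welch_t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return GroupTestResult(
            statistic=float(res.statistic),
            df=float(res.df),
            p_raw=float(res.pvalue),
            test_used="welch_t",
            normality_p=normality,
            degenerate=bool(np.ptp(np.concatenate([x, y])) == 0),
        )
    if method == "wilcoxon":
        out = wilcoxon_rank_sum(x, y)
        out.normality_p = normality
        return out
    raise ValueError(f"unknown method {method!r}")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full validation report
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticReport:
    n_pos: int
    n_neg: int
    group_stats: dict[str, dict[str, float]]
    mean_ratio: float
    effect: dict[str, float]
    power: float
    roc: RocResult
    metrics: dict[str, float | None]
    predictive: dict[str, float | None]
    tests: dict[str, GroupTestResult]

    def to_dict(self) -> dict:
        return {
            "n": {"SB": self.n_pos, "non-SB": self.n_neg},
            "group_stats": self.group_stats,
            "mean_ratio": self.mean_ratio,
            "effect_size": {k: self.effect[k] for k in ("cohen_d", "hedges_g")},
            "power": self.power,
            "auc": self.roc.auc,
            "youden_cutoff": self.roc.youden_cutoff,
            "youden_j": self.roc.youden_j,
            "confusion": self.roc.confusion,
            "metrics": self.metrics,
            "predictive_values": self.predictive,
            "tests": {
                name: {
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_raw": t.p_raw,
                    "p_adjusted": t.p_adjusted,
                    "test_used": t.test_used,
                }
                for name, t in self.tests.items()
            },
        }


def validation_report(
    cohort: pd.DataFrame,
    score_col: str = "pixel_score",
    group_col: str = "group",
    positive: str = "SB",
    extra_variables: list[str] | None = None,
    alpha: float = 0.05,
) -> DiagnosticReport:
    """Full validation of the score against the reference labels.

    Runs the group comparison for the score (plus any ``extra_variables``,
    with BH-FDR across all of them), effect size and post-hoc power,
    Student-t CIs for group means, and the ROC analysis with Youden
    cut-off, confusion metrics and predictive values.
    """
    for col in (score_col, group_col):
        if col not in cohort.columns:
            raise KeyError(f"missing column: {col}")
    is_pos = cohort[group_col] == positive
    pos = cohort.loc[is_pos, score_col].to_numpy(dtype=float)
    neg = cohort.loc[~is_pos, score_col].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be nonempty")

    group_stats = {}
    for name, vals in (("SB", pos), ("non-SB", neg)):
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        lo, hi = mean_ci(mean, sd, len(vals)) if len(vals) > 1 else (mean, mean)
        group_stats[name] = {"n": len(vals), "mean": mean, "sd": sd, "ci95": [lo, hi]}

    variables = [score_col] + list(extra_variables or [])
    tests: dict[str, GroupTestResult] = {}
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"missing column: {var}")
        tests[var] = compare_groups(
            cohort.loc[is_pos, var].to_numpy(dtype=float),
            cohort.loc[~is_pos, var].to_numpy(dtype=float),
        )
    adjusted = fdr_adjust([tests[v].p_raw for v in variables])
    for var, p_adj in zip(variables, adjusted):
        tests[var].p_adjusted = float(p_adj)

    eff = effect_size(
        group_stats["SB"]["mean"], group_stats["SB"]["sd"], len(pos),
        group_stats["non-SB"]["mean"], group_stats["non-SB"]["sd"], len(neg),
    )
    power = ttest_power(eff["cohen_d"], len(pos), len(neg), alpha=alpha)
    roc = roc_analysis(cohort[score_col], cohort[group_col], positive=positive)
    metrics = confusion_metrics(roc.confusion)
    predictive = predictive_values(
        metrics["sensitivity"], metrics["specificity"], len(pos), len(neg)
    )
    ratio = (
        group_stats["SB"]["mean"] / group_stats["non-SB"]["mean"]
        if group_stats["non-SB"]["mean"] != 0
        else math.inf
    )
    return DiagnosticReport(
        n_pos=len(pos),
        n_neg=len(neg),
        group_stats=group_stats,
        mean_ratio=float(ratio),
        effect=eff,
        power=power,
        roc=roc,
        metrics=metrics,
        predictive=predictive,
        tests=tests,
    )
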