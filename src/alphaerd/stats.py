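"""Group inference for genotype-stratified ERD tables.

The inferential layer mirrors a classical quantitative-EEG workflow:

* Shapiro–Wilk normality screening (warn, don't abort);
* one-sample two-sided t tests of group-mean ERD against 0 (is the task
  eliciting desynchronization at all?);
* a subject-level general linear model (OLS) of ERD on pooled *CLU* genotype
  with *APOE* group, sex (factors) and age (continuous) as covariates, with
  the genotype F test reported with its exact residual degrees of freedom
  df_den = N − 5 under the default model;
* Duncan's multiple range post hoc test, computed from the studentized-range
  distribution (protection level 1 − (1−α)^(k−1) for a span of k ordered
  means) rather than from printed tables;
* Pearson age correlations with the usual t transform;
* demographic comparisons reconstructed from summary statistics
  (mean ± SE, n) with a pooled-variance two-sample t, and a chi-square
  proportion test (Fisher exact behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GLMResult",
    "PosthocResult",
    "CorrelationResult",
    "SummaryGroup",
    "DegenerateDataError",
    "shapiro_wilk_screen",
    "one_sample_erd_test",
    "glm_genotype_effect",
    "duncan_posthoc",
    "pearson_age_correlation",
    "summary_two_sample_test",
    "proportion_test",
]


class DegenerateDataError(ValueError):
    """Raised when a test's input has no usable variance."""


@dataclass
class GLMResult:
    """F test for one model term plus the fitted coefficient table."""

    factor: str
    F: float
    df_num: int
    df_den: int
    p: float
    coefficients: pd.DataFrame  # term, estimate, se
    anova: pd.DataFrame = field(repr=False, default=None)
    n: int = 0


@dataclass
class PosthocResult:
    comparison: str
    mean_difference: float
    critical_range: float
    p: float
    significant: bool


@dataclass
class CorrelationResult:
    pair: str
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class SummaryGroup:
    """Printed summary of one group: size, mean and standard error."""

    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("SummaryGroup needs n >= 2")
        if self.se <= 0:
            raise ValueError("SummaryGroup needs se > 0")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


def shapiro_wilk_screen(values, label: str = "") -> tuple[float, float]:
    """Shapiro–Wilk W and p; warns (never aborts) when normality is rejected."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"constant sample{f' ({label})' if label else ''}")
    w, p = sstats.shapiro(x)
    if p < 0.05:
        warnings.warn(
            f"Shapiro–Wilk rejects normality{f' for {label}' if label else ''} "
            f"(W={w:.3f}, p={p:.3g})",
            stacklevel=2,
        )
    return float(w), float(p)


def one_sample_erd_test(values, method: str = "t") -> tuple[float, int, float]:
    """Two-sided one-sample test of mean ERD against 0: (statistic, df, p).

    ``method='t'`` (default) is the one-sample t; ``method='wilcoxon'`` the
    signed-rank alternative (df is reported as n − 1 in both cases).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"one-sample test needs n >= 3, got {x.size}")
    if np.std(x, ddof=1) == 0:
        raise DegenerateDataError("zero variance in ERD values")
    if method == "t":
        res = sstats.ttest_1samp(x, 0.0)
    elif method == "wilcoxon":
        res = sstats.wilcoxon(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


_DEFAULT_FORMULA = "{response} ~ C(clu_group) + C(apoe_group) + C(sex) + age"


def glm_genotype_effect(
    data: pd.DataFrame,
    response: str = "erd_percent",
    factor: str = "C(clu_group)",
    formula: str | None = None,
) -> GLMResult:
    """OLS general linear model; F test for the pooled-genotype term.

    ``data`` must carry the response plus clu_group, apoe_group, sex and age.
    df_den is the residual degrees of freedom, N − (number of estimated terms):
    N − 5 under the default genotype + APOE + sex + age model.
    """
    formula = formula or _DEFAULT_FORMULA.format(response=response)
    required = {"clu_group", "apoe_group", "sex", "age", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    if data[list(required)].isna().any().any():
        raise ValueError("missing covariate or response values")
    if data["clu_group"].value_counts().min() < 2 or data["clu_group"].nunique() < 2:
        raise ValueError("need >= 2 subjects in each genotype level")
    model = smf.ols(formula, data=data)
    fit = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear terms)")
    anova = sm.stats.anova_lm(fit, typ=2)
    if factor not in anova.index:
        raise ValueError(f"factor {factor!r} not in model terms {list(anova.index)}")
    row = anova.loc[factor]
    coef = pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.values, "se": fit.bse.values}
    )
    f_stat = float(row["F"])
    if not np.isfinite(f_stat):  # degenerate (e.g. response identically 0)
        f_stat, p = 0.0, 1.0
    else:
        p = float(row["PR(>F)"])
    return GLMResult(
        factor=factor,
        F=f_stat,
        df_num=int(row["df"]),
        df_den=int(fit.df_resid),
        p=p,
        coefficients=coef,
        anova=anova,
        n=int(fit.nobs),
    )


def duncan_posthoc(
    means: dict[str, float],
    mse: float,
    df_error: int,
    sizes: dict[str, int],
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Duncan's multiple range test on ordered group means.

    For a pair spanning k ordered means, the critical range is
    q(1 − α_k; k, df_error) · sqrt(MSE / n_h) with protection level
    α_k = 1 − (1 − α)^(k−1) and n_h the harmonic mean of the span's group
    sizes.  The reported p is the Duncan-adjusted 1 − (1 − p_q)^(1/(k−1)).
    Step-down protection: a pair is significant only if every enclosing span
    is.  With two groups the procedure reduces to the pooled two-sample t.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if mse <= 0:
        raise ValueError("within-group variance estimate must be > 0")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    order = sorted(means, key=means.get)
    n_groups = len(order)

    raw: dict[tuple[int, int], tuple[float, float, float, bool]] = {}
    for i, j in combinations(range(n_groups), 2):
        span = order[i : j + 1]
        k = j - i + 1
        n_h = k / sum(1.0 / sizes[g] for g in span)  # harmonic mean of span sizes
        se = np.sqrt(mse / n_h)
        diff = means[order[j]] - means[order[i]]
        q_stat = abs(diff) / se
        q_crit = sstats.studentized_range.ppf((1.0 - alpha) ** (k - 1), k, df_error)
        p_q = float(sstats.studentized_range.sf(q_stat, k, df_error))
        p_adj = 1.0 - (1.0 - p_q) ** (1.0 / (k - 1))
        raw[(i, j)] = (diff, q_crit * se, min(max(p_adj, 0.0), 1.0), q_stat > q_crit)

    # step-down protection: a span is testable/significant only if every
    # enclosing span is significant
    significant: dict[tuple[int, int], bool] = {}
    for width in range(n_groups - 1, 0, -1):
        for i in range(n_groups - width):
            j = i + width
            ok = raw[(i, j)][3]
            enclosing = [
                significant.get((a, b), True)
                for (a, b) in significant
                if a <= i and j <= b and (a, b) != (i, j)
            ]
            significant[(i, j)] = ok and all(enclosing)

    results = []
    for (i, j), (diff, crit, p_adj, _) in sorted(raw.items()):
        results.append(
            PosthocResult(
                comparison=f"{order[j]} vs {order[i]}",
                mean_difference=diff,
                critical_range=crit,
                p=p_adj,
                significant=bool(significant[(i, j)]),
            )
        )
    return results


def pearson_age_correlation(x, y, pair: str = "age vs erd") -> CorrelationResult:
    """Pearson r with two-sided p via the t transform t = r·sqrt((n−2)/(1−r²))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"correlation needs n >= 3, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the variables")
    res = sstats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic), n=int(x.size), p=float(res.pvalue))


def summary_two_sample_test(a: SummaryGroup, b: SummaryGroup, equal_var: bool = True):
    """Two-sample t reconstructed from printed summaries (n, mean ± SE).

    Pooled variance by default (Welch via ``equal_var=False``).
    Returns (t, df, p).
    """
    res = sstats.ttest_ind_from_stats(
        mean1=a.mean, std1=a.sd, nobs1=a.n,
        mean2=b.mean, std2=b.sd, nobs2=b.n,
        equal_var=equal_var,
    )
    df = a.n + b.n - 2 if equal_var else _welch_df(a, b)
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_df(a: SummaryGroup, b: SummaryGroup) -> float:
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    return (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))


def proportion_test(counts, fisher: bool = False) -> tuple[float, float]:
    """2×2 proportion comparison: chi-square without continuity correction.

    ``fisher=True`` switches to Fisher's exact test (statistic = odds ratio).
    Returns (statistic, p).
    """
    table = np.asarray(counts)
    if table.shape != (2, 2) or (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be a 2×2 table of nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty row or column margin")
    if fisher:
        odds, p = sstats.fisher_exact(table)
        return float(odds), float(p)
    res = sstats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
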