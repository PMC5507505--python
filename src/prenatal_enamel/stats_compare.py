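"""Statistical battery for enamel-growth comparisons, conventions pinned down.

Thin wrappers around scipy/statsmodels where conventions are unambiguous;
the Mann-Whitney U is computed directly because the headline statistic
here is the *smaller* of the two one-sided U values (the convention of
common statistical software when reporting W for small samples), with
midrank tie handling and a continuity-corrected normal approximation.
Every result carries a ``notes`` string recording the convention used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .enamel_data import Table1Row

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "levene_test",
    "pearson_r_test",
    "ancova_interaction",
    "t_from_summary",
    "two_sample_distribution_tests",
    "group_error_summary",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: "float | tuple | None"
    p: float
    notes: str = ""
    extra: dict = field(default_factory=dict)


def _check_nonempty(*samples) -> list[np.ndarray]:
    out = []
    for s in samples:
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError("empty sample")
        out.append(a)
    return out


def mann_whitney_u(x, y, continuity: bool = True) -> TestResult:
    """Mann-Whitney U with midrank ties; headline statistic is min(U_x, U_y).

    U_x counts pairs where x beats y (ties credited 0.5); U_x + U_y always
    equals n_x * n_y.  The p-value uses the normal approximation with tie
    correction and, by default, a 0.5 continuity correction.
    """
    x, y = _check_nonempty(x, y)
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    rx = float(ranks[:nx].sum())
    u_x = rx - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    u_min = min(u_x, u_y)

    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        p = 1.0  # all observations identical
        z = 0.0
    else:
        cc = 0.5 if continuity else 0.0
        z = (abs(u_x - mu) - cc) / np.sqrt(sigma2)
        z = max(z, 0.0)
        p = 2.0 * stats.norm.sf(z)
    return TestResult(
        method="mann-whitney-u",
        statistic=float(u_min),
        df=None,
        p=float(min(p, 1.0)),
        notes="midrank ties; normal approximation"
        + (" with continuity correction" if continuity else "")
        + "; statistic = min(U_x, U_y), both exposed in extra",
        extra={"u_x": float(u_x), "u_y": float(u_y), "z": float(z)},
    )


def kruskal_wallis(groups: "list[list[float]]") -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    arrays = _check_nonempty(*groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    h, p = stats.kruskal(*arrays)
    return TestResult(
        method="kruskal-wallis",
        statistic=float(h),
        df=len(arrays) - 1,
        p=float(p),
        notes="tie-corrected H; chi-square approximation",
    )


def levene_test(groups: "list[list[float]]", center: str = "mean") -> TestResult:
    """Levene homogeneity-of-variance test (ANOVA on |deviations|).

    Default centering is the group mean (classic Levene); ``center='median'``
    gives the Brown-Forsythe variant.
    """
    arrays = _check_nonempty(*groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for a in arrays:
        if a.size < 2:
            raise ValueError("every group needs n >= 2")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    f, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return TestResult(
        method="levene",
        statistic=float(f),
        df=(k - 1, n - k),
        p=float(p),
        notes=f"center = {center}",
    )


def pearson_r_test(x, y) -> TestResult:
    """Pearson correlation with t = r*sqrt((n-2)/(1-r^2)), df = n - 2."""
    x, y = _check_nonempty(x, y)
    if x.size != y.size:
        raise ValueError("x and y must align")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one variable")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return TestResult(
        method="pearson-r",
        statistic=r,
        df=n - 2,
        p=float(p),
        notes="two-sided t test of r",
        extra={"t": float(t)},
    )


def ancova_interaction(response, covariate, factor) -> TestResult:
    """F-test of the covariate x factor interaction (parallel-slopes check).

    Fits response ~ covariate * factor and response ~ covariate + factor by
    OLS and compares them by extra sum of squares; a non-significant F
    supports a common slope across factor levels.
    """
    y, x = _check_nonempty(response, covariate)
    f = pd.Series(factor).astype("category")
    if f.nunique() < 2:
        raise ValueError("factor needs >= 2 levels")
    if not (len(y) == len(x) == len(f)):
        raise ValueError("inputs must align")
    df = pd.DataFrame({"y": y, "x": x, "g": f})
    full = sm.OLS.from_formula("y ~ x * g", data=df).fit()
    add = sm.OLS.from_formula("y ~ x + g", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient interaction design")
    df_num = add.df_resid - full.df_resid
    f_stat = ((add.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    p = float(stats.f.sf(f_stat, df_num, full.df_resid))
    return TestResult(
        method="ancova-interaction",
        statistic=float(f_stat),
        df=(int(df_num), int(full.df_resid)),
        p=p,
        notes="extra-sum-of-squares F: (covariate + factor) vs (covariate * factor)",
    )


def t_from_summary(m1, s1, n1, m2, s2, n2) -> TestResult:
    """Pooled-variance two-sample t from summary statistics; df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult(
        method="t-two-sample-pooled",
        statistic=float(t),
        df=n1 + n2 - 2,
        p=float(p),
        notes="pooled variance from summary statistics",
    )


def two_sample_distribution_tests(x, y) -> tuple[TestResult, TestResult]:
    """Wilcoxon rank-sum (continuity-corrected) and two-sample KS.

    The rank-sum statistic follows the R convention W = U of the first
    sample; the KS D is the supremum of the ECDF difference (invariant
    under any common strictly monotone transform).
    """
    x, y = _check_nonempty(x, y)
    mw = mann_whitney_u(x, y, continuity=True)
    ranksum = TestResult(
        method="wilcoxon-rank-sum",
        statistic=mw.extra["u_x"],
        df=None,
        p=mw.p,
        notes="W = U of first sample (R convention); midranks + continuity correction",
        extra=mw.extra,
    )
    ks = stats.ks_2samp(x, y, method="asymp")
    ks_res = TestResult(
        method="kolmogorov-smirnov",
        statistic=float(ks.statistic),
        df=None,
        p=float(ks.pvalue),
        notes="two-sample sup|ECDF difference|",
    )
    return ranksum, ks_res


def group_error_summary(rows: "list[Table1Row]", grouping: str) -> dict:
    """Per-group mean |deviation| (days) and mean percent error of the
    regression estimate, the percent denominator being the direct count."""
    if grouping not in ("arch", "nl_present"):
        raise ValueError("grouping must be 'arch' or 'nl_present'")
    groups: dict = {}
    for row in rows:
        key = getattr(row, grouping)
        groups.setdefault(key, []).append(row)
    out = {}
    for key, rs in groups.items():
        dev = np.array([abs(r.deviation_days) for r in rs])
        pct = np.array([abs(r.deviation_days) / r.pcft_direct_days * 100.0 for r in rs])
        out[key] = {
            "n": len(rs),
            "mean_abs_deviation_days": float(dev.mean()),
            "mean_percent_error": float(pct.mean()),
        }
    return out
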