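"""Statistical layer with exact small-sample branches.

Mann-Whitney U (exact enumeration for small samples, tie-corrected normal
approximation otherwise), Welch/Student t, Spearman correlation (exact
permutation p for n <= 8), two-way ANOVA with Type-II sums of squares,
mixed (split-plot) ANOVA with an optional log10(x+1) transform and a
Greenhouse-Geisser-corrected p, and Grubbs outlier screening.

All p values are two-sided; no multiple-testing correction is applied
(noted in each result's ``extra`` metadata).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult", "mann_whitney_u", "t_test", "spearman",
    "two_way_anova", "mixed_anova", "grubbs_critical", "grubbs_outlier",
    "grubbs_screen",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | tuple | None = None
    effect: str = ""
    n: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of [0, 1]: {self.p}")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks: np.ndarray, nx: int) -> float:
    """U of the first sample given mid-ranks of the pooled data."""
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Reports U = min(U_x, U_y).  For n_x + n_y <= ``exact_max_n`` the p value
    is exact, by full enumeration of the C(n_x+n_y, n_x) group labelings of
    the pooled mid-ranks (ties handled naturally); otherwise a normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    ux = _u_statistic(ranks, nx)
    uy = nx * ny - ux
    u = min(ux, uy)

    if nx + ny <= exact_max_n:
        idx_all = range(nx + ny)
        us = np.array([ranks[list(c)].sum() - nx * (nx + 1) / 2.0
                       for c in itertools.combinations(idx_all, nx)])
        p_le = float(np.mean(us <= ux + 1e-9))
        p_ge = float(np.mean(us >= ux - 1e-9))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        n = nx + ny
        mu = nx * ny / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(ux - mu) - 0.5) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        method = "normal_tie_corrected"
    return TestResult(test="mann_whitney_u", statistic=u, p=p, n=(nx, ny),
                      effect=f"U_x={ux:g}",
                      extra={"U_x": ux, "U_y": uy, "method": method,
                             "correction": "none"})


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------

def t_test(x, y, welch: bool = True) -> TestResult:
    """Two-sided two-sample t test (Welch by default, fractional df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(test="t_test", statistic=0.0, p=1.0,
                              df=float(x.size + y.size - 2), n=(x.size, y.size),
                              extra={"welch": welch, "correction": "none"})
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(test="t_test", statistic=float(res.statistic),
                      p=float(res.pvalue), df=float(res.df),
                      n=(x.size, y.size),
                      effect=f"mean_diff={np.mean(x) - np.mean(y):g}",
                      extra={"welch": welch, "correction": "none"})


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _rho_midranks(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (Spearman rho with ties)."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if den == 0:
        return float("nan")
    return float((rx * ry).sum() / den)


def spearman(x, y, exact_max_n: int = 8) -> TestResult:
    """Spearman rank correlation on mid-ranks.

    For n <= ``exact_max_n`` the two-sided p is exact, by enumerating all
    n! pairings of the rank vectors; larger samples use the
    t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(test="spearman", statistic=float("nan"),
                          p=float("nan"), n=(n,),
                          extra={"constant_input": True, "correction": "none"})
    rho = _rho_midranks(x, y)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        rxc = rx - rx.mean()
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            ryp = ry[list(perm)]
            ryc = ryp - ryp.mean()
            den = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
            r = (rxc * ryc).sum() / den
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact_permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "t_approximation"
    return TestResult(test="spearman", statistic=rho, p=p, n=(n,),
                      extra={"method": method, "correction": "none"})


# ---------------------------------------------------------------------------
# Two-way ANOVA (Type-II)
# ---------------------------------------------------------------------------

def two_way_anova(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> dict[str, TestResult]:
    """Two-way fixed-effects ANOVA with Type-II sums of squares.

    Returns TestResults keyed ``factor_a``, ``factor_b`` and
    ``interaction``.  Type II is robust to the unequal group sizes typical
    of animal cohorts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "A", factor_b: "B"}).copy()
    counts = df.groupby(["A", "B"], observed=True).size()
    if (counts < 1).any() or counts.size < \
            df["A"].nunique() * df["B"].nunique():
        raise ValueError("every factor-level cell needs observations")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row_name in ((factor_a, "C(A)"), (factor_b, "C(B)"),
                          ("interaction", "C(A):C(B)")):
        row = tab.loc[row_name]
        out[key] = TestResult(
            test="two_way_anova", statistic=float(row["F"]),
            p=float(row["PR(>F)"]),
            df=(float(row["df"]), float(tab.loc["Residual", "df"])),
            n=(len(df),),
            extra={"ss": float(row["sum_sq"]), "type": "II",
                   "ss_resid": float(tab.loc["Residual", "sum_sq"])})
    return out


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _gg_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = Y.shape[1]
    S = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        Z = Y[groups == g]
        if Z.shape[0] > 1:
            S += (Z - Z.mean(axis=0)).T @ (Z - Z.mean(axis=0))
            dof += Z.shape[0] - 1
    S /= max(dof, 1)
    row = S.mean(axis=0)
    dc = S - row[None, :] - row[:, None] + S.mean()
    num = np.trace(dc) ** 2
    den = (k - 1) * np.sum(dc ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def mixed_anova(data: pd.DataFrame, value: str, between: str, within: str,
                subject: str, log_transform: bool = False
                ) -> dict[str, TestResult]:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    Requires complete within-subject profiles (no imputation).  The
    between effect is tested over the subject-within-group error; the
    within and interaction effects over the subject x within error.  With
    ``log_transform`` the response is log10(x + 1) first (the transform
    used for shell-wise intersection counts, defined at zero).  The
    Greenhouse-Geisser-corrected p accompanies the within-factor results
    in ``extra['p_gg']``.
    """
    df = data[[value, between, within, subject]].copy()
    if log_transform:
        df[value] = np.log10(df[value].astype(float) + 1.0)
    wide = df.pivot_table(index=[subject, between], columns=within,
                          values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("incomplete within-subject profiles")
    Y = wide.to_numpy(dtype=float)
    groups = np.asarray([g for (_, g) in wide.index])
    n_sub, k = Y.shape
    glabels = np.unique(groups)
    G = glabels.size
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    grp_means = np.array([subj_means[groups == g].mean() for g in glabels])
    n_g = np.array([(groups == g).sum() for g in glabels])
    within_means = Y.mean(axis=0)
    cell_means = np.vstack([Y[groups == g].mean(axis=0) for g in glabels])

    ss_between = k * float(np.sum(n_g * (grp_means - grand) ** 2))
    ss_subj = k * float(np.sum(
        (subj_means - grp_means[np.searchsorted(glabels, groups)]) ** 2))
    ss_within = n_sub * float(np.sum((within_means - grand) ** 2))
    ss_inter = float(np.sum(
        n_g[:, None] * (cell_means - grp_means[:, None]
                        - within_means[None, :] + grand) ** 2))
    resid = (Y - cell_means[np.searchsorted(glabels, groups)]
             - subj_means[:, None]
             + grp_means[np.searchsorted(glabels, groups), None])
    ss_err2 = float(np.sum(resid ** 2))

    df_b, df_s = G - 1, n_sub - G
    df_w, df_i = k - 1, (G - 1) * (k - 1)
    df_e2 = (n_sub - G) * (k - 1)
    def ms(ss, d):
        return ss / d if d > 0 else np.nan

    def fratio(num, den):
        if not np.isfinite(den) or den == 0:
            return 0.0 if num == 0 else np.nan
        return num / den

    f_b = fratio(ms(ss_between, df_b), ms(ss_subj, df_s))
    f_w = fratio(ms(ss_within, df_w), ms(ss_err2, df_e2))
    f_i = fratio(ms(ss_inter, df_i), ms(ss_err2, df_e2))
    eps = _gg_epsilon(Y, groups)

    def pf(F, d1, d2):
        return float(sps.f.sf(F, d1, d2)) if np.isfinite(F) else float("nan")

    out = {
        "between": TestResult(
            test="mixed_anova", statistic=float(f_b), p=pf(f_b, df_b, df_s),
            df=(df_b, df_s), n=(n_sub,),
            extra={"ss": ss_between, "ss_error": ss_subj,
                   "log_transform": log_transform}),
        "within": TestResult(
            test="mixed_anova", statistic=float(f_w), p=pf(f_w, df_w, df_e2),
            df=(df_w, df_e2), n=(n_sub,),
            extra={"ss": ss_within, "ss_error": ss_err2, "epsilon_gg": eps,
                   "p_gg": pf(f_w, eps * df_w, eps * df_e2),
                   "log_transform": log_transform}),
        "interaction": TestResult(
            test="mixed_anova", statistic=float(f_i), p=pf(f_i, df_i, df_e2),
            df=(df_i, df_e2), n=(n_sub,),
            extra={"ss": ss_inter, "ss_error": ss_err2, "epsilon_gg": eps,
                   "p_gg": pf(f_i, eps * df_i, eps * df_e2),
                   "log_transform": log_transform}),
    }
    return out


# ---------------------------------------------------------------------------
# Grubbs outlier screen
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2)))


def grubbs_outlier(x, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme point if it exceeds the Grubbs
    critical value at ``alpha`` (two-sided); None otherwise."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant data: Grubbs test undefined")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    return i if g > grubbs_critical(x.size, alpha) else None


def grubbs_screen(x, alpha: float = 0.05,
                  max_iter: int | None = None) -> list[int]:
    """Iterative Grubbs screen: repeatedly remove the flagged point and
    re-test.  Returns original indices of all removed points."""
    x = np.asarray(x, dtype=float)
    idx = np.arange(x.size)
    removed: list[int] = []
    while x.size >= 3 and (max_iter is None or len(removed) < max_iter):
        if x.std(ddof=1) == 0:
            break
        i = grubbs_outlier(x, alpha)
        if i is None:
            break
        removed.append(int(idx[i]))
        x = np.delete(x, i)
        idx = np.delete(idx, i)
    return removed
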