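"""Statistical layer: exact branches vs oracles, ANOVA SS fixtures,
Grubbs critical values, and cross-checks against reference libraries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from matcare.stats import (grubbs_critical, grubbs_outlier, grubbs_screen,
                           mann_whitney_u, mixed_anova, spearman, t_test,
                           two_way_anova)

from oracles import spearman_perm_p, splitplot_ss_balanced, twoway_ss_balanced


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mw_fully_separated_exact_p():
    res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(0.1, abs=1e-12)    # 2/20 labelings
    assert res.extra["method"] == "exact"


def test_mw_identical_samples():
    x = [1.0, 2.0, 3.0]
    res = mann_whitney_u(x, x)
    assert res.extra["U_x"] == pytest.approx(4.5)    # n^2 / 2
    assert res.p == pytest.approx(1.0)


def test_mw_u_identity(rng):
    for _ in range(20):
        x = rng.normal(size=rng.integers(2, 15))
        y = rng.normal(size=rng.integers(2, 15))
        res = mann_whitney_u(x, y)
        assert res.extra["U_x"] + res.extra["U_y"] \
            == pytest.approx(len(x) * len(y))


def test_mw_exact_branch_matches_scipy(rng):
    """Exact-enumeration p equals scipy's exact distribution on tie-free
    data."""
    for _ in range(25):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_mw_exact_and_asymptotic_agree_at_crossover(rng):
    """At the n threshold the two branches differ by < 0.02 in p."""
    diffs = []
    for _ in range(100):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        p_exact = mann_whitney_u(x, y, exact_max_n=12).p
        p_asym = mann_whitney_u(x, y, exact_max_n=0).p
        diffs.append(abs(p_exact - p_asym))
    assert np.mean(diffs) < 0.02
    assert np.max(diffs) < 0.06


def test_mw_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------

def test_t_identical_means():
    res = t_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_antisymmetry(rng):
    x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=10)
    assert t_test(x, y).statistic == pytest.approx(-t_test(y, x).statistic)


def test_t_welch_hand_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    res = t_test(x, y, welch=True)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df_hand = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1)
                                + vy ** 2 / (y.size - 1))
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.df == pytest.approx(df_hand, abs=1e-9)
    assert res.p == pytest.approx(
        2 * sps.t.sf(abs(t_hand), df_hand), abs=1e-12)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone():
    x = np.arange(6.0)
    assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
    assert spearman(x, -x).statistic == pytest.approx(-1.0)


def test_spearman_ties_equal_pearson_on_ranks(rng):
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = rng.normal(size=6)
    rho = spearman(x, y).statistic
    assert rho == pytest.approx(
        np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1], abs=1e-12)


def test_spearman_exact_p_matches_enumeration(rng):
    for _ in range(5):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        assert res.extra["method"] == "exact_permutation"
        assert res.p == pytest.approx(spearman_perm_p(x, y), abs=1e-12)


def test_spearman_constant_flagged():
    res = spearman(np.ones(5), np.arange(5.0))
    assert np.isnan(res.statistic) and res.extra["constant_input"]


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def _twoway_frame(rng, effects=(0.0, 0.0, 0.0), n_cell=4):
    rows = []
    for i, a in enumerate(("nulliparous", "mother")):
        for j, b in enumerate(("vehicle", "polyic")):
            mu = effects[0] * i + effects[1] * j + effects[2] * i * j
            for v in mu + rng.normal(size=n_cell):
                rows.append({"y": v, "preg": a, "treat": b})
    return pd.DataFrame(rows)


def test_twoway_balanced_matches_hand_ss(rng):
    df = _twoway_frame(rng, effects=(1.0, 0.5, 0.8))
    res = two_way_anova(df, "y", "preg", "treat")
    ss = twoway_ss_balanced(df["y"], df["preg"], df["treat"])
    for key, hand in (("preg", "a"), ("treat", "b"), ("interaction", "ab")):
        f_hand = (ss[hand] / ss["df"][hand]) / (ss["err"] / ss["df"]["err"])
        assert res[key].statistic == pytest.approx(f_hand, abs=1e-10)
        assert res[key].extra["ss"] == pytest.approx(ss[hand], abs=1e-10)


def test_twoway_additive_means_zero_interaction():
    rows = []
    for i, a in enumerate(("x0", "x1")):
        for j, b in enumerate(("y0", "y1")):
            for r in range(3):
                rows.append({"v": 1.0 * i + 2.0 * j + 0.1 * r,
                             "A": a, "B": b})
    df = pd.DataFrame(rows)
    res = two_way_anova(df, "v", "A", "B")
    assert res["interaction"].extra["ss"] == pytest.approx(0.0, abs=1e-12)


def test_twoway_permutation_within_cells_invariance(rng):
    df = _twoway_frame(rng, effects=(0.5, 0.2, 0.0))
    res1 = two_way_anova(df, "y", "preg", "treat")
    df2 = df.copy()
    shuffler = np.random.default_rng(1)
    for _, idx in df2.groupby(["preg", "treat"]).groups.items():
        vals = df2.loc[idx, "y"].to_numpy()
        df2.loc[idx, "y"] = shuffler.permutation(vals)
    res2 = two_way_anova(df2, "y", "preg", "treat")
    for k in ("preg", "treat", "interaction"):
        assert res1[k].statistic == pytest.approx(res2[k].statistic)


def test_twoway_empty_cell_errors(rng):
    df = _twoway_frame(rng)
    df = df[~((df["preg"] == "mother") & (df["treat"] == "polyic"))]
    with pytest.raises(ValueError):
        two_way_anova(df, "y", "preg", "treat")


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _mixed_frame(rng, n_sub=4, k=4, b_effect=0.0, w_effect=0.0):
    rows = []
    for g_i, g in enumerate(("vehicle", "polyic")):
        for s in range(n_sub):
            sid = f"{g}_{s}"
            base = rng.normal()
            for w in range(k):
                rows.append({"y": base + b_effect * g_i + w_effect * w
                             + rng.normal(scale=0.5),
                             "group": g, "radius": 20.0 * (w + 1),
                             "subject": sid})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_hand_splitplot(rng):
    df = _mixed_frame(rng, b_effect=1.0, w_effect=0.3)
    res = mixed_anova(df, "y", between="group", within="radius",
                      subject="subject")
    wide = df.pivot_table(index=["subject", "group"], columns="radius",
                          values="y")
    Y = wide.to_numpy()
    groups = np.array([g for _, g in wide.index])
    ss = splitplot_ss_balanced(Y, groups)
    f_b = (ss["between"] / ss["df"]["between"][0]) \
        / (ss["subj"] / ss["df"]["between"][1])
    f_w = (ss["within"] / ss["df"]["within"][0]) \
        / (ss["err"] / ss["df"]["within"][1])
    f_i = (ss["interaction"] / ss["df"]["interaction"][0]) \
        / (ss["err"] / ss["df"]["interaction"][1])
    assert res["between"].statistic == pytest.approx(f_b, abs=1e-10)
    assert res["within"].statistic == pytest.approx(f_w, abs=1e-10)
    assert res["interaction"].statistic == pytest.approx(f_i, abs=1e-10)


def test_mixed_anova_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    df = _mixed_frame(rng, b_effect=0.8, w_effect=0.2)
    res = mixed_anova(df, "y", between="group", within="radius",
                      subject="subject")
    ref = pg.mixed_anova(data=df, dv="y", between="group", within="radius",
                        subject="subject")
    ref = ref.set_index("Source")
    assert res["between"].statistic == pytest.approx(
        float(ref.loc["group", "F"]), rel=1e-8)
    assert res["within"].statistic == pytest.approx(
        float(ref.loc["radius", "F"]), rel=1e-8)
    assert res["interaction"].statistic == pytest.approx(
        float(ref.loc["Interaction", "F"]), rel=1e-8)
    assert res["between"].p == pytest.approx(
        float(ref.loc["group", "p_unc"]), abs=1e-10)


def test_mixed_anova_degenerate_cases(rng):
    # identical profiles in both groups -> between F == 0
    prof = rng.normal(size=4)
    rows = [{"y": prof[w], "group": g, "w": w, "s": f"{g}{s}"}
            for g in ("a", "b") for s in range(3) for w in range(4)]
    res = mixed_anova(pd.DataFrame(rows), "y", "group", "w", "s")
    assert res["between"].statistic == pytest.approx(0.0, abs=1e-12)
    # profiles constant across the within factor -> within SS == 0
    rows = [{"y": 1.0 * s + 2.0 * (g == "b"), "group": g, "w": w,
             "s": f"{g}{s}"}
            for g in ("a", "b") for s in range(3) for w in range(4)]
    res = mixed_anova(pd.DataFrame(rows), "y", "group", "w", "s")
    assert res["within"].extra["ss"] == pytest.approx(0.0, abs=1e-12)


def test_mixed_anova_rejects_incomplete_profiles(rng):
    df = _mixed_frame(rng).iloc[:-1]
    with pytest.raises(ValueError):
        mixed_anova(df, "y", "group", "radius", "subject")


def test_mixed_anova_log_transform_applied(rng):
    df = _mixed_frame(rng, w_effect=1.0)
    df["y"] = np.abs(df["y"])
    res_log = mixed_anova(df, "y", "group", "radius", "subject",
                          log_transform=True)
    df2 = df.copy()
    df2["y"] = np.log10(df2["y"] + 1.0)
    res_manual = mixed_anova(df2, "y", "group", "radius", "subject")
    assert res_log["within"].statistic == pytest.approx(
        res_manual["within"].statistic)


# ---------------------------------------------------------------------------
# Grubbs
# ---------------------------------------------------------------------------

def test_grubbs_critical_closed_form_n3():
    assert grubbs_critical(3, 0.05) == pytest.approx(1.1543, abs=2e-4)


def test_grubbs_small_sample_no_outlier():
    assert grubbs_outlier([1.0, 2.0, 3.0]) is None


def test_grubbs_flags_extreme_point(rng):
    x = np.r_[rng.normal(size=12), 100.0]
    assert grubbs_outlier(x) == 12
    assert grubbs_screen(x) == [12]


def test_grubbs_tests_single_most_extreme(rng):
    x = np.array([-5.0, 0.0, 0.1, -0.1, 0.2, 5.00001])
    i = grubbs_outlier(x)
    assert i in (None, 5)                            # max deviation only


def test_grubbs_constant_data_errors():
    with pytest.raises(ValueError):
        grubbs_outlier([2.0, 2.0, 2.0])
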