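"""Statistics layer against brute-force oracles and algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from teatrace.stats_suite import (anova_from_summary, anova_lsd,
                                  compact_letters, linear_fit, pearson_matrix,
                                  significance_stars, threshold_fit)


def brute_force_pearson(x, y):
    """Product-moment formula evaluated directly."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x)**2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y)**2)
    return num / den


# ---------------------------------------------------------------------------
# Pearson


def test_perfect_correlation():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
    cm = pearson_matrix(df)
    assert cm.r.at["x", "y"] == pytest.approx(1.0)
    assert cm.p.at["x", "y"] < 1e-10
    assert cm.stars.at["x", "y"] == "**"


def test_pearson_four_point_oracle():
    x, y = [1.0, 2, 3, 4], [2.0, 1, 4, 3]
    cm = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
    assert cm.r.at["x", "y"] == pytest.approx(brute_force_pearson(x, y), rel=1e-12)


@given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                min_size=4, max_size=10))
def test_pearson_matches_brute_force_on_small_instances(pts):
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    cm = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
    expect = brute_force_pearson(x, y)
    if np.isfinite(expect) and abs(expect) <= 1:
        assert cm.r.at["x", "y"] == pytest.approx(expect, rel=1e-6, abs=1e-9)
        # p from the t transform
        n = len(x)
        if abs(expect) < 1:
            t = expect * np.sqrt((n - 2) / (1 - expect**2))
            assert cm.p.at["x", "y"] == pytest.approx(
                2 * sps.t.sf(abs(t), n - 2), rel=1e-6, abs=1e-12)


def test_constant_variable_warns_and_is_missing():
    df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
    with pytest.warns(UserWarning, match="constant"):
        cm = pearson_matrix(df)
    assert np.isnan(cm.r.at["x", "y"])


def test_stars_thresholds():
    assert significance_stars(0.049) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.2) == ""


# ---------------------------------------------------------------------------
# ANOVA + LSD letters


def test_identical_groups_share_a():
    res = anova_lsd([1.0, 1.1, 0.9, 1.0, 1.1, 0.9], ["a", "a", "a", "b", "b", "b"])
    assert res.letters == {"a": "a", "b": "a"}


def test_well_separated_groups_get_distinct_letters():
    rng = np.random.default_rng(0)
    vals, grp = [], []
    for g, m in (("lo", 0.0), ("mid", 10.0), ("hi", 20.0)):
        vals += list(m + 0.1 * rng.normal(size=3))
        grp += [g] * 3
    res = anova_lsd(vals, grp)
    assert res.letters["hi"] == "a"
    assert res.letters["mid"] == "b"
    assert res.letters["lo"] == "c"


def test_close_means_share_letter_per_hand_computed_lsd():
    """Gap 0.05 << LSD = t(4) * sqrt(MSE * 2/3) at sd 0.1, n=3."""
    rng = np.random.default_rng(1)
    a = 10.0 + 0.1 * rng.normal(size=3)
    b = 10.05 + 0.1 * rng.normal(size=3)
    res = anova_lsd(np.r_[a, b], ["a"] * 3 + ["b"] * 3)
    mse = (a.std(ddof=1)**2 + b.std(ddof=1)**2) / 2
    lsd = sps.t.ppf(0.975, 4) * np.sqrt(mse * 2 / 3)
    assert abs(a.mean() - b.mean()) < lsd
    assert set(res.letters["a"]) & set(res.letters["b"])


def test_summary_anova_equals_raw_anova():
    rng = np.random.default_rng(7)
    for _ in range(10):
        k = rng.integers(2, 6)
        vals, grps = [], []
        means, sds, ns, labs = [], [], [], []
        for g in range(k):
            n = int(rng.integers(2, 8))
            v = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 2), size=n)
            vals += list(v)
            grps += [f"g{g}"] * n
            means.append(v.mean())
            sds.append(v.std(ddof=1))
            ns.append(n)
            labs.append(f"g{g}")
        raw = anova_lsd(vals, grps)
        summ = anova_from_summary(means, sds, ns, labels=labs)
        assert summ.F == pytest.approx(raw.F, rel=1e-10)
        assert summ.p == pytest.approx(raw.p, rel=1e-10)
        assert summ.letters == raw.letters


def test_summary_anova_zero_between_variance():
    res = anova_from_summary([5.0, 5.0, 5.0], [1.0, 1.0, 1.0], [3, 3, 3])
    assert res.F == pytest.approx(0.0)
    assert set(res.letters.values()) == {"a"}


def test_summary_anova_input_contracts():
    with pytest.raises(ValueError):
        anova_from_summary([1.0, 2.0], [0.1, -0.1], [3, 3])
    with pytest.raises(ValueError):
        anova_from_summary([1.0, 2.0], [0.1, 0.1], [1, 3])
    with pytest.raises(ValueError, match="n < 2"):
        anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_protected_lsd_suppresses_letters_without_omnibus_significance():
    rng = np.random.default_rng(3)
    vals = list(rng.normal(0, 1, 4)) + list(rng.normal(0.1, 1, 4))
    res = anova_lsd(vals, ["a"] * 4 + ["b"] * 4)
    assert res.p >= 0.05
    assert res.letters == {"a": "a", "b": "a"}


def test_letters_partition_consistency_exhaustive():
    """For random <=6-group problems, the display shares a letter exactly for
    the pairs the LSD test does not reject."""
    rng = np.random.default_rng(11)
    for _ in range(60):
        k = int(rng.integers(2, 7))
        means = rng.uniform(0, 10, k)
        sds = rng.uniform(0.3, 2.0, k)
        ns = rng.integers(2, 6, k)
        res = anova_from_summary(means, sds, ns, alpha=0.05)
        pp = res.pairwise_p.to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                shares = bool(set(res.letters[res.groups[i]])
                              & set(res.letters[res.groups[j]]))
                if res.p < 0.05:
                    rejected = pp[i, j] < 0.05
                else:
                    rejected = False
                assert shares != rejected, (means, sds, ns)


def test_reference_leaching_letters_separate_extreme_sites(infusion_summary):
    """The lowest (no.6) and highest (no.11) leaching sites must not share
    a letter; the published table prints them as 'e' and 'a'."""
    res = anova_from_summary(infusion_summary["cd_leach_mean"],
                             infusion_summary["cd_leach_sd"],
                             infusion_summary["n"],
                             labels=infusion_summary["site_id"])
    assert res.letters["no.11"].startswith("a")  # largest mean
    assert not set(res.letters["no.6"]) & set(res.letters["no.11"])


# ---------------------------------------------------------------------------
# OLS


def test_exact_line_fit():
    x = np.arange(5.0)
    fit = linear_fit(x, 3 * x + 1)
    assert fit.slope == pytest.approx(3.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r2 == pytest.approx(1.0)


def test_five_point_normal_equations_oracle():
    x = np.array([0.0, 1, 2, 3, 5])
    y = np.array([1.1, 1.9, 3.2, 3.9, 6.1])
    X = np.c_[np.ones_like(x), x]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    fit = linear_fit(x, y)
    assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
    assert fit.slope == pytest.approx(beta[1], rel=1e-10)


def test_band_width_minimized_at_mean_x():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 10, 30)
    y = 2 * x + rng.normal(0, 1, 30)
    fit = linear_fit(x, y)
    grid = np.linspace(0, 10, 101)
    lo, hi = fit.confidence_band(grid)
    width = hi - lo
    assert grid[np.argmin(width)] == pytest.approx(x.mean(), abs=0.06)


def test_linear_fit_contracts():
    with pytest.raises(ValueError):
        linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        linear_fit([1.0, 2.0], [1.0, 2.0])


def test_ols_cross_checked_against_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 5, 25)
    y = 1.5 - 0.7 * x + rng.normal(0, 0.4, 25)
    fit = linear_fit(x, y)
    ref = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.slope == pytest.approx(ref.params[1], rel=1e-10)
    assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-8)
    assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)


# ---------------------------------------------------------------------------
# Two-phase threshold regression


def make_threshold_data(seed=7, n=60, noise=0.05):
    """Slope +0.4 below 2.0 and -0.3 above, with a visible offset at the break."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 3, n)
    y = np.where(x <= 2.0, 1 + 0.4 * x, 3 - 0.3 * x) + rng.normal(0, noise, n)
    return x, y


def test_search_recovers_breakpoint_and_slope_signs():
    x, y = make_threshold_data()
    seg = threshold_fit(x, y)
    xs = np.sort(np.unique(x))
    step = np.max(np.diff(xs)[(xs[:-1] > 1.8) & (xs[1:] < 2.2)])
    assert abs(seg.breakpoint - 2.0) <= step
    assert seg.below.slope > 0 and seg.above.slope < 0
    assert seg.below.n + seg.above.n == len(x)
    assert seg.searched


def test_search_never_beats_truth_breakpoint_on_sse():
    x, y = make_threshold_data(seed=3)
    seg = threshold_fit(x, y)
    fixed = threshold_fit(x, y, breakpoint=2.0)
    assert seg.sse <= fixed.sse + 1e-12


def test_no_break_data_degenerates_gracefully():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 10, 40)
    y = 0.5 * x + 1 + rng.normal(0, 0.2, 40)
    seg = threshold_fit(x, y)
    glob = linear_fit(x, y)
    se = np.sqrt(glob.resid_var / glob.sxx)
    for line in (seg.below, seg.above):
        assert abs(line.slope - glob.slope) < 4 * se * 3  # within a generous CI
    assert seg.sse >= 0


def test_fixed_breakpoint_min_points_contract():
    x = np.arange(10.0)
    y = x.copy()
    with pytest.raises(ValueError, match="needs >= 3"):
        threshold_fit(x, y, breakpoint=8.5)  # leaves 1 point above


def test_search_requires_enough_points():
    with pytest.raises(ValueError, match="no candidate"):
        threshold_fit([1.0, 2, 3, 4], [1.0, 2, 3, 4])
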