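"""Statistical layer: correlation, ANOVA + protected LSD letters, OLS, two-phase fits.

* :func:`pearson_matrix` — pairwise-complete Pearson r with two-sided
  p-values from the t transform and significance stars (* p<=0.05,
  ** p<=0.01).  No multiple-testing correction is applied anywhere.
* :func:`anova_lsd` / :func:`anova_from_summary` — one-way ANOVA with
  Fisher's *protected* LSD (pairwise tests only after a significant
  omnibus F) and a compact letter display built by insert-and-absorb,
  groups ordered by descending mean so the largest mean reads "a".  The
  summary-statistics variant reconstructs the sums of squares exactly
  from (mean, sd, n) triples, enabling post-hoc letters for published
  tables that print only mean +/- sd.
* :func:`linear_fit` — OLS with r^2, two-sided slope p, and the pointwise
  confidence band of the conditional mean.
* :func:`threshold_fit` — discontinuous two-phase regression: independent
  OLS lines below/above a breakpoint, either fixed or searched over the
  midpoints of consecutive sorted unique x (min 3 points per segment,
  ties broken toward the smaller breakpoint).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "LsdResult",
    "LinearFit",
    "SegmentLine",
    "SegmentedFit",
    "significance_stars",
    "pearson_matrix",
    "anova_lsd",
    "anova_from_summary",
    "linear_fit",
    "threshold_fit",
    "compact_letters",
]


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, r, p, stars), upper triangle only."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append({"var1": a, "var2": b, "r": self.r.at[a, b],
                             "p": self.p.at[a, b], "stars": self.stars.at[a, b]})
        return pd.DataFrame(rows)


def pearson_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of the numeric columns.

    Each pair uses its complete observations; pairs with fewer than
    ``min_pairs`` complete rows, or with a constant variable, yield NaN
    with a warning.
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < min_pairs:
                warnings.warn(f"pearson_matrix: <{min_pairs} complete pairs for "
                              f"({cols[i]}, {cols[j]})")
                continue
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"pearson_matrix: constant variable in "
                              f"({cols[i]}, {cols[j]}) -> r missing")
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(significance_stars)
    return CorrelationMatrix(cols, rdf, pdf, sdf)


# ---------------------------------------------------------------------------
# ANOVA + protected LSD + compact letter display


@dataclass
class LsdResult:
    groups: list[str]
    means: np.ndarray
    ns: np.ndarray
    F: float
    p: float
    letters: dict[str, str]
    mse: float
    df_error: int
    alpha: float
    pairwise_p: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.groups, "mean": self.means,
                             "n": self.ns,
                             "letter": [self.letters[g] for g in self.groups]})


def compact_letters(labels: list[str], means: np.ndarray,
                    significant: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when groups i and j differ.  Groups are
    lettered in descending-mean order ("a" = largest mean).  The display
    satisfies both directions: a significantly different pair never
    shares a letter, and a non-different pair always shares one.
    """
    k = len(labels)
    order = np.argsort(-np.asarray(means, dtype=float), kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)

    columns: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if not significant[a, b]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: keep only distinct maximal sets
            uniq: list[set[int]] = []
            for col in new_cols:
                if col not in uniq:
                    uniq.append(col)
            columns = [c for c in uniq if c and not any(c < o for o in uniq)]
    # order columns by the best (lowest) rank they contain, so the column
    # holding the largest mean gets "a"
    columns.sort(key=lambda col: min(rank[g] for g in col) if col else k)
    alphabet = string.ascii_lowercase
    letters = {lab: "" for lab in labels}
    for idx, col in enumerate(columns):
        ch = alphabet[idx] if idx < 26 else f"z{idx}"
        for g in sorted(col, key=lambda g: rank[g]):
            letters[labels[g]] += ch
    return {lab: "".join(sorted(s)) for lab, s in letters.items()}


def anova_from_summary(means, sds, ns, labels=None, alpha: float = 0.05) -> LsdResult:
    """One-way ANOVA + protected LSD letters from per-group (mean, sd, n).

    Between/within sums of squares are reconstructed exactly from the
    summary statistics (no resampling), so the result is identical to
    running :func:`anova_lsd` on the raw data the summaries came from.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = len(means)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    labels = list(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0) or np.any(np.isnan(sds)):
        raise ValueError("sds must be nonnegative and finite")

    N = int(ns.sum())
    grand = float(np.sum(ns * means)) / N
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = ms_between / mse
        p = float(stats.f.sf(F, df_b, df_w))

    sig = np.zeros((k, k), dtype=bool)
    pair_p = np.full((k, k), np.nan)
    np.fill_diagonal(pair_p, 1.0)
    if p < alpha:  # protected LSD: only test pairs after a significant omnibus F
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                if se == 0:
                    pij = 0.0 if means[i] != means[j] else 1.0
                else:
                    t = abs(means[i] - means[j]) / se
                    pij = float(2 * stats.t.sf(t, df_w))
                pair_p[i, j] = pair_p[j, i] = pij
                sig[i, j] = sig[j, i] = pij < alpha
    letters = compact_letters(labels, means, sig)
    return LsdResult(groups=labels, means=means, ns=ns, F=float(F), p=float(p),
                     letters=letters, mse=mse, df_error=df_w, alpha=alpha,
                     pairwise_p=pd.DataFrame(pair_p, index=labels, columns=labels))


def anova_lsd(values, groups, alpha: float = 0.05) -> LsdResult:
    """One-way ANOVA with protected LSD letters on raw observations."""
    df = pd.DataFrame({"g": np.asarray(groups), "v": np.asarray(values, dtype=float)})
    df = df.dropna()
    labels, means, sds, ns = [], [], [], []
    for g, sub in df.groupby("g", sort=False):
        labels.append(g)
        means.append(sub["v"].mean())
        sds.append(sub["v"].std(ddof=1))
        ns.append(len(sub))
    if any(n < 2 for n in ns):
        small = [lab for lab, n in zip(labels, ns) if n < 2]
        raise ValueError(f"groups with n < 2: {small}")
    return anova_from_summary(means, sds, ns, labels=labels, alpha=alpha)


# ---------------------------------------------------------------------------
# Linear and two-phase regression


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float  # two-sided p for the slope
    n: int
    conf: float
    x_mean: float
    sxx: float
    resid_var: float  # s^2 with n-2 dof

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise band for the conditional mean at ``x`` (narrowest at x-bar)."""
        x = np.asarray(x, dtype=float)
        se = np.sqrt(self.resid_var * (1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx))
        tq = stats.t.ppf(0.5 + self.conf / 2.0, self.n - 2)
        yhat = self.predict(x)
        return yhat - tq * se, yhat + tq * se


def linear_fit(x, y, conf: float = 0.95) -> LinearFit:
    """Ordinary least squares of y on x with confidence-band support."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is unidentifiable")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    s2 = sse / (n - 2)
    if s2 == 0:
        p = 0.0
    else:
        t = slope / np.sqrt(s2 / sxx)
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return LinearFit(slope=slope, intercept=intercept, r2=r2, p=p, n=n,
                     conf=conf, x_mean=xm, sxx=sxx, resid_var=s2)


@dataclass
class SegmentLine:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass
class SegmentedFit:
    breakpoint: float
    below: SegmentLine
    above: SegmentLine
    sse: float
    search_grid: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def searched(self) -> bool:
        return self.search_grid.size > 0


def _segment(x, y, conf: float) -> tuple[SegmentLine, float]:
    fit = linear_fit(x, y, conf=conf)
    sse = fit.resid_var * (fit.n - 2)
    return SegmentLine(fit.slope, fit.intercept, fit.r2, fit.p, fit.n), sse


def threshold_fit(x, y, breakpoint: float | None = None,
                  min_segment: int = 3, conf: float = 0.95) -> SegmentedFit:
    """Two-phase (threshold) regression: independent OLS lines per side.

    ``breakpoint=None`` searches the midpoints between consecutive sorted
    unique x values, keeping candidates that leave at least
    ``min_segment`` points per side, and selects the one minimising the
    total residual sum of squares (ties toward the smaller breakpoint).
    Observations with x equal to the breakpoint fall in the lower segment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]

    def fit_at(bp: float) -> SegmentedFit:
        lo = x <= bp
        n_lo, n_hi = int(lo.sum()), int((~lo).sum())
        if n_lo < min_segment or n_hi < min_segment:
            raise ValueError(
                f"breakpoint {bp} leaves {n_lo}/{n_hi} points below/above; "
                f"each segment needs >= {min_segment}")
        below, sse_lo = _segment(x[lo], y[lo], conf)
        above, sse_hi = _segment(x[~lo], y[~lo], conf)
        return SegmentedFit(breakpoint=bp, below=below, above=above,
                            sse=sse_lo + sse_hi)

    if breakpoint is not None:
        return fit_at(float(breakpoint))

    xs = np.unique(x)
    mids = (xs[:-1] + xs[1:]) / 2.0
    grid = np.array([bp for bp in mids
                     if (x <= bp).sum() >= min_segment
                     and (x > bp).sum() >= min_segment])
    if grid.size == 0:
        raise ValueError(
            f"no candidate breakpoint leaves >= {min_segment} points per side "
            f"(n = {len(x)})")
    best: SegmentedFit | None = None
    for bp in grid:  # ascending, so strict < keeps the smaller bp on ties
        cand = fit_at(float(bp))
        if best is None or cand.sse < best.sse:
            best = cand
    assert best is not None
    best.search_grid = grid
    return best
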