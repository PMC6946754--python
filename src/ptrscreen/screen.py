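"""Screening statistics for transgenic-line emission tables.

Per-compound genotype comparisons use Welch's heteroscedastic one-way
test (group variances are wildly unequal between wild type and emitting
transgenics), with Bonferroni correction over the family of compounds
tested and a compact letter display from pairwise Welch t-tests.
Distribution diagnostics (median, moment skewness/kurtosis, Shapiro–Wilk)
describe the spread of emissions across lines; emission–expression
association uses closed-form least squares with a case-resampling
bootstrap (N = 1999) for the 95 % confidence band; whole-profile
similarity between genotypes is the squared Pearson correlation of their
per-ion emission vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "DistributionSummary",
    "RegressionResult",
    "welch_anova",
    "pairwise_welch_p",
    "letter_groups",
    "bonferroni",
    "significance_stars",
    "distribution_summary",
    "ols_bootstrap",
    "profile_correlation",
    "select_lines",
    "fold_change",
    "compare_genotypes",
]


# ---------------------------------------------------------------------------
# Welch's heteroscedastic one-way test (closed form)

def welch_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, tuple[float, float], float]:
    """Welch's one-way test for ≥2 groups with unequal variances.

    Returns ``(F, (df1, df2), p)`` where the statistic is

        F = Σ w_i (x̄_i − x̄_w)² / (k − 1)
            ───────────────────────────────
            1 + 2(k − 2)/(k² − 1) · Σ (1 − w_i/W)²/(n_i − 1)

    with weights w_i = n_i/s_i², W = Σ w_i, weighted grand mean x̄_w, and
    Welch–Satterthwaite denominator degrees of freedom
    df2 = (k² − 1) / (3 Σ (1 − w_i/W)²/(n_i − 1)).
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(groups[k], dtype=float) for k in keys]
    n = np.array([a.size for a in arrs], dtype=float)
    if np.any(n < 2):
        small = keys[int(np.argmin(n))]
        raise ValueError(f"group {small!r} has fewer than 2 observations")
    mean = np.array([a.mean() for a in arrs])
    var = np.array([a.var(ddof=1) for a in arrs])
    if np.all(var == 0):
        raise ValueError("all groups have zero variance")
    w = n / var
    W = w.sum()
    xw = (w * mean).sum() / W
    k = len(keys)
    num = (w * (mean - xw) ** 2).sum() / (k - 1)
    h = ((1 - w / W) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * h
    F = num / den
    df1 = k - 1.0
    df2 = (k ** 2 - 1) / (3 * h)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def pairwise_welch_p(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Symmetric matrix of two-sided Welch t-test p-values between groups."""
    keys = list(groups)
    m = pd.DataFrame(np.ones((len(keys), len(keys))), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            p = stats.ttest_ind(np.asarray(groups[a], float),
                                np.asarray(groups[b], float),
                                equal_var=False).pvalue
            m.loc[a, b] = m.loc[b, a] = float(p)
    return m


# ---------------------------------------------------------------------------
# compact letter display

def letter_groups(p_matrix: pd.DataFrame, means: Mapping[str, float],
                  alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by greedy insert-and-absorb.

    Genotypes are processed in ascending order of mean (so 'a' marks the
    lowest-mean group, as in the reference-first table convention).  Each
    genotype joins every letter column none of whose members it differs
    from significantly; where it conflicts with only part of a column,
    the column is duplicated without the conflicting members (so chains
    like a / ab / b come out correctly); letters that end up as subsets
    of another are absorbed.  The output is a deterministic function of
    the p-matrix and the means, and guarantees that two genotypes share
    a letter exactly when their pairwise p ≥ alpha.
    """
    if not p_matrix.index.equals(p_matrix.columns):
        raise ValueError("p-matrix must be square with matching labels")
    order = sorted(p_matrix.index, key=lambda g: (means[g], str(g)))
    letters: list[set] = []
    for g in order:
        joined = False
        new_cols: list[set] = []
        for members in letters:
            conflicts = {h for h in members if p_matrix.loc[g, h] < alpha}
            if not conflicts:
                members.add(g)
                joined = True
            elif members - conflicts:
                new_cols.append((members - conflicts) | {g})
        if not joined and not new_cols:
            new_cols.append({g})
        letters.extend(new_cols)
        # absorb: drop columns contained in another, dedupe
        letters = [s for i, s in enumerate(letters)
                   if not any(s <= t for j, t in enumerate(letters) if i != j
                              and (s < t or (s == t and j < i)))]
    kept = letters
    labels = "abcdefghijklmnopqrstuvwxyz"
    # order letters by the mean of their lowest member for stable naming
    kept.sort(key=lambda s: min((means[g], str(g)) for g in s))
    out = {g: "" for g in p_matrix.index}
    for lab, members in zip(labels, kept):
        for g in members:
            out[g] += lab
    return {g: "".join(sorted(out[g])) for g in p_matrix.index}


# ---------------------------------------------------------------------------
# multiple testing

def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, m·p); m defaults to len(p)."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of p-values")
    return [min(1.0, m * float(x)) for x in p]


def significance_stars(p: float) -> str:
    """Significance codes 0 '***' 0.001 '**' 0.01 '*' 0.05 '' 1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# distribution diagnostics

@dataclass
class DistributionSummary:
    n: int
    median: float
    skewness: float          # moment coefficient g1 = m3 / m2^1.5
    excess_kurtosis: float   # g2 = m4 / m2² − 3
    shapiro_w: float
    shapiro_p: float
    convention: str = "moment g1 / excess g2 (no small-sample correction)"


def distribution_summary(values: Sequence[float]) -> DistributionSummary:
    """Median, g1 skewness, g2 excess kurtosis and Shapiro–Wilk normality.

    Moment conventions (population g1/g2, no small-sample bias
    correction) are recorded in the output so results are auditable
    against software using Fisher-corrected estimators.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: Shapiro-Wilk undefined")
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    g1 = np.mean(m ** 3) / m2 ** 1.5
    g2 = np.mean(m ** 4) / m2 ** 2 - 3.0
    w, p = stats.shapiro(x)
    return DistributionSummary(
        n=int(x.size), median=float(np.median(x)),
        skewness=float(g1), excess_kurtosis=float(g2),
        shapiro_w=float(w), shapiro_p=float(p),
    )


# ---------------------------------------------------------------------------
# regression with bootstrap band

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_uncorrelated: float
    x_grid: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    n_boot: int
    seed: int
    method: str = "case"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def ols_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1999,
    seed: int = 0,
    n_grid: int = 50,
    method: str = "case",
) -> RegressionResult:
    """Least-squares line with a bootstrap 95 % confidence band.

    The point fit is closed-form OLS; its p-value against the null of no
    correlation is the two-sided t-test on the slope.  The band is the
    pointwise 2.5/97.5 percentile of the fitted line over ``n_boot``
    bootstrap replicates — case resampling by default (pairs (x, y)
    resampled with replacement), residual resampling as an option —
    evaluated on an even x-grid.  Reproducible from ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    slope, intercept = _ols(x, y)
    resid = y - (intercept + slope * x)
    sxx = np.sum((x - x.mean()) ** 2)
    ssr = np.sum(resid ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if sst == 0 else 1.0 - ssr / sst
    if ssr <= 0:
        p = 0.0
    else:
        se = np.sqrt(ssr / (n - 2) / sxx)
        t = slope / se
        p = float(2 * stats.t.sf(abs(t), n - 2))

    rng = np.random.default_rng(seed)
    grid = np.linspace(x.min(), x.max(), n_grid)
    # vectorized bootstrap: one (n_boot, n) index matrix, closed-form slopes
    if method == "case":
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
    elif method == "residual":
        idx = rng.integers(0, n, size=(n_boot, n))
        xb = np.broadcast_to(x, (n_boot, n))
        yb = intercept + slope * xb + resid[idx]
    else:
        raise ValueError("method must be 'case' or 'residual'")
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxxb = np.sum((xb - xm) ** 2, axis=1)
    sxxb = np.where(sxxb == 0, np.nan, sxxb)
    slopes = np.sum((xb - xm) * (yb - ym), axis=1) / sxxb
    intercepts = ym[:, 0] - slopes * xm[:, 0]
    lines = intercepts[:, None] + slopes[:, None] * grid[None, :]
    lo = np.nanpercentile(lines, 2.5, axis=0)
    hi = np.nanpercentile(lines, 97.5, axis=0)
    fit_line = intercept + slope * grid
    lo = np.minimum(lo, fit_line)
    hi = np.maximum(hi, fit_line)
    return RegressionResult(
        slope=float(slope), intercept=float(intercept), r_squared=float(r2),
        p_uncorrelated=p, x_grid=grid, ci_lower=lo, ci_upper=hi,
        n=n, n_boot=n_boot, seed=seed, method=method,
    )


# ---------------------------------------------------------------------------
# profile correlation

def profile_correlation(profile_a: Sequence[float], profile_b: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation between two emission profiles.

    The inputs are per-ion emission vectors of equal length (e.g. the
    full spectral profile of each genotype); returns (R², p) where p is
    the two-sided t-test of zero correlation.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance profile")
    r, p = stats.pearsonr(a, b)
    return float(r ** 2), float(p)


# ---------------------------------------------------------------------------
# line ranking / selection

def select_lines(
    per_line: Mapping[str, float] | pd.Series,
    top_k: int | None = None,
    thresholds: Sequence[tuple[str, float]] = (),
) -> tuple[pd.Series, dict[str, int]]:
    """Rank lines by emission and count threshold strata.

    ``per_line`` maps line → summary emission (mean over replicate vials,
    computed upstream).  Returns the ranked series (descending emission,
    ties broken by line ID for determinism; truncated to ``top_k`` if
    given) and a dict of counts for each ``('<'|'>', value)`` stratum.
    """
    s = pd.Series(dict(per_line), dtype=float)
    ranked = s.sort_index().sort_values(ascending=False, kind="stable")
    counts: dict[str, int] = {}
    for op, val in thresholds:
        if op == "<":
            counts[f"<{val:g}"] = int((s < val).sum())
        elif op == ">":
            counts[f">{val:g}"] = int((s > val).sum())
        else:
            raise ValueError("threshold op must be '<' or '>'")
    if top_k is not None:
        ranked = ranked.head(top_k)
    return ranked, counts


def fold_change(delta_delta_ct: float) -> float:
    """Relative expression by the ΔΔCt method: fold change = 2^(−ΔΔCt)."""
    return float(2.0 ** (-np.asarray(delta_delta_ct, dtype=float)))


# ---------------------------------------------------------------------------
# per-compound genotype comparison (table-style output)

@dataclass
class GroupComparison:
    """Welch/Bonferroni comparison of genotype means for one compound."""

    mz: float
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    welch_f: float
    welch_df: tuple[float, float]
    p_value: float
    p_adjusted: float
    stars: str
    letters: dict[str, str]


def compare_genotypes(
    emissions: pd.DataFrame,
    genotype_of: Mapping[str, str],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Per-compound Welch comparison across genotypes.

    ``emissions`` is a samples × ions table (columns = m/z, index =
    sample IDs); ``genotype_of`` maps sample ID → genotype.  The
    Bonferroni family size defaults to the number of compound columns
    (one adjusted significance per compound row).  Letters come from
    unadjusted pairwise Welch t-tests at ``alpha``, 'a' marking the
    lowest-mean genotype.
    """
    cols = list(emissions.columns)
    m = family_size if family_size is not None else len(cols)
    geno = pd.Series({s: genotype_of[s] for s in emissions.index})
    out: list[GroupComparison] = []
    raw_ps = []
    for mz in cols:
        groups = {g: emissions.loc[geno[geno == g].index, mz].to_numpy()
                  for g in sorted(geno.unique())}
        F, df, p = welch_anova(groups)
        raw_ps.append(p)
        pw = pairwise_welch_p(groups)
        means = {g: float(np.mean(v)) for g, v in groups.items()}
        letters = letter_groups(pw, means, alpha)
        out.append(GroupComparison(
            mz=float(mz), means=means,
            sds={g: float(np.std(v, ddof=1)) for g, v in groups.items()},
            ns={g: int(len(v)) for g, v in groups.items()},
            welch_f=F, welch_df=df, p_value=p,
            p_adjusted=np.nan, stars="", letters=letters,
        ))
    adj = bonferroni(raw_ps, m)
    for gc, pa in zip(out, adj):
        gc.p_adjusted = float(pa)
        gc.stars = significance_stars(pa)
    return out
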