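"""Paired-comparison and repeated-measures statistics.

The battery mirrors common practice in human-factors studies:

* paired condition contrasts are normality-gated — a Shapiro-Wilk test
  on the paired differences routes to Student's paired t-test when the
  differences look normal and to the Wilcoxon signed-rank test
  otherwise;
* effect sizes follow the test: paired Cohen's d for Student, matched
  rank-biserial correlation for Wilcoxon;
* three-level within-subject factors go through a one-way
  repeated-measures ANOVA with Mauchly's sphericity test and, on
  violation, Huynh-Feldt degrees-of-freedom correction, followed by
  pairwise post-hoc paired t-tests with Holm adjustment.

The Wilcoxon test handles zero differences by Pratt's method (zeros are
ranked, then discarded), uses mid-ranks for ties, no continuity
correction, and computes the exact null distribution of the positive
rank sum by dynamic programming for small samples (the normal
approximation with tie/zero variance corrections otherwise).

Comparisons are always first-listed minus second-listed, so the sign of
an effect is negative when the second condition exceeds the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_LIMIT = 25


@dataclass(frozen=True)
class StatResult:
    """Outcome of one gated paired comparison."""

    test_name: str  # "student-paired" or "wilcoxon-signed-rank"
    statistic: float
    z: float | None
    p_value: float
    effect_size: float
    shapiro_p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    p_value: float
    p_adjusted: float
    effect_size: float
    correction_method: str


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling."""

    f_statistic: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_p: float
    correction: str  # "none" or "huynh-feldt"
    epsilon_hf: float
    corrected_p: float
    posthoc: tuple[PosthocResult, ...]


def shapiro_gate(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[str, float]:
    """Choose the paired test from a Shapiro-Wilk test on differences."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.allclose(d, d[0]):
        # Shapiro is undefined on constant input; the comparison itself
        # is degenerate and flagged downstream.
        return "student-paired", 1.0
    shapiro_p = float(sps.shapiro(d).pvalue)
    test = "wilcoxon-signed-rank" if shapiro_p < alpha else "student-paired"
    return test, shapiro_p


def _signed_rank_stats(d: np.ndarray) -> tuple[float, float, float, float, np.ndarray, int]:
    """Pratt signed ranks: (w_plus, w_minus, mu, sigma, nonzero_ranks, n_zero)."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    nonzero = d != 0
    n0 = int(n - nonzero.sum())
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
    # mid-rank tie correction over nonzero groups
    _, counts = np.unique(np.abs(d[nonzero]), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    return w_plus, w_minus, mu, np.sqrt(var), ranks[nonzero], n0


def _exact_wplus_pvalue(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the positive rank sum by DP over sign patterns.

    Works with tied mid-ranks (half-integers) by doubling to integers.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r] if r > 0 else counts
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    d: np.ndarray, exact_limit: int = EXACT_WILCOXON_LIMIT
) -> tuple[float, float, float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Returns ``(w_plus, z, p_value, rank_biserial)``.  Zeros are handled
    by Pratt's method; p-values come from the exact positive-rank-sum
    distribution when the number of pairs is at most ``exact_limit``,
    otherwise from the normal approximation (no continuity correction).
    """
    d = np.asarray(d, float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    w_plus, w_minus, mu, sigma, nz_ranks, n0 = _signed_rank_stats(d)
    if w_plus + w_minus == 0:
        raise ValueError("all differences are zero; test degenerate")
    z = (w_plus - mu) / sigma if sigma > 0 else 0.0
    if d.size <= exact_limit:
        p = _exact_wplus_pvalue(w_plus, nz_ranks)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    rank_biserial = (w_plus - w_minus) / (w_plus + w_minus)
    return float(w_plus), float(z), p, float(rank_biserial)


def paired_compare(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> StatResult:
    """Shapiro-gated paired comparison with the matching effect size.

    Differences are ``x - y``: the effect size is negative when the
    second sample exceeds the first.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    test, shapiro_p = shapiro_gate(x, y, alpha)
    d = x - y
    n = d.size
    if np.std(d, ddof=1) == 0:
        return StatResult(
            test_name=test, statistic=np.nan, z=None, p_value=np.nan,
            effect_size=np.nan, shapiro_p=shapiro_p, n=n, degenerate=True,
        )
    if test == "student-paired":
        res = sps.ttest_rel(x, y)
        cohen_d = float(np.mean(d) / np.std(d, ddof=1))
        return StatResult(
            test_name=test, statistic=float(res.statistic), z=None,
            p_value=float(res.pvalue), effect_size=cohen_d,
            shapiro_p=shapiro_p, n=n,
        )
    w_plus, z, p, rb = wilcoxon_signed_rank(d)
    return StatResult(
        test_name=test, statistic=w_plus, z=z, p_value=p,
        effect_size=rb, shapiro_p=shapiro_p, n=n,
    )


def _orthonormal_contrast_cov(data: np.ndarray) -> np.ndarray:
    n, k = data.shape
    c = helmert(k, full=False)  # (k-1) x k, orthonormal rows
    s = np.cov(data, rowvar=False, ddof=1)
    return c @ s @ c.T


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an n-by-k repeated-measures array.

    Returns ``(W, p_value)`` from the chi-square approximation.  With
    two levels sphericity holds trivially and ``(1.0, 1.0)`` is
    returned.
    """
    data = np.asarray(data, float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if k == 2:
        return 1.0, 1.0
    if n <= k:
        raise ValueError("need more subjects than conditions")
    sc = _orthonormal_contrast_cov(data)
    eig = np.linalg.eigvalsh(sc)
    d = k - 1
    if eig.min() <= np.finfo(float).eps * max(eig.max(), 1.0) * d:
        # singular contrast covariance: sphericity maximally violated
        return 0.0, 0.0
    w = float(np.prod(eig) / np.mean(eig) ** d)
    # chi-square approximation with the second-order Box correction
    df = d * (d + 1) / 2 - 1
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    chi2 = -(n - 1) * f * np.log(w)
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, p


def epsilon_gg(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity-correction factor."""
    data = np.asarray(data, float)
    k = data.shape[1]
    eig = np.clip(np.linalg.eigvalsh(_orthonormal_contrast_cov(data)), 0, None)
    d = k - 1
    denom = d * (eig**2).sum()
    if denom == 0:
        return 1.0  # degenerate (constant) contrasts; correction vacuous
    eps = eig.sum() ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def epsilon_hf(data: np.ndarray) -> float:
    """Huynh-Feldt correction factor (capped at 1, floored at 1/(k-1))."""
    data = np.asarray(data, float)
    n, k = data.shape
    d = k - 1
    gg = epsilon_gg(data)
    hf = (n * d * gg - 2.0) / (d * (n - 1.0 - d * gg))
    return float(np.clip(hf, 1.0 / d, 1.0))


def rm_anova(
    data: np.ndarray,
    condition_names: list[str] | None = None,
    alpha_sphericity: float = 0.05,
    posthoc_adjust: str = "holm",
) -> AnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, k_conditions)
        Complete cases only (rows with missing values are rejected).
    condition_names : list of str, optional
        Labels for the post-hoc pairs, in column order.
    alpha_sphericity : float
        Mauchly threshold below which the Huynh-Feldt correction is
        applied to the F-test degrees of freedom.
    posthoc_adjust : {"holm", "bonferroni", "none"}
        Multiplicity adjustment for the pairwise post-hoc p-values.
    """
    data = np.asarray(data, float)
    if np.isnan(data).any():
        raise ValueError("missing cells; repeated-measures ANOVA needs complete cases")
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    names = condition_names or [f"c{j}" for j in range(k)]

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_err = np.sum((data - subj_means[:, None] - cond_means[None, :] + grand) ** 2)
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    # treat round-off level sums of squares as exact zeros
    tiny = 1e-12 * max(np.sum(data**2), 1.0)
    ss_cond, ss_err = (0.0 if s < tiny else s for s in (ss_cond, ss_err))
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    if ms_err == 0:
        f_stat, p_unc = (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
    else:
        f_stat = ms_cond / ms_err
        p_unc = float(sps.f.sf(f_stat, df1, df2))

    w, mauchly_p = mauchly_test(data)
    if mauchly_p < alpha_sphericity:
        correction = "huynh-feldt"
        eps = epsilon_hf(data)
        corrected_p = float(sps.f.sf(f_stat, eps * df1, eps * df2)) if ms_err > 0 else p_unc
    else:
        correction = "none"
        eps = epsilon_hf(data)
        corrected_p = p_unc

    raw_p, effects = [], []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        sd = np.std(d, ddof=1)
        if sd == 0:
            raw_p.append(1.0)
            effects.append(0.0)
        else:
            raw_p.append(float(sps.ttest_rel(data[:, i], data[:, j]).pvalue))
            effects.append(float(np.mean(d) / sd))
    if posthoc_adjust == "none":
        adj = list(raw_p)
    else:
        adj = list(multipletests(raw_p, method=posthoc_adjust)[1])
    posthoc = tuple(
        PosthocResult(
            pair=(names[i], names[j]),
            p_value=raw_p[m],
            p_adjusted=adj[m],
            effect_size=effects[m],
            correction_method=posthoc_adjust,
        )
        for m, (i, j) in enumerate(pairs)
    )
    return AnovaResult(
        f_statistic=float(f_stat), df1=df1, df2=df2, p_uncorrected=p_unc,
        mauchly_w=w, mauchly_p=mauchly_p, correction=correction,
        epsilon_hf=eps, corrected_p=corrected_p, posthoc=posthoc,
    )
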