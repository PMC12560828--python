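"""Shared statistical primitives.

Two-sample Student's t, Holm step-down adjustment, exact small-sample
Spearman rank test, one-way ANOVA, Dunn's rank-based post-hoc test with
compact letter display, and interquartile-range outlier flagging.

The t-test defaults to the pooled-variance (equal-variance) form; a
``pooled=False`` flag exposes Welch's test for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "student_t_two_sided",
    "holm_adjust",
    "spearman_exact",
    "anova_oneway",
    "kruskal_oneway",
    "dunn_test",
    "iqr_outliers",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``direction`` is the sign of the estimated effect (+1, -1 or 0);
    ``exact`` marks p-values computed by full enumeration rather than a
    distributional approximation.  ``estimate`` carries the test's
    natural effect measure (mean difference, rho, F, ...).
    """

    statistic: float
    p_value: float
    df: float | None = None
    exact: bool = False
    direction: int = 0
    estimate: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def student_t_two_sided(x, y, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t-test.

    Pooled-variance Student's t by default; Welch with ``pooled=False``.
    Identical constant samples give t=0, p=1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(np.mean(x) - np.mean(y))
    direction = int(np.sign(diff))
    if np.var(x) == 0 and np.var(y) == 0 and diff == 0:
        df = x.size + y.size - 2 if pooled else float(x.size + y.size - 2)
        return TestResult(0.0, 1.0, df=df, direction=0, estimate=0.0)
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        df=float(res.df),
        direction=direction,
        estimate=diff,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _spearman_rho(rx, ry):
    n = rx.shape[-1]
    d2 = np.sum((rx - ry) ** 2, axis=-1)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))


def spearman_exact(x, y) -> TestResult:
    """Spearman rank correlation with an exact permutation p-value.

    For tie-free samples of size <= 10 the two-sided p-value is computed
    by enumerating all n! rank permutations; otherwise (ties present or
    n > 10) the t-distribution approximation is used and ``exact`` is
    False.  Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("samples must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    rho = float(sps.spearmanr(x, y).statistic)
    if ties or n > 10:
        # t approximation, matching scipy's default
        p = float(sps.spearmanr(x, y).pvalue)
        return TestResult(rho, min(p, 1.0), exact=False,
                          direction=int(np.sign(rho)), estimate=rho)
    # exact: enumerate the permutation distribution of rho in chunks
    total = math.factorial(n)
    count = 0
    abs_obs = abs(rho) - 1e-12
    chunk = []
    for perm in itertools.permutations(range(1, n + 1)):
        chunk.append(perm)
        if len(chunk) == 40320:  # 8! rows per vectorised block
            rhos = _spearman_rho(np.asarray(chunk, float), rx)
            count += int(np.sum(np.abs(rhos) >= abs_obs))
            chunk = []
    if chunk:
        rhos = _spearman_rho(np.asarray(chunk, float), rx)
        count += int(np.sum(np.abs(rhos) >= abs_obs))
    p = count / total
    return TestResult(rho, p, exact=True, direction=int(np.sign(rho)),
                      estimate=rho)


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA F-test across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        k = len(groups)
        return TestResult(0.0, 1.0, df=float(k - 1), estimate=0.0)
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      df=float(len(groups) - 1), estimate=float(res.statistic))


def kruskal_oneway(groups) -> TestResult:
    """Kruskal-Wallis rank test, the nonparametric global companion to Dunn."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return TestResult(0.0, 1.0, df=float(len(groups) - 1))
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      df=float(len(groups) - 1))


@dataclass(frozen=True)
class DunnResult:
    """Pairwise Dunn comparisons plus a compact letter display.

    ``z`` and ``p_adjusted`` are symmetric k x k arrays over groups;
    ``letters[i]`` is the letter string of group i (groups sharing a
    letter are not significantly different at ``alpha``).
    """

    labels: tuple
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    letters: tuple
    alpha: float


def _compact_letters(labels, nonsig):
    """Insert-and-absorb compact letter display from a no-difference matrix."""
    k = len(labels)
    # each letter group is a set of indices that are mutually non-different
    groups: list[set] = []
    for i in range(k):
        placed = False
        for g in groups:
            if all(nonsig[i, j] for j in g):
                g.add(i)
                placed = True
        if not placed:
            groups.append({i})
    # absorb: drop letter groups fully contained in another
    groups = [g for g in groups
              if not any(g < h for h in groups)]
    # deterministic order by smallest member
    groups.sort(key=min)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for li, g in enumerate(groups):
        for i in sorted(g):
            letters[i] += alphabet[li % 26]
    return tuple(letters)


def dunn_test(groups, labels=None, p_adjust: str = "holm",
              alpha: float = 0.05) -> DunnResult:
    """Dunn's post-hoc test on joint ranks with tie correction.

    All observations are ranked jointly (average ranks for ties); the
    pairwise statistic is z = (Rbar_i - Rbar_j)/SE with
    SE^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j).
    Pairwise two-sided p-values are adjusted (Holm by default,
    ``p_adjust=None`` for raw) and a compact letter display is derived
    from the resulting significance graph.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(groups)))
    labels = tuple(labels)
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    allv = np.concatenate(groups)
    N = allv.size
    ranks = sps.rankdata(allv)
    means = []
    start = 0
    for n in sizes:
        means.append(ranks[start:start + n].mean())
        start += n
    means = np.array(means)
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    z = np.zeros((k, k))
    p = np.ones((k, k))
    pairs = list(itertools.combinations(range(k), 2))
    pvec = []
    for i, j in pairs:
        se2 = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:  # all observations tied
            zij, pij = 0.0, 1.0
        else:
            zij = (means[i] - means[j]) / math.sqrt(se2)
            pij = 2.0 * sps.norm.sf(abs(zij))
        z[i, j], z[j, i] = zij, -zij
        p[i, j] = p[j, i] = pij
        pvec.append(pij)
    if p_adjust is None:
        padj_vec = np.asarray(pvec)
    elif p_adjust == "holm":
        padj_vec = holm_adjust(pvec)
    else:
        padj_vec = multipletests(pvec, method=p_adjust)[1]
    padj = np.ones((k, k))
    for (i, j), pa in zip(pairs, padj_vec):
        padj[i, j] = padj[j, i] = pa
    nonsig = padj > alpha
    np.fill_diagonal(nonsig, True)
    letters = _compact_letters(labels, nonsig)
    return DunnResult(labels, z, p, padj, letters, alpha)


def iqr_outliers(values) -> np.ndarray:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use the linear-interpolation (type-7) convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR screening")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
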