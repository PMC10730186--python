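"""Group comparisons, exact contingency tests, multiplicity control, and
classifier metrics.

Conventions chosen to match how small surgical-cohort tables are analyzed in
practice: the 2×2 chi-square carries no continuity correction, the two-sided
Fisher p-value sums hypergeometric point probabilities no larger than the
observed table's, and the Freeman–Halton test generalizes that rule to 2×K
tables by full enumeration over the fixed margins.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from math import exp, lgamma
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "ContingencyTable",
    "ClassifierMetrics",
    "PosthocResult",
    "anova_oneway",
    "posthoc_pairwise",
    "kruskal_wallis",
    "spearman",
    "chi_square_2x2",
    "chi_square_rxc",
    "fisher_exact_2x2",
    "freeman_halton_exact",
    "select_categorical_test",
    "bonferroni_alpha",
    "classifier_metrics",
]

# slack used when comparing hypergeometric point probabilities for ties
_EXACT_TIE_SLACK = 1e-7


@dataclass
class TestResult:
    """A named test statistic with its p-value (df where defined)."""

    method: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable:
    """Nonnegative integer outcome table; rows are groups, columns outcomes."""

    cells: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    column_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 2 or min(self.cells.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.cells < 0):
            raise ValueError("contingency table cells must be nonnegative")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.cells.shape[0])]
        if not self.column_labels:
            self.column_labels = [f"col{j}" for j in range(self.cells.shape[1])]


def _as_cells(table: ContingencyTable | np.ndarray | Sequence) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.cells
    arr = np.asarray(table, dtype=np.int64)
    return ContingencyTable(arr).cells  # validates


@dataclass
class ClassifierMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class PosthocResult:
    """Pairwise adjusted p-values plus a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``
    (the "(a, b)" convention of diversity summary tables).
    """

    method: str
    p_values: pd.DataFrame       # symmetric, NaN diagonal
    letters: dict[str, str]
    alpha: float


# ---------------------------------------------------------------------------
# group comparisons


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F test."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # zero within- and between-variance (all identical)
        stat, p = 0.0, 1.0
    return TestResult("anova", stat, p, df=(k - 1, n - k))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from chi-square(k−1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    k = len(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, df=k - 1)
    res = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue), df=k - 1)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation on mid-ranks; two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", np.nan, np.nan, note="constant input; rho undefined")
    res = stats.spearmanr(x, y)
    return TestResult("spearman", float(res.statistic), float(res.pvalue), df=x.size - 2)


# ---------------------------------------------------------------------------
# post-hoc procedures


def _compact_letter_display(labels: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``nonsig`` holds unordered pairs that are NOT significantly different;
    groups sharing a letter must all be pairwise non-significant.
    """
    # start from the full set, split on each significant pair, absorb subsets
    cliques: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if (a, b) in nonsig or (b, a) in nonsig:
            continue
        new = []
        for cl in cliques:
            if a in cl and b in cl:
                new.extend([cl - {a}, cl - {b}])
            else:
                new.append(cl)
        cliques = new
    cliques = [cl for cl in cliques if cl and not any(cl < other for other in cliques if other is not cl)]
    seen: list[set[str]] = []
    for cl in cliques:
        if cl not in seen:
            seen.append(cl)
    cliques = seen
    cliques.sort(key=lambda cl: min(labels.index(x) for x in cl))
    letters = {lab: "" for lab in labels}
    for letter, cl in zip(string.ascii_lowercase, cliques):
        for lab in sorted(cl, key=labels.index):
            letters[lab] += letter
    return letters


def _dunn_pairwise(arrays: list[np.ndarray]) -> np.ndarray:
    """Dunn's z-test on pooled mid-ranks with tie correction; Bonferroni-adjusted."""
    k = len(arrays)
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    m = k * (k - 1) // 2
    p = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) *
                     (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0:
            pij = 1.0
        else:
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = min(1.0, 2.0 * stats.norm.sf(z) * m)
        p[i, j] = p[j, i] = pij
    return p


def _duncan_pairwise(arrays: list[np.ndarray], alpha: float) -> np.ndarray:
    """Duncan's multiple range test, expressed as pairwise p-values.

    Means are ordered and each pair is tested against the studentized-range
    distribution with the span-dependent significance level
    1 − (1 − alpha)^(r−1) of Duncan's procedure.  The returned "p-values" are
    the studentized-range tail probabilities rescaled so that comparing to
    ``alpha`` reproduces the Duncan accept/reject decision — an approximate
    device (the classical test is a fixed-level multiple range procedure, not
    a p-value one).
    """
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df_w = n - k
    means = np.array([a.mean() for a in arrays])
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_w = ss_w / df_w if df_w > 0 else 0.0
    order = np.argsort(means)
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    p = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        if ms_w == 0:
            p[i, j] = p[j, i] = 1.0 if means[i] == means[j] else 0.0
            continue
        span = abs(rank_of[i] - rank_of[j]) + 1  # number of ordered means covered
        n_h = 2.0 / (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        q = abs(means[i] - means[j]) / np.sqrt(ms_w / n_h)
        p_range = float(stats.studentized_range.sf(q, span, df_w))
        # Duncan's protection level for a span of r means
        level = 1.0 - (1.0 - alpha) ** (span - 1)
        # rescale so p < alpha  <=>  p_range < level
        p[i, j] = p[j, i] = min(1.0, p_range * alpha / level)
    return p


def posthoc_pairwise(groups: Sequence[Sequence[float]],
                     method: Literal["tukey", "dunn", "duncan"] = "tukey",
                     labels: Sequence[str] | None = None,
                     alpha: float = 0.05) -> PosthocResult:
    """Pairwise adjusted p-values with a compact letter display."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    labels = list(labels)
    k = len(arrays)
    if method == "tukey":
        if all(np.all(a == arrays[0][0]) for a in arrays):
            p = np.full((k, k), 1.0)
            np.fill_diagonal(p, np.nan)
        else:
            res = stats.tukey_hsd(*arrays)
            p = np.asarray(res.pvalue, dtype=float).copy()
            np.fill_diagonal(p, np.nan)
    elif method == "dunn":
        p = _dunn_pairwise(arrays)
    elif method == "duncan":
        p = _duncan_pairwise(arrays, alpha)
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    pdf = pd.DataFrame(p, index=labels, columns=labels)
    nonsig = {
        (labels[i], labels[j])
        for i, j in itertools.combinations(range(k), 2)
        if not (p[i, j] < alpha)
    }
    letters = _compact_letter_display(labels, nonsig)
    return PosthocResult(method=method, p_values=pdf, letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# contingency tests


def chi_square_2x2(table: ContingencyTable | np.ndarray | Sequence) -> TestResult:
    """Pearson chi-square on a 2×2 table, no continuity correction, df=1."""
    cells = _as_cells(table)
    if cells.shape != (2, 2):
        raise ValueError("chi_square_2x2 requires a 2x2 table")
    if np.any(cells.sum(axis=0) == 0) or np.any(cells.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(cells, correction=False)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue), df=1)


def chi_square_rxc(table: ContingencyTable | np.ndarray | Sequence) -> TestResult:
    """Pearson chi-square on an r×c table (asymptotic)."""
    cells = _as_cells(table)
    if np.any(cells.sum(axis=0) == 0) or np.any(cells.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(cells, correction=False)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue), df=float(res.dof))


def fisher_exact_2x2(table: ContingencyTable | np.ndarray | Sequence) -> TestResult:
    """Two-sided Fisher exact test by point-probability ordering."""
    cells = _as_cells(table)
    if cells.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    res = stats.fisher_exact(cells, alternative="two-sided")
    return TestResult("fisher_exact", float(res.statistic), float(res.pvalue))


def _log_table_prob(cells: np.ndarray, row_sums: np.ndarray,
                    col_sums: np.ndarray, log_n_fact: float) -> float:
    lp = sum(lgamma(r + 1) for r in row_sums)
    lp += sum(lgamma(c + 1) for c in col_sums)
    lp -= log_n_fact
    lp -= sum(lgamma(x + 1) for x in cells.flat)
    return lp


def freeman_halton_exact(table: ContingencyTable | np.ndarray | Sequence,
                         max_enumeration_margin: int = 30) -> TestResult:
    """Freeman–Halton exact test on a K×2 (or 2×K) table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one (with a
    small relative slack for floating-point ties), under the multivariate
    hypergeometric null.
    """
    cells = _as_cells(table)
    if 2 not in cells.shape:
        raise ValueError("freeman_halton_exact requires a table with 2 rows or 2 columns")
    if cells.shape[1] != 2:
        cells = cells.T  # orient as K groups x 2 outcomes
    row_sums = cells.sum(axis=1)
    col_sums = cells.sum(axis=0)
    n = int(cells.sum())
    if min(col_sums) > max_enumeration_margin:
        raise ValueError(
            f"smaller outcome margin {min(col_sums)} exceeds the enumeration "
            f"bound {max_enumeration_margin}; use a Monte-Carlo approximation"
        )
    # enumerate over the smaller outcome column
    col = int(np.argmin(col_sums))
    target = int(col_sums[col])
    log_n_fact = lgamma(n + 1)
    lp_obs = _log_table_prob(cells, row_sums, col_sums, log_n_fact)
    k = cells.shape[0]
    total = 0.0
    stat = 0.0  # -2 sum log likelihood ratio not needed; report observed log-prob

    def recurse(i: int, remaining: int, acc: list[int]) -> None:
        nonlocal total
        if i == k - 1:
            if remaining > row_sums[i]:
                return
            entries = acc + [remaining]
            tab = np.empty((k, 2), dtype=np.int64)
            tab[:, col] = entries
            tab[:, 1 - col] = row_sums - tab[:, col]
            lp = _log_table_prob(tab, row_sums, col_sums, log_n_fact)
            if lp <= lp_obs + abs(lp_obs) * _EXACT_TIE_SLACK + _EXACT_TIE_SLACK:
                total += exp(lp)
            return
        lo = max(0, remaining - int(row_sums[i + 1:].sum()))
        hi = min(int(row_sums[i]), remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, acc + [a])

    recurse(0, target, [])
    return TestResult("freeman_halton", float(exp(lp_obs)), min(1.0, total))


def select_categorical_test(table: ContingencyTable | np.ndarray | Sequence) -> str:
    """Choose the categorical test: exact when any cell is below 5.

    Returns ``"fisher"`` (2×2 small cells), ``"freeman_halton"`` (K>2 small
    cells) or ``"chi_square"``.
    """
    cells = _as_cells(table)
    small = bool((cells < 5).any())
    if not small:
        return "chi_square"
    if cells.shape == (2, 2):
        return "fisher"
    return "freeman_halton"


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance level family_alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


def classifier_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassifierMetrics:
    """Accuracy / sensitivity / specificity with leak as the positive class."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be nonnegative")
    if tp + fn == 0:
        raise ValueError("no positive (leak) samples: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative (no-leak) samples: specificity undefined")
    return ClassifierMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )
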