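"""Statistical comparison scheme for the tilt-test analysis.

Between-group comparisons use the Mann–Whitney U test, within-group phase
comparisons the Wilcoxon signed-rank test, asymmetry-occurrence proportions
McNemar's test (χ² without continuity correction by default) and the
Cochran Q omnibus over the three tilt phases; multi-comparison families are
Holm-corrected.  All tests are two-sided at α = 0.05; normality is checked
only for reporting (Shapiro–Wilk) since every downstream test is
nonparametric.

The heavy lifting is delegated to scipy.stats and statsmodels; this module
fixes the variants (exact vs approximate branches, correction choices) and
wraps everything in a uniform :class:`TestResult`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "TestResult",
    "PairedTable",
    "ThreeWayPattern",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "mcnemar",
    "cochran_q",
    "reconstruct_threeway",
    "holm_adjust",
    "friedman",
    "friedman_with_posthoc",
    "cochran_q_with_posthoc",
    "shapiro_wilk",
]

#: combined-sample-size ceiling for exact rank-test p-values (no ties)
EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    method: str
    df: int | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p-value below raw p-value")


@dataclass(frozen=True)
class PairedTable:
    """2×2 paired-occurrence table for phases (first, second).

    a, b, c, d count subjects with states (1,1), (1,0), (0,1), (0,0);
    the first label's state comes first.
    """

    labels: tuple[str, str]
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margin_first(self) -> int:
        return self.a + self.b

    @property
    def margin_second(self) -> int:
        return self.a + self.c


_PATTERNS = tuple(itertools.product((1, 0), repeat=3))


@dataclass(frozen=True)
class ThreeWayPattern:
    """Counts of the 8 binary occurrence patterns over three phases."""

    labels: tuple[str, str, str]
    counts: dict[tuple[int, int, int], int]

    def __post_init__(self) -> None:
        counts = {p: int(self.counts.get(p, 0)) for p in _PATTERNS}
        if any(v < 0 for v in counts.values()):
            raise ValueError("pattern counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_matrix(self) -> np.ndarray:
        """Subjects × 3 binary matrix (subject order arbitrary)."""
        rows = [p for p, c in self.counts.items() for _ in range(c)]
        return np.array(rows, dtype=int).reshape(-1, 3)

    def pairwise_table(self, i: int, j: int) -> PairedTable:
        cells = {(1, 1): 0, (1, 0): 0, (0, 1): 0, (0, 0): 0}
        for p, c in self.counts.items():
            cells[(p[i], p[j])] += c
        return PairedTable(
            labels=(self.labels[i], self.labels[j]),
            a=cells[(1, 1)], b=cells[(1, 0)], c=cells[(0, 1)], d=cells[(0, 0)],
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, labels: tuple[str, str, str]) -> "ThreeWayPattern":
        matrix = np.asarray(matrix, dtype=int)
        counts: dict[tuple[int, int, int], int] = {}
        for row in matrix:
            key = tuple(int(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
        return cls(labels=labels, counts=counts)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test between two independent samples.

    Exact p for combined n ≤ 25 without ties, otherwise the tie-corrected
    normal approximation; the branch taken is recorded in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    exact = len(x) + len(y) <= EXACT_N_MAX and not _has_ties(np.concatenate([x, y]))
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    label = "mann-whitney exact" if exact else "mann-whitney normal approx (tie-corrected)"
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method=label)


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; exact p for n ≤ 25 without tied |d|,
    otherwise the normal approximation (no continuity correction).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return TestResult(statistic=0.0, p_raw=1.0, method="wilcoxon degenerate (all zero)")
    if len(d) < 2:
        raise ValueError("fewer than 2 nonzero differences")
    exact = len(d) <= EXACT_N_MAX and not _has_ties(np.abs(d))
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(d, correction=False, method=method, alternative="two-sided")
    label = "wilcoxon exact" if exact else "wilcoxon normal approx"
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method=label)


def mcnemar(table: PairedTable, variant: str = "chi2") -> TestResult:
    """McNemar's test on a paired 2×2 table.

    The default ``chi2`` variant is the uncorrected χ² = (b − c)²/(b + c)
    with df = 1; ``chi2_corrected`` applies the continuity correction and
    ``exact`` uses the binomial reference.  b + c = 0 degenerates to p = 1.
    """
    b, c = table.b, table.c
    if b + c == 0:
        warnings.warn("no discordant pair; McNemar degenerate, p = 1")
        return TestResult(statistic=0.0, p_raw=1.0, method=f"mcnemar {variant} (degenerate)", df=1)
    arr = np.array([[table.a, b], [c, table.d]], dtype=float)
    if variant == "chi2":
        res = _sm_mcnemar(arr, exact=False, correction=False)
    elif variant == "chi2_corrected":
        res = _sm_mcnemar(arr, exact=False, correction=True)
    elif variant == "exact":
        res = _sm_mcnemar(arr, exact=True)
    else:
        raise ValueError(f"unknown McNemar variant {variant!r}")
    df = 1 if variant.startswith("chi2") else None
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method=f"mcnemar {variant}", df=df)


def cochran_q(pattern: ThreeWayPattern) -> TestResult:
    """Cochran Q omnibus test for equal occurrence across the three phases.

    Q = (k−1)·[k·ΣC_j² − (ΣC_j)²] / (k·ΣR_i − ΣR_i²) with column totals C_j
    and row totals R_i, referred to χ² with df = k − 1.  All-concordant data
    degenerate to p = 1.
    """
    if pattern.n < 2:
        raise ValueError("Cochran Q needs at least 2 subjects")
    m = pattern.to_matrix()
    r = m.sum(axis=1)
    k = m.shape[1]
    if k * int(r.sum()) - int((r**2).sum()) == 0:
        warnings.warn("all subjects concordant; Cochran Q degenerate, p = 1")
        return TestResult(statistic=0.0, p_raw=1.0, method="cochran-q (degenerate)", df=k - 1)
    res = _sm_cochrans_q(m, return_object=True)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method="cochran-q", df=k - 1)


def reconstruct_threeway(t12: PairedTable, t13: PairedTable, t23: PairedTable) -> ThreeWayPattern:
    """Rebuild per-subject three-phase patterns from the three pairwise tables.

    The three 2×2 tables impose 7 independent linear constraints on the 8
    pattern counts, leaving one free integer t = n₁₁₁.  The feasible
    (non-negative) range of t is scanned; a unique solution is returned,
    anything else raises with the feasible range in the message.
    """
    if not (t12.n == t13.n == t23.n):
        raise ValueError("tables disagree on cohort size")
    if t12.margin_first != t13.margin_first:
        raise ValueError("inconsistent marginal for the first phase")
    if t12.margin_second != t23.margin_first:
        raise ValueError("inconsistent marginal for the second phase")
    if t13.margin_second != t23.margin_second:
        raise ValueError("inconsistent marginal for the third phase")

    labels = (t12.labels[0], t12.labels[1], t13.labels[1])
    solutions = []
    for t in range(t12.n + 1):
        n111 = t
        n110 = t12.a - t
        n101 = t13.a - t
        n100 = t13.b - n110
        n011 = t23.a - n111
        n010 = t23.b - n110
        n001 = t23.c - n101
        n000 = t23.d - n100
        counts = {
            (1, 1, 1): n111, (1, 1, 0): n110, (1, 0, 1): n101, (1, 0, 0): n100,
            (0, 1, 1): n011, (0, 1, 0): n010, (0, 0, 1): n001, (0, 0, 0): n000,
        }
        if min(counts.values()) < 0:
            continue
        pattern = ThreeWayPattern(labels=labels, counts=counts)
        if pattern.n == t12.n:
            solutions.append(pattern)
    if not solutions:
        raise ValueError("no non-negative pattern reproduces the three tables")
    if len(solutions) > 1:
        lo = min(p.counts[(1, 1, 1)] for p in solutions)
        hi = max(p.counts[(1, 1, 1)] for p in solutions)
        raise ValueError(f"pattern not unique: n111 feasible in [{lo}, {hi}]")
    return solutions[0]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, order preserved, capped at 1.

    Sorted ascending, p'_(i) = max_{j ≤ i} min(1, (m − j + 1) · p_(j)),
    which enforces monotonicity of the adjusted sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted = np.maximum.accumulate(stepped)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def friedman(matrix: np.ndarray) -> TestResult:
    """Friedman rank test over subjects × 3 (or k) related conditions.

    Tie-corrected statistic referred to χ² with df = k − 1; rows with any
    missing cell are rejected (no imputation).  All-tied rows throughout
    degenerate to statistic 0, p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need a subjects × k matrix with N ≥ 2, k ≥ 3")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed")
    k = m.shape[1]
    if np.all(m == m[:, [0]]):
        warnings.warn("every row fully tied; Friedman degenerate, p = 1")
        return TestResult(statistic=0.0, p_raw=1.0, method="friedman (degenerate)", df=k - 1)
    res = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method="friedman", df=k - 1)


def friedman_with_posthoc(matrix: np.ndarray, labels: Sequence[str]) -> tuple[TestResult, list[TestResult]]:
    """Friedman omnibus plus Holm-corrected pairwise Wilcoxon post-hoc tests."""
    m = np.asarray(matrix, dtype=float)
    omnibus = friedman(m)
    pairs = list(itertools.combinations(range(m.shape[1]), 2))
    raws = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, j in pairs:
            raws.append(wilcoxon_signed_rank(m[:, i] - m[:, j]))
    adjusted = holm_adjust([r.p_raw for r in raws])
    out = [
        TestResult(
            statistic=r.statistic, p_raw=r.p_raw, p_adjusted=float(adj),
            method=f"{r.method} [{labels[i]} vs {labels[j]}], holm",
        )
        for r, adj, (i, j) in zip(raws, adjusted, pairs)
    ]
    return omnibus, out


def cochran_q_with_posthoc(pattern: ThreeWayPattern, variant: str = "chi2") -> tuple[TestResult, list[TestResult]]:
    """Cochran Q omnibus plus Holm-corrected pairwise McNemar post-hoc tests."""
    omnibus = cochran_q(pattern)
    pairs = [(0, 1), (0, 2), (1, 2)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raws = [mcnemar(pattern.pairwise_table(i, j), variant=variant) for i, j in pairs]
    adjusted = holm_adjust([r.p_raw for r in raws])
    out = [
        TestResult(
            statistic=r.statistic, p_raw=r.p_raw, p_adjusted=float(adj), df=r.df,
            method=f"{r.method} [{pattern.labels[i]} vs {pattern.labels[j]}], holm",
        )
        for r, adj, (i, j) in zip(raws, adjusted, pairs)
    ]
    return omnibus, out


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (reporting only; 3 ≤ n ≤ 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), method="shapiro-wilk")
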