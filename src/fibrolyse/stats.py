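"""Group-comparison and agreement statistics for labelled count tables.

Implements the statistics a two-group diagnostic-agreement analysis needs:
the Fisher-Freeman-Halton exact test for r x c tables (full enumeration of
margin-consistent tables; scipy only covers 2 x 2), Pearson chi-square with
optional Yates continuity correction, the pooled two-sample t computed from
summary statistics alone, the Mann-Whitney test, and Cohen's kappa with
identity/linear/quadratic weights plus its large-sample standard error
(Fleiss-Cohen-Everitt) and observed/conditional concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "AgreementResult",
    "fisher_exact_rxc",
    "chi_square",
    "t_from_summary",
    "mann_whitney",
    "cohen_kappa",
    "conditional_concordance",
    "crosstab",
]

#: Largest table total for which exact enumeration is attempted.
EXACT_ENUMERATION_LIMIT = 200

#: Relative tolerance for deciding that two table probabilities tie.
PROBABILITY_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with row/column category labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(int)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if len(self.row_labels) != c.shape[0] or len(self.col_labels) != c.shape[1]:
            raise ValueError("label lengths must match table shape")
        if len(set(self.row_labels)) != len(self.row_labels) or len(
            set(self.col_labels)
        ) != len(self.col_labels):
            raise ValueError("labels must be unique")

    @classmethod
    def from_counts(
        cls,
        counts,
        row_labels: Optional[Sequence[str]] = None,
        col_labels: Optional[Sequence[str]] = None,
    ) -> "ContingencyTable":
        c = np.asarray(counts)
        rl = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(c.shape[0]))
        cl = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c.shape[1]))
        return cls(c, rl, cl)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def drop_empty(self) -> "ContingencyTable":
        """Remove all-zero rows and columns (margins stay structural otherwise)."""
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            self.counts[np.ix_(keep_r, keep_c)],
            tuple(l for l, k in zip(self.row_labels, keep_r) if k),
            tuple(l for l, k in zip(self.col_labels, keep_c) if k),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value and method description."""

    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with CI and concordance summaries."""

    kappa: float
    se: float
    ci95: tuple[float, float]
    observed_concordance: float  # percent
    weighting: str

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.kappa <= 1 + 1e-9:
            raise ValueError("kappa must lie in [-1, 1]")
        if not self.ci95[0] <= self.kappa <= self.ci95[1]:
            raise ValueError("kappa must lie inside its CI")
        if not 0 <= self.observed_concordance <= 100:
            raise ValueError("observed_concordance is a percentage")


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton exact test


def _log_table_prob(flat_counts, log_margin_const, cells) -> float:
    # P(table | margins) = (prod r_i! prod c_j!) / (n! prod n_ij!)
    return log_margin_const - sum(lgamma(v + 1) for v in flat_counts[:cells])


def _enumerate_probs(row_sums: list[int], col_sums: list[int]):
    """Yield log-probabilities of every table with the given margins.

    Fills row by row; within a row, cells are bounded by the remaining
    column totals, and the last cell of each row is forced by the row sum.
    """
    r, c = len(row_sums), len(col_sums)
    log_margin_const = (
        sum(lgamma(x + 1) for x in row_sums)
        + sum(lgamma(x + 1) for x in col_sums)
        - lgamma(sum(row_sums) + 1)
    )
    cells: list[int] = []

    def fill_row(i: int, j: int, row_left: int, col_left: list[int]):
        if i == r - 1:
            # final row forced by the remaining column totals
            if all(v >= 0 for v in col_left):
                yield _log_table_prob(cells + col_left, log_margin_const, len(cells) + c)
            return
        if j == c - 1:
            if 0 <= row_left <= col_left[j]:
                cells.append(row_left)
                col_left[j] -= row_left
                yield from fill_row(i + 1, 0, row_sums[i + 1], col_left)
                col_left[j] += row_left
                cells.pop()
            return
        for v in range(min(row_left, col_left[j]) + 1):
            cells.append(v)
            col_left[j] -= v
            yield from fill_row(i, j + 1, row_left - v, col_left)
            col_left[j] += v
            cells.pop()

    yield from fill_row(0, 0, row_sums[0], list(col_sums))


def fisher_exact_rxc(table: ContingencyTable, variant: str = "midp") -> TestResult:
    """Two-sided Fisher-Freeman-Halton exact test for an r x c table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table (probability-ordering rule, ties within relative
    tolerance 1e-7).

    ``variant="midp"`` (default) gives the mid-p value: tables tying the
    observed probability (including the observed table itself) contribute
    half weight.  ``variant="prob"`` is the conventional rule where ties
    contribute full weight.  Mid-p is the default because it is what
    common clinical statistics packages report for this test.

    Raises on degenerate margins (an all-zero row or column) and refuses
    tables with n > 200 (enumeration would be too large; reduce or pool
    categories, or use a Monte Carlo approach outside this function).
    """
    if variant not in ("midp", "prob"):
        raise ValueError("variant must be 'midp' or 'prob'")
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError(
            "degenerate margin (all-zero row or column); drop_empty() first"
        )
    n = table.n
    if n > EXACT_ENUMERATION_LIMIT:
        raise ValueError(
            f"n = {n} too large for exact enumeration (limit "
            f"{EXACT_ENUMERATION_LIMIT}); use simulation mode externally"
        )
    log_const = (
        sum(lgamma(x + 1) for x in row_sums)
        + sum(lgamma(x + 1) for x in col_sums)
        - lgamma(n + 1)
    )
    lp_obs = log_const - sum(lgamma(v + 1) for v in counts.ravel())
    log_tie_tol = np.log1p(PROBABILITY_TIE_RTOL)
    p_below = 0.0
    p_tie = 0.0
    for lp in _enumerate_probs(list(row_sums), list(col_sums)):
        if lp < lp_obs - log_tie_tol:
            p_below += exp(lp)
        elif lp <= lp_obs + log_tie_tol:
            p_tie += exp(lp)
    if variant == "midp":
        p = p_below + 0.5 * p_tie
    else:
        p = p_below + p_tie
    p = min(p, 1.0)
    return TestResult(
        statistic=float(exp(lp_obs)),
        p_value=p,
        method=f"Fisher-Freeman-Halton exact ({variant})",
    )


# ---------------------------------------------------------------------------
# Chi-square, t, Mann-Whitney


def chi_square(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    With ``yates=True`` (2 x 2 only) the statistic uses the continuity
    correction sum((|O - E| - 0.5)^2 / E).
    """
    counts = table.counts.astype(float)
    if yates and counts.shape != (2, 2):
        raise ValueError("Yates correction applies to 2 x 2 tables only")
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    if np.any(expected == 0):
        raise ValueError("zero expected cell count (empty margin)")
    dev = np.abs(counts - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(
        statistic=stat,
        p_value=max(p, np.finfo(float).tiny),
        method="chi-square" + (" (Yates)" if yates else ""),
        df=df,
    )


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample Student t from summary statistics.

    Computable directly from published group means and SDs; no raw data
    needed.  Two-sided p on n1 + n2 - 2 degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("need sd > 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (mean1 - mean2) / se
    p = 2 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(max(p, np.finfo(float).tiny), 1.0),
                      method="pooled two-sample t", df=df)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (U for the x-vs-y orientation).

    Exact p for small untied samples (combined n <= 20); otherwise the
    tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        method=f"Mann-Whitney ({method})",
    )


# ---------------------------------------------------------------------------
# Agreement


def _weight_matrix(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i == j).astype(float)
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    raise ValueError("weighting must be 'none', 'linear' or 'quadratic'")


def cohen_kappa(table: ContingencyTable, weighting: str = "linear") -> AgreementResult:
    """Cohen's kappa for a square rater-agreement table.

    kappa = (p_o - p_e) / (1 - p_e) with weighted observed and expected
    agreement; weights are 1 - |i-j|/(k-1) (linear, the default for
    ordinal severity grades), 1 - ((i-j)/(k-1))^2 (quadratic), or identity
    (unweighted).  The standard error is the Fleiss-Cohen-Everitt
    large-sample formula for weighted kappa (which reduces to the
    unweighted formula under identity weights); ci95 = kappa +/- 1.96 se.
    """
    counts = table.counts
    if counts.shape[0] != counts.shape[1] or counts.shape[0] < 2:
        raise ValueError("kappa needs a square table with k >= 2 categories")
    if table.row_labels != table.col_labels:
        raise ValueError("row and column categories must match")
    k = counts.shape[0]
    n = table.n
    p = counts / n
    w = _weight_matrix(k, weighting)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(p_row, p_col)).sum())
    if p_e >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1 (all mass in one category); "
                         "kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa
    wbar_row = (w * p_col[None, :]).sum(axis=1)  # E[w | rater-1 category i]
    wbar_col = (w * p_row[:, None]).sum(axis=0)  # E[w | rater-2 category j]
    term = (
        p * (w * (1 - p_e) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - p_o)) ** 2
    ).sum()
    var = (term - (p_o * p_e - 2 * p_e + p_o) ** 2) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    obs = 100.0 * float(np.trace(p))
    return AgreementResult(
        kappa=float(kappa),
        se=se,
        ci95=(float(kappa - 1.96 * se), float(kappa + 1.96 * se)),
        observed_concordance=obs,
        weighting=weighting,
    )


def conditional_concordance(table: ContingencyTable, category: str) -> float:
    """Concordance restricted to subjects either method put in ``category``.

    100 x diagonal / (row margin + column margin - diagonal): of everyone
    assigned the category by at least one method, the percentage on which
    both methods agree.
    """
    if table.row_labels != table.col_labels:
        raise ValueError("row and column categories must match")
    if category not in table.row_labels:
        raise ValueError(f"category {category!r} not in table labels")
    i = table.row_labels.index(category)
    diag = table.counts[i, i]
    denom = table.counts[i, :].sum() + table.counts[:, i].sum() - diag
    if denom == 0:
        raise ValueError(f"no subject assigned {category!r} by either method")
    return 100.0 * float(diag) / float(denom)


def crosstab(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    categories: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Cross-classify two aligned per-subject label vectors.

    Cell (i, j) counts subjects with a-label i and b-label j.  ``categories``
    fixes the (shared) category order and retains structural zeros; by
    default the sorted union of observed labels is used.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    if categories is None:
        categories = sorted(set(labels_a) | set(labels_b))
    categories = list(categories)
    idx = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for a, b in zip(labels_a, labels_b):
        counts[idx[a], idx[b]] += 1
    return ContingencyTable(counts, tuple(categories), tuple(categories))
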