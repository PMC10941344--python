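"""Cohort-level nonparametric statistics.

Subjects are measured under k ordered conditions (rest, sympathetic
stimulation, recovery); per-metric comparisons use Friedman's repeated
measures ANOVA by ranks (chi-square approximation with the standard tie
correction) followed by Dunn's pairwise z-tests with Bonferroni
adjustment over the k(k-1)/2 condition pairs.  Associations between
condition-to-condition changes (deltas) and covariates use Spearman's
rank correlation with the two-sided t approximation.

The Friedman statistic is computed here from the rank formula (and is
cross-checked against an independent implementation in the test suite);
Spearman correlation delegates to :func:`scipy.stats.spearmanr`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

DELTA_PAIRS = {
    "stim-rest": ("snsa_stim", "rest"),
    "recovery-stim": ("recovery", "snsa_stim"),
}


@dataclass(frozen=True)
class RepeatedMeasuresBlock:
    """Complete n-subject x k-condition matrix for one metric."""

    data: np.ndarray  # shape (n, k)
    metric: str = ""
    conditions: tuple[str, ...] = ("rest", "snsa_stim", "recovery")

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be an n x k matrix")
        if np.isnan(data).any():
            raise ValueError("missing cells: exclude incomplete subjects upstream")
        if data.shape[1] != len(self.conditions):
            raise ValueError("conditions must match the number of columns")
        object.__setattr__(self, "data", data)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test, optionally with pairwise post-hocs."""

    statistic: float
    p_value: float
    n: int
    k: int
    pairwise: Mapping[tuple[str, str], tuple[float, float]] | None = None
    # pairwise maps (condition_i, condition_j) -> (z, adjusted two-sided p)


def _row_ranks(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, data)


def _tie_term(data: np.ndarray) -> float:
    """Sum over rows of sum(t^3 - t) across tie groups."""
    total = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        total += float(np.sum(counts**3 - counts))
    return total


def friedman_test(block: RepeatedMeasuresBlock, method: str = "chisq") -> TestResult:
    """Friedman ANOVA by ranks with tie correction.

    With mid-ranks R_ij within each subject row and column rank sums R_j,
    the uncorrected statistic is Q = 12/(n k (k+1)) sum_j R_j^2 - 3n(k+1),
    divided by the tie factor 1 - sum(t^3 - t)/(n k (k^2 - 1)); the
    p-value is the chi-square tail with k-1 degrees of freedom
    (``method="chisq"``, the convention of common statistical software
    even at small n) or, for k = 3 tie-free blocks, the exact permutation
    tail (``method="exact"``).  A block whose rows are entirely tied
    carries no ranking information and returns Q = 0, p = 1.
    """
    n, k = block.n, block.k
    if n < 3:
        raise InsufficientDataError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise InsufficientDataError(f"need at least 2 conditions, got {k}")
    ranks = _row_ranks(block.data)
    col_sums = ranks.sum(axis=0)
    q_uncorr = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    tie_term = _tie_term(block.data)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0 or q_uncorr <= 0:
        return TestResult(statistic=0.0, p_value=1.0, n=n, k=k)
    q = q_uncorr / correction
    if method == "chisq":
        p = float(stats.chi2.sf(q, k - 1))
    elif method == "exact":
        if k != 3:
            raise ValueError("exact permutation p-value implemented for k = 3 only")
        if tie_term > 0:
            raise ValueError("exact permutation p-value requires tie-free rows")
        p = _exact_friedman_p_k3(n, q)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(q), p_value=p, n=n, k=k)


def _exact_friedman_p_k3(n: int, q_obs: float) -> float:
    """Exact permutation tail P(Q >= q_obs) for k = 3, tie-free rows.

    Under the null each row contributes one of the 6 permutations of
    (1, 2, 3) independently; dynamic programming over the pair of column
    rank sums (R1, R2) enumerates the full distribution in O(n^3) states
    (R3 = 6n - R1 - R2).
    """
    from itertools import permutations

    states: dict[tuple[int, int], float] = {(0, 0): 1.0}
    perms = list(permutations((1, 2, 3)))
    for _ in range(n):
        nxt: dict[tuple[int, int], float] = {}
        for (r1, r2), weight in states.items():
            for a, b, _c in perms:
                key = (r1 + a, r2 + b)
                nxt[key] = nxt.get(key, 0.0) + weight
        states = nxt
    total = 6.0**n
    tail = 0.0
    for (r1, r2), weight in states.items():
        r3 = 6 * n - r1 - r2
        q = (r1 * r1 + r2 * r2 + r3 * r3) / float(n) - 12.0 * n
        if q >= q_obs - 1e-9:
            tail += weight
    return tail / total


def dunn_bonferroni(block: RepeatedMeasuresBlock) -> TestResult:
    """Dunn's pairwise rank-mean z-tests with Bonferroni adjustment.

    For conditions i < j, z = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(6n)); the
    two-sided normal p is multiplied by the number of pairs and capped at
    1.  The returned result carries the Friedman statistic plus the
    ``pairwise`` map.
    """
    base = friedman_test(block)
    n, k = block.n, block.k
    ranks = _row_ranks(block.data)
    rank_means = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(combinations(range(k), 2))
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i, j in pairs:
        z = (rank_means[i] - rank_means[j]) / se
        p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        pairwise[(block.conditions[i], block.conditions[j])] = (float(z), float(p_adj))
    return TestResult(
        statistic=base.statistic, p_value=base.p_value, n=n, k=k, pairwise=pairwise
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation, two-sided p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant variable")
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), n=int(x.size), k=2)


def condition_deltas(
    table: pd.DataFrame,
    metric: str,
    pair: str,
    subject_col: str = "subject_id",
    condition_col: str = "condition",
) -> pd.Series:
    """Per-subject metric changes between two conditions.

    ``table`` is a tidy per-(subject, condition) metric table (as produced
    by the pipeline); ``pair`` is ``stim-rest`` or ``recovery-stim``.
    Subjects missing either condition are dropped with a logged warning.
    Returns deltas indexed by subject, in the table's subject order.
    """
    if pair not in DELTA_PAIRS:
        raise KeyError(f"unknown pair {pair!r}; expected one of {sorted(DELTA_PAIRS)}")
    hi, lo = DELTA_PAIRS[pair]
    wide = table.pivot_table(
        index=subject_col, columns=condition_col, values=metric, sort=False
    )
    missing = [c for c in (hi, lo) if c not in wide.columns]
    if missing:
        raise KeyError(f"conditions absent from table: {missing}")
    complete = wide[[hi, lo]].dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        logger.warning(
            "dropping %d subject(s) with missing conditions for %s: %s",
            len(dropped), metric, sorted(map(str, dropped)),
        )
    deltas = complete[hi] - complete[lo]
    deltas.name = f"{metric}:{pair}"
    return deltas
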