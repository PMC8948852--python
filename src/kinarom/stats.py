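"""Group summaries, the rank-sum comparison, and capacity-share reports.

The validation design compares two groups of n=18 children (control vs
spastic hemiparesis) on measured angles and FMA totals with the Wilcoxon
rank-sum test (equivalently the Mann-Whitney U-test) at alpha = 0.05.
Two computational routes are provided:

* ``exact`` — mid-ranks for ties, then full enumeration of all
  C(nx+ny, nx) group assignments of the pooled ranks; the two-sided p
  is twice the smaller tail probability, capped at 1. Feasible (and the
  automatic choice) for nx+ny <= 16.
* ``normal_approx`` — the large-sample normal approximation with
  tie-corrected variance and continuity correction (delegated to
  scipy.stats.mannwhitneyu, the same recipe as the common
  statistics-toolbox ranksum for samples this size).

Summaries are mean +/- sample SD (ddof=1) with half-up rounding to the
requested number of decimals, matching the printed clinical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _sps

from ._rounding import round_half_up
from .errors import DomainError
from .fma import HYBRID_BANDS, CapacityBands

_EXACT_MAX_N = 16


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float | None      # None when n < 2 (sample SD undefined)
    decimals: int = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sd = "undefined" if self.sd is None else f"{self.sd}"
        return f"{self.mean} ± {sd} (n={self.n})"


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float    # U of the first sample
    rank_sum: float       # rank sum of the first sample
    p_two_sided: float
    method: str           # "exact" | "normal_approx"
    alpha: float = 0.05

    @property
    def h0_rejected(self) -> bool:
        return self.p_two_sided < self.alpha


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    a: SummaryStats
    b: SummaryStats
    test: RankSumResult

    @property
    def h0(self) -> int:
        """1 = the no-difference hypothesis is rejected at alpha."""
        return int(self.test.h0_rejected)


def group_summary(values, decimals: int = 2) -> SummaryStats:
    """Mean and sample SD (n-1), half-up rounded to ``decimals``."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarise an empty group")
    mean = round_half_up(float(np.mean(arr)), decimals)
    sd = (round_half_up(float(np.std(arr, ddof=1)), decimals)
          if arr.size >= 2 else None)
    return SummaryStats(int(arr.size), mean, sd, decimals)


def _u_from_ranksum(rank_sum: float, nx: int) -> float:
    return rank_sum - nx * (nx + 1) / 2.0


def rank_sum_test(x, y, method: str = "auto", alpha: float = 0.05) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U comparison of x and y.

    ``method='auto'`` enumerates exactly when nx+ny <= 16 and falls back
    to the tie-corrected continuity-corrected normal approximation
    otherwise. Two completely identical groups (zero rank variance) give
    the degenerate p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both groups must be non-empty")
    if method not in ("auto", "exact", "normal_approx"):
        raise DomainError(f"unknown method {method!r}")
    nx, ny = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)          # mid-ranks for ties
    rank_sum = float(ranks[:nx].sum())
    u = _u_from_ranksum(rank_sum, nx)

    if np.ptp(pooled) == 0:                # all values identical across groups
        chosen = method if method != "auto" else (
            "exact" if nx + ny <= _EXACT_MAX_N else "normal_approx")
        return RankSumResult(u, rank_sum, 1.0, chosen, alpha)

    if method == "auto":
        method = "exact" if nx + ny <= _EXACT_MAX_N else "normal_approx"

    if method == "exact":
        p = _exact_two_sided_p(ranks, nx)
    else:
        p = float(_sps.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic", use_continuity=True).pvalue)
    return RankSumResult(u, rank_sum, min(p, 1.0), method, alpha)


def _exact_two_sided_p(ranks: np.ndarray, nx: int) -> float:
    """Enumerate all C(n, nx) assignments of the pooled (mid-)ranks.

    p = 2 * min(P(R <= r_obs), P(R >= r_obs)), capped at 1. The rank-sum
    R is equivalent to U up to a constant shift, so tails agree.
    """
    n = ranks.size
    r_obs = ranks[:nx].sum()
    total = math.comb(n, nx)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), nx):
        r = ranks[list(idx)].sum()
        if r <= r_obs + eps:
            le += 1
        if r >= r_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def compare_groups(a, b, label: str, alpha: float = 0.05,
                   decimals: int = 2, method: str = "auto") -> ComparisonRow:
    """One report row: both group summaries plus the rank-sum verdict."""
    return ComparisonRow(label, group_summary(a, decimals), group_summary(b, decimals),
                         rank_sum_test(a, b, method=method, alpha=alpha))


def cohort_classification_shares(
    scores, bands: CapacityBands = HYBRID_BANDS,
) -> dict[str, tuple[int, int]]:
    """Capacity-category counts and integer percents for a list of totals.

    Percents are count/n*100 rounded half-up, so they can sum to
    100 +/- 1 point. Every category of the scheme appears, including
    zero-count ones; out-of-scheme totals land in 'unclassified'.
    """
    scores = [int(s) for s in scores]
    for s in scores:
        if not (0 <= s <= 66):
            raise DomainError(f"score {s} outside [0, 66]")
    n = len(scores)
    counts = {label: 0 for label in bands.labels}
    for s in scores:
        cat = bands.category(s)
        counts[cat] = counts.get(cat, 0) + 1
    return {label: (c, int(round_half_up(100.0 * c / n, 0)) if n else 0)
            for label, c in counts.items()}
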