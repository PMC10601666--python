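"""Per-region two-group comparisons: exact rank-sum, BH FDR, sign imbalance.

At the sample sizes this pipeline targets (a handful of hemispheres per sex)
the Wilcoxon–Mann–Whitney null distribution is discrete and sparse, so
p-values are computed by exact enumeration of all C(n1+n2, n1) group
assignments (via a subset-sum dynamic program over mid-ranks, which counts
exactly the same assignments without materializing them). A tie- and
continuity-corrected normal approximation takes over beyond group size 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .quantify import HemisphereSample, compute_metrics

__all__ = [
    "RegionComparison",
    "CohortResult",
    "rank_sum_exact",
    "bh_fdr",
    "sign_imbalance",
    "compare_cohort",
]

EXACT_MAX_GROUP = 12  # exact enumeration up to this per-group size


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, observed2: int) -> float:
    """Exact two-sided p via subset-sum DP over doubled mid-ranks.

    dp[k, s] counts size-k subsets of ranks2 with sum s; row n1 is the exact
    permutation distribution of the (doubled) rank-sum statistic. Two-sided
    p = min(1, 2 * min(lower tail, upper tail)).
    """
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # reversed row order so each rank is used at most once
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    lower = dist[: observed2 + 1].sum()
    upper = dist[observed2:].sum()
    p = 2.0 * min(lower, upper) / n_total
    return min(1.0, float(p))


def _approx_rank_sum_p(ranks: np.ndarray, n1: int, n2: int, r1: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = r1 - mu
    z = (abs(diff) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def rank_sum_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p-value, exact for small groups.

    Mid-ranks handle ties; for both group sizes <= 12 the full permutation
    distribution is enumerated, otherwise a corrected normal approximation is
    used. Always in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    n1, n2 = x.size, y.size
    r1 = float(ranks[:n1].sum())
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        # mid-ranks are multiples of 1/2; doubling makes them integers
        ranks2 = np.round(ranks * 2).astype(np.int64)
        observed2 = int(round(r1 * 2))
        return _exact_rank_sum_p(ranks2, n1, observed2)
    return _approx_rank_sum_p(ranks, n1, n2, r1)


def bh_fdr(
    p_values: Sequence[float], level: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j.

    Returns (q_values, rejected) in the input order; rejected iff q <= level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return [], []
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("all p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    rejected = q <= level
    return q.tolist(), rejected.tolist()


def sign_imbalance(
    n_one_direction: int, n_total: int, mode: str = "binomial"
) -> float:
    """Two-sided test of a directional split against a balanced null.

    ``binomial`` (default): exact sign test against proportion 1/2.
    ``fisher``: 2x2 Fisher exact test of the observed split against an evenly
    balanced row of the same total.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_one_direction <= n_total:
        raise ValueError("n_one_direction must lie in [0, n_total]")
    if mode == "binomial":
        return float(sps.binomtest(n_one_direction, n_total, 0.5).pvalue)
    if mode == "fisher":
        table = [
            [n_one_direction, n_total - n_one_direction],
            [n_total // 2, n_total - n_total // 2],
        ]
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"mode must be 'binomial' or 'fisher', got {mode!r}")


@dataclass(frozen=True)
class RegionComparison:
    region_id: int
    metric: str
    male_values: tuple[float, ...]
    female_values: tuple[float, ...]
    direction: str  # "male_higher" | "female_higher" | "tie"
    p_value: float
    q_value: float = math.nan
    significant: bool = False

    @property
    def male_mean(self) -> float:
        return float(np.mean(self.male_values))

    @property
    def female_mean(self) -> float:
        return float(np.mean(self.female_values))


@dataclass(frozen=True)
class CohortResult:
    comparisons: tuple[RegionComparison, ...]
    n_male: int
    n_female: int
    metric: str
    fdr_level: float = 0.05

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.comparisons)

    @property
    def sign_counts(self) -> tuple[int, int]:
        """(number of male-higher regions, number of regions compared)."""
        n_male_higher = sum(c.direction == "male_higher" for c in self.comparisons)
        return n_male_higher, len(self.comparisons)

    def sign_imbalance_p(self, mode: str = "binomial") -> float:
        n_higher, _ = self.sign_counts
        n_non_tie = sum(c.direction != "tie" for c in self.comparisons)
        if n_non_tie == 0:
            return 1.0
        return sign_imbalance(n_higher, n_non_tie, mode=mode)


def compare_cohort(
    samples: Sequence[HemisphereSample],
    metric: str = "pps",
    included_regions: set[int] | None = None,
    fdr_level: float = 0.05,
) -> CohortResult:
    """Per-region male-vs-female comparison with BH correction.

    For each included region the per-sample metric values are split by sex,
    direction is decided by group medians, the exact rank-sum p is computed,
    and BH is applied across the whole included set.
    """
    if metric not in ("pps", "fpr"):
        raise ValueError(f"metric must be 'pps' or 'fpr', got {metric!r}")
    males = [s for s in samples if s.sex == "male"]
    females = [s for s in samples if s.sex == "female"]
    if len(males) < 2 or len(females) < 2:
        raise ValueError(
            f"need >= 2 samples per sex, got {len(males)} male / {len(females)} female"
        )
    if not included_regions:
        raise ValueError("included region set must be non-empty")

    metrics = {s.sample_id: compute_metrics(s) for s in samples}

    def values(group: list[HemisphereSample], rid: int) -> tuple[float, ...]:
        return tuple(
            getattr(metrics[s.sample_id], metric).get(rid, 0.0) for s in group
        )

    comparisons: list[RegionComparison] = []
    for rid in sorted(included_regions):
        mv = values(males, rid)
        fv = values(females, rid)
        m_med, f_med = median(mv), median(fv)
        if m_med > f_med:
            direction = "male_higher"
        elif f_med > m_med:
            direction = "female_higher"
        else:
            direction = "tie"
        p = rank_sum_exact(mv, fv)
        comparisons.append(
            RegionComparison(
                region_id=rid,
                metric=metric,
                male_values=mv,
                female_values=fv,
                direction=direction,
                p_value=p,
            )
        )

    q_values, rejected = bh_fdr([c.p_value for c in comparisons], level=fdr_level)
    comparisons = [
        RegionComparison(
            region_id=c.region_id,
            metric=c.metric,
            male_values=c.male_values,
            female_values=c.female_values,
            direction=c.direction,
            p_value=c.p_value,
            q_value=q,
            significant=rej,
        )
        for c, q, rej in zip(comparisons, q_values, rejected)
    ]
    return CohortResult(
        comparisons=tuple(comparisons),
        n_male=len(males),
        n_female=len(females),
        metric=metric,
        fdr_level=fdr_level,
    )
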