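"""Symmetry statistics over closest-point distance maps.

Summarises absolute distance errors (mean, sample SD, 95th percentile,
maximum), converts them to tolerance-threshold surface percentages
(strictly-smaller-than counting at 0.5 / 1.0 / 1.5 / 2.0 mm), grades mean
displacements against Matta's reduction criteria, bins them into the
assessor-agreement categories, and compares the two registration
directions with a normality-gated two-sample location test.

Two interval conventions are resolved here and flagged as interpretations:
Matta's grades name "anatomical <= 1 mm", "imperfect 2-3 mm" and
"poor > 3 mm", leaving (1, 2) mm unassigned — the whole interval (1, 3] is
treated as imperfect so the map is total.  The agreement bins are
half-open, lower-inclusive, and include a [1.5, 2) bin so they partition
[0, inf).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .distance_map import DistanceMap

__all__ = [
    "SymmetrySummary",
    "ThresholdProfile",
    "MattaGrade",
    "AgreementCategory",
    "DirectionComparison",
    "MATTA_THRESHOLDS_MM",
    "summarize",
    "threshold_percentages",
    "cumulative_curve",
    "matta_grade",
    "categorize_distance",
    "percent_agreement",
    "compare_directions",
    "rank_sum_exact_p",
]

#: Tolerance thresholds (mm) derived from Matta's reduction criteria.
MATTA_THRESHOLDS_MM = (0.5, 1.0, 1.5, 2.0)

#: Largest combined sample size for which the rank-sum null distribution is
#: enumerated exactly rather than approximated normally.
EXACT_RANK_SUM_MAX_N = 20


def _distances(dmap) -> np.ndarray:
    d = dmap.distances if isinstance(dmap, DistanceMap) else np.asarray(dmap, dtype=np.float64)
    d = np.abs(np.asarray(d, dtype=np.float64).ravel())
    if len(d) == 0:
        raise ValueError("empty distance map")
    return d


@dataclass
class SymmetrySummary:
    """Mean / SD / 95th percentile / max of absolute distance errors (mm)."""

    mean_error: float
    sd: float
    p95: float
    max_dev: float
    n_points: int


@dataclass
class ThresholdProfile:
    """Percentage of surface points strictly below each tolerance threshold."""

    thresholds: tuple
    surface_percent: tuple


class MattaGrade(Enum):
    """Matta's reduction grading of a residual displacement."""

    ANATOMICAL = "anatomical"
    IMPERFECT = "imperfect"
    POOR = "poor"


class AgreementCategory(Enum):
    """Half-open displacement bins used for assessor agreement."""

    BELOW_0_5 = "<0.5"
    FROM_0_5_TO_1 = "0.5-1"
    FROM_1_TO_1_5 = "1-1.5"
    FROM_1_5_TO_2 = "1.5-2"
    ABOVE_2 = ">2"


@dataclass
class DirectionComparison:
    """Report of the two-direction location test.

    ``normal`` records which branch ran: a Kolmogorov-Smirnov normality
    check on the pooled means decides between the unpaired t test and the
    (rank-sum) Mann-Whitney U test.
    """

    normality_p: float
    normal: bool
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    exact: bool


def summarize(dmap) -> SymmetrySummary:
    """Mean, sample SD (n-1), interpolated 95th percentile and maximum of the
    absolute distances.  A single-point map returns SD 0 with a warning."""
    d = _distances(dmap)
    if len(d) == 1:
        warnings.warn("single-distance map: SD undefined, reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(d, ddof=1))
    return SymmetrySummary(
        mean_error=float(np.mean(d)),
        sd=sd,
        p95=float(np.percentile(d, 95)),  # linear interpolation between order stats
        max_dev=float(np.max(d)),
        n_points=len(d),
    )


def threshold_percentages(dmap, thresholds=MATTA_THRESHOLDS_MM) -> ThresholdProfile:
    """Percentage of points with distance strictly smaller than each
    threshold (the comprehensive symmetry value)."""
    d = _distances(dmap)
    thresholds = tuple(float(t) for t in thresholds)
    if any(t <= 0 for t in thresholds) or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thresholds must be positive and strictly increasing")
    pct = tuple(float(100.0 * np.count_nonzero(d < t) / len(d)) for t in thresholds)
    return ThresholdProfile(thresholds=thresholds, surface_percent=pct)


def cumulative_curve(dmap, grid) -> np.ndarray:
    """Empirical cumulative percentage (strict <) at each grid point; reaches
    100 beyond the maximum distance.  Consistent with
    :func:`threshold_percentages` on the same grid."""
    d = _distances(dmap)
    grid = np.asarray(grid, dtype=np.float64)
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise ValueError("grid must be increasing")
    return 100.0 * np.searchsorted(np.sort(d), grid, side="left") / len(d)


def matta_grade(displacement: float) -> MattaGrade:
    """Grade a displacement: <= 1 mm anatomical, (1, 3] imperfect, > 3 poor.

    The published grades leave (1, 2) mm unnamed; mapping all of (1, 3] to
    imperfect makes the grading total (an interpretation, flagged here).
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    if displacement <= 1.0:
        return MattaGrade.ANATOMICAL
    if displacement <= 3.0:
        return MattaGrade.IMPERFECT
    return MattaGrade.POOR


def categorize_distance(mean_distance: float) -> AgreementCategory:
    """Bin a mean distance into the half-open agreement categories
    [0,0.5), [0.5,1), [1,1.5), [1.5,2), [2,inf)."""
    if mean_distance < 0:
        raise ValueError("mean_distance must be non-negative")
    if mean_distance < 0.5:
        return AgreementCategory.BELOW_0_5
    if mean_distance < 1.0:
        return AgreementCategory.FROM_0_5_TO_1
    if mean_distance < 1.5:
        return AgreementCategory.FROM_1_TO_1_5
    if mean_distance < 2.0:
        return AgreementCategory.FROM_1_5_TO_2
    return AgreementCategory.ABOVE_2


def percent_agreement(cats_a, cats_b) -> float:
    """Percentage of positions on which two assessors assign the same bin."""
    cats_a = list(cats_a)
    cats_b = list(cats_b)
    if len(cats_a) != len(cats_b):
        raise ValueError("category lists must have equal length")
    if not cats_a:
        raise ValueError("category lists must be non-empty")
    same = sum(a == b for a, b in zip(cats_a, cats_b))
    return 100.0 * same / len(cats_a)


def rank_sum_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p-value by full enumeration.

    Midranks handle ties.  Returns (U of sample a, p).  The two-sided
    p-value doubles the smaller tail (including the observed value), capped
    at 1 — for identical samples the symmetry of the null gives p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
        dtype=np.int64,
    ).reshape(-1, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    p_le = np.count_nonzero(u_all <= u_obs + eps) / len(u_all)
    p_ge = np.count_nonzero(u_all >= u_obs - eps) / len(u_all)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def compare_directions(means_a, means_b, alpha: float = 0.05) -> DirectionComparison:
    """Compare per-case mean distances of the two registration directions.

    Pooled normality is tested first (Kolmogorov-Smirnov against a normal
    with the pooled sample's moments).  If normal, the unpaired t test runs;
    otherwise the Mann-Whitney U test, with the null distribution enumerated
    exactly for combined n <= 20 and normally approximated above.
    """
    a = np.asarray(means_a, dtype=np.float64)
    b = np.asarray(means_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([a, b])
    sd = pooled.std(ddof=1)
    if sd > 0:
        norm_p = float(sps.kstest(pooled, "norm", args=(pooled.mean(), sd)).pvalue)
    else:
        norm_p = 0.0  # constant sample: treat as non-normal, use ranks
    normal = norm_p >= alpha
    if normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p, name, exact = float(res.statistic), float(res.pvalue), "unpaired t", False
    else:
        if len(pooled) <= EXACT_RANK_SUM_MAX_N:
            stat, p = rank_sum_exact_p(a, b)
            name, exact = "Mann-Whitney U (exact)", True
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p, name, exact = float(res.statistic), float(res.pvalue), "Mann-Whitney U (asymptotic)", False
    return DirectionComparison(
        normality_p=norm_p,
        normal=normal,
        test_name=name,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        exact=exact,
    )
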