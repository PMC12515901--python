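"""Age partitioning: CART cut proposal, Harris-Boyd and Lahti validation.

A depth-limited regression tree proposes candidate age cut points; every
adjacent pair of age bins is then tested with three split-recommending
rules:

* the Harris-Boyd z-test on subgroup means, with critical value
  z* = 3 * sqrt((n1 + n2) / 240);
* the Harris-Boyd SD-ratio rule (split when the larger SD exceeds 1.5x the
  smaller);
* the Lahti proportionality criterion: compute the combined pair's 2.5th
  and 97.5th percentiles and, per subgroup, the percent of observations
  strictly outside each limit; a proportion >= 4.1% or <= 0.9% advises a
  split.

Adjacent bins are merged when none of the three rules supports splitting;
surviving bins are then offered back to the tree for re-subdivision, any
proposed cut being accepted only if the same three rules validate it.  The
loop runs to a fixed point (capped), and every decision is recorded in an
audit trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cleaning import compute_quantile

__all__ = [
    "SubgroupSummary",
    "HBResult",
    "LahtiResult",
    "AgePartition",
    "PartitionDecision",
    "subgroup_summaries",
    "fit_age_tree",
    "harris_boyd",
    "lahti",
    "refine_partition",
    "InsufficientDataError",
]

log = logging.getLogger(__name__)

#: Lahti split thresholds, in percent outside the common limits.
LAHTI_HIGH = 4.1
LAHTI_LOW = 0.9

#: Minimum subgroup size for the Lahti criterion: below this the empirical
#: 2.5th/97.5th percentiles carry no information.
LAHTI_MIN_N = 20

#: SD-ratio threshold of the Harris-Boyd rule.
SD_RATIO_LIMIT = 1.5

#: Default minimum records per age bin.
DEFAULT_MIN_LEAF = 50

#: Bins below this size are flagged in reports (reference-interval guidance
#: recommends at least 120 reference individuals per group).
RECOMMENDED_BIN_N = 120

_MAX_REFINE_PASSES = 20
_GAIN_RTOL = 1e-12


class InsufficientDataError(ValueError):
    """A statistical rule was asked for on too small a subgroup."""


@dataclass
class SubgroupSummary:
    """Sample statistics of one half-open age bin [age_lo, age_hi) months."""

    age_lo_months: int
    age_hi_months: int
    n: int
    mean: float
    sd: float
    q025: float
    q500: float
    q975: float


def subgroup_summaries(ages, values, bins) -> list[SubgroupSummary]:
    """Summaries of single-analyte, single-sex records over age bins.

    ``bins`` is a sequence of half-open (lo, hi) month intervals.  Mean and
    SD are ordinary sample statistics (n-1 denominator; SD 0 for n=1);
    quantiles use the package quantile convention.  Empty bins are omitted
    with a warning.
    """
    ages = np.asarray(ages)
    values = np.asarray(values, dtype=float)
    out = []
    for lo, hi in bins:
        sel = values[(ages >= lo) & (ages < hi)]
        if sel.size == 0:
            log.warning("empty age bin [%s, %s) omitted", lo, hi)
            continue
        out.append(
            SubgroupSummary(
                age_lo_months=int(lo),
                age_hi_months=int(hi),
                n=int(sel.size),
                mean=float(sel.mean()),
                sd=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                q025=compute_quantile(sel, 0.025),
                q500=compute_quantile(sel, 0.5),
                q975=compute_quantile(sel, 0.975),
            )
        )
    return out


def _best_split(
    ages: np.ndarray, values: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best single age cut by SSE reduction, or None if no admissible gain.

    Candidate thresholds are midpoints between consecutive distinct observed
    ages; both children must hold at least ``min_leaf`` points.  Equal gains
    (within 1e-12 relative) resolve to the youngest age.
    """
    order = np.argsort(ages, kind="stable")
    a = ages[order].astype(float)
    v = values[order]
    n = a.size
    if n < 2 * min_leaf:
        return None

    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    # boundaries k: left = first k points; admissible when ages differ across
    # the boundary and both sides hold min_leaf
    ks = np.arange(min_leaf, n - min_leaf + 1)
    ks = ks[a[ks - 1] < a[ks]]
    if ks.size == 0:
        return None
    sl = csum[ks - 1]
    ssl = csq[ks - 1]
    nl = ks.astype(float)
    nr = n - nl
    sse_left = ssl - sl**2 / nl
    sse_right = (csq[-1] - ssl) - (csum[-1] - sl) ** 2 / nr
    gains = total_sse - sse_left - sse_right

    best_gain = float(gains.max())
    tol = _GAIN_RTOL * max(abs(total_sse), 1.0)
    if best_gain <= tol:
        return None
    # youngest age among ties
    tied = np.nonzero(gains >= best_gain - tol)[0]
    k = int(ks[tied[0]])
    threshold = (a[k - 1] + a[k]) / 2.0
    return threshold, best_gain


def fit_age_tree(
    ages, values, max_depth: int = 2, min_leaf: int = DEFAULT_MIN_LEAF
) -> list[float]:
    """Candidate age cut points from recursive binary splitting on age.

    Classic CART regression splitting restricted to the single covariate
    age: each node takes the cut (midpoint between consecutive distinct
    ages) that maximises the squared-error reduction, subject to both
    children holding ``min_leaf`` points, recursing to ``max_depth``.
    Returns the sorted thresholds (at most 2**max_depth - 1); nodes with no
    achievable gain do not split, so constant data yields an empty list.
    """
    ages = np.asarray(ages)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape:
        raise ValueError("ages and values must be paired")
    cuts: list[float] = []

    def recurse(mask: np.ndarray, depth: int) -> None:
        if depth >= max_depth:
            return
        found = _best_split(ages[mask], values[mask], min_leaf)
        if found is None:
            return
        threshold, _ = found
        cuts.append(threshold)
        recurse(mask & (ages < threshold), depth + 1)
        recurse(mask & (ages >= threshold), depth + 1)

    recurse(np.ones(ages.size, dtype=bool), 0)
    return sorted(cuts)


@dataclass
class HBResult:
    """Harris-Boyd comparison of two adjacent subgroups."""

    z: float
    z_star: float
    sd_ratio: float
    split_by_z: bool
    split_by_sd: bool


def harris_boyd(s1: SubgroupSummary, s2: SubgroupSummary) -> HBResult:
    """Harris-Boyd z-test and SD-ratio rule for two adjacent subgroups.

    z = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2) and
    z* = 3 * sqrt((n1 + n2) / 240); |z| > z* supports splitting, as does an
    SD ratio above 1.5.  Two degenerate cases: equal means with zero SDs
    give z = 0; unequal means with zero SDs give an infinite z (logged).
    """
    if s1.n < 2 or s2.n < 2:
        raise InsufficientDataError("harris_boyd: both subgroups need n >= 2")
    z_star = 3.0 * math.sqrt((s1.n + s2.n) / 240.0)
    se = math.sqrt(s1.sd**2 / s1.n + s2.sd**2 / s2.n)
    diff = s1.mean - s2.mean
    if se == 0.0:
        if diff == 0.0:
            z = 0.0
        else:
            z = math.copysign(math.inf, diff)
            log.warning("harris_boyd: zero SDs with unequal means; z = inf")
    else:
        z = diff / se
    sds = sorted([s1.sd, s2.sd])
    sd_ratio = sds[1] / sds[0] if sds[0] > 0 else (math.inf if sds[1] > 0 else 1.0)
    return HBResult(
        z=z,
        z_star=z_star,
        sd_ratio=sd_ratio,
        split_by_z=abs(z) > z_star,
        split_by_sd=sd_ratio > SD_RATIO_LIMIT,
    )


@dataclass
class LahtiResult:
    """Lahti proportionality test of two adjacent subgroups.

    ``proportions`` are percentages: (subgroup1 below the common lower
    limit, subgroup1 above the common upper limit, subgroup2 below,
    subgroup2 above).
    """

    common_lower: float
    common_upper: float
    proportions: tuple[float, float, float, float]
    split: bool


def lahti(values1, values2) -> LahtiResult:
    """Lahti criterion on two adjacent subgroups.

    The 2.5th and 97.5th percentiles of the pooled pair define common
    reference limits; for each subgroup the percent of observations
    strictly below the lower and strictly above the upper limit is
    computed.  Any proportion >= 4.1% or <= 0.9% advises a split.

    Raises
    ------
    InsufficientDataError
        If either subgroup has fewer than 20 observations; callers treat
        this as "no split evidence".
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size < LAHTI_MIN_N or v2.size < LAHTI_MIN_N:
        raise InsufficientDataError(
            f"lahti: subgroups of n={v1.size}, {v2.size} "
            f"(minimum {LAHTI_MIN_N} each)"
        )
    combined = np.concatenate([v1, v2])
    lower = compute_quantile(combined, 0.025)
    upper = compute_quantile(combined, 0.975)
    props = (
        100.0 * float((v1 < lower).sum()) / v1.size,
        100.0 * float((v1 > upper).sum()) / v1.size,
        100.0 * float((v2 < lower).sum()) / v2.size,
        100.0 * float((v2 > upper).sum()) / v2.size,
    )
    split = any(p >= LAHTI_HIGH or p <= LAHTI_LOW for p in props)
    return LahtiResult(
        common_lower=lower, common_upper=upper, proportions=props, split=split
    )


@dataclass
class PartitionDecision:
    """One audited merge/split decision on an adjacent bin pair."""

    left_bin: tuple[int, int]
    right_bin: tuple[int, int]
    hb: HBResult | None
    lahti: LahtiResult | None
    action: str  # "keep" | "merge" | "split" | "reject-split"


@dataclass
class AgePartition:
    """Final ordered age bins for one analyte x sex, with decision audit."""

    analyte: str
    sex: str
    bins: list[tuple[int, int]]
    decisions: list[PartitionDecision] = field(default_factory=list)

    @property
    def edges(self) -> list[int]:
        return [b[0] for b in self.bins] + [self.bins[-1][1]]


def _pair_tests(ages, values, left, right):
    """(HBResult, LahtiResult|None, split_supported) for one adjacent pair."""
    summaries = subgroup_summaries(ages, values, [left, right])
    if len(summaries) != 2:
        return None, None, False
    hb = harris_boyd(summaries[0], summaries[1])
    sel1 = values[(ages >= left[0]) & (ages < left[1])]
    sel2 = values[(ages >= right[0]) & (ages < right[1])]
    try:
        lr = lahti(sel1, sel2)
        lahti_split = lr.split
    except InsufficientDataError:
        lr = None
        lahti_split = False
    supported = hb.split_by_z or hb.split_by_sd or lahti_split
    return hb, lr, supported


def refine_partition(
    ages,
    values,
    candidate_cuts,
    min_leaf: int = DEFAULT_MIN_LEAF,
    max_depth: int = 2,
    analyte: str = "",
    sex: str = "",
) -> AgePartition:
    """Merge/re-split candidate age bins to a validated final partition.

    Starting from the bins induced by ``candidate_cuts`` (plus the data's
    age span), repeat until stable: scan adjacent pairs left to right and
    merge any pair for which none of the three rules (Harris-Boyd z,
    SD-ratio, Lahti) supports splitting; then offer each surviving bin back
    to the regression tree for a single re-subdivision, accepting a proposed
    cut only when the three rules validate it on the resulting pair.  Cuts
    that would create a bin below ``min_leaf`` are never accepted.  The loop
    is capped at 20 passes; every decision lands in the audit trail.
    """
    ages = np.asarray(ages)
    values = np.asarray(values, dtype=float)
    if ages.size == 0:
        raise ValueError("refine_partition: no records")

    lo = int(ages.min())
    hi = int(ages.max()) + 1
    # integer month edges: a float threshold c sends ages < c left
    edges = sorted({lo, hi} | {int(math.ceil(c)) for c in candidate_cuts})
    edges = [e for e in edges if lo <= e <= hi]
    bins = [(a, b) for a, b in zip(edges, edges[1:])]

    def bin_n(b):
        return int(((ages >= b[0]) & (ages < b[1])).sum())

    decisions: list[PartitionDecision] = []

    # drop candidate cuts creating undersized bins (left-to-right)
    i = 0
    while i < len(bins) - 1:
        if bin_n(bins[i]) < min_leaf or (
            i == len(bins) - 2 and bin_n(bins[i + 1]) < min_leaf
        ):
            merged = (bins[i][0], bins[i + 1][1])
            decisions.append(
                PartitionDecision(bins[i], bins[i + 1], None, None, "merge")
            )
            bins[i : i + 2] = [merged]
        else:
            i += 1

    for _ in range(_MAX_REFINE_PASSES):
        changed = False

        # merge pass: greedy left-to-right, repeated until stable
        merging = True
        while merging:
            merging = False
            i = 0
            while i < len(bins) - 1:
                hb, lr, supported = _pair_tests(ages, values, bins[i], bins[i + 1])
                if supported:
                    decisions.append(
                        PartitionDecision(bins[i], bins[i + 1], hb, lr, "keep")
                    )
                    i += 1
                else:
                    decisions.append(
                        PartitionDecision(bins[i], bins[i + 1], hb, lr, "merge")
                    )
                    bins[i : i + 2] = [(bins[i][0], bins[i + 1][1])]
                    changed = True
                    merging = True

        # re-split pass: one validated tree cut per bin
        new_bins: list[tuple[int, int]] = []
        for b in bins:
            mask = (ages >= b[0]) & (ages < b[1])
            sub_cuts = fit_age_tree(
                ages[mask], values[mask], max_depth=1, min_leaf=min_leaf
            )
            accepted = False
            if sub_cuts:
                cut = int(math.ceil(sub_cuts[0]))
                left, right = (b[0], cut), (cut, b[1])
                if bin_n(left) >= min_leaf and bin_n(right) >= min_leaf:
                    hb, lr, supported = _pair_tests(ages, values, left, right)
                    if supported:
                        decisions.append(
                            PartitionDecision(left, right, hb, lr, "split")
                        )
                        new_bins.extend([left, right])
                        accepted = True
                        changed = True
                    else:
                        decisions.append(
                            PartitionDecision(left, right, hb, lr, "reject-split")
                        )
            if not accepted:
                new_bins.append(b)
        bins = new_bins

        if not changed:
            break
    else:
        log.warning("refine_partition: pass cap reached before stability")

    return AgePartition(analyte=analyte, sex=sex, bins=bins, decisions=decisions)
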