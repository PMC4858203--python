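"""Statistical comparisons: KS tests of mutation-count distributions and
Pearson correlation of per-site mutation profiles.

Replica crosses of the same construct are checked for congruence with the
two-sample Kolmogorov-Smirnov test; the minimum pairwise p-value across all
replica pairs is the reported congruence statistic.  No multiple-testing
correction is applied; p_min < 0.05 is only flagged in logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .calling import SiteProfile

_log = logging.getLogger(__name__)

# exact two-sample KS p-values are computed when n*m is at most this
EXACT_LIMIT = 10_000


@dataclass
class CountSample:
    """Per-spore mutation totals for one construct/cross."""

    label: str
    values: Sequence[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size < 1:
            raise ValueError(f"sample {self.label!r} is empty")
        if (self.values < 0).any():
            raise ValueError(f"sample {self.label!r} has negative counts")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class KsResult:
    statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic"


def _pooled_boundary_counts(a: np.ndarray, b: np.ndarray):
    """Per distinct pooled value: (count in a, count in b), plus the integer
    KS height M = max |i*m - j*n| over the observed ECDF boundaries."""
    a, b = np.sort(a), np.sort(b)
    grid = np.unique(np.concatenate([a, b]))
    ca = np.diff(np.searchsorted(a, grid, side="right"), prepend=0)
    cb = np.diff(np.searchsorted(b, grid, side="right"), prepend=0)
    n, m = a.size, b.size
    i = np.cumsum(ca)
    j = np.cumsum(cb)
    M = int(np.abs(i * m - j * n).max())
    return list(zip(ca.tolist(), cb.tolist())), M


def _exact_ks_pvalue(a: np.ndarray, b: np.ndarray, M: int,
                     groups: list[tuple[int, int]]) -> float:
    """Permutation-exact two-sided p-value by recursion over label
    assignments of the pooled sample.

    Equivalent to enumerating all C(n+m, n) assignments of the pooled
    values to the two samples and taking the fraction whose KS statistic
    reaches the observed one; ties are respected exactly because the ECDFs
    are only compared at the distinct pooled values.  Computed by dynamic
    programming over tie groups in exact integer arithmetic: paths are
    counted that keep |i*m - j*n| < M at every group boundary, where (i, j)
    are the items assigned to each sample so far.
    """
    from math import comb

    n, m = int(a.size), int(b.size)
    if M == 0:  # identical ECDFs: no assignment can be more extreme
        return 1.0
    # survivors[i] = number of ways to reach i items in sample a after the
    # current group while never touching |i*m - j*n| >= M
    survivors = {0: 1}
    total_so_far = 0
    for ca, cb in groups:
        c = ca + cb
        nxt: dict[int, int] = {}
        total_so_far += c
        for i_prev, ways in survivors.items():
            placed_prev = total_so_far - c
            j_prev = placed_prev - i_prev
            for take in range(c + 1):
                i = i_prev + take
                j = j_prev + (c - take)
                if i > n or j > m:
                    continue
                if abs(i * m - j * n) >= M:
                    continue
                nxt[i] = nxt.get(i, 0) + ways * comb(c, take)
        survivors = nxt
    below = survivors.get(n, 0)
    return 1.0 - below / comb(n + m, n)


def ks_compare(a: CountSample, b: CountSample) -> KsResult:
    """Two-sided two-sample KS test of two count samples.

    D is the maximum absolute difference between the two empirical CDFs,
    evaluated at the pooled unique values.  For n*m <= 10,000 the p-value
    is the permutation-exact one (it equals full enumeration over all
    C(n+m, n) label assignments, ties included); larger samples use the
    asymptotic Kolmogorov distribution.  The method used is reported.
    """
    av = np.asarray(a.values)
    bv = np.asarray(b.values)
    groups, M = _pooled_boundary_counts(av, bv)
    statistic = M / (a.n * b.n)
    if a.n * b.n <= EXACT_LIMIT:
        return KsResult(statistic, _exact_ks_pvalue(av, bv, M, groups), "exact")
    res = sps.ks_2samp(av, bv, alternative="two-sided", method="asymp")
    return KsResult(statistic, float(min(res.pvalue, 1.0)), "asymptotic")


@dataclass
class CongruenceResult:
    """Minimum pairwise KS p across replica crosses of one construct."""

    p_min: Optional[float]
    applicable: bool
    worst_pair: Optional[tuple[str, str]] = None
    pairwise: list[tuple[str, str, KsResult]] = field(default_factory=list)


def replica_congruence(crosses: Sequence[CountSample]) -> CongruenceResult:
    """KS congruence of replica crosses: the lowest p over all pairs.

    With a single cross the comparison is not applicable and a flagged
    result (p_min None) is returned rather than an error.  Samples are
    never pooled here; pooling is the caller's decision.
    """
    if len(crosses) < 2:
        _log.info("replica congruence not applicable: %d cross(es)", len(crosses))
        return CongruenceResult(p_min=None, applicable=False)
    result = CongruenceResult(p_min=None, applicable=True)
    for a, b in combinations(crosses, 2):
        ks = ks_compare(a, b)
        result.pairwise.append((a.label, b.label, ks))
        if result.p_min is None or ks.pvalue < result.p_min:
            result.p_min = ks.pvalue
            result.worst_pair = (a.label, b.label)
    if result.p_min is not None and result.p_min < 0.05:
        _log.warning(
            "replica congruence p_min=%.4g < 0.05 for pair %s",
            result.p_min, result.worst_pair,
        )
    return result


def profile_correlation(
    p1: SiteProfile,
    p2: SiteProfile,
    region: Optional[tuple[int, int]] = None,
) -> Optional[float]:
    """Pearson correlation of two per-site profiles over a 1-based region.

    Counts and percents give the same r (Pearson is scale-invariant).
    Returns None when either profile has zero variance over the region
    (the correlation is undefined there).
    """
    if region is None:
        region = (1, min(p1.length, p2.length))
    lo, hi = region
    if lo < 1 or hi > p1.length or hi > p2.length or lo > hi:
        raise ValueError(f"region {region} not covered by both profiles")
    x = p1.site_counts[lo - 1 : hi].astype(float)
    y = p2.site_counts[lo - 1 : hi].astype(float)
    if x.std() == 0 or y.std() == 0:
        _log.warning("profile correlation undefined: zero variance in region %s", region)
        return None
    r, _ = sps.pearsonr(x, y)
    return float(r)
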