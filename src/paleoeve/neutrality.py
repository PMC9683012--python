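"""Neutrality test for an EVE region against a resampled noncoding null.

The observable is the set of pairwise p-distances between taxa computed over
the EVE region, compared with the pooled distances over randomly placed
noncoding regions of the same length.  A one-tailed Kolmogorov-Smirnov
statistic quantifies whether the EVE distances are stochastically smaller
than the noncoding ones, which is the signature of purifying constraint.

Because pairwise distances share the underlying species tree they are not
independent draws, so the classical KS p-value is only a reference number;
the calibrated inference is the region-rank permutation test
(:func:`ks_region_rank_test`), which exploits exchangeability of the focal
region with the null regions under neutrality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .alnkit import MultipleAlignment, pairwise_p_distance


@dataclass
class EmpiricalDistribution:
    label: str
    values: np.ndarray
    n_undefined: int = 0
    source_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("p-distances must lie in [0, 1]")
        self.values = v[~np.isnan(v)]


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    alternative: str
    n_focal: int
    n_null: int
    method: str

    def __post_init__(self):
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("KS statistic must be in [0, 1]")


@dataclass(frozen=True)
class Interval:
    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval {self.name!r} is empty")


# ---------------------------------------------------------------------------
# Null-region sampling
# ---------------------------------------------------------------------------

def sample_noncoding_regions(
    excluded: list[tuple[int, int]],
    window: tuple[int, int],
    length: int,
    n: int,
    seed: int,
) -> list[tuple[int, int]]:
    """Place ``n`` regions of ``length`` uniformly in ``window``.

    Regions never intersect any excluded interval (annotated genes and the
    EVE itself) but may overlap each other; placements are drawn without
    replacement from the distinct admissible start positions.  If fewer than
    ``n`` are admissible, the error reports the achievable number.
    """
    lo, hi = window
    if length <= 0 or hi - lo < length:
        raise ValueError("window shorter than the requested region length")
    occupied = np.zeros(hi - lo, dtype=bool)
    for s, e in excluded:
        s, e = max(s, lo), min(e, hi)
        if s < e:
            occupied[s - lo:e - lo] = True
    cum = np.concatenate(([0], np.cumsum(occupied)))
    starts = np.arange(0, hi - lo - length + 1)
    free = (cum[starts + length] - cum[starts]) == 0
    candidates = starts[free] + lo
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} placeable windows of length {length}; "
            f"requested {n}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    return [(int(s), int(s) + length) for s in sorted(chosen)]


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------

def region_distances(aln: MultipleAlignment, region: tuple[int, int]) -> np.ndarray:
    """Condensed pairwise p-distances over one alignment-column region."""
    sub = aln.slice_columns(*region)
    return pairwise_p_distance(sub).condensed()


def tiled_region_distances(aln: MultipleAlignment, length: int,
                           n_regions: int) -> list[np.ndarray]:
    """Condensed p-distances for ``n_regions`` consecutive windows of
    ``length`` columns — vectorised equivalent of calling
    :func:`region_distances` window by window."""
    arr = aln.to_array()[:, : n_regions * length]
    arr = np.where((arr >= ord("a")) & (arr <= ord("z")), arr - 32, arr)
    valid = np.isin(arr, _ACGT_BYTES)
    ntax = arr.shape[0]
    out = [np.empty(ntax * (ntax - 1) // 2) for _ in range(n_regions)]
    k = 0
    for i in range(ntax):
        for j in range(i + 1, ntax):
            both = (valid[i] & valid[j]).reshape(n_regions, length)
            diff = ((arr[i] != arr[j]) & valid[i] & valid[j]).reshape(n_regions, length)
            den = both.sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = diff.sum(axis=1) / den
            for r in range(n_regions):
                out[r][k] = d[r]
            k += 1
    return out


_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def build_distance_samples(
    aln: MultipleAlignment,
    eve_region: tuple[int, int],
    null_regions: list[tuple[int, int]],
) -> tuple[EmpiricalDistribution, EmpiricalDistribution]:
    """Pooled distance distributions for the EVE and for all null regions.

    Taxon pairs without comparable sites in a region are skipped and counted
    in ``n_undefined``.
    """
    eve_vals = region_distances(aln, eve_region)
    n_und = int(np.isnan(eve_vals).sum())
    eve = EmpiricalDistribution("eve", eve_vals, n_und, [eve_region])
    null_vals, null_und = [], 0
    for region in null_regions:
        v = region_distances(aln, region)
        null_und += int(np.isnan(v).sum())
        null_vals.append(v)
    pooled = np.concatenate(null_vals) if null_vals else np.empty(0)
    null = EmpiricalDistribution("noncoding", pooled, null_und, list(null_regions))
    return eve, null


# ---------------------------------------------------------------------------
# One-tailed Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _dplus(focal: np.ndarray, null: np.ndarray) -> float:
    """sup_x [F_focal(x) - F_null(x)]: positive when focal values run smaller."""
    focal = np.sort(focal)
    null = np.sort(null)
    m, n = len(focal), len(null)
    # sup of a right-continuous difference is attained at focal jump points
    f_focal = np.arange(1, m + 1) / m
    f_null = np.searchsorted(null, focal, side="right") / n
    return float(max(0.0, np.max(f_focal - f_null)))


def ks_test_one_tailed(
    sample_focal,
    sample_null,
    alternative: str = "less",
    method: str = "asymptotic",
    n_permutations: int = 9999,
    seed: int = 0,
    exact_limit: int = 20000,
) -> KSResult:
    """One-tailed two-sample KS test.

    ``alternative='less'`` tests whether the focal sample is stochastically
    smaller (its ECDF lies above), using D+ = sup [F_focal - F_null]; the
    asymptotic one-sided p-value is exp(-2 m n D^2 / (m + n)).  The
    permutation method relabels pooled values (exhaustively when the number
    of splits is at most ``exact_limit``); it treats the values as
    exchangeable, which pairwise distances are not — see
    :func:`ks_region_rank_test` for the calibrated region-level test.
    """
    a = np.asarray(sample_focal, dtype=float)
    b = np.asarray(sample_null, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative == "less":
        d = _dplus(a, b)
    elif alternative == "greater":
        d = _dplus(-a, -b)
    else:
        raise ValueError("alternative must be 'less' or 'greater'")
    m, n = len(a), len(b)

    if method == "asymptotic":
        p = min(1.0, math.exp(-2.0 * m * n * d * d / (m + n)))
    elif method == "permutation":
        pooled = np.concatenate([a, b])
        total = math.comb(m + n, m)
        count = 0
        if total <= exact_limit:
            n_splits = total
            for idx in combinations(range(m + n), m):
                mask = np.zeros(m + n, dtype=bool)
                mask[list(idx)] = True
                da = pooled[mask] if alternative == "less" else -pooled[mask]
                db = pooled[~mask] if alternative == "less" else -pooled[~mask]
                if _dplus(da, db) >= d - 1e-12:
                    count += 1
        else:
            rng = np.random.default_rng(seed)
            n_splits = n_permutations + 1
            count = 1  # the observed split
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                da = perm[:m] if alternative == "less" else -perm[:m]
                db = perm[m:] if alternative == "less" else -perm[m:]
                if _dplus(da, db) >= d - 1e-12:
                    count += 1
        p = count / n_splits
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return KSResult(d, p, alternative, m, n, method)


def ks_region_rank_test(
    focal_values: np.ndarray,
    null_values_by_region: list[np.ndarray],
    alternative: str = "less",
) -> KSResult:
    """Region-level permutation KS test (calibrated under region exchangeability).

    The observed D+ of the focal region against the pool of all other
    regions is ranked among the D+ obtained by letting each null region play
    the focal role in turn; p = (1 + #{D_r >= D_obs}) / (R + 1).  Under
    neutral evolution the focal region is exchangeable with the null
    regions, so the p-value is exactly uniform on its achievable grid even
    though pairwise distances within a region are dependent.
    """
    regions = [np.asarray(focal_values, dtype=float)]
    regions += [np.asarray(v, dtype=float) for v in null_values_by_region]
    regions = [r[~np.isnan(r)] for r in regions]
    if any(len(r) == 0 for r in regions):
        raise ValueError("every region must contribute at least one distance")
    sign = 1.0 if alternative == "less" else -1.0
    stats = []
    for i, reg in enumerate(regions):
        rest = np.concatenate([r for j, r in enumerate(regions) if j != i])
        stats.append(_dplus(sign * reg, sign * rest))
    d_obs = stats[0]
    r = len(regions) - 1
    count = sum(1 for s in stats[1:] if s >= d_obs - 1e-12)
    p = (1 + count) / (r + 1)
    return KSResult(d_obs, p, alternative, len(regions[0]),
                    sum(len(x) for x in regions[1:]), "region-rank")


# ---------------------------------------------------------------------------
# piRNA-cluster overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapRecord:
    cluster: str
    overlap_start: int
    overlap_end: int

    @property
    def length(self) -> int:
        return self.overlap_end - self.overlap_start


def pirna_overlap(eve_region: tuple[int, int], clusters: list[Interval]) -> list[OverlapRecord]:
    """Clusters intersecting the EVE interval (half-open; touching is not overlap)."""
    lo, hi = eve_region
    out = []
    for c in clusters:
        s, e = max(lo, c.start), min(hi, c.end)
        if s < e:
            out.append(OverlapRecord(c.name, s, e))
    return out
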