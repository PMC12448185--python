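"""Cohort-consistent segmentation.

Four optional steps applied in order: (i) choose regions of interest,
(ii) subtract exclusion regions with a fragment filter of size ``f``,
(iii) pool every sample's breakpoints, merge them greedily within distance
``m``, and split the regions at the merged positions, (iv) subdivide into
fixed-width bins of split size ``s`` with one of three strategies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .genome import ReferenceGenome, Region
from .io import RegionSet
from .profile import CNProfile

__all__ = [
    "Segmentation",
    "SegmentationParams",
    "bin_region",
    "cohort_breakpoints",
    "consistent_segmentation",
    "merge_breakpoints",
    "subtract_exclusions",
]

STRATEGIES = ("a", "b", "c")


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the four-step segmentation pipeline.

    filter_size ``f``: exclusion regions and leftover fragments smaller than
    this are dropped. merge_distance ``m``: breakpoints within this distance
    of the cluster anchor are averaged into one. split_size ``s``: target bin
    width; 0 disables binning. strategy: 'a' (start-anchored), 'b'
    (centered padding), or 'c' (equal-size bins).
    """

    filter_size: int = 0
    merge_distance: int = 0
    split_size: int = 0
    strategy: str = "a"

    def __post_init__(self) -> None:
        if min(self.filter_size, self.merge_distance, self.split_size) < 0:
            raise ValueError("f, m, s must be non-negative")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown binning strategy {self.strategy!r}")


@dataclass
class Segmentation:
    """A cohort-shared, disjoint, sorted list of segments plus provenance."""

    regions: List[Region]
    params: Optional[SegmentationParams] = None
    source: str = "custom"

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"segmentation regions overlap: {a} / {b}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


# ---------------------------------------------------------------------------
# step ii: exclusion subtraction


def _subtract_one(region: Region, exclusions: Sequence[Region]) -> List[Region]:
    pieces = [(region.start, region.end)]
    for ex in exclusions:
        nxt = []
        for s, e in pieces:
            if ex.end <= s or ex.start >= e:
                nxt.append((s, e))
                continue
            if ex.start > s:
                nxt.append((s, ex.start))
            if ex.end < e:
                nxt.append((ex.end, e))
        pieces = nxt
    return [Region(region.chrom, s, e, region.name) for s, e in pieces]


def subtract_exclusions(
    regions: RegionSet, exclusions: RegionSet, filter_size: int = 0
) -> RegionSet:
    """Remove exclusion regions, with fragment filtering.

    Exclusion regions shorter than ``filter_size`` are ignored, and any
    fragment shorter than ``filter_size`` left after subtraction is dropped.
    """
    usable = [ex for ex in exclusions if ex.length >= filter_size]
    by_chrom: Dict[str, List[Region]] = {}
    for ex in usable:
        by_chrom.setdefault(ex.chrom, []).append(ex)
    out: List[Region] = []
    for region in regions:
        for frag in _subtract_one(region, by_chrom.get(region.chrom, [])):
            if frag.length >= max(filter_size, 1):
                out.append(frag)
    return RegionSet(regions.name, out)


# ---------------------------------------------------------------------------
# step iii: greedy breakpoint merging


def merge_breakpoints(positions: Sequence[int], merge_distance: int) -> List[int]:
    """Greedy left-to-right clustering of breakpoint positions.

    Starting at the leftmost unmerged breakpoint (the anchor), every
    position within ``merge_distance`` of the anchor joins the cluster; the
    cluster is replaced by the floor of its arithmetic mean, and the scan
    restarts at the next unmerged position. Output is strictly increasing.
    """
    pos = sorted(int(p) for p in positions)
    if len(pos) != len(set(pos)):
        pos = sorted(set(pos))
    out: List[int] = []
    i = 0
    n = len(pos)
    while i < n:
        anchor = pos[i]
        j = i
        while j + 1 < n and pos[j + 1] - anchor <= merge_distance:
            j += 1
        cluster = pos[i : j + 1]
        out.append(int(sum(cluster) // len(cluster)))
        i = j + 1
    return out


def cohort_breakpoints(cohort: "Dict[str, CNProfile] | Iterable[CNProfile]") -> Dict[str, List[int]]:
    """Union of all samples' segment boundaries per chromosome.

    Boundaries at position 0 or at the chromosome end are not breakpoints.
    """
    profiles = list(cohort.values()) if isinstance(cohort, dict) else list(cohort)
    out: Dict[str, set] = {}
    for p in profiles:
        for chrom, grp in p.segments.groupby("chrom", sort=False):
            chrom_len = p.genome.length_of(chrom)
            acc = out.setdefault(chrom, set())
            for v in np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()]):
                if 0 < v < chrom_len:
                    acc.add(int(v))
    return {c: sorted(v) for c, v in out.items()}


def _split_at(region: Region, positions: Iterable[int]) -> List[Region]:
    cuts = sorted(p for p in positions if region.start < p < region.end)
    bounds = [region.start, *cuts, region.end]
    return [
        Region(region.chrom, s, e, region.name)
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# step iv: binning


def bin_region(region: Region, split_size: int, strategy: str = "a") -> List[Region]:
    """Subdivide one region into ~``split_size`` bins; bins tile it exactly.

    Strategy 'a' inserts boundaries every ``s`` bases from the start and
    merges a final remainder bin into its predecessor when it is shorter
    than s/2. Strategy 'b' splits the remainder across both ends, merging
    end bins shorter than s/2 into their neighbours. Strategy 'c' emits
    equal-length bins: with c = floor(L/s) + 1 bins counting the padding
    bin, it uses c-1 bins when the padding is <= s/2 and c bins otherwise;
    integer boundaries by half-up rounding of cumulative positions, so bin
    lengths differ by at most one base.
    """
    s = int(split_size)
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    if s <= 0:
        raise ValueError("split size must be positive")
    L = region.length
    if L <= s:
        return [region]

    if strategy == "a":
        bounds = list(range(region.start, region.end, s))
        remainder = L % s
        if 0 < remainder < s / 2:
            bounds.pop()  # merge short tail into its predecessor
        bounds.append(region.end)
    elif strategy == "b":
        remainder = L % s
        pad_left = remainder // 2
        first = region.start + pad_left
        bounds = [region.start]
        if pad_left > 0:
            bounds.append(first)
        bounds.extend(range(first + s, region.end, s))
        bounds.append(region.end)
        # merge sub-half-size end bins into their neighbours
        if len(bounds) > 2 and bounds[1] - bounds[0] < s / 2:
            del bounds[1]
        if len(bounds) > 2 and bounds[-1] - bounds[-2] < s / 2:
            del bounds[-2]
    else:  # strategy c: equal-size bins
        c = L // s + 1  # bin count including the padding bin
        padding = L % s
        n_bins = c - 1 if padding <= s / 2 else c
        bounds = [region.start + int(np.floor(k * L / n_bins + 0.5)) for k in range(n_bins)]
        bounds.append(region.end)
    return [
        Region(region.chrom, a, b, region.name) for a, b in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# the full pipeline


def consistent_segmentation(
    regions: RegionSet,
    exclusions: Optional[RegionSet] = None,
    params: Optional[SegmentationParams] = None,
    cohort: "Optional[Dict[str, CNProfile]]" = None,
    use_cohort_breakpoints: bool = False,
) -> Segmentation:
    """Run steps i-iv; every step other than (i) is optional.

    With ``use_cohort_breakpoints`` the union of the cohort's breakpoints is
    clipped to the surviving regions, merged with ``merge_distance``, and
    used to split the regions before binning.
    """
    params = params or SegmentationParams()
    current = regions
    if exclusions is not None:
        current = subtract_exclusions(current, exclusions, params.filter_size)

    pieces: List[Region] = list(current)
    if use_cohort_breakpoints:
        if not cohort:
            raise ValueError("use_cohort_breakpoints requires a non-empty cohort")
        bps = cohort_breakpoints(cohort)
        split: List[Region] = []
        for region in pieces:
            inside = [p for p in bps.get(region.chrom, []) if region.start < p < region.end]
            merged = merge_breakpoints(inside, params.merge_distance)
            split.extend(_split_at(region, merged))
        pieces = split

    if params.split_size > 0:
        binned: List[Region] = []
        for region in pieces:
            binned.extend(bin_region(region, params.split_size, params.strategy))
        pieces = binned

    return Segmentation(pieces, params=params, source=regions.name)
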