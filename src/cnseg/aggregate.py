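"""Project profiles onto a shared segmentation: the samples x segments matrix."""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .genome import Region
from .profile import CNProfile
from .segmentation import Segmentation

__all__ = ["AggregatedMatrix", "aggregate", "aggregate_cohort", "refine"]

HOW = ("min", "max", "mean", "none")


@dataclass
class AggregatedMatrix:
    """Samples x segments CN values, one matrix per allele.

    ``values`` maps an allele column name (``cn_major``, ``cn_minor`` or
    ``cn_total``) to a float matrix of shape (n_samples, n_segments).
    Missing cells (segments with no covered base) are NaN.
    """

    sample_ids: List[str]
    segments: List[Region]
    values: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.segments))
        for allele, mat in self.values.items():
            if mat.shape != shape:
                raise ValueError(
                    f"matrix for {allele} has shape {mat.shape}, expected {shape}"
                )

    @property
    def allele_names(self) -> List[str]:
        return list(self.values)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total(self) -> np.ndarray:
        """Total-CN matrix (sum across alleles)."""
        return np.sum(list(self.values.values()), axis=0)

    def row(self, sample_id: str) -> Dict[str, np.ndarray]:
        i = self.sample_ids.index(sample_id)
        return {a: m[i] for a, m in self.values.items()}

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        single = len(self.values) == 1
        for allele, mat in self.values.items():
            suffix = "" if single else f":{allele.removeprefix('cn_')}"
            for j, seg in enumerate(self.segments):
                cols[f"{seg.chrom}:{seg.start}-{seg.end}{suffix}"] = mat[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AggregatedMatrix":
        pat = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?::(?P<allele>\w+))?$")
        segments: List[Region] = []
        seg_index: Dict[Region, int] = {}
        parsed = []
        for col in df.columns:
            m = pat.match(col)
            if not m:
                raise ValueError(f"unparseable matrix column {col!r}")
            region = Region(m["chrom"], int(m["start"]), int(m["end"]))
            if region not in seg_index:
                seg_index[region] = len(segments)
                segments.append(region)
            allele = f"cn_{m['allele']}" if m["allele"] else "cn_total"
            parsed.append((col, allele, seg_index[region]))
        alleles = sorted({a for _, a, _ in parsed})
        values = {
            a: np.full((len(df), len(segments)), np.nan) for a in alleles
        }
        for col, allele, j in parsed:
            values[allele][:, j] = df[col].to_numpy(dtype=float)
        return cls(list(df.index.astype(str)), segments, values)


# ---------------------------------------------------------------------------


def _pieces_in(profile: CNProfile, region: Region):
    """Covered (length, values) pieces of the profile inside one region."""
    starts, ends, vals = profile.chrom_arrays(region.chrom)
    lo = np.maximum(starts, region.start)
    hi = np.minimum(ends, region.end)
    mask = lo < hi
    return (hi - lo)[mask], vals[mask]


def aggregate(
    profile: CNProfile, seg: Segmentation, how: str = "mean"
) -> Dict[str, np.ndarray]:
    """One CN value per segment and allele: min, max, or length-weighted mean.

    Aggregation only weighs covered bases; a segment with no covered base
    for an allele yields NaN, never a silent 0.
    """
    if how not in ("min", "max", "mean"):
        raise ValueError(f"unknown aggregation {how!r} (use refine() for 'none')")
    cols = profile.allele_columns
    out = {c: np.full(len(seg.regions), np.nan) for c in cols}
    for j, region in enumerate(seg.regions):
        lengths, vals = _pieces_in(profile, region)
        for k, col in enumerate(cols):
            v = vals[:, k]
            ok = ~np.isnan(v)
            if not ok.any():
                continue
            if how == "min":
                out[col][j] = np.min(v[ok])
            elif how == "max":
                out[col][j] = np.max(v[ok])
            else:
                w = lengths[ok]
                out[col][j] = float(np.dot(v[ok], w) / w.sum())
    return out


def refine(profile: CNProfile, seg: Segmentation) -> CNProfile:
    """The ``none`` strategy: restrict the profile to the segmentation,
    splitting segments at segmentation boundaries without merging values."""
    rows = []
    cols = profile.allele_columns
    for region in seg.regions:
        starts, ends, vals = profile.chrom_arrays(region.chrom)
        lo = np.maximum(starts, region.start)
        hi = np.minimum(ends, region.end)
        for s, e, v in zip(lo, hi, vals):
            if s < e:
                rows.append({"chrom": region.chrom, "start": int(s), "end": int(e),
                             **dict(zip(cols, v))})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *cols])
    return profile.with_segments(df)


def aggregate_cohort(
    cohort: Dict[str, CNProfile], seg: Segmentation, how: str = "mean"
) -> AggregatedMatrix:
    """Aggregate every profile; rows follow input order, columns follow seg."""
    profiles = list(cohort.values())
    if not profiles:
        raise ValueError("empty cohort")
    modes = {p.mode for p in profiles}
    if len(modes) > 1:
        raise ValueError("cohort mixes total and allele-specific profiles")
    cols = profiles[0].allele_columns
    values = {c: np.full((len(profiles), len(seg.regions)), np.nan) for c in cols}
    for i, p in enumerate(profiles):
        row = aggregate(p, seg, how)
        for c in cols:
            values[c][i] = row[c]
    return AggregatedMatrix([p.sample_id for p in profiles], list(seg.regions), values)
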