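"""The per-sample copy-number profile container shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .genome import CoordinateError, ReferenceGenome, Sex

__all__ = ["CNProfile", "ValidationError", "ALLELE_SPECIFIC", "TOTAL"]

ALLELE_SPECIFIC = "allele_specific"
TOTAL = "total"

SEGMENT_COLUMNS = ["chrom", "start", "end"]


class ValidationError(ValueError):
    """Input segments violate the profile contract (overlap, bad CN, ...)."""


@dataclass
class CNProfile:
    """One sample's ordered, non-overlapping copy-number segments.

    ``segments`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    and either ``cn_major``/``cn_minor`` (mode ``allele_specific``) or
    ``cn_total`` (mode ``total``). Coordinates are 0-based half-open.
    Missing CN values are NaN; fractional values are preserved.
    """

    sample_id: str
    segments: pd.DataFrame
    mode: str
    genome: ReferenceGenome
    declared_sex: Optional[Sex] = None
    _sex: Optional[Sex] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in (ALLELE_SPECIFIC, TOTAL):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        cols = SEGMENT_COLUMNS + self.allele_columns
        missing = [c for c in cols if c not in self.segments.columns]
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: segment table lacks columns {missing}"
            )
        seg = self.segments.loc[:, cols].copy()
        seg["start"] = seg["start"].astype(np.int64)
        seg["end"] = seg["end"].astype(np.int64)
        for c in self.allele_columns:
            seg[c] = seg[c].astype(float)
        seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.segments = seg
        self.validate()

    # -- contract --------------------------------------------------------

    @property
    def allele_columns(self) -> list:
        return ["cn_major", "cn_minor"] if self.mode == ALLELE_SPECIFIC else ["cn_total"]

    def validate(self) -> None:
        seg = self.segments
        bad = seg["start"] >= seg["end"]
        if bad.any():
            row = seg[bad].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id}: empty or inverted segment "
                f"{row.chrom}:{row.start}-{row.end}"
            )
        vals = seg[self.allele_columns].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError(f"sample {self.sample_id}: negative CN value")
        for chrom, grp in seg.groupby("chrom", sort=False):
            if chrom not in self.genome:
                raise CoordinateError(
                    f"sample {self.sample_id}: unknown chromosome {chrom!r} "
                    f"for genome {self.genome.name}"
                )
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ovl = starts[1:] < ends[:-1]
            if ovl.any():
                i = int(np.argmax(ovl))
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            if ends[-1] > self.genome.length_of(chrom):
                raise ValidationError(
                    f"sample {self.sample_id}: segment beyond end of {chrom} "
                    f"({ends[-1]} > {self.genome.length_of(chrom)})"
                )

    # -- derived ---------------------------------------------------------

    @property
    def sex(self) -> Sex:
        if self.declared_sex is not None:
            return self.declared_sex
        if self._sex is None:
            from .genome import infer_sex

            object.__setattr__(self, "_sex", infer_sex(self, self.genome))
        return self._sex

    def chrom_arrays(self, chrom: str):
        """(starts, ends, values[n, n_alleles]) for one chromosome; sorted."""
        grp = self.segments[self.segments["chrom"] == chrom]
        return (
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
            grp[self.allele_columns].to_numpy(dtype=float),
        )

    def with_segments(self, segments: pd.DataFrame) -> "CNProfile":
        return replace(self, segments=segments, _sex=self._sex)

    def total_values(self) -> pd.Series:
        """Per-segment total CN (major+minor, or cn_total)."""
        if self.mode == TOTAL:
            return self.segments["cn_total"]
        return self.segments["cn_major"] + self.segments["cn_minor"]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CNProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.mode == other.mode
            and self.genome.name == other.genome.name
            and self.segments.shape == other.segments.shape
            and self.segments.reset_index(drop=True).equals(
                other.segments.reset_index(drop=True)
            )
        )
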