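"""Readers and writers for segment tables, BED files, and UCSC track formats.

All files are plain TSV. Input coordinates may be 0-based half-open (the
internal convention) or 1-based inclusive; the :class:`Dialect` converts at
the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import CoordinateError, ReferenceGenome, Region, Sex
from .profile import ALLELE_SPECIFIC, TOTAL, CNProfile, ValidationError

__all__ = [
    "Dialect",
    "RegionSet",
    "load_region_set",
    "read_bed",
    "read_cytobands",
    "read_segments",
    "write_bed",
    "write_matrix",
    "read_matrix",
    "write_segments",
]

PREDEFINED_REGION_KINDS = (
    "chromosomes",
    "arms",
    "cytobands",
    "cosmic_genes",
    "ensembl_genes",
)


@dataclass(frozen=True)
class Dialect:
    """Column mapping and coordinate-base convention of a segment table."""

    sample_id: str = "sample_id"
    chrom: str = "chrom"
    start: str = "start"
    end: str = "end"
    cn_major: str = "cn_major"
    cn_minor: str = "cn_minor"
    cn_total: str = "cn_total"
    one_based: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Dialect":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class RegionSet:
    """A named, sorted collection of genomic regions."""

    name: str
    regions: List[Region]

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self) -> Dict[str, List[Region]]:
        out: Dict[str, List[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def total_length(self) -> int:
        return sum(r.length for r in self.regions)


# ---------------------------------------------------------------------------
# segment tables


def read_segments(
    path,
    genome: ReferenceGenome,
    dialect: Optional[Dialect] = None,
    sex_map: Optional[Dict[str, Sex]] = None,
) -> Dict[str, CNProfile]:
    """Read a TSV segment table into a cohort of per-sample profiles.

    The table must carry either major(+minor) or total CN columns,
    consistently for the whole file. Returns a mapping preserving first
    appearance order of samples.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in (dialect.sample_id, dialect.chrom, dialect.start, dialect.end):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")

    has_major = dialect.cn_major in df.columns
    has_total = dialect.cn_total in df.columns
    if has_major:
        mode = ALLELE_SPECIFIC
    elif has_total:
        mode = TOTAL
    else:
        raise ValidationError(
            f"{path}: need either {dialect.cn_major!r} or {dialect.cn_total!r} column"
        )

    out = pd.DataFrame(
        {
            "sample_id": df[dialect.sample_id].astype(str),
            "chrom": df[dialect.chrom].astype(str),
            "start": df[dialect.start].astype(np.int64),
            "end": df[dialect.end].astype(np.int64),
        }
    )
    if dialect.one_based:
        out["start"] = out["start"] - 1
    if mode == ALLELE_SPECIFIC:
        out["cn_major"] = pd.to_numeric(df[dialect.cn_major], errors="coerce")
        if dialect.cn_minor in df.columns:
            out["cn_minor"] = pd.to_numeric(df[dialect.cn_minor], errors="coerce")
        else:
            out["cn_minor"] = np.nan
    else:
        out["cn_total"] = pd.to_numeric(df[dialect.cn_total], errors="coerce")

    cohort: Dict[str, CNProfile] = {}
    for sample_id, grp in out.groupby("sample_id", sort=False):
        declared = sex_map.get(sample_id) if sex_map else None
        cohort[str(sample_id)] = CNProfile(
            sample_id=str(sample_id),
            segments=grp.drop(columns="sample_id"),
            mode=mode,
            genome=genome,
            declared_sex=declared,
        )
    return cohort


def write_segments(cohort: Dict[str, CNProfile], path) -> None:
    """Write a cohort back to the default-dialect TSV (0-based half-open)."""
    frames = []
    for sample_id, profile in cohort.items():
        df = profile.segments.copy()
        df.insert(0, "sample_id", sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and UCSC tracks


def read_bed(path, genome: Optional[ReferenceGenome] = None, name: str = "custom") -> RegionSet:
    """Read a BED3/BED4 file; clips regions to genome bounds when given."""
    regions: List[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            region = Region(
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[3] if len(fields) > 3 else None,
            )
            if genome is not None:
                clipped = genome.clip(region)
                if clipped is None:
                    continue
                region = clipped
            regions.append(region)
    return RegionSet(name, regions)


def write_bed(regions: "RegionSet | Sequence[Region]", path) -> None:
    rows = regions.regions if isinstance(regions, RegionSet) else list(regions)
    with open(path, "w") as fh:
        for r in rows:
            if r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_cytobands(path, genome: ReferenceGenome) -> RegionSet:
    """Read a UCSC cytoBand.txt layout (chrom, start, end, name, gieStain)."""
    regions: List[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, band = line.split("\t")[:4]
            if chrom not in genome:
                raise CoordinateError(
                    f"{path}: cytoband chromosome {chrom!r} absent from "
                    f"genome {genome.name}"
                )
            region = genome.clip(Region(chrom, int(start), int(end), band))
            if region is not None:
                regions.append(region)
    return RegionSet("cytobands", regions)


def _arms_from_cytobands(bands: RegionSet, genome: ReferenceGenome) -> RegionSet:
    arms: List[Region] = []
    for chrom, rows in bands.by_chrom().items():
        for letter in ("p", "q"):
            members = [r for r in rows if (r.name or "").startswith(letter)]
            if members:
                arms.append(
                    Region(
                        chrom,
                        min(r.start for r in members),
                        max(r.end for r in members),
                        f"{chrom}{letter}",
                    )
                )
    return RegionSet("arms", arms)


def load_region_set(
    kind: str,
    genome: ReferenceGenome,
    cytobands: Optional[str] = None,
    bed: Optional[str] = None,
) -> RegionSet:
    """Load one of the predefined region sets or a custom BED.

    ``chromosomes`` needs nothing beyond the genome; ``arms`` and
    ``cytobands`` need a UCSC cytoBand file; the two gene sets are
    user-supplied BED files (they are not redistributable).
    """
    if kind == "chromosomes":
        return RegionSet(
            "chromosomes",
            [Region(c, 0, l, c) for c, l in genome.chromosomes],
        )
    if kind in ("arms", "cytobands"):
        if cytobands is None:
            raise ValueError(f"region set {kind!r} requires a cytoband file")
        bands = read_cytobands(cytobands, genome)
        return bands if kind == "cytobands" else _arms_from_cytobands(bands, genome)
    if kind in ("cosmic_genes", "ensembl_genes", "custom"):
        if bed is None:
            raise ValueError(f"region set {kind!r} requires a BED file")
        return read_bed(bed, genome, name=kind)
    if Path(str(kind)).exists():
        return read_bed(kind, genome, name="custom")
    raise ValueError(
        f"unknown region set {kind!r}; expected one of "
        f"{PREDEFINED_REGION_KINDS + ('custom',)} or a BED path"
    )


# ---------------------------------------------------------------------------
# aggregated matrices


def write_matrix(matrix, path) -> None:
    """Write an aggregated matrix as TSV: rows = samples, columns = segments.

    Columns are named ``chrom:start-end`` (total mode) or
    ``chrom:start-end:<allele>`` (allele-specific mode, paired columns).
    """
    matrix.to_dataframe().to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix(path):
    """Read back a matrix written by :func:`write_matrix`."""
    from .aggregate import AggregatedMatrix

    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return AggregatedMatrix.from_dataframe(df)
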