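"""Reference genomes, genomic regions, and sex-aware expected copy numbers.

Coordinates are 0-based half-open throughout the library (BED convention).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Allele",
    "CoordinateError",
    "Region",
    "ReferenceGenome",
    "Sex",
    "infer_sex",
    "load_genome",
    "normal_copy",
]


class CoordinateError(ValueError):
    """A coordinate or chromosome name is invalid for the given genome."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        try:
            return cls(value.lower())
        except ValueError:
            raise ValueError(f"unknown sex {value!r}; expected 'male' or 'female'")


class Allele(enum.Enum):
    MAJOR = "major"
    MINOR = "minor"
    TOTAL = "total"

    @classmethod
    def parse(cls, value: "Allele | str") -> "Allele":
        if isinstance(value, Allele):
            return value
        try:
            return cls(value.lower())
        except ValueError:
            raise ValueError(f"unknown allele {value!r}")


@dataclass(frozen=True, order=True)
class Region:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ReferenceGenome:
    """An ordered set of named chromosomes with lengths and sex-chromosome labels.

    Parameters
    ----------
    name:
        Identifier of the assembly, e.g. ``"hg19"``.
    chromosomes:
        Ordered ``(name, length)`` pairs. Lengths are in bases.
    sex_chromosomes:
        The ``(X-like, Y-like)`` pair. Both must be absent or both present
        in ``chromosomes``.
    """

    name: str
    chromosomes: tuple
    sex_chromosomes: tuple = ("chrX", "chrY")

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in genome {self.name}")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "sex_chromosomes", tuple(self.sex_chromosomes))
        present = [c for c in self.sex_chromosomes if c in names]
        if present and len(present) != 2:
            raise ValueError(
                "sex chromosomes must be both present or both absent; "
                f"found only {present}"
            )

    # -- lookups ---------------------------------------------------------

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def chrom_names(self) -> tuple:
        return tuple(c for c, _ in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r} in genome {self.name}")

    @property
    def has_sex_chromosomes(self) -> bool:
        return self.sex_chromosomes[0] in self

    @property
    def autosomes(self) -> tuple:
        return tuple(c for c in self.chrom_names if c not in self.sex_chromosomes)

    def scope_chromosomes(self, scope: str, sex: Sex) -> tuple:
        """Chromosomes contributing to a feature scope for a sample of ``sex``.

        The linear genome is sex-aware: the Y-like chromosome is excluded
        entirely for female samples, so scope lengths depend on sex.
        """
        sex = Sex.parse(sex)
        if scope == "autosomes":
            return self.autosomes
        x_name, y_name = self.sex_chromosomes
        sex_chroms = tuple(
            c
            for c in self.chrom_names
            if c in self.sex_chromosomes and not (c == y_name and sex is Sex.FEMALE)
        )
        if scope == "sex_chromosomes":
            return sex_chroms
        if scope == "genome":
            return self.autosomes + sex_chroms
        raise ValueError(f"unknown scope {scope!r}")

    def scope_length(self, scope: str, sex: Sex) -> int:
        return sum(self.length_of(c) for c in self.scope_chromosomes(scope, sex))

    def clip(self, region: Region) -> Optional[Region]:
        """Clip a region to chromosome bounds; None if nothing remains."""
        if region.chrom not in self:
            return None
        end = min(region.end, self.length_of(region.chrom))
        if region.start >= end:
            return None
        return Region(region.chrom, region.start, end, region.name)


SCOPES = ("autosomes", "sex_chromosomes", "genome")


def normal_copy(
    chrom: str,
    allele: "Allele | str",
    sex: "Sex | str",
    genome: ReferenceGenome,
) -> int:
    """Expected copy number of ``allele`` on ``chrom`` in a normal cell of ``sex``.

    Autosomes are (major, minor) = (1, 1); male X and Y are (1, 0);
    female X is (1, 1) and female Y is (0, 0). Totals are the allele sums.
    """
    if chrom not in genome:
        raise CoordinateError(f"unknown chromosome {chrom!r} in genome {genome.name}")
    allele = Allele.parse(allele)
    sex = Sex.parse(sex)
    x_name, y_name = genome.sex_chromosomes
    if chrom == y_name:
        major, minor = (1, 0) if sex is Sex.MALE else (0, 0)
    elif chrom == x_name:
        major, minor = (1, 0) if sex is Sex.MALE else (1, 1)
    else:
        major, minor = 1, 1
    if allele is Allele.MAJOR:
        return major
    if allele is Allele.MINOR:
        return minor
    return major + minor


def infer_sex(profile, genome: ReferenceGenome) -> Sex:
    """Infer sample sex from the presence of Y-chromosome copy number.

    A sample is called male iff it has at least one segment on the Y-like
    chromosome with a non-missing CN > 0 on any allele; otherwise female.
    An explicit CN=0 Y record (as some callers emit for females) does not
    count as presence.
    """
    if profile.declared_sex is not None:
        return profile.declared_sex
    y_name = genome.sex_chromosomes[1]
    seg = profile.segments
    on_y = seg[seg["chrom"] == y_name]
    if len(on_y):
        vals = on_y[profile.allele_columns].to_numpy(dtype=float)
        import numpy as np

        if np.any(np.nan_to_num(vals, nan=0.0) > 0):
            return Sex.MALE
    return Sex.FEMALE


def _read_chrom_sizes(handle: Iterable) -> list:
    out = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1])))
    return out


def load_genome(name_or_path: str, name: Optional[str] = None) -> ReferenceGenome:
    """Load a bundled assembly (``hg19``/``hg38``) or a chrom.sizes file."""
    if name_or_path in ("hg19", "hg38"):
        ref = resources.files("cnseg.data").joinpath(f"{name_or_path}.chrom.sizes")
        with ref.open() as fh:
            chroms = _read_chrom_sizes(fh)
        return ReferenceGenome(name_or_path, tuple(chroms))
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown genome {name_or_path!r}: not a bundled assembly "
            "(hg19/hg38) and not an existing chrom.sizes file"
        )
    with open(path) as fh:
        chroms = _read_chrom_sizes(fh)
    return ReferenceGenome(name or path.stem, tuple(chroms))
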