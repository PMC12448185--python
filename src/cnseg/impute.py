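"""Gap imputation: make every base of the reference carry a CN value.

Three methods are provided. *extension* stretches terminal segments to the
chromosome ends and splits each interior gap at ``gap_start +
floor(gap_len/2)``, the halves inheriting the flanking CNs; chromosomes
with no data at all are set to 0. *diploid* fills all newly created
territory with the sex-expected normal copy number, and *null* with 0.
Originally covered bases always keep their value, and equal-CN neighbours
are merged afterwards, so imputation is idempotent.

Alleles are imputed independently: a segment whose minor CN is missing is a
gap for the minor allele even though the major allele is covered.
"""
from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .genome import Allele, ReferenceGenome, Sex, normal_copy
from .profile import ALLELE_SPECIFIC, CNProfile

__all__ = ["impute", "merge_equal_neighbors", "IMPUTE_METHODS"]

IMPUTE_METHODS = ("extension", "diploid", "null")

_ALLELE_OF_COLUMN = {
    "cn_major": Allele.MAJOR,
    "cn_minor": Allele.MINOR,
    "cn_total": Allele.TOTAL,
}


def _prune(profile: CNProfile, genome: ReferenceGenome) -> pd.DataFrame:
    """Clip segments to chromosome bounds; drop unknown chromosomes."""
    seg = profile.segments
    keep = seg["chrom"].isin(genome.chrom_names)
    seg = seg[keep].copy()
    lengths = seg["chrom"].map(genome.lengths)
    seg["start"] = seg["start"].clip(lower=0)
    seg["end"] = np.minimum(seg["end"], lengths)
    return seg[seg["start"] < seg["end"]].reset_index(drop=True)


def _fill_allele(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    chrom_len: int,
    method: str,
    fill_value: float,
) -> List[Tuple[int, int, float]]:
    """Tile [0, chrom_len) for one allele given its covered pieces."""
    mask = ~np.isnan(values)
    starts, ends, values = starts[mask], ends[mask], values[mask]
    if len(starts) == 0:
        return [(0, chrom_len, 0.0 if method == "extension" else fill_value)]

    pieces: List[Tuple[int, int, float]] = []
    if method == "extension":
        # stretch terminals, split interior gaps at the floored midpoint
        cur_start = 0
        for i in range(len(starts)):
            if i + 1 < len(starts):
                gap = int(starts[i + 1] - ends[i])
                right_edge = int(ends[i]) + gap // 2
            else:
                right_edge = chrom_len
            pieces.append((cur_start, right_edge, float(values[i])))
            cur_start = right_edge
    else:
        cursor = 0
        for s, e, v in zip(starts, ends, values):
            if s > cursor:
                pieces.append((cursor, int(s), fill_value))
            pieces.append((int(s), int(e), float(v)))
            cursor = int(e)
        if cursor < chrom_len:
            pieces.append((cursor, chrom_len, fill_value))
    return pieces


def impute(profile: CNProfile, method: str, genome: ReferenceGenome = None) -> CNProfile:
    """Return a profile tiling every chromosome of the genome without gaps."""
    if method not in IMPUTE_METHODS:
        raise ValueError(f"unknown imputation method {method!r}; use one of {IMPUTE_METHODS}")
    genome = genome or profile.genome
    sex = profile.sex
    pruned = profile.with_segments(_prune(profile, genome))

    rows = []
    cols = profile.allele_columns
    for chrom, chrom_len in genome.chromosomes:
        starts, ends, vals = pruned.chrom_arrays(chrom)
        per_allele = []
        for j, col in enumerate(cols):
            fill = (
                float(normal_copy(chrom, _ALLELE_OF_COLUMN[col], sex, genome))
                if method == "diploid"
                else 0.0
            )
            per_allele.append(
                _fill_allele(starts, ends, vals[:, j], chrom_len, method, fill)
            )
        # recombine alleles on the union of their boundaries
        bounds = sorted({b for pieces in per_allele for s, e, _ in pieces for b in (s, e)})
        idx = [0] * len(cols)
        for s, e in zip(bounds[:-1], bounds[1:]):
            row = {"chrom": chrom, "start": s, "end": e}
            for j, col in enumerate(cols):
                while per_allele[j][idx[j]][1] <= s:
                    idx[j] += 1
                row[col] = per_allele[j][idx[j]][2]
            rows.append(row)

    out = pd.DataFrame(rows, columns=["chrom", "start", "end", *cols])
    return merge_equal_neighbors(profile.with_segments(out))


def merge_equal_neighbors(profile: CNProfile) -> CNProfile:
    """Merge abutting segments whose CN is identical on every allele.

    Equality is exact (NaN matches NaN); the per-base CN function is
    unchanged.
    """
    seg = profile.segments
    if len(seg) < 2:
        return profile
    cols = profile.allele_columns
    vals = seg[cols].to_numpy(dtype=float)
    same_chrom = seg["chrom"].to_numpy()[1:] == seg["chrom"].to_numpy()[:-1]
    abutting = seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1]
    equal_vals = np.all(
        (vals[1:] == vals[:-1]) | (np.isnan(vals[1:]) & np.isnan(vals[:-1])), axis=1
    )
    new_group = ~(same_chrom & abutting & equal_vals)
    group = np.concatenate([[0], np.cumsum(new_group)])
    merged = seg.groupby(group, sort=False).agg(
        {"chrom": "first", "start": "first", "end": "last", **{c: "first" for c in cols}}
    )
    return profile.with_segments(merged.reset_index(drop=True))
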