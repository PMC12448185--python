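"""Per-sample statistics over autosomes, sex chromosomes, and the whole genome.

Six statistics are computed: CN-coverage (monoallelic/biallelic), genome-
not-diploid, loss of heterozygosity (hemi-/nullizygous), allelic imbalance,
breakpoint counts, and breakpoint step. All proportions are weighted by
base length, with the full sex-aware scope length as the denominator (the
Y-like chromosome does not contribute to female genomes at all).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import SCOPES, Allele, ReferenceGenome, normal_copy
from .profile import ALLELE_SPECIFIC, TOTAL, CNProfile

__all__ = [
    "BreakpointCounts",
    "allelic_imbalance",
    "breakpoint_counts",
    "breakpoint_step",
    "cn_coverage",
    "feature_table",
    "genome_not_diploid",
    "loh",
]

_ALLELE_OF_COLUMN = {
    "cn_major": Allele.MAJOR,
    "cn_minor": Allele.MINOR,
    "cn_total": Allele.TOTAL,
}


def _piecewise(profile: CNProfile, chrom: str):
    """Abutting pieces tiling [0, chrom_len): (starts, ends, values).

    Uncovered stretches appear as NaN rows, so the result is the complete
    per-base CN step function of the chromosome.
    """
    chrom_len = profile.genome.length_of(chrom)
    starts, ends, vals = profile.chrom_arrays(chrom)
    k = vals.shape[1] if vals.size else len(profile.allele_columns)
    out_s: List[int] = []
    out_e: List[int] = []
    out_v: List[np.ndarray] = []
    cursor = 0
    for s, e, v in zip(starts, ends, vals):
        if s > cursor:
            out_s.append(cursor)
            out_e.append(int(s))
            out_v.append(np.full(k, np.nan))
        out_s.append(int(s))
        out_e.append(int(e))
        out_v.append(v)
        cursor = int(e)
    if cursor < chrom_len:
        out_s.append(cursor)
        out_e.append(chrom_len)
        out_v.append(np.full(k, np.nan))
    return (
        np.asarray(out_s, dtype=np.int64),
        np.asarray(out_e, dtype=np.int64),
        np.vstack(out_v) if out_v else np.empty((0, k)),
    )


def _scope_chroms(profile: CNProfile, scope: str) -> Tuple[str, ...]:
    return profile.genome.scope_chromosomes(scope, profile.sex)


def _scope_length(profile: CNProfile, scope: str) -> int:
    return sum(profile.genome.length_of(c) for c in _scope_chroms(profile, scope))


def _expected(profile: CNProfile, chrom: str) -> np.ndarray:
    return np.array(
        [
            float(normal_copy(chrom, _ALLELE_OF_COLUMN[c], profile.sex, profile.genome))
            for c in profile.allele_columns
        ]
    )


def _fraction(profile: CNProfile, scope: str, base_counter) -> float:
    """Sum base_counter(chrom) over the scope, divided by scope length."""
    denom = _scope_length(profile, scope)
    if denom == 0:
        return float("nan")
    return sum(base_counter(c) for c in _scope_chroms(profile, scope)) / denom


# ---------------------------------------------------------------------------


def cn_coverage(profile: CNProfile, scope: str = "genome") -> Tuple[float, float]:
    """(monoallelic, biallelic) fraction of the scope with an assigned CN.

    Monoallelic counts bases where any allele has a value; biallelic where
    every allele does. In total-CN mode the two coincide.
    """

    def covered(chrom: str, how) -> int:
        starts, ends, vals = _piecewise(profile, chrom)
        mask = how(~np.isnan(vals), axis=1)
        return int(np.sum((ends - starts)[mask]))

    mono = _fraction(profile, scope, lambda c: covered(c, np.any))
    if profile.mode == TOTAL:
        return mono, mono
    return mono, _fraction(profile, scope, lambda c: covered(c, np.all))


def genome_not_diploid(profile: CNProfile, scope: str = "genome") -> float:
    """Fraction of the scope where an assigned allele deviates from the
    sex-expected normal CN. In total-CN mode this is a lower bound."""

    def deviant(chrom: str) -> int:
        starts, ends, vals = _piecewise(profile, chrom)
        exp = _expected(profile, chrom)
        mask = np.any(~np.isnan(vals) & (vals != exp), axis=1)
        return int(np.sum((ends - starts)[mask]))

    return _fraction(profile, scope, deviant)


def loh(profile: CNProfile, scope: str = "genome") -> Tuple[float, float]:
    """(hemizygous, nullizygous) LoH fractions.

    A base counts only where the lost allele's normal CN is non-zero, so
    e.g. an absent Y never registers. In total-CN mode the hemizygous
    component is undefined (NaN) and nullizygous uses total CN = 0.
    """

    def count(chrom: str, nulli: bool) -> int:
        starts, ends, vals = _piecewise(profile, chrom)
        exp = _expected(profile, chrom)
        zero = ~np.isnan(vals) & (vals == 0.0)
        if nulli:
            mask = np.all(zero, axis=1) & (exp.sum() > 0)
        else:
            mask = np.any(zero & (exp > 0), axis=1)
        return int(np.sum((ends - starts)[mask]))

    nulli = _fraction(profile, scope, lambda c: count(c, True))
    if profile.mode == TOTAL:
        return float("nan"), nulli
    hemi = _fraction(profile, scope, lambda c: count(c, False))
    return hemi, nulli


def allelic_imbalance(profile: CNProfile, scope: str = "genome") -> float:
    """Fraction of the scope where one allele strictly exceeds the other.

    Undefined (NaN) in total-CN mode.
    """
    if profile.mode == TOTAL:
        return float("nan")

    def imbalanced(chrom: str) -> int:
        starts, ends, vals = _piecewise(profile, chrom)
        both = np.all(~np.isnan(vals), axis=1)
        mask = both & (vals[:, 0] != vals[:, 1])
        return int(np.sum((ends - starts)[mask]))

    return _fraction(profile, scope, imbalanced)


# ---------------------------------------------------------------------------
# breakpoints


@dataclass
class BreakpointCounts:
    """Breakpoint tallies: per chromosome and per allele, plus totals.

    ``total`` counts distinct positions where any allele changes, which can
    be less than the sum over alleles when both alleles break at the same
    position.
    """

    allele_names: List[str]
    per_chrom: Dict[str, np.ndarray]  # chrom -> per-allele counts
    per_chrom_total: Dict[str, int]

    @property
    def per_allele(self) -> np.ndarray:
        if not self.per_chrom:
            return np.zeros(len(self.allele_names), dtype=int)
        return np.sum(list(self.per_chrom.values()), axis=0)

    @property
    def total(self) -> int:
        return sum(self.per_chrom_total.values())


def _changes(profile: CNProfile, chrom: str):
    """Positions and per-allele change flags between consecutive pieces."""
    starts, ends, vals = _piecewise(profile, chrom)
    if len(starts) < 2:
        k = len(profile.allele_columns)
        return np.empty(0, dtype=np.int64), np.empty((0, k), dtype=bool), vals, starts
    left, right = vals[:-1], vals[1:]
    changed = (left != right) & ~(np.isnan(left) & np.isnan(right))
    return starts[1:], changed, vals, starts


def breakpoint_counts(profile: CNProfile, scope: str = "genome") -> BreakpointCounts:
    per_chrom: Dict[str, np.ndarray] = {}
    per_chrom_total: Dict[str, int] = {}
    for chrom in _scope_chroms(profile, scope):
        _, changed, _, _ = _changes(profile, chrom)
        per_chrom[chrom] = changed.sum(axis=0).astype(int)
        per_chrom_total[chrom] = int(np.any(changed, axis=1).sum())
    return BreakpointCounts(list(profile.allele_columns), per_chrom, per_chrom_total)


def breakpoint_step(profile: CNProfile, scope: str = "genome") -> float:
    """Mean |CN difference| across all allele-level breakpoints in scope.

    Alleles are pooled into one mean. Transitions into or out of missing
    territory have no defined step and are excluded; NaN if no breakpoint
    has both sides assigned.
    """
    diffs: List[float] = []
    for chrom in _scope_chroms(profile, scope):
        starts, ends, vals = _piecewise(profile, chrom)
        if len(starts) < 2:
            continue
        left, right = vals[:-1], vals[1:]
        changed = (left != right) & ~np.isnan(left) & ~np.isnan(right)
        diffs.extend(np.abs(right[changed] - left[changed]).tolist())
    return float(np.mean(diffs)) if diffs else float("nan")


# ---------------------------------------------------------------------------


def feature_table(cohort: "Dict[str, CNProfile] | Iterable[CNProfile]") -> pd.DataFrame:
    """One row per (sample, scope) with all six statistics."""
    profiles = list(cohort.values()) if isinstance(cohort, dict) else list(cohort)
    rows = []
    for p in profiles:
        for scope in SCOPES:
            mono, bi = cn_coverage(p, scope)
            hemi, nulli = loh(p, scope)
            bc = breakpoint_counts(p, scope)
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "scope": scope,
                    "sex": p.sex.value,
                    "coverage_mono": mono,
                    "coverage_bi": bi,
                    "gnd": genome_not_diploid(p, scope),
                    "loh_hemi": hemi,
                    "loh_nulli": nulli,
                    "ai": allelic_imbalance(p, scope),
                    "breakpoints": bc.total,
                    **{
                        f"breakpoints_{col.removeprefix('cn_')}": int(n)
                        for col, n in zip(bc.allele_names, bc.per_allele)
                    },
                    "breakpoint_step": breakpoint_step(p, scope),
                }
            )
    return pd.DataFrame(rows)
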