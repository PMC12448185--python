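"""Independent brute-force oracles used to cross-check the interval code.

Everything here works on explicit per-base numpy arrays (or direct
simulation of a stated rule) and deliberately shares no code with the
package implementation.
"""
from __future__ import annotations

import itertools
import math
from typing import Dict, List, Tuple

import numpy as np

from cnseg.genome import Allele, ReferenceGenome, Sex, normal_copy
from cnseg.profile import CNProfile

ALLELES = {"cn_major": Allele.MAJOR, "cn_minor": Allele.MINOR, "cn_total": Allele.TOTAL}


# ---------------------------------------------------------------------------
# per-base expansion


def per_base_arrays(profile: CNProfile) -> Dict[str, np.ndarray]:
    """chrom -> (chrom_len, n_alleles) array, NaN where no CN is assigned."""
    out = {}
    cols = profile.allele_columns
    for chrom, length in profile.genome.chromosomes:
        arr = np.full((length, len(cols)), np.nan)
        grp = profile.segments[profile.segments["chrom"] == chrom]
        for _, row in grp.iterrows():
            for j, c in enumerate(cols):
                arr[int(row["start"]) : int(row["end"]), j] = row[c]
        out[chrom] = arr
    return out


def brute_impute_allele(col: np.ndarray, method: str, fill: float) -> np.ndarray:
    """Fill one allele's per-base vector.

    extension: nearest covered run, the left neighbour owning the first
    floor(gap/2) bases of each interior gap; all-missing -> 0.
    diploid/null: missing bases get ``fill``.
    """
    col = col.copy()
    missing = np.isnan(col)
    if missing.all():
        col[:] = 0.0 if method == "extension" else fill
        return col
    if method != "extension":
        col[missing] = fill
        return col
    idx = np.flatnonzero(~missing)
    # leading and trailing stretches
    col[: idx[0]] = col[idx[0]]
    col[idx[-1] + 1 :] = col[idx[-1]]
    # interior gaps
    gaps = np.flatnonzero(np.diff(idx) > 1)
    for g in gaps:
        left, right = idx[g], idx[g + 1]
        gap_len = right - left - 1
        half = gap_len // 2
        col[left + 1 : left + 1 + half] = col[left]
        col[left + 1 + half : right] = col[right]
    return col


def brute_impute(profile: CNProfile, method: str) -> Dict[str, np.ndarray]:
    arrays = per_base_arrays(profile)
    sex = profile.sex
    out = {}
    for chrom, arr in arrays.items():
        filled = np.empty_like(arr)
        for j, colname in enumerate(profile.allele_columns):
            fill = (
                float(normal_copy(chrom, ALLELES[colname], sex, profile.genome))
                if method == "diploid"
                else 0.0
            )
            filled[:, j] = brute_impute_allele(arr[:, j], method, fill)
        out[chrom] = filled
    return out


# ---------------------------------------------------------------------------
# per-base features


def _scope_chroms(profile: CNProfile, scope: str):
    return profile.genome.scope_chromosomes(scope, profile.sex)


def _expected(profile: CNProfile, chrom: str) -> np.ndarray:
    return np.array(
        [
            float(normal_copy(chrom, ALLELES[c], profile.sex, profile.genome))
            for c in profile.allele_columns
        ]
    )


def brute_features(profile: CNProfile, scope: str) -> dict:
    """All six features from explicit per-base arrays."""
    arrays = per_base_arrays(profile)
    chroms = _scope_chroms(profile, scope)
    denom = sum(profile.genome.length_of(c) for c in chroms)
    n_alleles = len(profile.allele_columns)
    counts = dict(mono=0, bi=0, gnd=0, hemi=0, nulli=0, ai=0)
    bp_allele = np.zeros(n_alleles, dtype=int)
    bp_total = 0
    steps: List[float] = []
    for chrom in chroms:
        arr = arrays[chrom]
        exp = _expected(profile, chrom)
        assigned = ~np.isnan(arr)
        counts["mono"] += int(assigned.any(axis=1).sum())
        counts["bi"] += int(assigned.all(axis=1).sum())
        counts["gnd"] += int(np.any(assigned & (arr != exp), axis=1).sum())
        zero = assigned & (arr == 0.0)
        counts["hemi"] += int(np.any(zero & (exp > 0), axis=1).sum())
        counts["nulli"] += int((np.all(zero, axis=1) & (exp.sum() > 0)).sum())
        if n_alleles == 2:
            counts["ai"] += int(
                (assigned.all(axis=1) & (arr[:, 0] != arr[:, 1])).sum()
            )
        for i in range(1, len(arr)):
            a, b = arr[i - 1], arr[i]
            for j in range(n_alleles):
                both_nan = math.isnan(a[j]) and math.isnan(b[j])
                if not both_nan and not (a[j] == b[j]):
                    bp_allele[j] += 1
                    if not math.isnan(a[j]) and not math.isnan(b[j]):
                        steps.append(abs(b[j] - a[j]))
            changed_any = any(
                not (math.isnan(a[j]) and math.isnan(b[j])) and not (a[j] == b[j])
                for j in range(n_alleles)
            )
            bp_total += int(changed_any)
    frac = lambda key: counts[key] / denom if denom else float("nan")
    total_mode = n_alleles == 1
    return {
        "coverage_mono": frac("mono"),
        "coverage_bi": frac("mono") if total_mode else frac("bi"),
        "gnd": frac("gnd"),
        "loh_hemi": float("nan") if total_mode else frac("hemi"),
        "loh_nulli": frac("nulli"),
        "ai": float("nan") if total_mode else frac("ai"),
        "breakpoints": bp_total,
        "breakpoints_per_allele": bp_allele,
        "breakpoint_step": float(np.mean(steps)) if steps else float("nan"),
    }


# ---------------------------------------------------------------------------
# other oracles


def simulate_greedy_merge(positions, m: int) -> List[int]:
    """Direct simulation of the stated merging loop."""
    remaining = sorted(set(int(p) for p in positions))
    merged = []
    while remaining:
        anchor = remaining[0]
        cluster = [p for p in remaining if p - anchor <= m]
        merged.append(math.floor(sum(cluster) / len(cluster)))
        remaining = remaining[len(cluster):]
    return merged


def exhaustive_knee(values) -> Tuple[int, float, str]:
    """Loop over every candidate threshold; (index, angle, kind)."""
    x = np.asarray(values, float)
    t = sorted(set(x.tolist()))
    y = [float(np.sum(x <= ti)) for ti in t]
    tn = [(ti - t[0]) / (t[-1] - t[0]) for ti in t]
    yn = [(yi - y[0]) / (y[-1] - y[0]) for yi in y]
    best_i, best_angle = None, 0.0
    for i in range(1, len(t) - 1):
        v1 = (tn[i], yn[i])
        v2 = (1 - tn[i], 1 - yn[i])
        ang = math.atan2(v1[0] * v2[1] - v1[1] * v2[0], v1[0] * v2[0] + v1[1] * v2[1])
        if abs(round(ang, 15)) > abs(round(best_angle, 15)):
            best_i, best_angle = i, ang
    kind = "knee" if best_angle < 0 else "elbow"
    return best_i, best_angle, kind


def exact_mwu_p(a, b) -> float:
    """Two-sided Mann-Whitney p by full enumeration (tiny groups only)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in group_a_idx]
        u = 0.0
        for x in ga:
            for y in gb:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    observed = u_stat(tuple(range(n_a)))
    n_bigger = 0
    total = 0
    mean_u = n_a * len(b) / 2.0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(combo) - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_bigger += 1
    return n_bigger / total
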