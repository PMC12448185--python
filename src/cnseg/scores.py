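"""Exploratory statistics on aggregated matrices.

Normalized Manhattan distance (NMD) between sum-normalized profiles, the
outlier score (mean NMD to a cluster) and its contrastive variant, the
peak score (discrete second difference with reflected boundaries), and a
per-segment two-group rank test with Benjamini-Hochberg correction.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "contrastive_outlier_score",
    "discriminatory_features",
    "nmd",
    "nmd_matrix",
    "outlier_score",
    "peak_score",
]


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("NMD input contains missing values; aggregate a full profile")
    total = v.sum()
    if total <= 0:
        raise ValueError("NMD undefined for a zero-sum vector")
    return v / total


def nmd(s: Sequence[float], r: Sequence[float]) -> float:
    """Normalized Manhattan distance: sum |s_i/sum(S) - r_i/sum(R)|.

    Dividing by the per-sample sum makes the distance invariant to
    whole-genome doubling; values lie in [0, 2].
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if s.shape != r.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {r.shape}")
    return float(np.abs(_normalize(s) - _normalize(r)).sum())


def nmd_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise NMD for a samples x segments matrix: symmetric, zero diagonal."""
    rows = np.asarray(rows, dtype=float)
    norm = np.stack([_normalize(r) for r in rows])
    diff = np.abs(norm[:, None, :] - norm[None, :, :]).sum(axis=2)
    return diff


def outlier_score(
    s: Sequence[float], cluster: "np.ndarray | Iterable[Sequence[float]]"
) -> float:
    """Mean NMD from a sample to the members of a cluster.

    If the sample itself appears in the cluster (zero distance), that copy
    is excluded so its self-distance does not deflate the score.
    """
    s = np.asarray(s, dtype=float)
    members = [np.asarray(m, dtype=float) for m in cluster]
    dists = [nmd(s, m) for m in members if not np.array_equal(s, m)]
    if not dists:
        raise ValueError("cluster is empty after excluding the sample itself")
    return float(np.mean(dists))


def contrastive_outlier_score(
    s: Sequence[float],
    own_cluster: "np.ndarray | Iterable[Sequence[float]]",
    other_cluster: "np.ndarray | Iterable[Sequence[float]]",
) -> float:
    """OS(S, C2) - OS(S, C1): low or negative values mean the sample looks
    more like the other class than its own."""
    return outlier_score(s, other_cluster) - outlier_score(s, own_cluster)


def peak_score(
    values: Sequence[float], chrom_ids: Optional[Sequence] = None
) -> np.ndarray:
    """PS_i = (s_i - s_{i-1}) - (s_{i+1} - s_i) with reflected boundaries.

    Positive where a bin stands above its neighbours, negative below. Bins
    must be contiguous and of comparable size; when ``chrom_ids`` is given
    the score is computed independently per chromosome so that no score
    bridges a chromosome boundary. Scores over one chromosome sum to 0.
    """
    v = np.asarray(values, dtype=float)
    if chrom_ids is not None:
        chrom_ids = np.asarray(chrom_ids)
        out = np.empty_like(v)
        # preserve appearance order of chromosomes
        _, first = np.unique(chrom_ids, return_index=True)
        for cid in chrom_ids[np.sort(first)]:
            mask = chrom_ids == cid
            out[mask] = peak_score(v[mask])
        return out
    if len(v) < 2:
        return np.zeros_like(v)
    padded = np.concatenate([[v[0]], v, [v[-1]]])
    return (padded[1:-1] - padded[:-2]) - (padded[2:] - padded[1:-1])


def discriminatory_features(
    a: np.ndarray,
    b: np.ndarray,
    segment_names: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-segment two-sided Mann-Whitney U test between two sample groups,
    BH-adjusted across all segments in one family; sorted by q then p.

    Segments that are constant across both groups get p = 1 by convention.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on the number of segments")
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("need at least 2 samples per group")
    n_seg = a.shape[1]
    stats = np.empty(n_seg)
    pvals = np.empty(n_seg)
    for j in range(n_seg):
        col_a, col_b = a[:, j], b[:, j]
        if np.all(col_a == col_a[0]) and np.all(col_b == col_a[0]):
            stats[j] = len(col_a) * len(col_b) / 2.0
            pvals[j] = 1.0
            continue
        res = mannwhitneyu(col_a, col_b, alternative="two-sided")
        stats[j] = res.statistic
        pvals[j] = res.pvalue
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    names = (
        list(segment_names)
        if segment_names is not None
        else [f"seg{j}" for j in range(n_seg)]
    )
    df = pd.DataFrame({"segment": names, "U": stats, "p": pvals, "q": qvals})
    return df.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
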