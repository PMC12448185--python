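"""Sample-level quality filters: z-score outliers and knee/elbow detection."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["KneePointResult", "ZScoreResult", "knee_point", "zscore_filter"]


@dataclass
class ZScoreResult:
    mu: float
    sigma: float
    z: np.ndarray
    keep: np.ndarray
    threshold: float
    degenerate: bool = False


def zscore_filter(values: Sequence[float], k: float = 3.0) -> ZScoreResult:
    """Flag samples whose feature is >= k population standard deviations
    from the mean (removal is |z| >= k, inclusive).

    With zero variance every sample is kept and the result is marked
    degenerate.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("z-score filtering needs at least 2 samples")
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population sigma
    if sigma == 0.0:
        return ZScoreResult(mu, 0.0, np.zeros_like(x), np.ones(len(x), bool), k, True)
    z = (x - mu) / sigma
    return ZScoreResult(mu, sigma, z, np.abs(z) < k, k)


@dataclass
class KneePointResult:
    """Knee/elbow of the cumulative feature curve.

    ``thresholds`` are the sorted distinct feature values T and ``counts``
    the cumulative tallies |f <= t|; both are also stored unit-normalized.
    The optimum maximizes the magnitude of the signed angle between the
    vector from the origin to (t', y') and the vector from (t', y') to
    (1, 1). Negative angle (clockwise) = knee, positive = elbow.
    """

    thresholds: np.ndarray
    counts: np.ndarray
    t_norm: np.ndarray
    y_norm: np.ndarray
    angles: np.ndarray
    index: Optional[int]
    knee_value: Optional[float]
    kind: Optional[str]
    angle: float
    degenerate: bool = False


def knee_point(
    values: Sequence[float],
    max_value: Optional[float] = None,
    min_value: Optional[float] = None,
) -> KneePointResult:
    """Locate the knee (or elbow) of the cumulative distribution of a feature.

    ``min_value``/``max_value`` restrict the candidate range first (e.g.
    "samples below 1%"). Ties in |angle| resolve to the smallest threshold.
    """
    x = np.asarray(values, dtype=float)
    if max_value is not None:
        x = x[x <= max_value]
    if min_value is not None:
        x = x[x >= min_value]
    t = np.unique(x)
    if len(t) < 3:
        raise ValueError("knee detection needs at least 3 distinct values")
    y = np.searchsorted(np.sort(x), t, side="right").astype(float)

    t_norm = (t - t[0]) / (t[-1] - t[0])
    y_norm = (y - y[0]) / (y[-1] - y[0]) if y[-1] > y[0] else np.zeros_like(y)

    angles = np.zeros(len(t))
    for i in range(1, len(t) - 1):
        v1 = np.array([t_norm[i], y_norm[i]])
        v2 = np.array([1.0 - t_norm[i], 1.0 - y_norm[i]])
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        dot = float(np.dot(v1, v2))
        angles[i] = np.arctan2(cross, dot)

    best = int(np.argmax(np.abs(np.round(angles, 15))))
    if abs(angles[best]) < 1e-12:
        return KneePointResult(
            t, y, t_norm, y_norm, angles, None, None, None, 0.0, degenerate=True
        )
    kind = "knee" if angles[best] < 0 else "elbow"
    return KneePointResult(
        t, y, t_norm, y_norm, angles, best, float(t[best]), kind, float(angles[best])
    )
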