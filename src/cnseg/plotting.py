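"""Minimal profile plotting: CN step functions along the linear genome."""
from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .profile import CNProfile

__all__ = ["plot_profile"]


def plot_profile(profile: CNProfile, path: Optional[str] = None, ax=None):
    """Draw per-allele CN as horizontal steps, chromosomes concatenated."""
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    offsets = {}
    cursor = 0
    for chrom, length in profile.genome.chromosomes:
        offsets[chrom] = cursor
        cursor += length
        ax.axvline(cursor, color="0.85", lw=0.5)
    colors = {"cn_major": "tab:red", "cn_minor": "tab:blue", "cn_total": "tab:purple"}
    for col in profile.allele_columns:
        for _, row in profile.segments.iterrows():
            off = offsets[row["chrom"]]
            ax.hlines(
                row[col], off + row["start"], off + row["end"],
                color=colors[col], lw=1.5,
            )
    ax.set_xlim(0, cursor)
    ax.set_ylabel("CN")
    ax.set_title(profile.sample_id)
    if path is not None:
        ax.figure.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
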