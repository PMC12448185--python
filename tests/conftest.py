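from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnseg.genome import ReferenceGenome, Sex
from cnseg.profile import ALLELE_SPECIFIC, TOTAL, CNProfile


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    """3 autosomes + X + Y, ~3.1 kb total: small enough for per-base oracles."""
    return ReferenceGenome(
        "toy",
        (("chr1", 1000), ("chr2", 800), ("chr3", 600), ("chrX", 500), ("chrY", 200)),
    )


@pytest.fixture
def autosome_genome() -> ReferenceGenome:
    """A single-chromosome genome without sex chromosomes."""
    return ReferenceGenome("mini", (("chr1", 100),), sex_chromosomes=("chrX", "chrY"))


def random_profile(
    genome: ReferenceGenome,
    rng: np.random.Generator,
    sample_id: str = "s",
    mode: str = ALLELE_SPECIFIC,
    declared_sex: Sex | None = None,
    nan_prob: float = 0.15,
    gap_prob: float = 0.4,
    max_cn: int = 5,
    fractional: bool = False,
) -> CNProfile:
    """Random sorted, non-overlapping segments with gaps and missing alleles."""
    rows = []
    cols = ["cn_major", "cn_minor"] if mode == ALLELE_SPECIFIC else ["cn_total"]
    for chrom, length in genome.chromosomes:
        if rng.random() < 0.1:  # sometimes whole chromosome missing
            continue
        n_cuts = int(rng.integers(1, 7))
        cuts = np.unique(rng.integers(0, length + 1, size=n_cuts * 2))
        if len(cuts) < 2:
            continue
        for s, e in zip(cuts[:-1], cuts[1:]):
            if s >= e or rng.random() < gap_prob:
                continue
            if fractional:
                vals = rng.uniform(0, max_cn, size=len(cols)).round(3)
            else:
                vals = rng.integers(0, max_cn + 1, size=len(cols)).astype(float)
            if mode == ALLELE_SPECIFIC:
                vals = np.sort(vals)[::-1]  # major >= minor
                if rng.random() < nan_prob:
                    vals[1] = np.nan
                if rng.random() < nan_prob / 3:
                    vals[0] = np.nan
            rows.append(
                {"chrom": chrom, "start": int(s), "end": int(e), **dict(zip(cols, vals))}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *cols])
    return CNProfile(sample_id, df, mode, genome, declared_sex=declared_sex)
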