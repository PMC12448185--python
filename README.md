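# cnseg

Integration and joint analysis of somatic copy-number (SCNA) profiles from
heterogeneous cohorts. `cnseg` imputes missing segments, computes sex-aware
per-sample statistics, builds a consistent segmentation shared by every
sample of a cohort, aggregates profiles into a samples × segments matrix,
and scores that matrix (outliers, peaks, discriminatory segments). A seeded
synthetic-cohort generator with full ground truth makes every step testable
offline.

## Library overview

| Module | Purpose |
| --- | --- |
| `cnseg.genome` | reference genomes, regions, sex-aware expected copy numbers, sex inference |
| `cnseg.io` | TSV segment tables (configurable dialects), BED, UCSC cytoband/gap tracks, matrix I/O |
| `cnseg.impute` | `extension` / `diploid` / `null` gap filling; equal-neighbour merging |
| `cnseg.features` | CN-coverage, genome-not-diploid, LoH, allelic imbalance, breakpoints, breakpoint step — each over autosomes, sex chromosomes and the whole genome |
| `cnseg.segmentation` | exclusion subtraction with fragment filter `f`, greedy breakpoint merging with distance `m`, fixed-width binning with split size `s` (strategies a/b/c) |
| `cnseg.aggregate` | min / max / length-weighted-mean projection onto a segmentation |
| `cnseg.qc` | z-score outlier filtering, knee/elbow detection on cumulative feature curves |
| `cnseg.scores` | normalized Manhattan distance, outlier score, contrastive outlier score, peak score, Mann–Whitney U + Benjamini–Hochberg segment tests |
| `cnseg.simulate` | seeded synthetic cohorts with planted events and recorded ground truth |

Coordinates are 0-based half-open throughout; 1-based input is converted at
the I/O boundary (`Dialect(one_based=True)`).

```python
import cnseg

genome = cnseg.load_genome("hg19")
cohort = cnseg.read_segments("segments.tsv", genome)
imputed = {sid: cnseg.impute(p, "extension") for sid, p in cohort.items()}
features = cnseg.feature_table(imputed)

regions = cnseg.load_region_set("chromosomes", genome)
seg = cnseg.consistent_segmentation(
    regions,
    params=cnseg.SegmentationParams(split_size=5_000_000, strategy="c"),
)
matrix = cnseg.aggregate_cohort(imputed, seg, "mean")
```

## Command line

```bash
cnseg simulate  --config sim.yaml --seed 17 --out cohort.tsv --truth truth.tsv
cnseg impute    --method extension --genome hg19 --in cohort.tsv --out imputed.tsv
cnseg stats     --genome hg19 --in imputed.tsv --out features.tsv
cnseg filter    --feature coverage_bi --method zscore --k 3 --in features.tsv --out keep.tsv
cnseg segment   --regions chromosomes --exclude gaps.bed --filter-size 100000 \
                --merge 500000 --split 5000000 --strategy c --genome hg19 --out segments.bed
cnseg aggregate --segments segments.bed --how mean --genome hg19 --in imputed.tsv --out matrix.tsv
cnseg score     nmd --in matrix.tsv --out nmd.tsv
cnseg score     mwu --in matrix.tsv --groups labels.tsv --out mwu.tsv
cnseg pipeline  --config pipeline.yaml --seed 17
```

Exit codes: 0 success, 1 validation/data error, 2 usage error. `--workers N`
parallelizes the per-sample statistics; results are identical for any
worker count.

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite cross-checks every interval algorithm against independent
per-base brute-force oracles and direct simulations of the stated rules
(see `tests/oracles.py`); `tests/test_acceptance.py` holds the end-to-end
acceptance criteria. The acceptance script recomputes the published worked
example from scratch and writes it as JSON.
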