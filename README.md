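# uwmc — unhealthy white matter connectivity

`uwmc` measures how much of a brain's structural connectome is routed
through white-matter lesions.  White-matter hyperintensities (WMH) — bright
lesions on T2 FLAIR MRI and a hallmark of cerebral small vessel disease —
damage cognition not only in proportion to their volume but according to
*which connections they interrupt*.  For every pair of parcellation regions
(i, j), the package computes

```
UWMC(i, j) = U(i, j) / T(i, j)
```

where `T(i, j)` is the number of tractography streamlines whose two
endpoints lie in regions i and j (end-to-end connectivity) and `U(i, j)` is
the number of those streamlines that pass through at least one WMH voxel.
A pair whose four connecting streamlines include two lesion-crossing ones
has UWMC = 0.5.  Lobar UWMC divides summed unhealthy streamlines by summed
total streamlines over all pairs within one bilateral lobe, and global UWMC
does the same over every pair in the brain.

The package is aimed at imaging groups studying vascular contributions to
cognitive ageing and Alzheimer's disease.  It provides:

- **imaging I/O** (`uwmc.io`) — NIfTI volumes, TCK/TRK tractograms
  (normalised to world RAS mm), TSV label tables carrying lobe, hemisphere
  and amyloid/tau pathology-set flags, and long-format pair tables.  All
  per-subject volumes must share one grid; mismatches are refused, never
  resampled.
- **WMH segmentation** (`uwmc.segmentation`) — FLAIR intensities
  z-normalised to a cerebellar white-matter reference, two-class fuzzy
  c-means memberships per cerebral voxel, and a strict `> 0.75`
  high-intensity membership threshold.
- **connectivity** (`uwmc.connectivity`) — exact streamline–voxel
  intersection geometry, end-to-end pair counting, pairwise/lobar/global
  UWMC, and amyloid/tau pathology-subset extraction.
- **lesion volumetry** (`uwmc.volumes`) — lobar WMH volume in mm³
  normalised to intracranial volume, the classical comparator measurement.
- **statistics** (`uwmc.stats`) — the cohort analysis linking UWMC to
  cognition (MoCA, 0–30): natural-log transform with 0 → 0.05 substitution,
  resampling elastic-net stability selection (120 refits on random 90%
  subsamples, ≥ 90% selection frequency) with forced covariates, Huber
  M-estimator robust regressions (full sample and stratified by racialized
  group), Benjamini–Hochberg FDR at 5%, a conditional group-interaction
  rule, Spearman validation against lobar WMH volume, and descriptive group
  comparisons.  `CognitionAnalysis(...).fit().summary()` packages the whole
  chain.
- **synthetic data** (`uwmc.simulate`) — ground-truth phantoms (labeled
  sphere ROIs, curved streamline bundles, lesions planted to hit an exact
  fraction of each bundle) and cohorts with known MoCA-generating
  parameters, so every stage is testable without scan data.

A regression coefficient β on the natural-log UWMC scale is reported both
raw and as β/100, the difference in MoCA points associated with 1% greater
UWMC (since β·ln(1.01) ≈ β/100).

## Worked example

```python
from uwmc.simulate import worked_example_config, make_phantom
from uwmc.connectivity import count_connections, pairwise_uwmc, global_uwmc

truth = make_phantom(worked_example_config(seed=1))   # 2 ROIs, 4 streamlines, 2 crossing
counts = count_connections(truth.streamlines, truth.labels, truth.lesion_mask)
print(counts.counts)         # {PairKey(a=1, b=2): (4, 2)}
print(pairwise_uwmc(counts).values)  # {PairKey(a=1, b=2): 0.5}
print(global_uwmc(counts))   # 0.5
```

The printed `(4, 2)` are the pair's total and lesion-crossing streamline
counts; their ratio 0.5 is the pair's UWMC, and with a single pair it is
also the lobar and global value.

The same computation is available from the shell:

```
uwmc simulate --preset worked-example --seed 1 --out phantom/
uwmc compute-uwmc --tractogram phantom/tractogram.tck \
    --labels phantom/labels.nii.gz --label-table phantom/labels.tsv \
    --wmh phantom/wmh.nii.gz --out pairs.csv --global-out global.txt
# -> "4 streamlines, 1 connected pairs", global UWMC = 0.5
```

`uwmc run --config run.yaml` chains segmentation, UWMC computation and
volumetry over a subject manifest and writes per-subject CSVs plus a
provenance manifest; `uwmc analyze` runs the cohort statistics.

## Documentation

`docs/methods.md` describes the model and its assumptions, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and known limitations.
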