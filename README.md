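# barcodekit

Analysis toolkit for single-marker DNA barcoding studies of the kind used
to inventory fish communities: pre-aligned, equal-length mitochondrial
*COI* fragments from a set of vouchered specimens, each carrying a
morphological (field) identification, are turned into a species inventory
by genetic distance analysis, and the molecular picture is compared back
against the morphological one.

The package is aimed at researchers running desk-scale barcoding surveys
(tens to hundreds of specimens) who want every step of the classic
pipeline scriptable and testable:

* **QC** — coding-integrity checks under the vertebrate mitochondrial
  genetic code (gaps, ambiguities, internal stop codons, reading-frame
  auto-detection) and alignment statistics (base composition, polymorphic
  and parsimony-informative sites).
* **Divergence** — Kimura two-parameter (K2P) distances with pairwise
  deletion, and divergence summaries per taxonomic level (within species
  / genus / family).
* **Barcoding gap** — per-species nearest-neighbour tables, the tenfold
  criterion (mean interspecific ≥ 10× mean intraspecific divergence), and
  an overlap scan that invalidates the gap when one species' intraspecific
  spread reaches into another's nearest-neighbour distance.
* **Species delimitation** — a deterministic single-linkage threshold
  sweep that enumerates candidate partitions of the specimens and ranks
  them by the relative width of the distance gap at each threshold, then
  reports which nominal species are split (cryptic-species signal) or
  lumped.
* **Phylogeny** — neighbour-joining trees from the K2P matrix with
  column-resampling bootstrap support and per-species monophyly checks.
* **Identification & concordance** — percent-identity matching against a
  local reference library (98% rule by default) and per-specimen
  classification of morphology-vs-molecular agreement as
  *matched* / *refined* / *invalid*.
* **Synthetic data** — a K2P sequence simulator with a nested taxonomy,
  calibrated divergence targets and stop-codon-free coding sequences, so
  the whole pipeline can be exercised against known truth.

## The statistics at the core

For two aligned sequences with observed transition proportion *P* and
transversion proportion *Q* over their comparable sites, the K2P distance
is

```
d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)]
```

undefined (saturated) when `1 - 2P - Q ≤ 0` or `1 - 2Q ≤ 0`. The
barcoding-gap test asks whether conspecific divergences and
heterospecific divergences are separable: the ratio criterion
`mean_inter / mean_intra ≥ 10` plus the absence of any species pair
`(i, j)` with `max_intra(i) > min_inter(j)`. The threshold sweep scores a
candidate partition by `(d_hi − d_lo) / d_hi`, where `d_lo` is the
largest within-unit and `d_hi` the smallest between-unit distance.

## Worked example

```python
from barcodekit import (SimulationConfig, simulate, distance_matrix,
                        rank_summaries, threshold_sweep, split_lump_report)

cfg = SimulationConfig(n_species=5, specimens_per_species=4,
                       n_genera=3, n_families=2, seed=7,
                       cryptic_species=("Gena spa",))
records, taxonomy, true_tree = simulate(cfg)
m = distance_matrix(records)
for s in rank_summaries(m, records):
    print(f"{s.rank:15s} n={s.n_pairs:3d} mean={s.mean:.2f}%")
top = threshold_sweep(m)[0]
report = split_lump_report(top, {r.specimen_id: r.morphological_label
                                 for r in records})
print("units:", top.n_units, "splits:", dict(report.splits))
```

prints

```
within_species  n= 30 mean=1.38%
within_genus    n= 32 mean=5.14%
within_family   n= 32 mean=10.96%
units: 6 splits: {'Gena spa': (0, 1)}
```

The within-genus and within-family means sit at the configured targets
(5% and 12%); the within-species mean reads above its 0.5% target
because the nominally conspecific pairs that straddle the cryptic
species' two clusters diverge at the congeneric level. The top-ranked
partition finds
six units among five nominal species: the simulated cryptic species
`Gena spa` is split into two units, exactly the signal a real survey
uses to flag candidate cryptic species.

The same analysis runs from the shell:

```
barcodekit simulate --outdir sim --n-species 5 --seed 7
barcodekit run-all --input sim/alignment.fasta --metadata sim/metadata.tsv \
    --outdir out --bootstrap 200 --seed 7
```

which writes per-stage tables plus `manifest.json` into `out/`.

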