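# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, in the order the pipeline runs them.

## Scope and assumptions

All analyses assume **pre-aligned, equal-length, indel-free barcode
fragments** (the intended use is ~650 bp protein-coding mitochondrial
markers such as *COI*). Alignment, chromatogram assembly and primer
trimming are upstream concerns. Specimen ids are unique within a
dataset; each carries a morphological label (binomial or genus-level
"Genus sp.") and optionally a molecular label, genus, family, station
and depth.

## Quality control

Coding integrity is checked under the **vertebrate mitochondrial genetic
code** (translation table 2; stop codons TAA, TAG, AGA, AGG), the code
of the marker this pipeline targets. When no reading frame is supplied,
the frame (0/1/2) minimising the number of internal stop codons is
chosen, ties going to the lowest frame index. A stop codon is *internal*
unless its codon ends exactly at the sequence end (a genuine terminator
is not an abnormality; mid-gene fragments never reach one). Codons
containing gaps or ambiguity codes never match a stop.

Alignment statistics treat ambiguity codes and gaps as missing
throughout, matching the pairwise-deletion convention used for
distances. A column is *polymorphic* with ≥ 2 distinct unambiguous
bases and *parsimony informative* when ≥ 2 distinct bases each occur in
≥ 2 sequences; hence informative ≤ polymorphic ≤ length. Base
composition is the per-sequence percentage over unambiguous sites,
averaged across sequences (an equally defensible alternative — pooling
all sites — differs slightly under missing data; the per-sequence mean
is implemented).

## K2P distances

For each pair, sites where either sequence is ambiguous or gapped are
excluded (**pairwise deletion**), and the transition proportion `P` and
transversion proportion `Q` are taken over the remaining comparable
sites. The distance is

    d = -1/2 · ln[(1 − 2P − Q) · √(1 − 2Q)]

in substitutions per site (reported as percent with two decimals in
tables; full precision in JSON). Pairs violating the log domain
(`1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0`) or sharing no comparable sites are
**undefined** and stored as NaN, never silently dropped: summaries
exclude them with a warning, tree building refuses them outright with
the offending pairs listed.

Per-level divergence summaries assign every pair to its **lowest shared
rank**: conspecific → within-species, congeneric heterospecific →
within-genus, confamilial heterogeneric → within-family; pairs sharing
no family are not summarised. The standard error is the sample standard
deviation of the pairwise distances divided by √(number of pairs);
pairwise distances sharing specimens are correlated, so this SE is a
descriptive figure, not an inferential one (distance-software bootstrap
SEs are a different estimator and are not reproduced here).

## Barcoding gap

The per-species gap table reports, in percent: the distance to the
nearest heterospecific specimen (`min_inter`, with the neighbour's
species named; ties broken lexicographically), the mean over all
heterospecific pairs, and the max/mean over conspecific pairs (absent
for singletons). The verdict combines

* the **tenfold criterion**: mean interspecific ≥ 10× mean
  intraspecific divergence (ratio reported; an all-zero intraspecific
  mean passes with an infinite ratio), and
* an **overlap scan**: any ordered species pair (i, j) with
  `max_intra(i) > min_inter(j)` — including i = j — invalidates a
  universal gap.

The intraspecific mean entering the ratio is, by default, the mean over
all conspecific pairs (species means weighted by their pair counts);
weighting each species equally is available as an option, since the
convention is genuinely ambiguous in the field's reporting. With no
multi-specimen species the verdict is *indeterminate*. The 10× factor
is itself a parameter (`ratio_required`).

## Threshold-sweep species delimitation

The partitioner is a deliberately simple, fully deterministic take on
automatic gap-based partitioning, not a reimplementation of any
published tool: single-linkage clustering of the K2P matrix defines a
ladder of merge heights; candidate thresholds are the midpoints between
consecutive distinct heights plus one below the smallest and one above
the largest; each threshold induces a partition (so partitions are
nested and unit counts weakly decrease with threshold). Unit indices
are renumbered contiguously in order of first appearance.

Each partition is scored by the **relative gap width**
`(d_hi − d_lo)/d_hi` with `d_lo` the largest within-unit and `d_hi` the
smallest between-unit pairwise distance, ranked descending with ties
going to fewer units. Two guards matter:

* partitions with no within-unit pairs (all singletons) or no
  between-unit pairs (one unit) score 0 — the gap is indeterminate
  without both sides;
* `d_lo` is floored at the smallest nonzero pairwise distance in the
  matrix. Distances are quantised by substitution counts, so an empty
  interval bounded below by less than one substitution carries no
  evidence; without the floor, any two identical conspecific sequences
  would hand a near-singleton partition a perfect score of 1.

The split/lump report then compares the chosen partition against
nominal species labels: species spread over several units (the
cryptic-species signal) and units containing several species.

## Neighbour joining and bootstrap

NJ follows the standard Q-matrix agglomeration. Determinism is pinned
down: among tied Q minima the smallest (i, j) index pair is joined
(row-major argmin), and the final three lineages are resolved around an
unrooted central vertex by the three-point formulas. Negative branch
length estimates are clamped to 0 (standard practice; the clamping is
applied after lengths are computed, so reconstruction remains exact on
additive inputs, where no negatives arise). Trees are dendropy objects;
Newick output carries branch lengths to six decimals with bootstrap
supports as internal node labels.

Bootstrap support resamples alignment columns with replacement,
rebuilds the distance matrix and NJ tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree. Replicates whose resampled matrix contains a saturated
pair are skipped and count against every support (conservative). The
default replicate count is 5000, the convention for publication-grade
trees; tests use ≤ 200, which is ample for the clean separations they
check. Runs are reproducible bit-exact given the seed.

Monophyly is assessed on the unrooted topology: a species is
monophyletic when its leaf set equals one side of some edge
bipartition; singletons are monophyletic by convention.

## Identification and concordance

Identity between a query and a reference of equal alignment length is
`100 · (1 − p)` with `p` the proportion of differing comparable sites
(pairwise deletion) — a global measure appropriate for pre-aligned
equal-length barcodes, deliberately not a local-alignment score. The
best hit wins by identity, ties broken lexicographically by label; a
hit at or above the threshold (default 98%, the conventional barcode
identification cut-off) counts as identified.

Concordance classification parses both labels, stripping authority
strings ("(Regan, 1913)", "Günther, 1878"), markdown emphasis and stray
punctuation; authority surnames are capitalised and therefore never
mistaken for epithets, and genus-level labels are recognised by an
"sp."/"spp." token with an optional numeral. Then:

* **matched** — both binomial, same genus and epithet;
* **refined** — morphological label genus-level, molecular label a
  congeneric binomial;
* **invalid** — everything else.

Occurrence-list comparison intersects two (family, species label)
lists: species shared by exact binomial, genera and families by name;
genus-level ("spp.") entries count at the genus rank only. Raw shared
counts are reported; percentage bases are left to the caller, because
published overlap percentages routinely leave their denominators
unstated.

## Synthetic data generator

The generator emulates the statistical shape of a barcode survey: a
nested taxonomy (species assigned round-robin to genera, genera to
families), an ultrametric genealogy, and a K2P substitution process
with transition/transversion rate ratio `kappa` on a coding sequence.
Node heights are set to half the target divergence for each level, so
the expected K2P distance between two specimens equals the configured
target for their lowest shared rank; cross-family pairs sit at 1.5× the
family target. Within species the genealogy is a star (all conspecifics
equidistant from the species ancestor). A species listed as *cryptic*
keeps its ancestor at the genus height and splits its specimens into
two clusters, so the two clusters diverge at the congeneric target
while remaining one nominal species.

Branches are simulated event-wise: the substitution count on a branch
of length `t` (expected substitutions per site) is Poisson with mean
`t·L`; each event picks a site uniformly and a target base with
transition probability `kappa/(kappa+2)`. An event that would create an
in-frame stop codon is rejected and redrawn entirely — site and change
— which conserves the substitution count and therefore keeps realised
K2P distances unbiased for the targets (rejecting and *discarding* such
events, or redrawing whole codons, measurably deflates divergence).
The root sequence is drawn codon-wise from the 60 sense codons; a
trailing partial codon (lengths not divisible by 3, e.g. the default
652) is truncated from a full simulated codon and can never form a
stop. Output is bit-exact reproducible from the seed.

Defaults are chosen as typical survey conditions: 652 bp fragments,
`kappa = 3` (typical for fish *COI*), divergence targets 0.5% within
species, 5% within genus, 12% within family — a hierarchy with roughly
the tenfold intra/inter separation the gap criterion expects.
Configurations whose maximum expected divergence exceeds 1.0
substitutions/site are rejected as unsatisfiable (K2P estimates would
routinely saturate).

What the generator does **not** emulate: coalescent variation in
intraspecific genealogies, rate heterogeneity across sites and
lineages, base-composition bias, indels, sequencing error and
misalignment. Passing recovery tests therefore demonstrates the
correctness of the estimators and the delimitation logic under the
model's assumptions, not robustness of barcoding itself against messy
real data.

## Packaged tables

Three small TSV transcriptions of a published survey's in-text tables
ship with the package: the 98-specimen morphological/molecular label
table (stored as printed, including stray parentheses and a year typo,
because the classifier must cope with real tables; the original table's
flag for overturned identifications is kept for cross-checking), the
two occurrence lists, and the per-species divergence table (fractions
in the file, percent in the API; per-species specimen counts are
rederived from the specimen table at load time). The overall
within-species mean divergence printed in the source study (0.63%) is
used as the intraspecific input when the acceptance script computes the
tenfold ratio, since the per-pair data behind it included database
reference sequences that are not redistributable.

## Test and acceptance problem sizes

The test suite and `scripts/acceptance.py` run the simulation-based
checks at 5 species × 4 specimens over 20 seeds, NJ exactness on random
additive matrices up to 12 taxa (path-length tolerance 1e-9), and the
K2P estimator against its algebraically expanded form on a (P, Q) grid
(tolerance 1e-12) — sizes at which every check is sharp while the whole
suite stays fast. Bootstrap tests use 20–200 replicates.

## Known limitations

* The delimitation ranking is distance-only; it has no model of
  within-species coalescent variation, so its scores are not
  probabilities and very uneven sampling across species can mislead it.
* Undefined (saturated) pairs abort tree building rather than being
  imputed; datasets mixing extremely divergent outgroups with the
  ingroup should be split by the caller.
* Intraspecific summaries use only the input dataset; studies that pool
  conspecific database sequences into their intraspecific statistics
  will not be numerically reproduced from specimen data alone.
* Label parsing targets Latin binomials with Western-alphabet authority
  strings; other nomenclatural conventions need pre-cleaning.
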