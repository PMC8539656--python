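# Methods

## Data model and labeling

The atomic observation is a perturbation record: (drug, gene, cell
line, dose value + unit, treatment time, Z-score). The pipeline treats
the Z-score as given per record and does not model its provenance
(replicate collapsing, landmark-gene inference and moderated statistics
happen upstream in the source catalogs).

Record filters are exact: treatment time must equal 24 h and the dose
unit must equal "µM" after NFKC Unicode normalization (so the MICRO SIGN
and GREEK MU spellings match). Records are then restricted to the
longevity gene set.

Direction labels use rank selection, not an interpolated quantile:
within each cell line, exactly `floor(fraction · n)` records are
positive — the largest Z-scores for the upregulation model, the
smallest for downregulation — with ties broken by (drug, gene) lexical
order. This makes labeling deterministic, tie-safe, and invariant to
input row order, and it reproduces "top 5% / bottom 5%" exactly rather
than approximately. The percentile is pooled over all genes of a cell
line (not computed per gene); `fraction` defaults to 0.05 and must lie
in (0, 0.5), which also guarantees the up- and down-positive sets are
disjoint. All non-selected records are negatives: unknown effect is
treated as absence of the modeled effect.

Duplicate (drug, gene, cell) records from multiple doses are kept as
separate samples through labeling; at assembly time they are collapsed
to the record with the extreme Z for the model's direction (max for up,
min for down), because dose replicates produce identical feature rows
and the extreme record is the one that earned the positive label. The
collapse is switchable (`assemble(..., dedup=False)`) and logged.

## Descriptors

**Genes.** One-hot GO membership over the vocabulary of terms that
annotate at least `min_genes = 3` of the study genes, sorted lexically.
Annotations are used exactly as given — no ancestor propagation over
the GO graph; a propagation step would only enlarge the vocabulary and
is left to the annotation source. Unannotated genes get all-zero rows
(logged), not errors: absence of annotation is information the model
may use.

**Drugs.** Morgan circular fingerprints, radius 2, folded to 2048 bits
(both configurable), computed with RDKit from the parsed molecule, so
any SMILES spelling of the same structure maps to the same vector. Bit
collisions from folding are accepted as-is. Unparseable SMILES produce
per-drug error records and exclusion downstream, never a crash.

**Methylation.** The beta value at probe j is
`max(meth,0) / (max(meth,0) + max(unmeth,0) + α)` with `α = 100` by
default — the BeadChip-convention stabilizer — giving values in
[0, 1) that increase in the methylated channel and decrease in the
unmethylated channel and in α. Feature selection against the cell
lines' histology class uses FCBF with symmetrical uncertainty
`SU(x, y) = 2·I(x;y) / (H(x) + H(y))` (plug-in entropies, bits;
SU := 0 when either variable is constant). Because SU needs discrete
inputs, beta values are discretized by three equal-width bins on [0, 1]
(`n_bins` configurable; three bins map naturally onto low /
intermediate / high methylation). Sites with SU against the class
below `delta = 0.6` are dropped; survivors are scanned in descending
relevance and removed when a stronger kept site predicts them at least
as well as they predict the class.

Numerical choice: SU values are rounded to 9 decimals before every
FCBF comparison. Rank ties and the `≥` dominance boundary routinely
fall on *mathematically equal* values (e.g. two sites that are
bijective relabelings of each other), where raw float results differ in
the last bits depending on summation order; rounding makes the
selection reproducible across computation routes. Remaining rank ties
break by site identifier.

**Mutations.** Binary marker status per cell line, used as given.
Normal (non-cancer) cell lines carry no mutation annotation and are
encoded with an all-zero mutation block; their methylation values must
be present for every selected site — a missing site is an error, never
imputed, since silent imputation would fabricate the very features the
model weighs.

## Model layouts and training

Eight layouts cross direction (up/down), cell scope (all lines vs a
named two-line subset), balancing, and feature subsets (type 1:
gene + drug + mutation + methylation; type 2: without methylation;
type 3: without mutation). Blocks concatenate in the fixed order
gene | drug | cell, and the input width is always derived from the
actual block widths — never a hard-coded total, since published totals
for comparable feature sets are not mutually consistent and any change
in vocabulary, bit length, marker panel or selected-site count moves
the sum. Layouts 1–2 balance classes by downsampling negatives
uniformly (seeded, across all cell lines jointly) to the positive
count; positives are never dropped. Cross-validation folds are
stratified — the plain variant risks starving the minority class in the
imbalanced layouts.

The network has four layers: input, two hidden layers each exactly as
wide as the input, and a 2-unit softmax output. The first hidden layer
uses SELU and the second ReLU (the order is a config switch; only the
activation set is fixed by design), each followed by 50% inverted
dropout during training — plain dropout, not SELU's alpha-dropout,
matching the design of a simple stochastic forward-propagation drop.
Weights initialize Lecun-normal (SELU layers), He-normal (ReLU), and
Glorot for the output. Training minimizes softmax cross-entropy with
Adam (lr 1e-3, batch 128, ≤ 100 epochs, patience 10 — conventional
defaults; only architecture, dropout, early stopping and 3-fold CV are
fixed by design), stops when validation loss fails to improve for
`patience` epochs, and restores the best-epoch weights; the recorded
best-loss sequence is non-increasing by construction. The final refit
on all rows carves out an internal stratified 10% split for the
stopping criterion. The implementation is direct NumPy; per-fold seeds
derive from the config seed.

Benchmarks via scikit-learn: random forest (500 trees, default depth),
Gaussian naive Bayes (the feature vector mixes binary and continuous
blocks, so the Gaussian variant is the default; a Bernoulli switch
would require binarizing the methylation block), and L2 (ridge)
logistic regression, whose penalty is what keeps the wide collinear
binary system solvable.

Evaluation: confusion counts at probability threshold 0.5 (the argmax
of the 2-unit softmax), precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
accuracy, rank-based ROC-AUC, and step-interpolated area under the
precision–recall curve. With single-class truth the rank metrics are
undefined and reported as NaN rather than a conventional constant.
APR is the headline metric: under the 5%-positive imbalance, accuracy
and AUC are dominated by the majority class.

## Repurposing

A drug's interaction count is its number of **unique** positive
(gene, cell) pairs in the desired mode — upregulation positives on
pro-longevity genes, or downregulation positives on anti-longevity
genes; dose replicates collapse to one pair. Pair-level deduplication
is asserted as this package's definition: it is the only reading under
which an interaction count, a unique-gene count and a unique-cell-line
count are mutually consistent. The diversity filter is strict
(`> min_genes` distinct genes and `> min_cells` distinct lines), drugs
sort by interaction count descending with lexical tie-break, and the
up/down intersection orders dual-action candidates by combined count.
Prediction pools are full Cartesian products (drugs × genes × normal
lines) in lexical order; per-drug positive rate = triples scored at or
above threshold 0.5, divided by the drug's pool size.

## The synthetic generator

`synthgen` emulates the statistical structure the pipeline assumes, at
desk scale, from a single seed (independent child streams per table, so
the planted ground truth is re-derivable from the config alone):

- **Perturbations.** A set of (drug, gene) pairs — `planted_pairs`
  forced-regulation pairs plus `n_background_pairs` random pairs —
  crossed with all cell lines. Z-scores are standard normal except
  planted pairs, shifted by ±`effect_size` consistently across cells;
  planted "up" pairs target pro-longevity genes and "down" pairs
  anti-longevity genes, so planted drugs carry the desired-mode signal
  the ranking looks for, and planted pairs concentrate on few drugs
  (about one quarter as many drugs as pairs) so those drugs accumulate
  rankable interaction counts. 10% of records are re-dosed in nM and
  10% re-timed to 6 h to exercise the condition filters; 20% of rows
  get a second dose replicate to exercise deduplication.
- **Longevity labels.** Exactly `floor(frac · n_genes)` pro and anti
  labels; the default fractions are 397/889 and 492/889, so the default
  889-gene world reproduces the canonical GenAge-derived split. Counts
  use `floor(frac·n + 1e-9)`: the exact rational `(397/889)·889` lands
  just below 397 in binary floating point, and the epsilon restores the
  mathematical floor.
- **SMILES.** A hard-coded pool of 50 valid, structurally diverse
  known drugs (stereochemistry stripped), extended past 50 by an
  enumerated homologous series — parseable structures for any drug
  count with no chemistry dependency at generation time.
- **Methylation.** Nonnegative gamma-distributed channel intensities
  (so the beta formula is actually exercised downstream rather than
  bypassed with precomputed betas). A leading block of CpG sites
  (one fifth by default) is histology-informative: each such site maps
  histology classes to well-separated beta levels through its own
  random class-to-level permutation plus per-cell jitter (σ = 0.1), so
  informative sites correlate strongly with histology without being
  exact copies of one another — FCBF then finds many relevant sites
  and keeps a small non-redundant subset, as on real arrays.
- **GO annotations / mutations.** Random term memberships whose sizes
  straddle the ≥ 3-gene vocabulary filter; Bernoulli(0.25) markers.

What the generator does **not** emulate: landmark-gene inference,
replicate structure and dose–response shapes, GO graph structure and
annotation bias, linkage between mutations and expression, batch
effects, and real compound–target pharmacology. Passing tests
therefore demonstrate the pipeline's mechanics and its ability to
recover a planted signal — not predictive performance on real
perturbation corpora, whose headline metrics depend on data this
package deliberately does not download.

## The planted-recovery study

The end-to-end check trains the layout-1 network (balanced, all cells,
full features) on a world designed to be separable, with conditions
fixed by the following analysis rather than by experiment:

- 200 genes, 30 drugs, 10 cell lines, 400 GO terms, 40 planted pairs,
  effect size 6, 360 background pairs, 256 fingerprint bits.
- The ~20 planted-up pairs fill the per-cell 5% quota
  (`floor(0.05 · 400 pairs) = 20`), and an effect size of 6 puts the
  weakest planted record above the strongest of ~380 background
  records per cell with high probability — so the positive class is
  almost purely planted signal instead of unlearnable background-tail
  noise.
- 400 terms over 200 genes make GO profiles effectively
  gene-identifying; with a sparse vocabulary the network cannot tell
  planted genes from colliding background genes no matter how it
  trains.
- Ten records per pair (one per cell) let the network memorize pair
  membership across folds.

Under these conditions the network's validation APR exceeds 0.9 and
ranking recovers the planted drugs (all ranked planted drugs ahead of
any non-planted drug) in ≥ 90% of replicate worlds; both quantities are
recomputed by `scripts/acceptance.py`. The 256-bit fingerprints and
reduced gene count keep the equal-width hidden layers small enough that
the whole study runs in seconds on one CPU; results are insensitive to
raising either.

## Known limitations

- The real corpora (perturbation catalogs, GenAge, mutation and
  methylation downloads) are out of scope by design; counts and metric
  tables conditioned on them are not reproduced.
- Binary long-format tables only; no GCTX/HDF5 parsing of level-5
  matrices (a converter to the expected long format is the user's
  side).
- The network's determinism contract is per-platform: identical seeds
  reproduce identical runs on the same BLAS; bit-identity across BLAS
  builds is not guaranteed (metrics agree to float tolerance).
- FCBF is the classic two-stage filter; no wrapper/embedded selection
  alternatives are provided.
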