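# gerochem

Chemogenomic prediction of how small molecules regulate
longevity-associated genes, and ranking of candidate geroprotectors for
repurposing.

## The problem

Large perturbation catalogs (LINCS/CMap-style L1000 signatures) record a
Z-score for the expression change of a gene in a cell line after
treatment with a compound. Separately, curated aging databases (GenAge)
label human genes as **pro-longevity** (more activity, longer lifespan)
or **anti-longevity**. A compound that *up*regulates pro-longevity genes
or *down*regulates anti-longevity genes across many cell lines is a
repurposing candidate for promoting longevity.

`gerochem` implements that pipeline end to end:

1. **Labeling.** After restricting records to 24-h treatments with doses
   in µM and to the longevity gene set, the *left–right percentile* rule
   marks, per cell line, the top 5% of Z-scores as upregulation
   positives (and the bottom 5% as downregulation positives); everything
   else is an unknown-effect negative.
2. **Descriptors.** Each (drug D, gene G, cell line C) sample is the
   concatenation of four blocks: one-hot Gene Ontology membership of G
   (terms annotating ≥ 3 study genes), a radius-2 Morgan fingerprint of
   D folded to 2048 bits, the binary mutation-marker profile of C, and
   C's CpG methylation beta values
   `B(j) = max(y_meth,0) / (max(y_meth,0) + max(y_unmeth,0) + α)`
   reduced by a fast correlation-based filter (FCBF, symmetrical
   uncertainty against tissue histology, cut-off 0.6).
3. **Models.** Eight layouts crossing direction (up/down), cell scope
   (all lines vs a two-line subset), class balancing, and feature
   subsets. The primary classifier is a four-layer feed-forward network
   — two hidden layers as wide as the input, SELU then ReLU activations,
   50% dropout, 2-unit softmax — trained with Adam, early stopping, and
   stratified 3-fold CV; random forest, Gaussian naive Bayes and ridge
   logistic regression are benchmarks. Metrics: accuracy, ROC-AUC,
   precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, and area under the
   precision–recall curve (APR).
4. **Repurposing.** Drugs are ranked by their number of unique desired
   positive (gene, cell) pairs, filtered to drugs covering > 100 genes
   and > 5 cell lines (scaled down on toy worlds); the up/down ranking
   intersection yields dual-action candidates. For prospective scoring
   on normal (non-cancer) cell lines, each candidate gets a pool
   `Pool(D) = D × {longevity genes} × {normal lines}` — e.g. 10 drugs ×
   397 pro-longevity genes × 2 lines = 7940 triples — scored by a
   trained model; the per-drug positive rate summarizes promise.

Because the real corpora are access-controlled downloads, the package
ships a seeded synthetic generator (`gerochem.synthgen`) that emulates
every input — perturbation tables with planted drug–gene regulation
signal, SMILES, GO annotations, mutation matrices, methylation
intensities with histology-correlated CpG sites, and a longevity gene
table reproducing the 397 pro / 492 anti split of 889 genes.

## Worked example

```sh
gerochem simulate --out world --seed 3
# world written to world (5952 perturbation records, 30 drugs, 889 genes, 8 cell lines)

gerochem ingest --perturbations world/perturbations.tsv \
    --longevity world/longevity.csv --direction up --out labeled.tsv
# 4816 labeled records (237 positive) -> labeled.tsv
```

The ~19% of generated records carrying 6-h times or nM doses were
filtered out; 237 = Σ per cell line floor(0.05·n) records are
upregulation positives. Ranking drugs by unique positive
(pro-longevity gene, cell) pairs, with the diversity filters scaled to
the 30-drug toy world:

```sh
gerochem rank --labeled labeled.tsv --longevity world/longevity.csv \
    --mode up-on-pro --min-genes 2 --min-cells 2 --out rank.tsv
#  Rank     Drug  # Interactions  # Unique Genes  # Unique Cell Lines
#     1 DRUG0016              22               6                    8
#     2 DRUG0003              18               6                    8
#     3 DRUG0010              13               6                    8
```

The top drugs are exactly those the generator planted with upregulation
effects on pro-longevity genes: each interaction is one (gene, cell
line) pair in which the drug's Z-score reached the top 5%. `gerochem
train --model 1 ...` then fits the network on such labels, and `gerochem
predict-pool` scores candidate × gene × normal-line pools with it
(normal lines get an all-zero mutation block).

Library use mirrors the CLI — see `gerochem.pipeline` for three-line
world → features → trained-model runs.

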