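# phagelink

Guilt-by-association prediction of functional links between bacteriophage
protein families.

Most bacteriophage protein families have no functional annotation: sequence
similarity searches fail for the majority of viral proteins, because
deposited phage sequences cover only a sliver of natural diversity and
evolve fast.  `phagelink` takes the comparative-genomics route instead.
Functionally associated genes leave genomic fingerprints — they co-occur on
the same genomes (similar phylogenetic profiles), sit close together in
conserved, co-oriented gene cassettes, and favour mutually similar genomes.
This package measures those signals for pairs of profile-HMM protein
orthologous groups (pVOG-style families) across a set of phage genomes and
integrates them with a Random Forest to predict which pairs are
functionally associated.  Predicted partners of annotated families then
provide preliminary functional hints for unannotated ones.

It is a library first (every stage is an importable module; see
`examples/`), with a thin `phagelink` command-line layer for running the
stages as a workflow.

## The method

For every unordered pair of groups (a, b) seven features are measured from
an occurrence index built out of significant profile-HMM hits placed on the
genomes in nucleotide coordinates:

| feature | definition |
| --- | --- |
| co-occurrence | Jaccard similarity of genome sets, \|G_a ∩ G_b\| / \|G_a ∪ G_b\| |
| average distance | minimum nucleotide gap between the two groups' hit envelopes, averaged over common genomes |
| co-orientation fraction | fraction of common genomes whose closest hit pair lies on the same strand |
| convergent fraction | opposite strands, 3′ ends facing each other |
| divergent fraction | opposite strands, 5′ ends facing each other |
| mean ANI | mean Average Nucleotide Identity over pairs of common genomes |
| mean AAI | mean Average Amino-acid Identity over pairs of common genomes |

Ground truth is built from a curated list of interacting protein pairs:
each protein is mapped to its best-scoring group, and pairs whose groups
never share a genome are excluded.  Because non-interaction cannot be
observed, ten balanced datasets are formed by combining the shared
positives with ten independently sampled negative sets.  Each dataset is
split 70/30 (stratified); a randomized hyperparameter search with
stratified five-fold cross-validation yields one candidate configuration
per dataset; every candidate is re-trained on every dataset's 70% and
scored on its 30%, and the final model/dataset combination is the one with
the best mean AUROC (ties: accuracy, then F1) across the grid.  The final
forest carries 500 trees, so a pair's interaction probability is the mean
vote of 500 decision trees; pairs above 0.5 are called interacting, and
0.65 marks high confidence.

A synthetic-data module generates complete desk-scale inputs — genomes on
a star phylogeny, planted gene cassettes, identity matrices, free-text
annotations — so every stage is testable end to end without any downloads.

## Worked example

`examples/02_train_and_select.py` builds a scenario with 20 planted
interacting pairs across 15 genomes, assembles ten balanced datasets and
runs the full selection protocol:

```
positives: 20; datasets: 10
selected dataset: N10
mean holdout AUROC across datasets: 1.000
mean holdout accuracy across datasets: 1.000
Gini importances (normalized, descending):
  avg_distance    0.980
  f_co            0.018
  co_occurrence   0.002
  ...
```

The selected model separates planted interacting pairs from background
perfectly (AUROC 1.0 on every holdout), and the importance mass sits on
the cassette signals (distance, co-occurrence, orientation).
`examples/03_predict_and_transfer.py` then scores every co-occurring pair
outside the ground truth and transfers annotations:

```
target pairs scored: 1449
predicted to interact: 54 (3.7%)
high confidence (p >= 0.65): 54 (100.0% of positives)
unannotated groups linked to an annotated partner: 18 of 58 (31.0%)
```

Each linked unannotated group inherits a preliminary functional hint from
its highest-probability annotated partner (guilt by association).
`examples/04_annotation_similarity.py` shows the annotation cross-check:
interacting pairs sit far closer in weighted-cosine annotation space
(mean distance ≈ 0.49) than random annotated pairs (≈ 0.95).

## Command line

```bash
phagelink synth --out run/inputs --seed 1 --positives 20
phagelink features --hits run/inputs/hits.tsv --ani run/inputs/ani.tsv \
    --aai run/inputs/aai.tsv --out run/features
phagelink pipeline --out run/all --seed 1     # chain everything, desk scale
```

Every command writes a `manifest.json` with its configuration, seed and
input checksums.  Real-scale inputs are supported through the same file
formats: HMMER3 `--domtblout` tables against 6-frame translations (target
names `<genome>_frame<k>`), fastANI and CompareM summary tables, and
two-column annotation TSVs.

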