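# signrepo

Network-based drug repositioning from sign-constrained shortest paths on a
directed gene network.

## The problem

Most network-based repositioning methods treat the interactome as an
unsigned graph: they measure how *close* a drug's targets are to a
disease's genes, but not whether the drug would push those genes up or
down. `signrepo` implements a method built on the opposite-regulation
hypothesis — a drug is a treatment candidate when it regulates the
disease's genes in the opposite direction — using only network topology and
known drug–disease associations, with no gene-expression profiles required.
It is aimed at computational biologists who have interaction tables
(gene–gene regulation, drug targets, disease genes, known indications) and
want ranked candidate indications with statistical validation.

## The model

The gene network is a directed multigraph with three edge types:
**positive** (activation/expression, sign +1), **negative**
(inhibition/repression, sign −1) and **neutral** (binding, no sign).
For a drug-target gene *t* and a disease gene *g*, all tied shortest
directed paths from *t* to *g* are enumerated. Each path gets

* a type `T = ∏ eᵢ` over its signed edges (±1; +1 if the path has no
  signed edge),
* a weight `W = ∏ 1/dᵢ` over the out-degrees of its departure nodes
  (influence is diluted at every branching gene),

and the pair score is `V = Σᵢ Tᵢ·Wᵢ` over the tied paths. When the
drug–target interaction is neutral (a binding with no direction of
regulation), paths must contain at least one signed edge; when it is
signed, all-neutral paths are allowed. The drug–disease value per disease
gene is

```
DV(g) = Σ_targets sign(drug→t) · V(t → g)
```

with sign −1 for inhibitory and +1 for activating or binding drug–target
interactions. Stacking DV vectors over all drugs gives a per-disease
matrix; known drugs are labelled TRUE, a 3× random sample of the rest
FALSE, and random-forest / neural-network classifiers are tuned and scored
by 10-fold cross-validation (AUC of pooled out-of-fold probabilities),
repeated with fresh negative samples. The tied-best classifiers rank the
remaining drugs by mean TRUE-probability. Predictions are validated by
exact hypergeometric enrichment against a reference pair set and by
comparing candidate vs non-candidate drugs' functional-module similarity to
known drugs (one-tailed Wilcoxon rank-sum).

## Worked example

Generate a synthetic study with a planted treatment signal and run the full
pipeline (random forest, 2 repetitions for a quick desk run):

```bash
signrepo simulate --seed 1 --out fx --n-genes 240 --n-drugs 40 \
    --n-diseases 1 --n-known 12
signrepo run --edges fx/edges.tsv --drug-targets fx/drug_targets.tsv \
    --disease-genes fx/disease_genes.tsv \
    --known-associations fx/known_associations.tsv \
    --model rf --repetitions 2 --seed 17 --out out
```

which prints

```
1 eligible disease(s), 0 candidate pair(s)
```

and writes `out/auc_report.tsv`:

```
disease_id  model          mean_auc  sd_auc    best_auc
DIS00       random_forest  0.985119  0.000000  0.985119
```

The single eligible disease (12 known drugs, strictly more than the
10-known-drug cut-off) reaches a mean cross-validated AUC of 0.985 over
the two negative-sampling repetitions: the classifier recovers the planted
"drug opposes disease genes" wiring almost perfectly. Zero candidate pairs
is the correct answer here — every planted treating drug is already in the
known list, so no unknown drug should cross the 0.5 probability threshold.
(Drop some drugs from `known_associations.tsv` and they reappear in
`out/predictions.tsv` with high TRUE-probability, which is exactly what
`scripts/acceptance.py` measures.) `out/manifest.json` records the exact
configuration and seed needed to reproduce the run byte-for-byte.

The same steps work on real interaction tables: `edges.tsv` rows are
`source  destination  interaction_name_or_type  [direction]`, where
interaction names (e.g. `Activation`, `Inhibition`, `Binding`) are mapped
to edge types and unassigned names (e.g. `Phosphorylation`) are dropped,
and undirected records are expanded to both orientations.

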