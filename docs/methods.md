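# Methods

## Model and assumptions

`signrepo` scores drug–disease associations on a directed gene network
whose edges carry one of three interaction types: positive
(activation/expression), negative (inhibition/repression) and neutral
(binding). The working assumptions are that (i) regulatory influence
propagates along directed paths and is attenuated at every branching gene,
(ii) the *sign* of the delivered influence is the product of the signs of
the signed edges traversed, with binding edges transparent to sign, and
(iii) a drug is a treatment candidate when it tends to regulate a
disease's genes oppositely to the disease — information the classifier
learns from known indications rather than from a hard-coded rule.

Influence of a target gene *t* on a disease gene *g* is computed over all
tied shortest paths from *t* to *g*:

* path type `T = ∏ sign(e)` over non-neutral edges; an all-neutral path
  has `T = +1` (empty product), so it transmits the drug–target sign
  unchanged. This convention is needed because all-neutral paths are
  legitimate exactly when the drug–target interaction itself carries the
  sign.
* path weight `W = ∏ 1/out-degree(node)` over the path's *departure*
  nodes. Out-degree counts outgoing typed edges (parallel edges of
  different types count separately); the destination node is excluded from
  the product — its fan-out cannot dilute influence that has already
  arrived, and a sink destination would otherwise divide by zero. Both
  choices are configurable (`distinct_neighbors`, `include_destination`).
* pair score `V = Σ T·W` over the tied paths; `V = 0` when unreachable.

Constraint cases: a **neutral** drug–target interaction requires at least
one signed edge on the path (an entirely neutral chain would carry no
regulatory direction at all), and the shortest *satisfying* length may
exceed the unconstrained shortest length; a **signed** drug–target
interaction lifts the constraint. The per-disease-gene drug value is
`DV = Σ_targets sign·V` with sign −1 for inhibitory interactions and +1
otherwise (binding does not flip the sign).

## Path enumeration

Paths are node-simple and enumerated by iterative-deepening DFS, pruned by
reverse-BFS hop distances to the destination, expanding parallel typed
edges into distinct paths; the first depth with a satisfying path is
minimal, so all returned paths are tied at the minimum. Choices that the
score definitions leave open:

* **Simple paths only.** A state-augmented search over (gene, signed-seen)
  can revisit genes; gene-level revisits have no biological reading here,
  and simple paths match standard shortest-path usage.
* **`max_length` = 6 edges** (configurable). All-shortest-path enumeration
  needs a tractability bound; on sparse regulatory networks essentially
  all informative paths are much shorter, and a pair with no satisfying
  path within the cap scores `V = 0`.
* **Safety cap of 10 000 tied paths per pair** (configurable). Exceeding
  it raises `PathExplosionError` rather than silently truncating, because
  a truncated `V` would be wrong in an unbounded way.
* A target equal to the disease gene contributes `sign · 1` — direct
  regulation with full weight (length-0 paths are otherwise undefined);
  a switch contributes 0 instead.

## Classification

Per eligible disease (strictly more than 10 known drugs among the
scoreable ones — 10-fold cross-validation needs at least one positive per
fold), the training set is the known drugs (TRUE) plus a seeded uniform
sample, without replacement, of 3× as many other scoreable drugs (FALSE);
if the pool is smaller it is used whole, with a warning. Disease-gene
columns that are zero across the training rows are dropped — a gene no
training drug reaches carries no signal for that fit. Folds are stratified
by label (a 1:3 ratio otherwise risks single-class folds) and one AUC per
repetition is computed from the pooled out-of-fold TRUE-probabilities,
which is stabler than averaging per-fold AUCs at these sample sizes.

Models and tuning:

* **random forest** — 500 trees; features-per-split tuned over
  {√p, p/3, p/2} by out-of-bag AUC. The forest's built-in out-of-bag
  estimate replaces an inner cross-validation: it uses every training row,
  costs one fit per grid point instead of one per grid point per inner
  fold, and is the canonical self-tuning route for bagged ensembles.
* **neural network** — single hidden layer, size ∈ {1, 3, 5}, weight decay
  ∈ {0, 1e-4, 1e-1}, L-BFGS, ≤ 500 iterations, tuned by inner
  stratified 5-fold AUC.

The procedure is repeated (default 100×; desk-scale runs use 5) with a
fresh negative sample per repetition (seed = base seed + repetition
index). All classifiers *tied* at the maximum AUC are kept; each is refit
on its full training set before scoring, every unknown drug is scored on
that classifier's retained columns, and a drug becomes a candidate when at
least one best classifier gives TRUE-probability > 0.5. Its reported
probability is the mean over the best classifiers that predicted it (a
switch averages over all best classifiers instead).

## Validation statistics

* **Reference enrichment.** Exact upper-tail hypergeometric test of the
  overlap between predicted and reference pairs after restricting
  predictions to the reference universes, with population
  N = |reference drugs| × |reference diseases| (the natural pair universe
  once both margins are fixed by the reference).
* **Gene direction on paths.** Each gene on a stored shortest path
  receives the drug–target sign times the product of signed-edge values on
  the path prefix ending at it — the natural restriction of the T and DV
  definitions to prefixes — summed over paths; positive totals are "up",
  negative "down", zero excluded.
* **Module enrichment** of the up and down sets separately
  (splitting by direction is more sensitive than pooling), raw p < 0.05
  with no multiplicity correction by default (a Benjamini–Hochberg switch
  exists); a drug's module profile is the union of the two significant
  sets, and two drugs with empty profiles have Jaccard similarity 0.
* **Candidate vs non-candidate comparison.** Each non-known drug scores
  its best Jaccard similarity to any known drug's profile; groups are
  compared by a one-tailed Wilcoxon rank-sum test (exact when ≤ 50 values
  and tie-free, tie-corrected normal approximation otherwise).

## Synthetic studies

The generator emulates the pipeline's data model, not real interactome
statistics. The network is a directed preferential-attachment graph
(default 600 genes, mean out-degree 3, edge types 1:1:2
positive:negative:neutral — signed edges are the minority, as regulatory
annotations are rarer than binding). Drugs (default 100) draw 1–5 typed
targets from per-drug disjoint gene blocks, so that target sharing between
drugs cannot leak the planted signal; diseases (default 3) draw 8–15 genes
from the residual genes, so no target coincides with a disease gene and
all signal is path-borne. For each disease, 15 drugs are designated
treating: each of their targets gains an edge to each disease gene with
probability 1 − exp(−signal_strength), typed to oppose the drug–target
sign, so the net drug effect on the disease gene is negative.
`noise_sd` adds Poisson-distributed spurious signed edges per drug target.
Every entity draws from a seed-derived substream, so the fixture is
bit-reproducible and locally perturbable.

What passing on these fixtures shows: the scoring, training and validation
machinery recovers a path-borne opposite-regulation signal and stays at
chance without it. What it does not show: performance on real
interactomes, whose degree distributions, edge-type frequencies, target
promiscuity and label noise the generator deliberately does not imitate.

## Problem sizes and numerical choices

Desk-scale runs and the acceptance script use the default fixture
(600 genes, 100 drugs, 3 diseases, 15 known drugs each) with 5
negative-sampling repetitions and the random-forest model; these sizes
exercise every stage while keeping a full run in minutes on one core.
Floating-point path weights are exact binary fractions only when
out-degrees are powers of two, so score comparisons in tests use relative
tolerances except where exactness is guaranteed; ties in classifier
selection are exact float equality on pooled-AUC values, which is
well-defined because identical seeds reproduce identical probability
vectors. All row/column orders are lexicographic and every sampler is
seeded, making pipeline outputs byte-identical across reruns.

## Known limitations

* Hop-count shortest paths only; no edge-confidence weighting or
  k-shortest-path generalisation.
* DV is linear in targets by construction; synergistic or saturating
  multi-target effects are out of scope.
* The probability threshold (0.5) is uncalibrated; reported probabilities
  are classifier scores, not treatment probabilities.
* With very dense networks the tied-path count can hit the safety cap;
  raising it trades memory and time for completeness.
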