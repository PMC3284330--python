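# Methods

## Problem setting

Given a GO-style term graph, dated and evidence-coded gene→term
associations, binary gene-centric features and pairwise evidence
(co-expression, interactions), produce for every (gene, term) pair a
log-odds score that the gene carries the term's function, and evaluate the
scores by precision–recall. Predicted ("IEA") associations are excluded
throughout so models learn from ground truth rather than from earlier
predictions.

## Data preparation

Associations are filtered by evidence code, then up-propagated: a gene
annotated to a term is annotated to every ancestor through `is_a` and
`part_of` edges, which are treated identically (set semantics — a diamond
contributes one ancestor annotation; the earliest date survives
propagation so prospective evaluation sees first-annotation dates). Terms
with 3–300 distinct annotated genes are selected and stratified into 12
categories: branch (BP/CC/MF) × breadth bin ([3,10], [11,30], [31,100],
[101,300]). Genes with ≥ 1 association to a selected term form the
training set; all other genes in the feature universe are *undetermined*.
Terms whose positives cover the entire training set (possible on small
universes, where a branch root is itself a selected term) cannot supply
negative examples and are skipped with a warning.

## Guilt-by-profiling (GBP)

One random forest per term: positives are the training genes annotated to
it, negatives all remaining training genes (closed world; undetermined
genes are excluded from fitting). Forests are the standard Breiman
algorithm — 100 trees grown to purity on bootstrap samples, √p candidate
features per split, Gini impurity — because that is the canonical,
assumption-free choice for a binary classifier on sparse binary features.
Training genes are scored by their out-of-bag vote fraction (only trees
whose bootstrap sample excluded the gene vote), undetermined genes by
ordinary prediction. Variable importance is mean impurity decrease;
permutation importance is available behind a flag.

Raw vote fractions are converted to a log-likelihood ratio
`LLR(s) = log p̂₊(s) − log p̂₋(s)` with class-conditional Gaussian KDEs of
the positive and negative OOB scores. This construction is an interpretive
choice — the combination equation consumes a likelihood ratio, and no raw-
score→LLR mapping is prescribed anywhere — and it deliberately mirrors the
density machinery of the transfer route (same augmentation, same
bandwidth rule) so the two LLRs are on comparable footing. The mapping is
monotone between the class centres, hence rank-preserving where it
matters; tests assert a high rank correlation on planted data.

## Guilt-by-association (GBA)

**Pair features.** Every unordered gene pair is an object. For each
gene-centric source the shared-annotation score is `sum_i f_i²` over
features carried by *both* genes (`f_i` = feature frequency in the full
gene universe); the score is discretized into nested top-10/20/30/40/50 %
indicators. Quantile thresholds are computed over pairs with a *nonzero*
score — shared-annotation scores are overwhelmingly zero, and quantiles
over all pairs would put every nonzero pair in every bin. Ties at a
threshold are included (deterministic and order-independent). A
`sum_inv_f2` switch inverts the weighting for sensitivity analyses, since
rewarding *common* shared features is the formula as specified but the
opposite of phenotype-similarity intuition. Co-expression uses the
minimum over samples of leave-one-sample-out Pearson correlation
(guarding against single-sample-driven correlation; pairs with an
undefined leave-one-out correlation are skipped), discretized into nested
top-1/5/10 % indicators per dataset; missing expression yields 0, absence
is not evidence. Interactions enter as one binary column after removing
self-pairs.

**FLN training.** One forest per category scores pairs. A training pair is
positive iff the two genes share ≥ 1 term of the category's branch with
an annotation count in [3, *upper bound of the bin*] — the cumulative
rule, so e.g. the BP [31,100] network is trained on pairs sharing any BP
term with at most 100 associations; a strict-bin switch exists. Training
pairs get OOB edge weights, all other pairs predicted weights, giving a
complete weighted graph; for n genes with m in training, the predicted
block has C(n,2) − C(m,2) pairs. Training on all pairs is quadratic in m;
a seeded `negative_subsample` fraction trains on all positives plus a
random fraction of negative pairs for desk-scale runs (pairs left out are
scored by prediction like non-training pairs).

**Annotation transfer.** For a term with core set C (its annotated
training genes), two edge-weight samples are formed: the C(|C|,2)
core-clique weights and the (training∖C)×C noncore-to-core weights. Each
is turned into a density and a candidate gene g is scored as

```
LLR_GBA(g) = Σ_{c∈C} [ log p_core(w(g,c)) − log p_noncore(w(g,c)) ].
```

Terms with ≤ 10 annotated genes use densities pooled across all terms of
their category (tiny cliques estimate densities poorly); pooling is
multiset — a pair belonging to two cores contributes twice — and
noncore-to-core samples are taken literally, without excluding pairs that
are core-to-core for some other term. Training genes are scored
leave-one-out: all edges incident to the held-out gene are removed, both
densities re-estimated, and the gene scored against the reduced core
(falling back to pooled densities when fewer than 2 core genes remain).

**Density estimation.** Densities are Gaussian KDEs with Silverman's
bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` (fallback 0.05 on zero-spread
samples, a visible bump rather than a delta spike). To keep every
log-ratio finite the estimate is augmented with a uniform safeguard. The
default is deterministic: a mixture of the KDE (weight n/(n+1)) with the
Uniform[0,1] density (weight 1/(n+1)) — the expectation of adding one
uniformly distributed pseudo-observation. The literal seeded pseudo-sample
variant is available as `density_mode="pseudo-sample"`. Evaluations are
clamped to [0,1] and floored at 1e-12. The evaluator is written out
explicitly because the mixture form is not expressible in off-the-shelf
KDE objects and degenerate one-value samples must be handled.

## Combination and evaluation

`LO_HF = α·LLR_GBP + (1−α)·LLR_GBA + LO_prior` with
`LO_prior = log(n_pos/(n_total − n_pos))`, constant per term. α is
grid-searched (0:0.01:1, ties to the smallest α) to maximise average
precision of the cross-validated (OOB/LOO) training scores — per term for
categories [11,30] and broader, one α per category for [3,10] terms to
avoid overfitting a coefficient to a handful of positives.

Precision–recall curves are computed over all distinct score thresholds
with pessimistic tie handling: a threshold keeps every object scoring ≥
it, so all members of a tie block share the block's final precision.
Average precision is the mean over positives of the precision at their
block — the area under the PR step curve under this tie rule — and is
checked in tests against both an O(n²) sweep and an independent library
implementation on tie-free inputs. P20R is the precision at the smallest
threshold reaching 20 % recall. Per-term curves aggregate into decile
contours on a 0.01 recall grid: the q % contour at recall r is the
(1 − q/100) quantile across terms of the cumulative (best-achievable at
recall ≥ r) precision; a flag switches to raw step values.

**Prospective protocol.** Predictions are frozen; a later annotation
snapshot is the judge. Per term, genes positive before the start date are
removed, the rest restricted to genes that gained *any* association on or
after the start date (only genes curators actually revisited can reveal
false negatives); surviving genes newly associated to the term are the
positives. Records with unparseable dates never mark a gene as
re-curated.

## FLN network operations

Thresholding keeps the ⌈q·|edges|⌉ highest-weight edges, ties at the
boundary included. Seed expansion recruits the 1-neighborhood of a seed
set through retained edges (a depth parameter exists, default 1) and
returns the subgraph induced on seeds ∪ recruited — so edges between two
recruited non-seed genes appear, which is how bridging candidates between
seed clusters surface. An external interaction edge list can be overlaid
as an annotation layer; it never drives recruitment.

## Synthetic data

The generator plants the structure the method assumes: genes belong to
functional modules, one GO-style leaf term per module under a
per-branch root/intermediate scaffold (the intermediate hangs off the
root via `part_of`, exercising both relation types). Module members carry
module-dedicated features with probability ρ_f = 0.8 against a 0.05
background (every gene gets at least one phylogenetic-profile anchor so
the feature universe covers all genes); expression of members loads on a
shared latent factor with variance fraction ρ_x = 0.6 over 30 samples;
interaction edges fall within modules with probability 0.8. Memberships
are revealed in two epochs around a 2008-07-19 start date (70 % before,
the rest after) and IEA-coded noise records exercise evidence filtering.
One master seed drives named substreams so any stage regenerates in
isolation, and a truth table records every planted membership.

Defaults describe a 120-gene universe with eight modules spanning the
[3,10], [11,30] and [31,100] bins; tests and the acceptance script use
45–60-gene bundles so full multi-seed pipelines stay in seconds. What
passing on this generator shows: the pipeline recovers planted
feature↔term and module↔term signal well above the permutation chance
level, and the α-combination is never materially worse than its better
component. What it does not show: performance on real GOA/InterPro-scale
data, where feature sparsity, annotation bias, term correlation and
ontology depth are far richer than this generator's independent modules
and flat three-level ontology.

## Numerical and design notes

- Feature frequencies are computed over the full loaded gene universe,
  not training genes only — the natural reading of "frequency of the
  feature".
- Random-forest determinism: fixed seed ⇒ identical scores; the rare
  training object in-bag for every tree falls back to its in-bag vote.
- Degenerate categories (all pair labels equal) skip FLN training with a
  warning and contribute zero GBA LLRs.
- `optimize_alpha` omits the per-term-constant prior: it cannot change a
  ranking.
- Quantile thresholds use linear-interpolation sample quantiles; with all
  scores tied every pair lands in every bin (the tie rule, not an error).
- The average precision of a *random* ranking exceeds the positive rate
  by a small-sample bias (≈ +0.05 at 60 objects / 12 positives); null
  calibration is therefore asserted against the label-permutation chance
  level computed on the same score lists, not against the raw positive
  rate.
- Known limitations: no hierarchical consistency enforcement between
  parent and child term scores; closed-world negatives understate truth
  for under-annotated genes; the per-category α for [3,10] terms trades
  per-term optimality for stability.
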