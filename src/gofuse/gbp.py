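"""Guilt-by-profiling: per-term random forests on gene-centric features.

For each selected GO term the training genes annotated to it are positives
and the remaining training genes negatives (closed world); undetermined
genes are scored by the fitted forest and training genes by their
out-of-bag vote fractions. Raw vote fractions are converted to a
log-likelihood ratio via class-conditional kernel densities, mirroring the
density machinery used for network-based transfer, because the downstream
combination is an affine sum of log-likelihood ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gofuse.density import augmented_kde
from gofuse.forest import ForestModel, predict, train_forest, variable_importance
from gofuse.gene_features import FeatureMatrix
from gofuse.ontology import AnnotationSet


@dataclass
class GbpTermResult:
    term: str
    scores: dict[str, float]  # raw forest vote fractions
    llr: dict[str, float]
    sets: dict[str, str]  # gene -> train_pos | train_neg | undetermined
    importance: list[tuple[str, float]]
    model: ForestModel | None = None


def train_gbp_term(
    t: str,
    m: FeatureMatrix,
    a: AnnotationSet,
    training: set[str],
    undetermined: set[str],
    seed: int = 0,
    n_trees: int = 100,
    keep_model: bool = False,
) -> GbpTermResult:
    """Fit the per-term profiling classifier and score every gene.

    Training genes are scored out-of-bag (an internal cross-validation
    estimate); undetermined genes get ordinary predictions and are never
    seen during fitting.
    """
    positives = sorted((a.genes_for(t) & training))
    negatives = sorted(training - set(positives))
    if not positives or not negatives:
        raise ValueError(
            f"term {t}: needs both positive and negative training genes "
            f"({len(positives)} positives of {len(training)} training genes)"
        )
    train_genes = positives + negatives
    train_genes = [g for g in train_genes if m.has_gene(g)]
    pos_set = set(positives)
    X = np.vstack([m.gene_row(g) for g in train_genes])
    y = np.array([1 if g in pos_set else 0 for g in train_genes])
    model = train_forest(X, y, n_trees=n_trees, seed=seed, feature_names=m.features)

    scores: dict[str, float] = {}
    sets: dict[str, str] = {}
    for g, s in zip(train_genes, model.oob_score):
        scores[g] = float(s)
        sets[g] = "train_pos" if g in pos_set else "train_neg"
    undet = sorted(g for g in undetermined if m.has_gene(g))
    if undet:
        Xu = np.vstack([m.gene_row(g) for g in undet])
        for g, s in zip(undet, predict(model, Xu)):
            scores[g] = float(s)
            sets[g] = "undetermined"

    labels = {g: (1 if lab == "train_pos" else 0)
              for g, lab in sets.items() if lab != "undetermined"}
    llr = gbp_score_to_llr(scores, labels)
    imp = variable_importance(model)
    return GbpTermResult(t, scores, llr, sets, imp, model if keep_model else None)


def gbp_score_to_llr(
    scores: dict[str, float],
    labels: dict[str, int],
    density_mode: str = "mixture",
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Convert raw vote fractions to log-likelihood ratios.

    LLR(s) = log p_hat_pos(s) - log p_hat_neg(s), where the two class
    densities are Gaussian KDEs of the positive and negative training-gene
    OOB scores, each augmented with a uniform safeguard so the ratio stays
    finite at scores where one class is unobserved.
    """
    pos = np.array([scores[g] for g, lab in labels.items() if lab == 1])
    neg = np.array([scores[g] for g, lab in labels.items() if lab == 0])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both labelled classes are required to calibrate LLRs")
    p_pos = augmented_kde(pos, mode=density_mode, rng=rng)
    p_neg = augmented_kde(neg, mode=density_mode, rng=rng)
    genes = list(scores)
    vals = np.array([scores[g] for g in genes])
    llr = p_pos.logpdf(vals) - p_neg.logpdf(vals)
    return {g: float(v) for g, v in zip(genes, llr)}
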