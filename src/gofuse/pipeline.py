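"""End-to-end orchestration: ontology -> features -> GBP -> FLN/GBA ->
combined HF scores -> evaluation.

``run_pipeline`` executes the full desk-scale flow on in-memory inputs (a
:class:`~gofuse.synthetic.SimBundle` or objects loaded from files) and
returns every intermediate a caller might want to inspect. The CLI wraps
this with file I/O and a JSON manifest recording the parameter digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gofuse import combine_eval, gba, gbp
from gofuse.combine_eval import PRCurve, optimize_alpha, optimize_alpha_category, pr_curve, prior_log_odds
from gofuse.gene_features import FeatureMatrix, build_feature_matrix, feature_frequencies
from gofuse.ontology import (
    AnnotationSet,
    OntologyGraph,
    TermCategory,
    all_categories,
    categorize_term,
    filter_evidence,
    propagate,
    select_terms,
    split_training_undetermined,
)
from gofuse.pair_features import build_pair_feature_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters with the framework's canonical defaults."""

    n_trees: int = 100
    min_term_size: int = 3
    max_term_size: int = 300
    excluded_evidence: tuple[str, ...] = ("IEA",)
    negative_subsample: float | None = None
    density_mode: str = "mixture"
    category_rule: str = "cumulative"
    similarity_mode: str = "sum_f2"
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    ontology: OntologyGraph
    annotations: AnnotationSet  # filtered + propagated
    selected_terms: list[str]
    categories: dict[str, TermCategory]
    training: set[str]
    undetermined: set[str]
    feature_matrix: FeatureMatrix
    flns: dict[str, gba.FLN]  # category label -> FLN
    gbp_results: dict[str, gbp.GbpTermResult]
    gba_loo: dict[str, dict[str, float]]
    gba_pred: dict[str, dict[str, float]]
    alphas: dict[str, float]
    priors: dict[str, float]
    score_table: pd.DataFrame
    training_curves: dict[str, PRCurve]

    def curves_by_category(self) -> dict[str, list[PRCurve]]:
        out: dict[str, list[PRCurve]] = {}
        for t, c in self.training_curves.items():
            out.setdefault(self.categories[t].label, []).append(c)
        return out


def training_labels_for_term(
    t: str, ann: AnnotationSet, training: set[str]
) -> dict[str, int]:
    pos = ann.genes_for(t) & training
    return {g: (1 if g in pos else 0) for g in training}


def run_pipeline(
    ontology: OntologyGraph,
    annotations_raw: AnnotationSet,
    feature_tables: list[pd.DataFrame],
    expression: list[pd.DataFrame] = (),
    ppi_edges: list[tuple[str, str]] = (),
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates.

    The gene universe is the set of genes carrying at least one
    gene-centric feature; training genes are those with a non-excluded,
    propagated association to a selected term.
    """
    cfg = config or RunConfig()
    t0 = time.time()

    ann = propagate(filter_evidence(annotations_raw, set(cfg.excluded_evidence)),
                    ontology)
    m = build_feature_matrix(feature_tables)
    freqs = feature_frequencies(m)
    universe = set(m.genes)
    selected = [
        t for t in select_terms(ann, cfg.min_term_size, cfg.max_term_size)
        if t in ontology.branch
    ]
    categories = {t: categorize_term(t, ann, ontology) for t in selected}
    training, undetermined = split_training_undetermined(ann, universe, selected)
    trainable = []
    for t in selected:
        n_pos = len(ann.genes_for(t) & training)
        if 0 < n_pos < len(training):
            trainable.append(t)
        else:
            # a term covering every training gene (or none of them) has no
            # negative (positive) examples and cannot be classified
            logger.warning(
                "term %s: %d positives of %d training genes, skipping",
                t, n_pos, len(training),
            )
    selected = trainable
    logger.info(
        "pipeline: %d genes (%d training), %d selected terms",
        len(universe), len(training), len(selected),
    )

    # guilt-by-profiling, one forest per term
    gbp_results: dict[str, gbp.GbpTermResult] = {}
    for t in selected:
        gbp_results[t] = gbp.train_gbp_term(
            t, m, ann, training, undetermined,
            seed=cfg.seed, n_trees=cfg.n_trees,
        )

    # pair features once, then one FLN per category that has terms
    pair_table = build_pair_feature_table(
        sorted(universe), m, freqs, expression, ppi_edges,
        similarity_mode=cfg.similarity_mode,
    )
    used_categories = sorted({categories[t].label for t in selected})
    cat_by_label = {c.label: c for c in all_categories()}
    flns: dict[str, gba.FLN] = {}
    for label in used_categories:
        cat = cat_by_label[label]
        labels = gba.build_training_labels(ann, ontology, cat, training,
                                           rule=cfg.category_rule)
        if not any(labels.values()) or all(labels.values()):
            logger.warning("category %s: degenerate pair labels, skipping FLN", label)
            continue
        flns[label] = gba.train_fln(
            pair_table, labels, seed=cfg.seed, n_trees=cfg.n_trees,
            negative_subsample=cfg.negative_subsample, category=cat,
        )

    # annotation transfer: LOO for training genes, prediction for the rest
    terms_by_cat: dict[str, list[str]] = {}
    for t in selected:
        terms_by_cat.setdefault(categories[t].label, []).append(t)
    gba_loo: dict[str, dict[str, float]] = {}
    gba_pred: dict[str, dict[str, float]] = {}
    for t in selected:
        label = categories[t].label
        fln = flns.get(label)
        if fln is None:
            gba_loo[t] = {g: 0.0 for g in training}
            gba_pred[t] = {g: 0.0 for g in undetermined}
            continue
        pooled_terms = terms_by_cat[label]
        gba_loo[t] = gba.loo_gba_scores(
            t, fln, ann, training, pooled_terms=pooled_terms,
            density_mode=cfg.density_mode,
        )
        res = gba.transfer_term(
            t, fln, ann, training, undetermined, pooled_terms=pooled_terms,
            density_mode=cfg.density_mode,
        )
        gba_pred[t] = res.llr

    # combination: per-term alpha for broad terms, per-category for [3,10]
    alphas: dict[str, float] = {}
    priors: dict[str, float] = {}
    training_curves: dict[str, PRCurve] = {}
    small_by_cat: dict[str, list[str]] = {}
    for t in selected:
        n_pos = len(ann.genes_for(t) & training)
        priors[t] = prior_log_odds(n_pos, len(training))
        if categories[t].bin == (3, 10):
            small_by_cat.setdefault(categories[t].label, []).append(t)
        else:
            labels = training_labels_for_term(t, ann, training)
            loo_gbp = {g: gbp_results[t].llr[g] for g in training}
            alphas[t] = optimize_alpha(loo_gbp, gba_loo[t], labels)
    for label, ts in small_by_cat.items():
        data = []
        for t in ts:
            labels = training_labels_for_term(t, ann, training)
            loo_gbp = {g: gbp_results[t].llr[g] for g in training}
            data.append((loo_gbp, gba_loo[t], labels))
        a_cat = optimize_alpha_category(data)
        for t in ts:
            alphas[t] = a_cat

    rows = []
    for t in selected:
        a = alphas[t]
        pos = ann.genes_for(t) & training
        for g in sorted(universe):
            lg = gbp_results[t].llr.get(g, 0.0)
            lb = gba_loo[t].get(g, gba_pred[t].get(g, 0.0))
            rows.append(
                (g, t, lg, lb, priors[t], a,
                 combine_eval.combine_hf(lg, lb, a, priors[t]))
            )
        hf_train = {
            g: combine_eval.combine_hf(
                gbp_results[t].llr[g], gba_loo[t][g], a, priors[t]
            )
            for g in training
        }
        training_curves[t] = pr_curve(hf_train, pos)
    score_table = pd.DataFrame(
        rows,
        columns=["gene", "term", "llr_gbp", "llr_gba", "lo_prior", "alpha", "lo_hf"],
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return PipelineResult(
        cfg, ontology, ann, selected, categories, training, undetermined,
        m, flns, gbp_results, gba_loo, gba_pred, alphas, priors,
        score_table, training_curves,
    )


def write_manifest(path: str, cfg: RunConfig, counts: dict[str, int]) -> None:
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "config_digest": cfg.digest(),
        "counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
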