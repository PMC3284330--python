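"""Combination of profiling and association scores, and PR evaluation.

The combined "HF" (human function) log-odds for gene i and a term is

    LO_HF = alpha * LLR_GBP + (1 - alpha) * LLR_GBA + LO_prior

where LO_prior = log(n_pos / (n_total - n_pos)) is the term's prior
log-odds, constant across genes. alpha is chosen on a grid to maximize the
leave-one-out / out-of-bag average precision — per term for broad terms,
once per category for [3,10] terms to avoid overfitting.

Evaluation is precision vs recall over score thresholds, with average
precision (area under the PR step curve) as the scalar summary and
precision at 20% recall (P20R) as the headline operating point. Per-term
curves are aggregated into decile contours on a fixed recall grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from gofuse.ontology import AnnotationSet

ALPHA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class ScoreRecord:
    gene: str
    term: str
    llr_gbp: float
    llr_gba: float
    lo_prior: float
    alpha: float

    @property
    def lo_hf(self) -> float:
        return combine_hf(self.llr_gbp, self.llr_gba, self.alpha, self.lo_prior)


@dataclass
class PRCurve:
    """Precision/recall at every distinct score threshold (descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float
    n_pos: int


@dataclass
class ContourSummary:
    category: object
    recall_grid: np.ndarray
    contours: dict[int, np.ndarray]  # decile percent -> precision curve
    mean_curve: np.ndarray
    median_curve: np.ndarray
    p20r_mean: float
    p20r_median: float


def prior_log_odds(n_pos: int, n_total: int) -> float:
    """Prior log-odds of a gene carrying the term: log(n_pos/(n_total-n_pos))."""
    if not 0 < n_pos < n_total:
        raise ValueError("need 0 < n_pos < n_total")
    return float(np.log(n_pos / (n_total - n_pos)))


def combine_hf(
    llr_gbp: float, llr_gba: float, alpha: float, lo_prior: float
) -> float:
    """Exact affine combination into the posterior HF log-odds."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0,1]")
    return alpha * llr_gbp + (1.0 - alpha) * llr_gba + lo_prior


def pr_curve(scores: dict[str, float], positives: set[str]) -> PRCurve:
    """Precision-recall curve over all distinct score thresholds.

    Ties are handled pessimistically: a threshold keeps *every* object
    scoring >= it, so all members of a tie block share the block's worst
    (final) precision. Average precision is the mean, over positives in
    rank order, of the precision at each positive's block — the area under
    the PR step curve under this tie rule.
    """
    genes = list(scores)
    pos = positives & set(genes)
    if not pos:
        raise ValueError("no positive objects among the scored genes")
    vals = np.array([scores[g] for g in genes])
    labels = np.array([g in pos for g in genes])
    order = np.argsort(-vals, kind="stable")
    vals, labels = vals[order], labels[order]
    # block boundaries: last index of each distinct score
    is_block_end = np.append(vals[1:] != vals[:-1], True)
    cum_tp = np.cumsum(labels)
    ranks = np.arange(1, len(vals) + 1)
    thr = vals[is_block_end]
    prec = cum_tp[is_block_end] / ranks[is_block_end]
    rec = cum_tp[is_block_end] / len(pos)
    # AP: each positive contributes the precision of its block's end
    ends = is_block_end.astype(int)
    block_id = np.cumsum(ends) - ends  # block index per sorted object
    ap = float(prec[block_id[labels]].sum() / len(pos))
    return PRCurve(thr, prec, rec, ap, len(pos))


def precision_at_recall(curve: PRCurve, r: float = 0.20) -> float:
    """Precision at the smallest threshold whose recall is >= r.

    When r exceeds the curve's maximum recall, the precision of the full
    ranking (last point) is returned.
    """
    idx = np.flatnonzero(curve.recall >= r)
    if idx.size == 0:
        return float(curve.precision[-1])
    return float(curve.precision[idx[0]])


def _combined_scores(
    llr_gbp: dict[str, float], llr_gba: dict[str, float], alpha: float
) -> dict[str, float]:
    return {g: alpha * llr_gbp[g] + (1 - alpha) * llr_gba[g] for g in llr_gbp}


def optimize_alpha(
    llr_gbp: dict[str, float],
    llr_gba: dict[str, float],
    labels: dict[str, int],
    grid: np.ndarray = ALPHA_GRID,
) -> float:
    """Grid-search the mixing weight maximizing average precision of the
    combined score over the labelled (training) genes; ties break to the
    smallest alpha. The per-term prior is constant and cannot change the
    ranking, so it is omitted here."""
    genes = [g for g in labels if g in llr_gbp and g in llr_gba]
    positives = {g for g in genes if labels[g] == 1}
    gbp = {g: llr_gbp[g] for g in genes}
    gba = {g: llr_gba[g] for g in genes}
    best_alpha, best_ap = 0.0, -1.0
    for alpha in grid:
        ap = pr_curve(_combined_scores(gbp, gba, float(alpha)), positives).average_precision
        if ap > best_ap + 1e-12:
            best_alpha, best_ap = float(alpha), ap
    return best_alpha


def optimize_alpha_category(
    term_data: list[tuple[dict[str, float], dict[str, float], dict[str, int]]],
    grid: np.ndarray = ALPHA_GRID,
) -> float:
    """One mixing weight for a whole category: maximize the mean across the
    category's terms of per-term average precision (used for [3,10] terms,
    where per-term optimization would overfit)."""
    prepared = []
    for llr_gbp, llr_gba, labels in term_data:
        genes = [g for g in labels if g in llr_gbp and g in llr_gba]
        prepared.append(
            (
                {g: llr_gbp[g] for g in genes},
                {g: llr_gba[g] for g in genes},
                {g for g in genes if labels[g] == 1},
            )
        )
    best_alpha, best_mean = 0.0, -1.0
    for alpha in grid:
        aps = [
            pr_curve(_combined_scores(gbp, gba, float(alpha)), pos).average_precision
            for gbp, gba, pos in prepared
        ]
        mean_ap = float(np.mean(aps))
        if mean_ap > best_mean + 1e-12:
            best_alpha, best_mean = float(alpha), mean_ap
    return best_alpha


def cumulative_precision_at(curve: PRCurve, r: float) -> float:
    """Best precision achievable at recall >= r (cumulative-max reading)."""
    mask = curve.recall >= r
    if not mask.any():
        return float(curve.precision[-1])
    return float(curve.precision[mask].max())


def aggregate_contours(
    curves: list[PRCurve],
    category: object = None,
    recall_grid: np.ndarray | None = None,
    deciles: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90),
    cumulative: bool = True,
) -> ContourSummary:
    """Aggregate many per-term PR curves into decile contours.

    At each recall point r, the q% contour is the precision met or exceeded
    by q% of terms — i.e. the (1 - q/100) quantile across terms of the
    per-term (cumulative) precision at r. Contours are therefore pointwise
    ordered: the 10% contour lies above the 90% one.
    """
    if recall_grid is None:
        recall_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    if not curves:
        raise ValueError("no curves to aggregate")
    reader = cumulative_precision_at if cumulative else precision_at_recall
    mat = np.array([[reader(c, r) for r in recall_grid] for c in curves])
    contours = {
        q: np.quantile(mat, 1.0 - q / 100.0, axis=0) for q in deciles
    }
    p20 = np.array([precision_at_recall(c, 0.20) for c in curves])
    return ContourSummary(
        category,
        recall_grid,
        contours,
        mat.mean(axis=0),
        np.median(mat, axis=0),
        float(p20.mean()),
        float(np.median(p20)),
    )


def prospective_survivors(
    term: str,
    scores: dict[str, float],
    old: AnnotationSet,
    new: AnnotationSet,
    start_date: date,
) -> tuple[list[str], set[str]]:
    """Gene list and positives for one term's prospective evaluation.

    Genes positive for the term before the start date are removed; the
    remainder is restricted to genes that gained at least one association
    anywhere in the ontology on/after the start date (those are the genes
    curators actually revisited). Positives are surviving genes associated
    to the term in the later annotation snapshot.
    """
    old_pos = old.genes_for(term)
    recurated = {
        r.gene for r in new.records if r.date is not None and r.date >= start_date
    }
    survivors = [g for g in scores if g not in old_pos and g in recurated]
    positives = set(survivors) & new.genes_for(term)
    return survivors, positives


def prospective_evaluate(
    scores: dict[str, dict[str, float]],
    old: AnnotationSet,
    new: AnnotationSet,
    start_date: date,
) -> dict[str, PRCurve]:
    """Per-term prospective PR curves for frozen prediction scores.

    *scores* maps term -> gene -> score (both annotation sets should be
    evidence-filtered and propagated). Terms with no surviving positive
    are skipped.
    """
    out: dict[str, PRCurve] = {}
    for term, gene_scores in scores.items():
        survivors, positives = prospective_survivors(
            term, gene_scores, old, new, start_date
        )
        if not positives:
            continue
        out[term] = pr_curve(
            {g: gene_scores[g] for g in survivors}, positives
        )
    return out
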