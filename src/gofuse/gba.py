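"""Guilt-by-association: functional-linkage networks and annotation transfer.

One FLN is trained per term category: a random forest scores every unordered
gene pair from pair-centric features, with training labels marking pairs of
training genes that share at least one qualifying term of the category.
Edge weights are out-of-bag vote fractions for training pairs and ordinary
predictions elsewhere.

To score a gene for a term, the "core set" C of genes annotated to the term
defines two edge-weight samples: the core clique (all pairs within C) and
the noncore-to-core pairs ((training \\ C) x C). Gaussian kernel densities
are estimated for both (with a uniform safeguard so neither vanishes), and
the candidate's score is the summed log-likelihood ratio of its edges to C
under core-to-core vs noncore-to-core densities. Terms with <= 10
annotated genes use densities pooled across all terms of their category,
because per-term samples are too small to estimate well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gofuse.density import AugmentedDensity, augmented_kde
from gofuse.forest import predict, train_forest
from gofuse.ontology import AnnotationSet, OntologyGraph, TermCategory
from gofuse.pair_features import PairFeatureTable, canonical_pair, Pair

logger = logging.getLogger(__name__)

#: terms with at most this many annotated genes use category-pooled densities
POOLED_MAX_CORE = 10


@dataclass
class FLN:
    """Symmetric weighted gene graph for one term category.

    ``weights`` maps every canonical pair to a weight in [0,1]: the OOB vote
    fraction for training pairs, the forest prediction elsewhere.
    """

    category: TermCategory | None
    weights: dict[Pair, float]
    oob_weights: dict[Pair, float]
    training_labels: dict[Pair, int]
    genes: set[str] = field(default_factory=set)

    def weight(self, g1: str, g2: str) -> float:
        return self.weights[canonical_pair(g1, g2)]

    def to_tsv(self, path: str) -> None:
        import gzip

        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            for (a, b), w in sorted(self.weights.items()):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str, category: TermCategory | None = None) -> "FLN":
        import gzip

        opener = gzip.open if path.endswith(".gz") else open
        weights: dict[Pair, float] = {}
        genes: set[str] = set()
        with opener(path, "rt") as fh:
            for line in fh:
                a, b, w = line.rstrip("\n").split("\t")
                weights[canonical_pair(a, b)] = float(w)
                genes.update((a, b))
        return cls(category, weights, {}, {}, genes)


@dataclass
class DensityPair:
    """Core-to-core and noncore-to-core edge-weight densities for a term."""

    core_pdf: AugmentedDensity
    noncore_pdf: AugmentedDensity

    @property
    def core_n(self) -> int:
        return self.core_pdf.n

    @property
    def noncore_n(self) -> int:
        return self.noncore_pdf.n


@dataclass
class TransferResult:
    term: str
    llr: dict[str, float]
    core: set[str]
    pooled: bool


def qualifying_terms(
    a: AnnotationSet,
    o: OntologyGraph,
    category: TermCategory,
    rule: str = "cumulative",
) -> list[str]:
    """Terms defining positive pairs for a category's FLN.

    The default ``cumulative`` rule keeps every term of the category's
    branch with an annotation count between 3 and the category's upper
    bound — e.g. the BP [31,100] network is trained on pairs sharing any BP
    term with at most 100 associations. ``strict`` restricts to the
    category's own bin.
    """
    lo = 3 if rule == "cumulative" else category.bin[0]
    hi = category.bin[1]
    out = []
    for t, gs in a.index.items():
        if o.branch.get(t) != category.branch:
            continue
        if lo <= len(gs) <= hi:
            out.append(t)
    return sorted(out)


def build_training_labels(
    a: AnnotationSet,
    o: OntologyGraph,
    category: TermCategory,
    training: set[str],
    rule: str = "cumulative",
) -> dict[Pair, int]:
    """Label every pair of training genes: 1 iff the genes share >= 1
    qualifying term of the category, else 0."""
    genes = sorted(training)
    labels = {
        canonical_pair(genes[i], genes[j]): 0
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    }
    for t in qualifying_terms(a, o, category, rule):
        members = sorted(a.genes_for(t) & training)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                labels[canonical_pair(members[i], members[j])] = 1
    return labels


def train_fln(
    p: PairFeatureTable,
    labels: dict[Pair, int],
    seed: int = 0,
    n_trees: int = 100,
    negative_subsample: float | None = None,
    category: TermCategory | None = None,
) -> FLN:
    """Fit the per-category edge classifier and weight every pair.

    Training pairs (keys of *labels*) receive out-of-bag weights; every
    other pair of the table's gene universe receives a predicted weight.
    ``negative_subsample`` trains the forest on all positives plus a seeded
    random fraction of the negatives (full pairwise training scales
    quadratically); pairs left out of the subsample are scored by
    prediction like non-training pairs.
    """
    train_pairs = [pr for pr in p.pairs if pr in labels]
    if len(train_pairs) != len(labels):
        missing = set(labels) - set(train_pairs)
        raise ValueError(f"{len(missing)} labelled pairs absent from table")
    y_full = np.array([labels[pr] for pr in train_pairs])
    rng = np.random.default_rng(seed)
    if negative_subsample is not None and 0 < negative_subsample < 1:
        neg_idx = np.flatnonzero(y_full == 0)
        pos_idx = np.flatnonzero(y_full == 1)
        keep_neg = rng.choice(
            neg_idx, size=max(1, int(round(negative_subsample * neg_idx.size))),
            replace=False,
        )
        fit_idx = np.sort(np.concatenate([pos_idx, keep_neg]))
    else:
        fit_idx = np.arange(len(train_pairs))
    fit_pairs = [train_pairs[i] for i in fit_idx]
    X_fit = p.rows(fit_pairs)
    y_fit = y_full[fit_idx]
    model = train_forest(
        X_fit, y_fit, n_trees=n_trees, seed=seed,
        feature_names=list(p.table.columns),
    )
    weights: dict[Pair, float] = {}
    oob: dict[Pair, float] = {}
    for pr, w in zip(fit_pairs, model.oob_score):
        weights[pr] = float(w)
        oob[pr] = float(w)
    rest = [pr for pr in p.pairs if pr not in weights]
    if rest:
        preds = predict(model, p.rows(rest))
        for pr, w in zip(rest, preds):
            weights[pr] = float(w)
    return FLN(category, weights, oob, dict(labels), set(p.genes))


def _clique_weights(fln: FLN, genes: list[str]) -> list[float]:
    return [
        fln.weight(genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]


def _cross_weights(fln: FLN, left: list[str], right: list[str]) -> list[float]:
    return [fln.weight(a, b) for a in left for b in right if a != b]


def estimate_densities(
    fln: FLN,
    C: set[str],
    training: set[str],
    density_mode: str = "mixture",
    rng: np.random.Generator | None = None,
) -> DensityPair:
    """Estimate core-to-core and noncore-to-core densities for a core set.

    The core sample is the C(|C|,2) clique of weights within C; the noncore
    sample crosses every noncore training gene with every core gene. Both
    are augmented (uniform safeguard) so no evaluation is zero.
    """
    core = sorted(C)
    if len(core) < 2:
        raise ValueError(
            f"core set of size {len(core)} cannot form a clique; "
            "use pooled densities for such terms"
        )
    noncore = sorted(training - C)
    core_w = _clique_weights(fln, core)
    noncore_w = _cross_weights(fln, noncore, core)
    if not noncore_w:
        raise ValueError("no noncore-to-core pairs available")
    return DensityPair(
        augmented_kde(core_w, mode=density_mode, rng=rng),
        augmented_kde(noncore_w, mode=density_mode, rng=rng),
    )


def llr_transfer(g: str, C: set[str], d: DensityPair, fln: FLN) -> float:
    """Summed log-likelihood ratio of g's edges to the core set having come
    from the core-to-core rather than the noncore-to-core distribution."""
    if g in C:
        raise ValueError(f"gene {g} is in the core set")
    w = np.array([fln.weight(g, c) for c in sorted(C)])
    if w.size == 0:
        return 0.0
    return float(np.sum(d.core_pdf.logpdf(w) - d.noncore_pdf.logpdf(w)))


def pooled_densities(
    fln: FLN,
    terms: list[str],
    a: AnnotationSet,
    training: set[str],
    density_mode: str = "mixture",
    rng: np.random.Generator | None = None,
    exclude_gene: str | None = None,
) -> DensityPair:
    """Category-pooled densities for small-core terms.

    Core-clique and noncore-to-core weight samples are pooled across all
    *terms* as multisets (a pair contributes once per core it belongs to).
    ``exclude_gene`` drops every edge incident to that gene and removes it
    from each core (leave-one-out re-estimation).
    """
    core_w: list[float] = []
    noncore_w: list[float] = []
    for t in terms:
        C = a.genes_for(t) & training
        if exclude_gene is not None:
            C = C - {exclude_gene}
        core = sorted(C)
        noncore = sorted(training - C - ({exclude_gene} if exclude_gene else set()))
        if len(core) >= 2:
            core_w.extend(_clique_weights(fln, core))
        if core:
            noncore_w.extend(_cross_weights(fln, noncore, core))
    if not core_w or not noncore_w:
        raise ValueError("pooled samples are empty for this category")
    return DensityPair(
        augmented_kde(core_w, mode=density_mode, rng=rng),
        augmented_kde(noncore_w, mode=density_mode, rng=rng),
    )


def transfer_term(
    t: str,
    fln: FLN,
    a: AnnotationSet,
    training: set[str],
    candidates: set[str],
    pooled_terms: list[str] | None = None,
    density_mode: str = "mixture",
    rng: np.random.Generator | None = None,
) -> TransferResult:
    """Score candidate (non-training) genes for term *t* by LLR transfer.

    Uses per-term densities when the core has more than ``POOLED_MAX_CORE``
    genes, otherwise densities pooled over *pooled_terms* (the term's
    category companions)."""
    C = a.genes_for(t) & training
    pooled = len(C) <= POOLED_MAX_CORE
    if pooled:
        if pooled_terms is None:
            pooled_terms = [t]
        d = pooled_densities(fln, pooled_terms, a, training, density_mode, rng)
    else:
        d = estimate_densities(fln, C, training, density_mode, rng)
    llr = {g: llr_transfer(g, C, d, fln) for g in sorted(candidates - C)}
    return TransferResult(t, llr, C, pooled)


def loo_gba_scores(
    t: str,
    fln: FLN,
    a: AnnotationSet,
    training: set[str],
    pooled_terms: list[str] | None = None,
    density_mode: str = "mixture",
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Leave-one-out LLRs for every training gene.

    Each training gene g is held out in turn: both densities are
    re-estimated from out-of-bag edge weights with every edge incident to g
    excluded (and g removed from the core), then g is scored against the
    reduced core. Terms whose core (after holdout) is below 2 genes — and
    all terms with core size <= ``POOLED_MAX_CORE`` — fall back to
    category-pooled densities with the same exclusion.
    """
    C = a.genes_for(t) & training
    use_pooled = len(C) <= POOLED_MAX_CORE
    out: dict[str, float] = {}
    for g in sorted(training):
        Cg = C - {g}
        if not Cg:
            out[g] = 0.0
            continue
        pooled_now = use_pooled or len(Cg) < 2
        if pooled_now:
            terms = pooled_terms if pooled_terms is not None else [t]
            d = pooled_densities(
                fln, terms, a, training, density_mode, rng, exclude_gene=g
            )
        else:
            core = sorted(Cg)
            noncore = sorted(training - C - {g})
            core_w = _clique_weights(fln, core)
            noncore_w = _cross_weights(fln, noncore, core)
            d = DensityPair(
                augmented_kde(core_w, mode=density_mode, rng=rng),
                augmented_kde(noncore_w, mode=density_mode, rng=rng),
            )
        out[g] = llr_transfer(g, Cg, d, fln)
    return out
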