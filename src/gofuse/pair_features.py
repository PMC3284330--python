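"""Pair-centric binary features for functional-linkage network training.

Every unordered gene pair is a classification object. Its features are:

* shared-annotation similarity per gene-centric source (sum of squared
  feature frequencies over features carried by both genes), discretized
  into nested top-10/20/30/40/50% quantile indicators;
* co-expression (minimum-jackknife-1 Pearson correlation per expression
  dataset), discretized into nested top-1/5/10% indicators;
* a protein-protein interaction indicator.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gofuse.gene_features import FeatureMatrix, SOURCES

logger = logging.getLogger(__name__)

SHARED_QUANTILES = (0.10, 0.20, 0.30, 0.40, 0.50)
COEXPR_QUANTILES = (0.01, 0.05, 0.10)

Pair = tuple[str, str]


def canonical_pair(g1: str, g2: str) -> Pair:
    """Canonical key for an unordered pair; self-pairs are invalid."""
    if g1 == g2:
        raise ValueError(f"self-pair ({g1},{g2}) is not a valid gene pair")
    return (g1, g2) if g1 < g2 else (g2, g1)


def logical_pair_count(n: int) -> int:
    """Number of unordered pairs over n genes, C(n,2)."""
    return math.comb(n, 2)


def predicted_pair_count(n: int, m: int) -> int:
    """Pairs needing predicted edge weights when m of n genes are training
    genes (training pairs get out-of-bag weights instead): C(n,2) - C(m,2)."""
    return math.comb(n, 2) - math.comb(m, 2)


def pair_similarity_score(
    g1: str,
    g2: str,
    m: FeatureMatrix,
    freqs: Mapping[str, float],
    source: str | None = None,
    mode: str = "sum_f2",
) -> float:
    """Shared-annotation similarity between two genes.

    The default score is ``sum_i f_i**2`` over features carried by BOTH
    genes, where ``f_i`` is the feature's frequency in the gene universe;
    this weights agreement on common features most heavily. The
    ``sum_inv_f2`` mode inverts the weighting (``sum 1/f_i**2``) so rare
    shared features dominate, for sensitivity analyses.
    """
    for g in (g1, g2):
        if not m.has_gene(g):
            raise KeyError(f"gene {g} absent from feature matrix")
    shared = m.gene_feature_set(g1) & m.gene_feature_set(g2)
    total = 0.0
    for j in shared:
        if source is not None and m.sources[j] != source:
            continue
        f = freqs[m.features[j]]
        total += f**2 if mode == "sum_f2" else 1.0 / f**2
    return total


def all_pair_similarity_scores(
    m: FeatureMatrix,
    freqs: Mapping[str, float],
    source: str,
    genes: Sequence[str] | None = None,
    mode: str = "sum_f2",
) -> dict[Pair, float]:
    """Similarity scores for every unordered pair, for one feature source.

    Vectorized as B W B^T where B is the source's binary submatrix and W a
    diagonal of squared (or inverse-squared) frequencies.
    """
    genes = list(genes) if genes is not None else list(m.genes)
    sub = m.subset_genes(genes)
    cols = [j for j, s in enumerate(sub.sources) if s == source]
    B = sub.values[:, cols].toarray().astype(float)
    f = np.array([freqs[sub.features[j]] for j in cols])
    w = f**2 if mode == "sum_f2" else 1.0 / f**2
    S = (B * w) @ B.T
    out: dict[Pair, float] = {}
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            out[canonical_pair(genes[a], genes[b])] = float(S[a, b])
    return out


def discretize_top_quantiles(
    scores: Mapping[Pair, float],
    quantiles: Sequence[float] = SHARED_QUANTILES,
    prefix: str = "shared",
) -> pd.DataFrame:
    """Nested top-quantile membership indicators for pair scores.

    The threshold for the top-q bin is the (1-q) quantile of the *nonzero*
    score distribution (shared-annotation scores are overwhelmingly zero and
    quantiles over all pairs would be degenerate). Ties at a boundary are
    included, so columns are deterministic and nested:
    top-10% membership implies top-20%, and so on.
    """
    pairs = list(scores)
    vals = np.array([scores[p] for p in pairs], dtype=float)
    nonzero = vals[vals > 0]
    out = {}
    for q in quantiles:
        name = f"{prefix}_top{int(round(q * 100))}"
        if nonzero.size == 0:
            out[name] = np.zeros(len(pairs), dtype=np.int8)
            continue
        thr = np.quantile(nonzero, 1.0 - q)
        out[name] = ((vals >= thr) & (vals > 0)).astype(np.int8)
    return pd.DataFrame(out, index=pd.Index(pairs, tupleize_cols=False))


def min_jackknife1_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum over samples i of Pearson r computed with sample i left out.

    Guards co-expression calls against correlation driven by a single
    sample. Requires length >= 4 (so each leave-one-out correlation uses
    >= 3 points). Returns NaN when any leave-one-out subvector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("min_jackknife1_pearson needs two vectors of length >= 4")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    # leave-one-out sufficient statistics, all i at once
    sx_i, sy_i = sx - x, sy - y
    sxx_i, syy_i, sxy_i = sxx - x * x, syy - y * y, sxy - x * y
    cov = sxy_i - sx_i * sy_i / m
    varx = sxx_i - sx_i**2 / m
    vary = syy_i - sy_i**2 / m
    tol = 1e-12
    if np.any(varx <= tol) or np.any(vary <= tol):
        return float("nan")
    r = cov / np.sqrt(varx * vary)
    return float(np.clip(r, -1.0, 1.0).min())


def expression_correlations(
    expr: pd.DataFrame, genes: Sequence[str] | None = None
) -> dict[Pair, float]:
    """Minimum-jackknife-1 Pearson correlation for every gene pair present
    in one expression matrix (genes x samples). Pairs with an undefined
    correlation are skipped with a warning."""
    if genes is None:
        genes = list(expr.index)
    else:
        genes = [g for g in genes if g in expr.index]
    X = expr.loc[genes].to_numpy(dtype=float)
    out: dict[Pair, float] = {}
    n_skipped = 0
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            r = min_jackknife1_pearson(X[a], X[b])
            if math.isnan(r):
                n_skipped += 1
                continue
            out[canonical_pair(genes[a], genes[b])] = r
    if n_skipped:
        logger.warning(
            "expression_correlations: skipped %d pairs with undefined "
            "leave-one-out correlation",
            n_skipped,
        )
    return out


def coexpression_bins(
    corr: Mapping[Pair, float],
    quantiles: Sequence[float] = COEXPR_QUANTILES,
    prefix: str = "coexpr",
) -> pd.DataFrame:
    """Nested top-quantile indicators for one dataset's pair correlations.

    Thresholds are quantiles of the defined correlations; pairs without a
    defined correlation simply get 0 (absence is not evidence)."""
    pairs = list(corr)
    vals = np.array([corr[p] for p in pairs], dtype=float)
    out = {}
    for q in quantiles:
        name = f"{prefix}_top{int(round(q * 100))}"
        if vals.size == 0:
            out[name] = np.zeros(0, dtype=np.int8)
        else:
            thr = np.quantile(vals, 1.0 - q)
            out[name] = (vals >= thr).astype(np.int8)
    return pd.DataFrame(out, index=pd.Index(pairs, tupleize_cols=False))


def ppi_column(edges: Iterable[tuple[str, str]], name: str = "ppi") -> pd.Series:
    """Binary interaction indicator keyed by canonical pair; self-pairs
    (homo-dimers) are removed, and (a,b)/(b,a) duplicates collapse."""
    pairs = set()
    for g1, g2 in edges:
        if g1 == g2:
            continue
        pairs.add(canonical_pair(g1, g2))
    idx = pd.Index(sorted(pairs), tupleize_cols=False)
    return pd.Series(np.ones(len(idx), dtype=np.int8), index=idx, name=name)


class PairFeatureTable:
    """Binary feature table over all unordered pairs of a gene universe.

    Stored densely as a pandas DataFrame indexed by canonical pair tuples
    (desk-scale universes); columns are int8 indicators.
    """

    def __init__(self, genes: Sequence[str], table: pd.DataFrame):
        self.genes = sorted(genes)
        self.table = table
        expected = logical_pair_count(len(self.genes))
        if len(table) != expected:
            raise ValueError(
                f"expected {expected} pair rows for {len(self.genes)} genes, "
                f"got {len(table)}"
            )

    @property
    def pairs(self) -> list[Pair]:
        return list(self.table.index)

    def rows(self, pairs: Sequence[Pair]) -> np.ndarray:
        return self.table.loc[pairs].to_numpy()


def build_pair_feature_table(
    genes: Sequence[str],
    m: FeatureMatrix,
    freqs: Mapping[str, float],
    expression: Sequence[pd.DataFrame] = (),
    ppi_edges: Iterable[tuple[str, str]] = (),
    similarity_mode: str = "sum_f2",
) -> PairFeatureTable:
    """Assemble the full pair-feature table for a gene universe.

    Five nested shared-annotation bins per gene-centric source, three nested
    co-expression bins per expression dataset, and one interaction column.
    """
    genes = sorted(genes)
    all_pairs = [
        canonical_pair(genes[a], genes[b])
        for a in range(len(genes))
        for b in range(a + 1, len(genes))
    ]
    idx = pd.Index(all_pairs, tupleize_cols=False)
    blocks: list[pd.DataFrame] = []
    present = [g for g in genes if m.has_gene(g)]
    for source in SOURCES:
        scores = all_pair_similarity_scores(
            m, freqs, source, genes=present, mode=similarity_mode
        )
        blocks.append(
            discretize_top_quantiles(scores, prefix=f"shared_{source}").reindex(
                idx, fill_value=0
            )
        )
    for k, expr in enumerate(expression):
        corr = expression_correlations(expr, genes=genes)
        blocks.append(
            coexpression_bins(corr, prefix=f"coexpr{k}").reindex(idx, fill_value=0)
        )
    ppi = ppi_column(ppi_edges).reindex(idx, fill_value=0)
    blocks.append(ppi.to_frame())
    table = pd.concat(blocks, axis=1).astype(np.int8)
    return PairFeatureTable(genes, table)
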