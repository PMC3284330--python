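"""Gene-centric binary feature matrix (the guilt-by-profiling feature set).

Features come from four sources: protein-domain signatures, disease
identifiers, top-level phenotype terms, and per-species phylogenetic-profile
presence calls. All are binary gene x feature indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from gofuse.ontology import OntologyGraph

logger = logging.getLogger(__name__)

SOURCES = ("domain", "disease", "phenotype", "phylo")


@dataclass
class FeatureMatrix:
    """Sparse binary gene x feature matrix with per-feature source tags."""

    genes: list[str]
    features: list[str]
    sources: list[str]
    values: sparse.csr_matrix  # binary

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.features)):
            raise ValueError("matrix shape does not match gene/feature lists")
        if len(self.sources) != len(self.features):
            raise ValueError("one source tag per feature required")
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}
        self._feat_pos = {f: j for j, f in enumerate(self.features)}

    def gene_row(self, gene: str) -> np.ndarray:
        return np.asarray(self.values[self._gene_pos[gene]].todense()).ravel()

    def gene_feature_set(self, gene: str) -> set[int]:
        row = self.values[self._gene_pos[gene]]
        return set(row.indices)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_pos

    def subset_genes(self, genes: list[str]) -> "FeatureMatrix":
        rows = [self._gene_pos[g] for g in genes]
        return FeatureMatrix(
            list(genes), list(self.features), list(self.sources), self.values[rows]
        )

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.genes, columns=self.features
        )

    def to_tsv(self, path: str) -> None:
        """Serialize as sparse triplets ``gene<TAB>feature<TAB>source``."""
        coo = self.values.tocoo()
        with open(path, "w") as fh:
            for i, j in zip(coo.row, coo.col):
                src = self.sources[j]
                feat = self.features[j]
                # column names are "source:id"; write the bare id back out
                if feat.startswith(src + ":"):
                    feat = feat[len(src) + 1:]
                fh.write(f"{self.genes[i]}\t{feat}\t{src}\n")


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a ``gene<TAB>feature<TAB>source`` TSV into a tidy frame."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["gene", "feature", "source"], dtype=str
    )


def build_feature_matrix(
    tables: list[pd.DataFrame], keep_empty_genes: bool = False
) -> FeatureMatrix:
    """Assemble the union of per-source feature tables into one binary matrix.

    Each table is a tidy frame with columns (gene, feature, source).
    Duplicate (gene, feature) pairs collapse to a single 1. Genes with no
    feature in any source are dropped with a warning unless
    *keep_empty_genes* (they cannot be scored by profiling).
    """
    tidy = pd.concat(tables, ignore_index=True)
    tidy = tidy.drop_duplicates(subset=["gene", "feature"])
    # feature identity is (source, feature_id) so identically-named ids from
    # different sources stay distinct columns
    tidy["col"] = tidy["source"] + ":" + tidy["feature"]
    genes = sorted(tidy["gene"].unique())
    cols = (
        tidy[["col", "source"]]
        .drop_duplicates("col")
        .sort_values("col")
        .reset_index(drop=True)
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    col_pos = {c: j for j, c in enumerate(cols["col"])}
    i = tidy["gene"].map(gene_pos).to_numpy()
    j = tidy["col"].map(col_pos).to_numpy()
    mat = sparse.csr_matrix(
        (np.ones(len(tidy), dtype=np.int8), (i, j)),
        shape=(len(genes), len(cols)),
    )
    mat.data[:] = 1  # collapse any accidental duplicates
    if not keep_empty_genes:
        nz = np.asarray(mat.sum(axis=1)).ravel() > 0
        if not nz.all():
            logger.warning(
                "build_feature_matrix: dropping %d genes with zero features",
                int((~nz).sum()),
            )
            genes = [g for g, keep in zip(genes, nz) if keep]
            mat = mat[nz]
    return FeatureMatrix(genes, list(cols["col"]), list(cols["source"]), mat)


def feature_frequencies(m: FeatureMatrix) -> dict[str, float]:
    """Fraction of genes carrying each feature (column mean of the binary
    matrix, over the full loaded gene universe)."""
    means = np.asarray(m.values.mean(axis=0)).ravel()
    return dict(zip(m.features, means.astype(float)))


def restrict_phenotype_top_level(
    table: pd.DataFrame, ontology: OntologyGraph
) -> pd.DataFrame:
    """Keep only phenotype features sitting directly under the ontology root.

    Deeper phenotype terms map nearly one-to-one onto specific process terms
    and would leak the label; top-level terms carry broad, legitimate signal.
    """
    roots = ontology.roots()
    top = {
        t
        for t in ontology.terms
        if ontology.parents[t] and ontology.parents[t] <= roots
    }
    return table[table["feature"].isin(top)].reset_index(drop=True)
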