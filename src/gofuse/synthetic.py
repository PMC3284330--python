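"""Self-contained synthetic fixtures with planted functional signal.

The generator emulates the statistical structure the prediction framework
assumes, at desk scale: genes belong to functional modules, each module is
a GO-style leaf term; module members preferentially carry module-specific
gene-centric features (profiling signal), co-express through a shared
latent factor (association signal), and interact more often than chance.
Annotations are revealed in two epochs around a start date so the
prospective protocol can be exercised, and a truth table records every
planted membership for scoring.

All outputs are plain text in the formats the toolkit reads (OBO, GAF,
tidy TSVs), generated deterministically from one master seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from gofuse.gene_features import SOURCES
from gofuse.ontology import AnnotationSet, OntologyGraph, parse_gaf, parse_obo

_ASPECT = {"BP": "P", "CC": "C", "MF": "F"}


@dataclass
class SimConfig:
    """Knobs of the planted-signal generator.

    ``rho_f`` is the probability a module member carries one of its module's
    dedicated features (vs ``background_f`` for everyone); ``rho_x`` is the
    shared-latent-factor variance fraction for module members' expression;
    ``interaction_precision`` is the fraction of interaction edges drawn
    within modules; ``epoch_fraction`` of each module's memberships is
    revealed before the start date, the rest after (prospective truth).
    """

    n_genes: int = 120
    module_sizes: dict[str, list[int]] = field(
        default_factory=lambda: {"BP": [4, 8, 15, 35], "CC": [5, 12], "MF": [4, 18]}
    )
    n_features: dict[str, int] = field(
        default_factory=lambda: {"domain": 40, "disease": 20, "phenotype": 8, "phylo": 12}
    )
    features_per_module: int = 3
    rho_f: float = 0.8
    background_f: float = 0.05
    n_samples: int = 30
    n_expression_datasets: int = 1
    rho_x: float = 0.6
    n_interactions: int = 60
    interaction_precision: float = 0.8
    epoch_fraction: float = 0.7
    n_iea_noise: int = 25
    start_date: date = date(2008, 7, 19)
    seed: int = 0


@dataclass
class SimBundle:
    """In-memory fixture bundle plus the raw file texts it round-trips from."""

    config: SimConfig
    genes: list[str]
    ontology: OntologyGraph
    obo_text: str
    gaf_old_text: str
    gaf_new_text: str
    ann_old: AnnotationSet
    ann_new: AnnotationSet
    feature_tables: list[pd.DataFrame]
    expression: list[pd.DataFrame]
    ppi_edges: list[tuple[str, str]]
    modules: dict[str, set[str]]  # leaf term -> true member genes
    truth: pd.DataFrame  # columns gene, term

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "ontology.obo"), "w") as fh:
            fh.write(self.obo_text)
        with open(os.path.join(outdir, "annotations_old.gaf"), "w") as fh:
            fh.write(self.gaf_old_text)
        with open(os.path.join(outdir, "annotations_new.gaf"), "w") as fh:
            fh.write(self.gaf_new_text)
        pd.concat(self.feature_tables).to_csv(
            os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
        )
        for k, expr in enumerate(self.expression):
            expr.to_csv(os.path.join(outdir, f"expression_{k}.tsv"), sep="\t")
        with open(os.path.join(outdir, "interactions.tsv"), "w") as fh:
            for a, b in self.ppi_edges:
                fh.write(f"{a}\t{b}\n")
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _term_id(k: int) -> str:
    return f"GO:{k:07d}"


def _obo_stanza(term: str, name: str, namespace: str, is_a: list[str],
                part_of: list[str] = ()) -> str:
    lines = [f"[Term]", f"id: {term}", f"name: {name}", f"namespace: {namespace}"]
    lines += [f"is_a: {p} ! parent" for p in is_a]
    lines += [f"relationship: part_of {p} ! parent" for p in part_of]
    return "\n".join(lines) + "\n\n"


_GAF_HEADER = "!gaf-version: 2.0\n"


def _gaf_line(gene: str, term: str, evidence: str, branch: str, when: date) -> str:
    cols = [
        "SIM", gene, gene, "", term, "SIM_REF:0000001", evidence, "",
        _ASPECT[branch], "", "", "gene", "taxon:9606", when.strftime("%Y%m%d"),
        "SIM", "", "",
    ]
    return "\t".join(cols) + "\n"


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate a full fixture bundle from one master seed.

    Substreams (ontology layout, memberships, features, expression,
    interactions, dates) are split off the master seed so each stage is
    reproducible in isolation.
    """
    root = np.random.default_rng(cfg.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("members", "features", "expression", "ppi", "dates", "noise"),
            root.integers(0, 2**31 - 1, size=6),
        )
    }
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- ontology: per branch a root, an intermediate, and one leaf per module
    next_id = 1
    obo = io.StringIO()
    obo.write("format-version: 1.2\nontology: simulated\n\n")
    ns_name = {"BP": "biological_process", "CC": "cellular_component",
               "MF": "molecular_function"}
    leaf_terms: dict[str, str] = {}  # leaf id -> branch
    module_leafs: dict[str, list[str]] = {}
    for branch, sizes in cfg.module_sizes.items():
        root_t, mid_t = _term_id(next_id), _term_id(next_id + 1)
        next_id += 2
        obo.write(_obo_stanza(root_t, f"{branch} root", ns_name[branch], []))
        # one intermediate exercises the part_of relation
        obo.write(_obo_stanza(mid_t, f"{branch} mid", ns_name[branch], [],
                              part_of=[root_t]))
        module_leafs[branch] = []
        for _ in sizes:
            leaf = _term_id(next_id)
            next_id += 1
            obo.write(_obo_stanza(leaf, f"{branch} module {leaf}", ns_name[branch],
                                  [mid_t]))
            leaf_terms[leaf] = branch
            module_leafs[branch].append(leaf)
    obo_text = obo.getvalue()
    ontology = parse_obo(io.StringIO(obo_text))

    # --- module membership (the planted truth)
    rng = streams["members"]
    modules: dict[str, set[str]] = {}
    for branch, sizes in cfg.module_sizes.items():
        for leaf, size in zip(module_leafs[branch], sizes):
            modules[leaf] = set(rng.choice(genes, size=size, replace=False))
    truth = pd.DataFrame(
        [(g, t) for t, ms in modules.items() for g in sorted(ms)],
        columns=["gene", "term"],
    )

    # --- gene-centric features: dedicated module features + background
    rng = streams["features"]
    feat_rows: list[tuple[str, str, str]] = []
    all_feats: dict[str, list[str]] = {
        s: [f"{s.upper()}{j:03d}" for j in range(n)]
        for s, n in cfg.n_features.items()
    }
    source_cycle = [s for s in SOURCES if cfg.n_features.get(s, 0) > 0]
    module_feats: dict[str, list[tuple[str, str]]] = {}
    si = 0
    for leaf in modules:
        picks = []
        for _ in range(cfg.features_per_module):
            s = source_cycle[si % len(source_cycle)]
            si += 1
            picks.append((s, str(rng.choice(all_feats[s]))))
        module_feats[leaf] = picks
    carried: set[tuple[str, str, str]] = set()
    for leaf, members in modules.items():
        for g in members:
            for s, f in module_feats[leaf]:
                if rng.random() < cfg.rho_f:
                    carried.add((g, f, s))
    for s, feats in all_feats.items():
        hit = rng.random((cfg.n_genes, len(feats))) < cfg.background_f
        for i, g in enumerate(genes):
            for j in np.flatnonzero(hit[i]):
                carried.add((g, feats[j], s))
    # every gene appears in >= 1 species of its phylogenetic profile
    anchor = all_feats.get("phylo") or all_feats[source_cycle[0]]
    for g in genes:
        carried.add((g, str(rng.choice(anchor)), "phylo" if "phylo" in all_feats
                     else source_cycle[0]))
    feat_rows = sorted(carried)
    tidy = pd.DataFrame(feat_rows, columns=["gene", "feature", "source"])
    feature_tables = [
        tidy[tidy["source"] == s].reset_index(drop=True)
        for s in sorted(tidy["source"].unique())
    ]

    # --- expression: module latent factor, loading sqrt(rho_x)
    rng = streams["expression"]
    expression = []
    for _ in range(cfg.n_expression_datasets):
        X = rng.normal(size=(cfg.n_genes, cfg.n_samples))
        gene_pos = {g: i for i, g in enumerate(genes)}
        for leaf, members in modules.items():
            z = rng.normal(size=cfg.n_samples)
            for g in members:
                i = gene_pos[g]
                X[i] = np.sqrt(cfg.rho_x) * z + np.sqrt(1 - cfg.rho_x) * X[i]
        expression.append(
            pd.DataFrame(X, index=genes,
                         columns=[f"s{j:02d}" for j in range(cfg.n_samples)])
        )

    # --- interactions: mostly within-module edges, remainder random
    rng = streams["ppi"]
    edges: set[tuple[str, str]] = set()
    big_modules = [sorted(ms) for ms in modules.values() if len(ms) >= 2]
    attempts = 0
    while len(edges) < cfg.n_interactions and attempts < 50 * cfg.n_interactions:
        attempts += 1
        if big_modules and rng.random() < cfg.interaction_precision:
            ms = big_modules[rng.integers(len(big_modules))]
            a, b = rng.choice(ms, size=2, replace=False)
        else:
            a, b = rng.choice(genes, size=2, replace=False)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    ppi_edges = sorted(edges)

    # --- two-epoch annotations around the start date
    rng = streams["dates"]
    old_lines, new_only_lines = [], []
    for leaf, members in sorted(modules.items()):
        members = sorted(members)
        n_old = max(2, int(round(cfg.epoch_fraction * len(members))))
        revealed = list(rng.permutation(members))
        early, late = revealed[:n_old], revealed[n_old:]
        branch = leaf_terms[leaf]
        for g in early:
            when = cfg.start_date - timedelta(days=int(rng.integers(30, 400)))
            old_lines.append(_gaf_line(g, leaf, "IDA", branch, when))
        for g in late:
            when = cfg.start_date + timedelta(days=int(rng.integers(1, 300)))
            new_only_lines.append(_gaf_line(g, leaf, "IDA", branch, when))
    # IEA noise records (present in both epochs; filtered out downstream)
    rng = streams["noise"]
    leafs = sorted(leaf_terms)
    iea_lines = []
    for _ in range(cfg.n_iea_noise):
        g = str(rng.choice(genes))
        t = str(rng.choice(leafs))
        when = cfg.start_date - timedelta(days=int(rng.integers(30, 400)))
        iea_lines.append(_gaf_line(g, t, "IEA", leaf_terms[t], when))
    gaf_old_text = _GAF_HEADER + "".join(sorted(old_lines + iea_lines))
    gaf_new_text = _GAF_HEADER + "".join(
        sorted(old_lines + new_only_lines + iea_lines)
    )
    ann_old = parse_gaf(io.StringIO(gaf_old_text))
    ann_new = parse_gaf(io.StringIO(gaf_new_text))

    return SimBundle(
        cfg, genes, ontology, obo_text, gaf_old_text, gaf_new_text,
        ann_old, ann_new, feature_tables, expression, ppi_edges, modules, truth,
    )


def scaled_config(n_genes: int, seed: int = 0) -> SimConfig:
    """Default module structure scaled proportionally to a smaller gene
    universe (module sizes keep their ratios, floored at 3 members)."""
    base = SimConfig()
    if n_genes >= base.n_genes:
        return SimConfig(n_genes=n_genes, seed=seed)
    factor = n_genes / base.n_genes
    sizes = {
        branch: [min(max(3, round(s * factor)), n_genes // 2) for s in ss]
        for branch, ss in base.module_sizes.items()
    }
    return SimConfig(n_genes=n_genes, module_sizes=sizes, seed=seed)


def make_worked_fixture() -> SimBundle:
    """Tiny fixed bundle (10 genes, 3 planted modules) for docs and
    hand-verifiable oracle tests; byte-identical on every call."""
    cfg = SimConfig(
        n_genes=10,
        module_sizes={"BP": [3, 4], "MF": [3]},
        n_features={"domain": 6, "disease": 4, "phenotype": 0, "phylo": 4},
        features_per_module=2,
        rho_f=1.0,
        background_f=0.08,
        n_samples=12,
        rho_x=0.7,
        n_interactions=8,
        epoch_fraction=0.7,
        n_iea_noise=4,
        seed=7,
    )
    return simulate(cfg)
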