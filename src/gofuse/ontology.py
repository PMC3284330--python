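"""Ontology and annotation handling.

Parses OBO-format term graphs and GAF-format gene/term associations,
filters associations by evidence code (IEA removal being the canonical
use), up-propagates annotations through ``is_a``/``part_of`` edges,
selects terms by annotation breadth, and stratifies terms into the
twelve branch x breadth evaluation categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, NamedTuple

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

BRANCHES = ("BP", "CC", "MF")

_NAMESPACE_TO_BRANCH = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

#: annotation-breadth bins (inclusive) crossing BP/CC/MF into 12 categories
CATEGORY_BINS: tuple[tuple[int, int], ...] = ((3, 10), (11, 30), (31, 100), (101, 300))


@dataclass(frozen=True)
class TermCategory:
    """One of the 12 evaluation strata: a GO branch crossed with a breadth bin."""

    branch: str
    bin: tuple[int, int]

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.bin not in CATEGORY_BINS:
            raise ValueError(f"unknown breadth bin {self.bin!r}")

    @property
    def label(self) -> str:
        return f"{self.branch}[{self.bin[0]},{self.bin[1]}]"


def all_categories() -> list[TermCategory]:
    return [TermCategory(b, bn) for b in BRANCHES for bn in CATEGORY_BINS]


class OntologyGraph:
    """Directed acyclic term graph with BP/CC/MF branch labels.

    Edges point child -> parent and include both ``is_a`` and ``part_of``
    relations, which are treated identically for propagation.
    """

    def __init__(
        self,
        parents: dict[str, set[str]],
        branch: dict[str, str],
        names: dict[str, str] | None = None,
    ):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self.branch = dict(branch)
        self.names = dict(names or {})
        self.terms: set[str] = set(self.parents)
        for t in self.terms:
            for p in self.parents[t]:
                if p not in self.terms:
                    raise ValueError(f"parent {p} of {t} is not a loaded term")
        g = nx.DiGraph((t, p) for t, ps in self.parents.items() for p in ps)
        g.add_nodes_from(self.terms)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of *term* (transitive is_a/part_of closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        res = frozenset(out)
        self._ancestor_cache[term] = res
        return res

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents[t]}

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def parse_obo(source) -> OntologyGraph:
    """Parse an OBO 1.2 document (path, URL or file-like) into an OntologyGraph.

    Obsolete terms are excluded; ``is_a`` and ``part_of`` edges are retained
    and treated alike. A cyclic graph is a hard failure.
    """
    g = obonet.read_obo(source, ignore_obsolete=True)
    parents: dict[str, set[str]] = {}
    branch: dict[str, str] = {}
    names: dict[str, str] = {}
    for term, data in g.nodes(data=True):
        parents.setdefault(term, set())
        ns = data.get("namespace")
        if ns in _NAMESPACE_TO_BRANCH:
            branch[term] = _NAMESPACE_TO_BRANCH[ns]
        if "name" in data:
            names[term] = data["name"]
    for child, parent, rel in g.edges(keys=True):
        if rel in ("is_a", "part_of") and parent in parents:
            parents[child].add(parent)
    return OntologyGraph(parents, branch, names)


class AnnotationRecord(NamedTuple):
    gene: str
    term: str
    evidence: str
    date: date | None


class AnnotationSet:
    """Dated, evidence-coded gene -> term associations with a term index."""

    def __init__(self, records: Iterable[AnnotationRecord | tuple]):
        self.records: list[AnnotationRecord] = [
            r if isinstance(r, AnnotationRecord) else AnnotationRecord(*r)
            for r in records
        ]
        self._index: dict[str, set[str]] | None = None

    @property
    def index(self) -> dict[str, set[str]]:
        """Map term -> set of annotated genes (built lazily, kept consistent)."""
        if self._index is None:
            idx: dict[str, set[str]] = {}
            for r in self.records:
                idx.setdefault(r.term, set()).add(r.gene)
            self._index = idx
        return self._index

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.records}

    @property
    def terms(self) -> set[str]:
        return {r.term for r in self.records}

    def genes_for(self, term: str) -> set[str]:
        return self.index.get(term, set())

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return set(self.records) == set(other.records)


def _parse_gaf_date(raw: str) -> date | None:
    try:
        return datetime.strptime(raw.strip(), "%Y%m%d").date()
    except (ValueError, AttributeError):
        return None


def parse_gaf(source) -> AnnotationSet:
    """Read a GAF 2.x association file.

    Columns used: DB Object ID (2), GO ID (5), Evidence code (7),
    Date (14, YYYYMMDD). ``NOT``-qualified rows are dropped. Records with
    unparseable dates are kept with ``date=None`` (they are excluded from
    prospective evaluation only).
    """
    close = False
    if isinstance(source, str):
        fh = open(source)
        close = True
    else:
        fh = source
    records = []
    try:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                continue
            qualifier = cols[3] if len(cols) > 3 else ""
            if "NOT" in qualifier.split("|"):
                continue
            gene, term, evidence = cols[1], cols[4], cols[6]
            when = _parse_gaf_date(cols[13]) if len(cols) > 13 else None
            records.append(AnnotationRecord(gene, term, evidence, when))
    finally:
        if close:
            fh.close()
    return AnnotationSet(records)


def filter_evidence(a: AnnotationSet, excluded: set[str]) -> AnnotationSet:
    """Drop every record whose evidence code is in *excluded* (e.g. {"IEA"})."""
    return AnnotationSet(r for r in a.records if r.evidence not in excluded)


def propagate(a: AnnotationSet, o: OntologyGraph) -> AnnotationSet:
    """Up-propagate annotations: a gene annotated to t is annotated to every
    ancestor of t.

    Idempotent. Records whose term is absent from the ontology are dropped
    with a logged warning. For a (gene, term) pair reachable several ways the
    earliest date and its evidence code are kept, so propagation is
    set-semantic on gene/term pairs.
    """
    best: dict[tuple[str, str], AnnotationRecord] = {}

    def _keep(rec: AnnotationRecord) -> None:
        key = (rec.gene, rec.term)
        old = best.get(key)
        if old is None:
            best[key] = rec
        elif rec.date is not None and (old.date is None or rec.date < old.date):
            best[key] = rec

    n_dropped = 0
    for r in a.records:
        if r.term not in o:
            n_dropped += 1
            continue
        _keep(r)
        for anc in o.ancestors(r.term):
            _keep(AnnotationRecord(r.gene, anc, r.evidence, r.date))
    if n_dropped:
        logger.warning("propagate: dropped %d records with unknown terms", n_dropped)
    return AnnotationSet(best.values())


def select_terms(a: AnnotationSet, min_n: int = 3, max_n: int = 300) -> list[str]:
    """Terms with between *min_n* and *max_n* distinct annotated genes
    (inclusive); *a* should already be evidence-filtered and propagated."""
    return sorted(t for t, gs in a.index.items() if min_n <= len(gs) <= max_n)


def categorize_term(t: str, a: AnnotationSet, o: OntologyGraph) -> TermCategory:
    """Place a selected term into its branch x breadth evaluation category."""
    n = len(a.genes_for(t))
    if t not in o.branch:
        raise KeyError(f"term {t} has no branch label")
    for lo, hi in CATEGORY_BINS:
        if lo <= n <= hi:
            return TermCategory(o.branch[t], (lo, hi))
    raise ValueError(f"term {t} has {n} annotations, outside [3,300]")


def split_training_undetermined(
    a: AnnotationSet, all_genes: set[str], selected: Iterable[str] | None = None
) -> tuple[set[str], set[str]]:
    """Partition *all_genes* into (training, undetermined).

    Training genes carry >=1 association to a selected term; the rest are
    undetermined. If *selected* is None every annotated term counts.
    """
    if selected is None:
        annotated = a.genes & all_genes
    else:
        sel = set(selected)
        annotated = {
            g for t in sel for g in a.genes_for(t) if g in all_genes
        }
    return annotated, all_genes - annotated
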