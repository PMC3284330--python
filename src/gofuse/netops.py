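"""FLN thresholding and disease seed-set expansion.

A functional-linkage network is complete, so exploring it requires keeping
only its strongest edges. Seed expansion retains the top fraction of edges
by weight, recruits the 1-neighborhood of a seed gene set through those
edges, and returns the induced subgraph — including edges between recruited
non-seed genes, which is how bridging candidates between seed components
surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from gofuse.gba import FLN
from gofuse.pair_features import Pair, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class SeedExpansion:
    seeds: set[str]
    retained_edges: dict[Pair, float]
    recruited: set[str]
    subgraph: nx.Graph


def threshold_top_fraction(fln: FLN, q: float) -> dict[Pair, float]:
    """Keep the ceil(q * |edges|) highest-weight edges; ties at the boundary
    weight are all kept (so the result can exceed the count)."""
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    items = sorted(fln.weights.items(), key=lambda kv: -kv[1])
    k = min(max(1, math.ceil(len(items) * q)), len(items))
    cutoff = items[k - 1][1]
    return {pair: w for pair, w in items if w >= cutoff}


def expand_seeds(
    edges: dict[Pair, float],
    seeds: set[str],
    depth: int = 1,
    overlay: dict[Pair, float] | None = None,
) -> SeedExpansion:
    """Expand a seed gene set through retained FLN edges.

    Recruits every gene within *depth* retained-edge hops of a seed
    (default 1-nearest-neighbor) and induces the subgraph on
    seeds + recruited genes — so edges among recruited genes appear too.
    Seeds absent from the edge universe are kept as isolated nodes with a
    warning. An *overlay* edge map (e.g. known physical interactions) is
    attached as an annotation layer with ``source='overlay'``.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w, source="fln")
    universe = set(g.nodes)
    missing = seeds - universe
    if missing:
        logger.warning("expand_seeds: %d seeds absent from edge universe", len(missing))
    frontier = seeds & universe
    recruited: set[str] = set()
    for _ in range(depth):
        nxt = {n for f in frontier for n in g.neighbors(f)}
        recruited |= nxt - seeds
        frontier = nxt
    nodes = seeds | recruited
    sub = nx.Graph()
    sub.add_nodes_from(
        (n, {"is_seed": n in seeds}) for n in nodes
    )
    for a, b, data in g.subgraph(nodes & universe).edges(data=True):
        sub.add_edge(a, b, **data)
    if overlay:
        for (a, b), w in overlay.items():
            if a in nodes and b in nodes and not sub.has_edge(a, b):
                sub.add_edge(a, b, weight=w, source="overlay")
    retained = {
        canonical_pair(a, b): data["weight"]
        for a, b, data in sub.edges(data=True)
        if data.get("source") == "fln"
    }
    return SeedExpansion(set(seeds), retained, recruited, sub)


def export_subgraph(exp: SeedExpansion, node_path: str, edge_path: str) -> None:
    """Write node and edge TSVs for a seed expansion."""
    with open(node_path, "w") as fh:
        fh.write("gene\tis_seed\n")
        for n in sorted(exp.subgraph.nodes):
            fh.write(f"{n}\t{int(exp.subgraph.nodes[n].get('is_seed', False))}\n")
    with open(edge_path, "w") as fh:
        fh.write("gene1\tgene2\tweight\tsource\n")
        for a, b, data in sorted(exp.subgraph.edges(data=True)):
            g1, g2 = canonical_pair(a, b)
            fh.write(f"{g1}\t{g2}\t{data['weight']:.6g}\t{data.get('source','fln')}\n")
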