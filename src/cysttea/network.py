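"""Tissue-sharing network built from an enrichment run.

Nodes are tissues whose characteristic protein set overlaps the query;
an edge connects two tissues that share at least one highly expressed
query protein, weighted by the number of shared proteins. Node size is
carried as -log10 of the adjusted enrichment p-value, so more enriched
tissues render larger. Export is GraphML plus a flat edge-list TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import ConsistencyError, UsageError
from .enrichment import EnrichmentRecord, QuerySet
from .reference_library import ReferenceLibrary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueNetwork:
    """Undirected tissue graph; wraps a :class:`networkx.Graph`.

    Node attributes: ``p_adj`` and ``size_attr`` (= -log10 p_adj).
    Edge attributes: ``weight`` (shared query-protein count) and
    ``shared_proteins`` (semicolon-joined, sorted).
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def build_network(
    records: list[EnrichmentRecord],
    query: QuerySet,
    library: ReferenceLibrary | None = None,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> TissueNetwork:
    """Assemble the tissue-sharing graph from one enrichment run.

    Nodes are tissues with overlap k >= 1 (all displayed, significant or
    not, unless `significant_only` restricts to p_adj < `alpha`). Edge
    (a, b) exists iff the two tissues share >= 1 query protein; its weight
    is the size of that shared set. Shared proteins are computed within
    the query — the overlap sets of the records — matching the "share
    highly expressed proteins" reading.
    """
    if not records:
        raise UsageError("no enrichment records to build a network from")
    for rec in records:
        if not rec.overlap_proteins <= query.proteins:
            raise ConsistencyError(
                f"record for tissue {rec.tissue!r} holds overlap proteins "
                "outside the query; records and query must come from the "
                "same run"
            )
        if library is not None and rec.tissue not in library.tissues:
            raise ConsistencyError(
                f"record tissue {rec.tissue!r} absent from the library"
            )

    kept = [r for r in records if r.overlap_k >= 1]
    if significant_only:
        kept = [r for r in kept if r.p_adj < alpha]

    graph = nx.Graph()
    for rec in sorted(kept, key=lambda r: r.tissue):
        graph.add_node(
            rec.tissue,
            p_adj=float(rec.p_adj),
            size_attr=float(-math.log10(rec.p_adj)),
        )
    for i, a in enumerate(sorted(kept, key=lambda r: r.tissue)):
        for b in sorted(kept, key=lambda r: r.tissue)[i + 1:]:
            shared = a.overlap_proteins & b.overlap_proteins
            if shared:
                graph.add_edge(
                    a.tissue,
                    b.tissue,
                    weight=len(shared),
                    shared_proteins=";".join(sorted(shared)),
                )
    return TissueNetwork(graph)


def export_network(network: TissueNetwork, path: str | Path) -> tuple[Path, Path]:
    """Write GraphML plus an edge-list TSV next to it.

    `path` is the GraphML file; the edge list goes to the same stem with
    ``_edges.tsv``. Elements are emitted in sorted order so the files are
    byte-stable across runs.
    """
    path = Path(path)
    ordered = nx.Graph()
    for node in sorted(network.graph.nodes):
        ordered.add_node(node, **network.graph.nodes[node])
    for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
        ordered.add_edge(a, b, **network.graph.edges[a, b])
    nx.write_graphml(ordered, path)

    edge_path = path.with_name(path.stem + "_edges.tsv")
    with open(edge_path, "w") as fh:
        fh.write("tissue_a\ttissue_b\tweight\tshared_proteins\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            attrs = network.graph.edges[a, b]
            fh.write(f"{a}\t{b}\t{attrs['weight']}\t{attrs['shared_proteins']}\n")
    return path, edge_path


def import_network(path: str | Path) -> TissueNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    graph = nx.read_graphml(Path(path))
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        out.add_node(
            str(node),
            p_adj=float(attrs["p_adj"]),
            size_attr=float(attrs["size_attr"]),
        )
    for a, b, attrs in graph.edges(data=True):
        out.add_edge(
            str(a),
            str(b),
            weight=int(attrs["weight"]),
            shared_proteins=str(attrs["shared_proteins"]),
        )
    return TissueNetwork(out)
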