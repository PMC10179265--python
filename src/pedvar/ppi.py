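"""Bounded-length path search over a gene-interaction graph.

Connects candidate genes to a known target gene set through simple paths
of at most ``max_edges`` unweighted edges; evidence labels ride along as
annotations only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx

from .types import InteractionGraph

__all__ = ["GenePath", "find_paths", "annotate_candidates"]


@dataclass(frozen=True)
class GenePath:
    nodes: Tuple[str, ...]
    is_self: bool = False  # source gene is itself a target (length-0 path)

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    def __str__(self) -> str:
        return "->".join(self.nodes)


def find_paths(
    graph: InteractionGraph,
    source_genes: Sequence[str],
    target_genes: Iterable[str],
    max_edges: int = 2,
) -> Dict[str, List[GenePath]]:
    """All simple paths of <= ``max_edges`` edges from each source to any
    target, deduplicated and sorted by (length, lexicographic order).

    A source that is itself a target is reported as a flagged length-0
    path. Sources or targets absent from the graph simply yield nothing.
    """
    if max_edges < 1:
        raise ValueError(f"max_edges must be >= 1: {max_edges}")
    g = graph.to_networkx()
    targets = set(target_genes)
    out: Dict[str, List[GenePath]] = {}
    for source in source_genes:
        found = set()
        if source in targets:
            found.add((source,))
        if source in g:
            for target in targets:
                if target == source or target not in g:
                    continue
                for path in nx.all_simple_paths(g, source, target, cutoff=max_edges):
                    found.add(tuple(path))
        out[source] = sorted(
            (GenePath(nodes, is_self=len(nodes) == 1) for nodes in found),
            key=lambda p: (p.n_edges, p.nodes),
        )
    return out


def annotate_candidates(
    candidate_genes: Sequence[str],
    paths: Dict[str, List[GenePath]],
) -> List[Dict[str, str]]:
    """Report rows with the targets each candidate reaches and its first
    shortest path (empty strings when unconnected)."""
    rows = []
    for gene in candidate_genes:
        gene_paths = paths.get(gene, [])
        connected = sorted({p.target for p in gene_paths})
        rows.append(
            {
                "gene": gene,
                "connected_targets": ",".join(connected),
                "shortest_path": str(gene_paths[0]) if gene_paths else "",
            }
        )
    return rows
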