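"""Upstream regulatory subgraph extraction (the Pathrider step).

Given a full signed interaction graph and a list of target gene symbols,
keep the regulators: every node with a directed path to a target gene node,
plus the targets themselves, with the induced edges.  Biomolecules on an
excluded list (genes whose expression is undetectable) are removed first so
they cannot serve as regulators.

With the upstream node set defined as ``seeds ∪ {x : x reaches a seed}``,
every induced edge (u, v) has v inside the set and therefore lies on a
directed path to a seed, so "induced subgraph" and "edges on upstream
paths" coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .model import SignedInteractionGraph, node_kind_of, NodeKind

logger = logging.getLogger(__name__)

__all__ = ["filter_excluded", "upstream_subgraph", "UpstreamResult", "NoTargetError"]


class NoTargetError(ValueError):
    """No target symbol matches a gene node of the graph."""


@dataclass
class UpstreamResult:
    graph: SignedInteractionGraph
    matched_targets: list[str]


def filter_excluded(
    graph: SignedInteractionGraph, excluded_genes: list[str]
) -> SignedInteractionGraph:
    """Remove every biomolecule derived from an excluded gene symbol.

    For each symbol X this drops X_gen, X_prot, every complex with X_prot
    among its members, and all incident edges.  Symbols absent from the
    graph are counted and logged, not an error.
    """
    excluded = {s.strip() for s in excluded_genes if s.strip()}
    if not excluded:
        return graph.copy()
    excluded_prots = {f"{s}_prot" for s in excluded}
    to_remove = []
    present = 0
    for node in graph.node_ids():
        kind = node_kind_of(node)
        if kind is NodeKind.COMPLEX:
            if any(m in excluded_prots for m in graph.complex_members(node)):
                to_remove.append(node)
        elif kind is NodeKind.GENE:
            if node.removesuffix("_gen") in excluded:
                to_remove.append(node)
                present += 1
        else:
            if node.removesuffix("_prot") in excluded:
                to_remove.append(node)
    out = graph.copy()
    out.remove_nodes(to_remove)
    logger.info(
        "excluded-list filter: removed %d nodes (%d symbols not present in graph)",
        len(to_remove),
        len(excluded) - present,
    )
    return out


def upstream_subgraph(
    graph: SignedInteractionGraph,
    targets: list[str],
    downstream: bool = False,
) -> UpstreamResult:
    """Induced subgraph of the targets' gene nodes and all their regulators.

    Seeds are the nodes ``T_gen`` present in the graph for target symbols T;
    a symbol matching only a protein node does not seed.  ``downstream=True``
    additionally keeps nodes reachable *from* the seeds (symmetric closure).
    """
    if not targets:
        raise NoTargetError("empty target list")
    symbols = [t.strip() for t in targets if t.strip()]
    seeds = {f"{s}_gen" for s in symbols} & set(graph.node_ids())
    if not seeds:
        raise NoTargetError(
            f"none of the {len(symbols)} target symbols matches a gene node of the graph"
        )
    g = graph.to_networkx()
    keep = set(seeds)
    for layer in nx.bfs_layers(g.reverse(copy=False), sorted(seeds)):
        keep.update(layer)
    if downstream:
        for layer in nx.bfs_layers(g, sorted(seeds)):
            keep.update(layer)
    matched = sorted(s for s in set(symbols) if f"{s}_gen" in seeds)
    logger.info(
        "upstream extraction: %d/%d targets matched, kept %d of %d nodes",
        len(matched),
        len(set(symbols)),
        len(keep),
        graph.n_nodes,
    )
    return UpstreamResult(graph=graph.induced_subgraph(keep), matched_targets=matched)
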