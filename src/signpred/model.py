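"""Core domain types: signs, node kinds, the signed interaction graph, observations.

The central object is :class:`SignedInteractionGraph`, a directed graph
``G(V, E, sigma)`` whose nodes represent genes, proteins and protein
complexes and whose edges carry an activation (``+``) or inhibition (``-``)
sign.  Node kinds are encoded in the identifier itself:

* ``X_gen``  — the gene X,
* ``X_prot`` — the protein product of X,
* ``A_prot::B_prot`` — the complex assembled from proteins A and B.

Sign ``0`` exists only as a *node* label (no change); edges are strictly
signed.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Sign",
    "NodeKind",
    "Edge",
    "SignedInteractionGraph",
    "ObservationSet",
    "influence",
    "node_kind_of",
    "canonical_complex_id",
    "complex_display_name",
    "read_sif",
    "write_sif",
    "read_observations",
    "write_observations",
    "GraphFormatError",
    "InvalidEdgeSignError",
]


class GraphFormatError(ValueError):
    """Raised when a SIF or observation file cannot be parsed."""


class InvalidEdgeSignError(ValueError):
    """Raised when a zero sign is used where an edge sign is required."""


class Sign(enum.Enum):
    """A qualitative change: up (+), down (-), or no change (0)."""

    PLUS = "+"
    MINUS = "-"
    ZERO = "0"

    def __str__(self) -> str:  # ASCII on output
        return self.value

    @classmethod
    def from_str(cls, token: str) -> "Sign":
        token = token.strip()
        # accept both the ASCII hyphen and the U+2212 minus glyph
        if token in ("-", "−", "-1", "inhibition"):
            return cls.MINUS
        if token in ("+", "1", "activation"):
            return cls.PLUS
        if token == "0":
            return cls.ZERO
        raise GraphFormatError(f"unrecognized sign token: {token!r}")

    def to_int(self) -> int:
        return _SIGN_TO_INT[self]


_SIGN_TO_INT = {Sign.PLUS: 1, Sign.MINUS: -1, Sign.ZERO: 0}
_INT_TO_SIGN = {1: Sign.PLUS, -1: Sign.MINUS, 0: Sign.ZERO}


def sign_from_int(value: int) -> Sign:
    return _INT_TO_SIGN[value]


def influence(label: Sign, edge_sign: Sign) -> Sign:
    """Sign product: the influence a node with ``label`` sends down an edge.

    Zero is absorbing; two minuses make a plus.  ``edge_sign`` must be
    strictly signed (edges never carry 0).
    """
    if edge_sign is Sign.ZERO:
        raise InvalidEdgeSignError("edge signs are restricted to {+, -}")
    return _INT_TO_SIGN[label.to_int() * edge_sign.to_int()]


class NodeKind(enum.Enum):
    GENE = "gene"
    PROTEIN = "protein"
    COMPLEX = "complex"


def node_kind_of(node_id: str) -> NodeKind:
    """Classify a node id by its suffix convention.

    ``_gen`` marks genes, ``_prot`` proteins, and ``::`` in the id marks a
    complex.  Identifiers carrying none of the markers are treated as
    proteins (with a log line) so third-party graphs remain loadable.
    """
    if not node_id:
        raise ValueError("empty node id")
    if "::" in node_id:
        return NodeKind.COMPLEX
    if node_id.endswith("_gen"):
        return NodeKind.GENE
    if not node_id.endswith("_prot"):
        logger.warning("node %r has no recognized suffix; treating as protein", node_id)
    return NodeKind.PROTEIN


def canonical_complex_id(members_or_id: str | Iterable[str]) -> str:
    """Canonical id of a complex: ``_prot``-suffixed members, sorted, ``::``-joined.

    Accepts either an iterable of member names (with or without the
    ``_prot`` suffix) or a raw ``::``-joined id in any member order.
    """
    if isinstance(members_or_id, str):
        members = members_or_id.split("::")
    else:
        members = list(members_or_id)
    suffixed = [m if m.endswith("_prot") else f"{m}_prot" for m in members]
    return "::".join(sorted(suffixed))


def complex_display_name(complex_id: str) -> str:
    """Human-readable complex name with member ``_prot`` suffixes stripped."""
    return "::".join(m.removesuffix("_prot") for m in complex_id.split("::"))


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: Sign
    relation: str = "other"  # PPrel | GErel | GPrel | other

    def __post_init__(self) -> None:
        if self.sign is Sign.ZERO:
            raise InvalidEdgeSignError("edges cannot carry sign 0")


class SignedInteractionGraph:
    """Directed graph with signed edges; at most one edge per (u, v, sign).

    Backed by a :class:`networkx.MultiDiGraph` keyed on the edge sign so a
    pair of nodes may be joined by both an activation and an inhibition, but
    duplicate (source, target, sign) triples collapse to one edge.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str) -> None:
        if not node_id or any(c.isspace() for c in node_id):
            raise ValueError(f"invalid node id: {node_id!r}")
        if "::" in node_id:
            node_id = canonical_complex_id(node_id)
        self._g.add_node(node_id)

    def add_edge(self, source: str, target: str, sign: Sign, relation: str = "other") -> None:
        if sign is Sign.ZERO:
            raise InvalidEdgeSignError("edges cannot carry sign 0")
        if "::" in source:
            source = canonical_complex_id(source)
        if "::" in target:
            target = canonical_complex_id(target)
        self.add_node(source)
        self.add_node(target)
        key = sign.value
        if not self._g.has_edge(source, target, key=key):
            self._g.add_edge(source, target, key=key, relation=relation)

    def remove_nodes(self, node_ids: Iterable[str]) -> None:
        self._g.remove_nodes_from(list(node_ids))

    # -- queries ------------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def node_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    def node_kind(self, node_id: str) -> NodeKind:
        return node_kind_of(node_id)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def iter_edges(self) -> Iterator[Edge]:
        for u, v, key, data in self._g.edges(keys=True, data=True):
            yield Edge(u, v, Sign.from_str(key), data.get("relation", "other"))

    def in_edges(self, node_id: str) -> list[Edge]:
        return [
            Edge(u, v, Sign.from_str(key), data.get("relation", "other"))
            for u, v, key, data in self._g.in_edges(node_id, keys=True, data=True)
        ]

    def in_degree(self, node_id: str) -> int:
        return self._g.in_degree(node_id)

    def out_degree(self, node_id: str) -> int:
        return self._g.out_degree(node_id)

    def complex_members(self, complex_id: str) -> list[str]:
        if node_kind_of(complex_id) is not NodeKind.COMPLEX:
            raise ValueError(f"{complex_id!r} is not a complex node")
        return complex_id.split("::")

    # -- derived graphs ------------------------------------------------
    def copy(self) -> "SignedInteractionGraph":
        out = SignedInteractionGraph()
        out._g = self._g.copy()
        return out

    def induced_subgraph(self, node_ids: Iterable[str]) -> "SignedInteractionGraph":
        out = SignedInteractionGraph()
        out._g = nx.MultiDiGraph(self._g.subgraph(node_ids))
        return out

    def reverse_view(self) -> nx.MultiDiGraph:
        return self._g.reverse(copy=False)

    def to_networkx(self) -> nx.MultiDiGraph:
        return self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedInteractionGraph):
            return NotImplemented
        mine = {(e.source, e.target, e.sign) for e in self.iter_edges()}
        theirs = {(e.source, e.target, e.sign) for e in other.iter_edges()}
        return set(self._g.nodes) == set(other._g.nodes) and mine == theirs

    def __repr__(self) -> str:
        return f"SignedInteractionGraph(nodes={self.n_nodes}, edges={self.n_edges})"


class ObservationSet(Mapping):
    """Immutable partial map node id -> :class:`Sign` (the observations (S, mu))."""

    def __init__(self, entries: Mapping[str, Sign]):
        self._entries = dict(entries)

    def __getitem__(self, key: str) -> Sign:
        return self._entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._entries))

    def __len__(self) -> int:
        return len(self._entries)

    def restricted_to(self, node_ids: Iterable[str]) -> "ObservationSet":
        keep = set(node_ids)
        return ObservationSet({k: v for k, v in self._entries.items() if k in keep})

    def by_sign(self, sign: Sign) -> list[str]:
        return sorted(k for k, v in self._entries.items() if v is sign)

    def __repr__(self) -> str:
        return f"ObservationSet({len(self)} observations)"


# ---------------------------------------------------------------------------
# SIF input/output
#
# Dialect: one edge per line, "source relation target" with whitespace
# separators; relation tokens 1/activation/+ mean activation and
# -1/inhibition/- (either minus glyph) inhibition.  Lines starting with '#'
# are comments; a line holding a single token declares an isolated node.
# ---------------------------------------------------------------------------

def read_sif(path_or_lines: str | Path | Iterable[str]) -> SignedInteractionGraph:
    if isinstance(path_or_lines, (str, Path)):
        lines: Iterable[str] = Path(path_or_lines).read_text().splitlines()
    else:
        lines = path_or_lines
    graph = SignedInteractionGraph()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 1:
            graph.add_node(tokens[0])
            continue
        if len(tokens) != 3:
            raise GraphFormatError(f"line {lineno}: expected 1 or 3 columns, got {len(tokens)}")
        source, rel, target = tokens
        sign = Sign.from_str(rel)
        if sign is Sign.ZERO:
            raise GraphFormatError(f"line {lineno}: edge sign cannot be 0")
        graph.add_edge(source, target, sign)
    return graph


def write_sif(graph: SignedInteractionGraph, path: str | Path) -> None:
    lines = []
    connected: set[str] = set()
    for e in sorted(graph.iter_edges(), key=lambda e: (e.source, e.target, e.sign.value)):
        token = "1" if e.sign is Sign.PLUS else "-1"
        lines.append(f"{e.source}\t{token}\t{e.target}")
        connected.add(e.source)
        connected.add(e.target)
    for node in graph.node_ids():
        if node not in connected:
            lines.append(node)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Observation files: one "node = sign" line per observation.
# ---------------------------------------------------------------------------

def read_observations(path_or_lines: str | Path | Iterable[str]) -> ObservationSet:
    if isinstance(path_or_lines, (str, Path)):
        lines: Iterable[str] = Path(path_or_lines).read_text().splitlines()
    else:
        lines = path_or_lines
    entries: dict[str, Sign] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise GraphFormatError(f"line {lineno}: expected 'node = sign'")
        node, _, token = line.partition("=")
        entries[node.strip()] = Sign.from_str(token)
    return ObservationSet(entries)


def write_observations(observations: ObservationSet, path: str | Path) -> None:
    lines = [f"{node} = {observations[node]}" for node in observations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
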