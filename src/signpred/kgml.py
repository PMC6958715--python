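"""Convert KEGG KGML pathway XML into a signed interaction graph.

The conversion separates genes from their protein products:

* PPrel (protein-protein) relations join ``_prot`` nodes;
* GErel (gene expression) relations run from a transcription factor
  ``_prot`` node to a target ``_gen`` node;
* KGML group entries become complex nodes ``A_prot::B_prot`` receiving one
  plus-signed membership edge from each member protein;
* for every protein node, a plus-signed GPrel edge from its gene models
  protein formation, linking expression data to signaling.

Edge signs come from the relation subtype keywords; the keyword -> sign map
is configuration, not code.  Relations carrying only neutral keywords
(binding/association, state changes...) are dropped: a causal edge is only
emitted where KEGG states an activator or inhibitor role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .model import Sign, SignedInteractionGraph, canonical_complex_id

logger = logging.getLogger(__name__)

__all__ = [
    "KgmlEntry",
    "KgmlRelation",
    "KgmlFormatError",
    "DEFAULT_SIGN_KEYWORDS",
    "parse_kgml",
    "sign_from_subtypes",
    "build_graph",
    "convert_pathways",
    "load_sign_config",
]


class KgmlFormatError(ValueError):
    """Raised on malformed or non-KGML XML input."""


#: Default subtype keyword -> role mapping; values "+", "-", or "drop".
DEFAULT_SIGN_KEYWORDS: dict[str, str] = {
    "activation": "+",
    "expression": "+",
    "indirect effect": "+",
    "inhibition": "-",
    "repression": "-",
    "binding/association": "drop",
    "dissociation": "drop",
    "phosphorylation": "drop",
    "dephosphorylation": "drop",
    "ubiquitination": "drop",
    "methylation": "drop",
    "state change": "drop",
    "missing interaction": "drop",
    "compound": "drop",
}


@dataclass(frozen=True)
class KgmlEntry:
    entry_id: str
    entry_type: str  # gene | group | compound | map | ortholog | ...
    names: tuple[str, ...] = ()  # resolved gene symbols
    component_ids: tuple[str, ...] = ()  # non-empty for groups


@dataclass(frozen=True)
class KgmlRelation:
    entry1: str
    entry2: str
    rel_type: str  # PPrel | GErel | PCrel | ECrel | maplink
    subtypes: tuple[str, ...] = ()


def _entry_symbols(entry_el: etree._Element) -> tuple[str, ...]:
    """Resolve gene symbols for an entry from its graphics name.

    KGML stores KEGG ids in ``name`` and display symbols in the graphics
    element.  Convention used here: the graphics name is split on commas;
    with k ids and at least k tokens the tokens map pairwise onto the ids,
    otherwise the first token stands for the whole entry.
    """
    ids = (entry_el.get("name") or "").split()
    graphics = entry_el.find("graphics")
    gname = graphics.get("name") if graphics is not None else None
    if not gname:
        return ()
    tokens = [t.strip().rstrip(".") for t in gname.split(",") if t.strip().rstrip(".")]
    if not tokens:
        return ()
    if len(ids) > 1 and len(tokens) >= len(ids):
        return tuple(tokens[: len(ids)])
    return (tokens[0],) if len(ids) <= 1 else tuple(tokens[:1])


def parse_kgml(source: str | Path) -> tuple[list[KgmlEntry], list[KgmlRelation]]:
    """Parse one KGML document (path or XML string) into entries and relations."""
    try:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            tree = etree.parse(str(source))
            root = tree.getroot()
        else:
            root = etree.fromstring(source.encode() if isinstance(source, str) else source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise KgmlFormatError(f"cannot parse KGML from {source!r:.80}: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlFormatError(f"expected a <pathway> root element, got <{root.tag}>")
    entries: list[KgmlEntry] = []
    relations: list[KgmlRelation] = []
    for el in root:
        if el.tag == "entry":
            components = tuple(c.get("id") for c in el.findall("component"))
            entries.append(
                KgmlEntry(
                    entry_id=el.get("id"),
                    entry_type=el.get("type", ""),
                    names=_entry_symbols(el),
                    component_ids=components,
                )
            )
        elif el.tag == "relation":
            subtypes = tuple(s.get("name", "") for s in el.findall("subtype"))
            relations.append(
                KgmlRelation(
                    entry1=el.get("entry1"),
                    entry2=el.get("entry2"),
                    rel_type=el.get("type", ""),
                    subtypes=subtypes,
                )
            )
        elif el.tag not in ("reaction",):
            logger.debug("ignoring KGML element <%s>", el.tag)
    return entries, relations


def sign_from_subtypes(
    subtypes: Sequence[str],
    config: Mapping[str, str] | None = None,
) -> tuple[Sign, ...]:
    """Edge signs implied by subtype keywords.

    Returns a tuple of signs: empty means the relation carries no causal
    role and is dropped; a keyword set mixing activating and inhibiting
    roles yields both signs (one edge each) with a logged ambiguity.
    """
    config = DEFAULT_SIGN_KEYWORDS if config is None else config
    roles = {config.get(s, "drop") for s in subtypes}
    signs: list[Sign] = []
    if "+" in roles:
        signs.append(Sign.PLUS)
    if "-" in roles:
        signs.append(Sign.MINUS)
    if len(signs) == 2:
        logger.warning("ambiguous subtypes %s: emitting both an activation and an inhibition", list(subtypes))
    return tuple(signs)


def load_sign_config(path: str | Path) -> dict[str, str]:
    """Read a keyword=role config file (roles: +, -, drop; '#' comments)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'keyword=role'")
        key, _, role = line.partition("=")
        role = role.strip()
        if role not in ("+", "-", "drop"):
            raise ValueError(f"{path}:{lineno}: role must be +, - or drop, got {role!r}")
        out[key.strip()] = role
    return out


def _entry_nodes(
    entry: KgmlEntry,
    entries_by_id: Mapping[str, KgmlEntry],
    as_target_of_gerel: bool = False,
) -> list[str]:
    """Graph node ids an entry stands for (one per symbol; complex id for groups)."""
    if entry.entry_type == "group":
        members = _group_member_symbols(entry, entries_by_id)
        return [canonical_complex_id(members)] if members else []
    if entry.entry_type not in ("gene", "ortholog"):
        return []
    suffix = "_gen" if as_target_of_gerel else "_prot"
    return [f"{sym}{suffix}" for sym in entry.names]


def _group_member_symbols(
    entry: KgmlEntry, entries_by_id: Mapping[str, KgmlEntry]
) -> list[str]:
    """Leaf protein member symbols of a group, nested groups flattened."""
    members: list[str] = []
    for cid in entry.component_ids:
        comp = entries_by_id.get(cid)
        if comp is None:
            logger.warning("group %s references missing entry %s", entry.entry_id, cid)
            continue
        if comp.entry_type == "group":
            members.extend(_group_member_symbols(comp, entries_by_id))
        elif comp.names:
            members.append(comp.names[0])
    return members


def build_graph(
    parsed: tuple[list[KgmlEntry], list[KgmlRelation]]
    | Iterable[tuple[list[KgmlEntry], list[KgmlRelation]]],
    sign_config: Mapping[str, str] | None = None,
    graph: SignedInteractionGraph | None = None,
) -> SignedInteractionGraph:
    """Build (or extend) a signed interaction graph from parsed pathways.

    Accepts a single ``(entries, relations)`` pair or an iterable of such
    pairs (entry ids are pathway-local, so pathways must be converted
    separately and merged by node id; duplicated edges collapse).
    """
    if graph is None:
        graph = SignedInteractionGraph()
    if isinstance(parsed, tuple) and len(parsed) == 2 and (
        not parsed[0] or isinstance(parsed[0][0], KgmlEntry)
    ):
        pathways = [parsed]
    else:
        pathways = list(parsed)  # type: ignore[arg-type]

    for entries, relations in pathways:
        by_id = {e.entry_id: e for e in entries}
        # group entries materialize their complex even without relations
        for entry in entries:
            if entry.entry_type != "group":
                continue
            members = _group_member_symbols(entry, by_id)
            if len(members) < 2:
                logger.warning("group %s has fewer than 2 resolvable members; skipped", entry.entry_id)
                continue
            complex_id = canonical_complex_id(members)
            for member in members:
                graph.add_edge(f"{member}_prot", complex_id, Sign.PLUS, relation="PPrel")
        for rel in relations:
            if rel.rel_type not in ("PPrel", "GErel"):
                logger.debug("dropping %s relation %s->%s", rel.rel_type, rel.entry1, rel.entry2)
                continue
            e1, e2 = by_id.get(rel.entry1), by_id.get(rel.entry2)
            if e1 is None or e2 is None:
                logger.warning(
                    "relation %s->%s references a missing entry; skipped", rel.entry1, rel.entry2
                )
                continue
            signs = sign_from_subtypes(rel.subtypes, sign_config)
            if not signs:
                continue
            sources = _entry_nodes(e1, by_id)
            targets = _entry_nodes(e2, by_id, as_target_of_gerel=(rel.rel_type == "GErel"))
            if not sources or not targets:
                logger.warning(
                    "relation %s->%s touches a non-gene/group entry; skipped",
                    rel.entry1,
                    rel.entry2,
                )
                continue
            for s in sources:
                for t in targets:
                    for sign in signs:
                        graph.add_edge(s, t, sign, relation=rel.rel_type)

    _add_gene_protein_edges(graph)
    return graph


def _add_gene_protein_edges(graph: SignedInteractionGraph) -> None:
    """Add the plus GPrel edge C_gen -> C_prot for every symbol C in the graph.

    Covers both directions of node creation: a protein node gains its
    coding gene, and a gene node gains its protein product.
    """
    symbols = set()
    for node in graph.node_ids():
        if "::" in node:
            continue
        if node.endswith("_prot"):
            symbols.add(node.removesuffix("_prot"))
        elif node.endswith("_gen"):
            symbols.add(node.removesuffix("_gen"))
    for sym in sorted(symbols):
        graph.add_edge(f"{sym}_gen", f"{sym}_prot", Sign.PLUS, relation="GPrel")


def convert_pathways(
    kgml_paths: Iterable[str | Path],
    sign_config: Mapping[str, str] | None = None,
) -> SignedInteractionGraph:
    """Parse and merge several KGML files into one signed interaction graph."""
    parsed = [parse_kgml(Path(p)) for p in kgml_paths]
    return build_graph(parsed, sign_config=sign_config)
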