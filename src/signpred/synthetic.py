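"""Synthetic graphs, planted labelings and fixture motifs.

The generator emulates the structural features the pipeline relies on in
curated pathway graphs: paired gene/protein nodes joined by GPrel edges,
protein-protein and transcription-factor edges that are mostly activations
(the default inhibition fraction, 0.153, reproduces the roughly 2110 : 13771
inhibition share of the curated human signaling graph the method was
developed on), and protein complexes wired from their members.  A planted
consistent total labeling provides ground truth: observations revealed from
it are guaranteed repair-free, and any sound predictor must agree with it
wherever it decides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consistency import is_consistent_labeling, sample_consistent_labeling
from .model import (
    NodeKind,
    ObservationSet,
    Sign,
    SignedInteractionGraph,
    canonical_complex_id,
    node_kind_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "random_signed_graph",
    "plant_consistent_labeling",
    "reveal_observations",
    "Fixture",
    "fixture_library",
]

#: Inhibition share of the curated reference graph (2110 of 13771 edges).
DEFAULT_INHIBITION_FRACTION = 2110 / 13771


def random_signed_graph(
    n_genes: int = 30,
    edge_density: float = 0.05,
    inhibition_fraction: float = DEFAULT_INHIBITION_FRACTION,
    complex_count: int = 3,
    seed: int | list[int] | np.random.Generator = 0,
) -> SignedInteractionGraph:
    """Random signed graph with gene/protein pairs, signaling edges, complexes.

    ``edge_density`` is the probability of a PPrel edge per ordered protein
    pair and of a GErel edge per (protein, other gene) pair; signs are minus
    with probability ``inhibition_fraction``.  Complexes pick 2 random member
    proteins each and are wired with plus-signed membership edges.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive (a graph needs edges)")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    if not 0 <= inhibition_fraction < 1:
        raise ValueError("inhibition_fraction must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    symbols = [f"G{i:03d}" for i in range(n_genes)]
    graph = SignedInteractionGraph()
    for sym in symbols:
        graph.add_edge(f"{sym}_gen", f"{sym}_prot", Sign.PLUS, relation="GPrel")

    def draw_sign() -> Sign:
        return Sign.MINUS if rng.random() < inhibition_fraction else Sign.PLUS

    for a in symbols:
        for b in symbols:
            if a == b:
                continue
            if rng.random() < edge_density:
                graph.add_edge(f"{a}_prot", f"{b}_prot", draw_sign(), relation="PPrel")
            if rng.random() < edge_density / 2:
                graph.add_edge(f"{a}_prot", f"{b}_gen", draw_sign(), relation="GErel")
    for _ in range(complex_count):
        if n_genes < 2:
            break
        members = rng.choice(symbols, size=2, replace=False)
        cid = canonical_complex_id(list(members))
        for m in members:
            graph.add_edge(f"{m}_prot", cid, Sign.PLUS, relation="PPrel")
    return graph


def plant_consistent_labeling(
    graph: SignedInteractionGraph,
    seed: int | list[int] | np.random.Generator = 0,
) -> dict[str, Sign]:
    """A consistent total labeling with no observations and no repairs.

    Drawn by running the consistency solver with randomized value order:
    free source nodes receive uniform random signs and downstream nodes any
    justifiable sign, cycles included.  Construction cannot fail (the
    all-zero labeling is always consistent).  The result is re-checked
    against the independent rule checker.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labeling = sample_consistent_labeling(graph, rng=rng)
    assert is_consistent_labeling(graph, labeling), "planted labeling failed the rule check"
    return labeling


def reveal_observations(
    labeling: dict[str, Sign],
    graph: SignedInteractionGraph,
    fraction: float = 50,
    genes_only: bool = True,
    seed: int | list[int] | np.random.Generator = 0,
) -> ObservationSet:
    """Reveal a fraction of the planted labels as observations.

    Mirrors the study setting where only gene nodes carry measurements, and
    measured genes are those with a non-zero shift.  The revealed set is
    consistent by construction (the planted labeling witnesses it).
    """
    if not 0 < fraction <= 100:
        raise ValueError("fraction must lie in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = sorted(
        node
        for node, sign in labeling.items()
        if sign is not Sign.ZERO
        and (not genes_only or node_kind_of(node) is NodeKind.GENE)
        and node in graph
    )
    if not eligible:
        raise ValueError("no eligible node to reveal (all labels zero?)")
    k = max(1, int(np.floor(fraction / 100 * len(eligible) + 0.5)))
    chosen = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
    return ObservationSet({str(n): labeling[str(n)] for n in chosen})


@dataclass
class Fixture:
    """A small named instance with hand-derived expected behavior.

    Expected predictions are stated for the decided nodes only; tests
    confirm them against both the production solver and the brute-force
    enumerator before trusting them.
    """

    name: str
    graph: SignedInteractionGraph
    observations: ObservationSet
    expected_k: int
    expected_predictions: dict[str, Sign] = field(default_factory=dict)
    expected_repairs: tuple[frozenset[str], ...] | None = None
    notes: str = ""


def _graph(edges: list[tuple[str, str, Sign]]) -> SignedInteractionGraph:
    g = SignedInteractionGraph()
    for u, v, s in edges:
        g.add_edge(u, v, s)
    return g


def fixture_library() -> dict[str, Fixture]:
    """Bundled toy instances: chains, forks, cycles, complexes, conflict motifs."""
    P, M = Sign.PLUS, Sign.MINUS
    lib: dict[str, Fixture] = {}

    lib["chain"] = Fixture(
        name="chain",
        graph=_graph([("A_prot", "B_prot", P), ("B_prot", "C_gen", P)]),
        observations=ObservationSet({"A_prot": P}),
        expected_k=0,
        expected_predictions={"B_prot": P, "C_gen": P},
        notes="activation chain propagates the + observation downstream",
    )
    lib["inhibitor_chain"] = Fixture(
        name="inhibitor_chain",
        graph=_graph([("A_prot", "B_prot", M)]),
        observations=ObservationSet({"A_prot": P}),
        expected_k=0,
        expected_predictions={"B_prot": M},
        notes="a + source through an inhibition forces a - downstream",
    )
    lib["fork"] = Fixture(
        name="fork",
        graph=_graph([("A_prot", "C_prot", P), ("B_prot", "C_prot", M)]),
        observations=ObservationSet({"A_prot": P, "B_prot": P}),
        expected_k=0,
        expected_predictions={},
        notes="opposing influences: C stays undecided (labelings give +, - and 0)",
    )
    lib["cycle"] = Fixture(
        name="cycle",
        graph=_graph(
            [("A_prot", "B_prot", P), ("B_prot", "A_prot", P), ("B_prot", "T_gen", P)]
        ),
        observations=ObservationSet({"T_gen": P}),
        expected_k=0,
        expected_predictions={"A_prot": P, "B_prot": P},
        notes="a feedback cycle upstream of the observed target is fully decided",
    )
    lib["complex_toy"] = Fixture(
        name="complex_toy",
        graph=_graph(
            [
                ("A_gen", "A_prot", P),
                ("B_gen", "B_prot", P),
                ("A_prot", "A_prot::B_prot", P),
                ("B_prot", "A_prot::B_prot", P),
                ("A_prot::B_prot", "T_gen", P),
            ]
        ),
        observations=ObservationSet({"A_gen": P, "B_gen": P, "T_gen": P}),
        expected_k=0,
        expected_predictions={
            "A_prot": P,
            "B_prot": P,
            "A_prot::B_prot": P,
        },
        notes="complex activity follows from both members' gene over-expression",
    )
    # Two-source / two-free-node motif: A and B fixed, C and D free, so the
    # candidate space is 3^2 = 9 labelings before the rules filter it.
    fig_edges = [("A_prot", "C_prot", P), ("B_prot", "C_prot", M), ("C_prot", "D_prot", P)]
    lib["two_source_consistent"] = Fixture(
        name="two_source_consistent",
        graph=_graph(fig_edges),
        observations=ObservationSet({"A_prot": P, "B_prot": P}),
        expected_k=0,
        expected_predictions={},
        notes="consistent scenario: 3 of the 9 candidate labelings survive, C and D undecided",
    )
    lib["two_source_inconsistent"] = Fixture(
        name="two_source_inconsistent",
        graph=_graph(fig_edges),
        observations=ObservationSet({"A_prot": Sign.ZERO, "B_prot": Sign.ZERO, "D_prot": P}),
        expected_k=1,
        expected_repairs=(frozenset({"C_prot"}), frozenset({"D_prot"})),
        expected_predictions={},
        notes=(
            "zero sources force C=0 and D=0, contradicting the + observation on D; "
            "exempting either C (freeing it to justify D) or D itself repairs it, and "
            "the two scenarios disagree on C, leaving it undecided"
        ),
    )
    # Contradiction motif: one + observation against three - observations
    # sharing a single upstream regulator; the unique minimal repair exempts
    # the + gene, after which the hub flips to - and the exempted gene's
    # protein is still driven + by its own gene.
    lib["insight_motif"] = Fixture(
        name="insight_motif",
        graph=_graph(
            [
                ("TP53_prot", "PMAIP1_gen", P),
                ("TP53_prot", "CCNG1_gen", P),
                ("TP53_prot", "SHISA5_gen", P),
                ("TP53_prot", "TP73_gen", P),
                ("PMAIP1_gen", "PMAIP1_prot", P),
            ]
        ),
        observations=ObservationSet(
            {"PMAIP1_gen": P, "CCNG1_gen": M, "SHISA5_gen": M, "TP73_gen": M}
        ),
        expected_k=1,
        expected_repairs=(frozenset({"PMAIP1_gen"}),),
        expected_predictions={"TP53_prot": M, "PMAIP1_prot": P},
        notes="1 '+' vs 3 '-' observations through a shared regulator: k=1, hub flips to -",
    )
    return lib
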