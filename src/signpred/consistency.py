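"""Sign-consistency inference: satisfiability, minimal correction sets, predictions.

A *total labeling* assigns every node of a signed interaction graph a sign
in {+, -, 0}.  It is consistent with a set of observations when

1. every observed node keeps its observed sign,
2. every node labeled + or - receives at least one influence equal to its
   label (the influence of a predecessor p over edge e is the sign product
   ``label(p) * sigma(e)``), and
3. every node labeled 0 receives either only 0 influences or at least one
   + and one - influence.

Nodes with no predecessors, and nodes granted an artificial incoming
influence by a repair, are exempt from rules 2-3 (rule 1 always binds).

The production path is a ternary-domain backtracking search with
achievability-based propagation; it decides satisfiability and entailment
without materializing the labeling space.  ``enumerate_consistent`` with
``method="exhaustive"`` is the independent brute-force enumerator kept as a
test oracle.

The *prediction function* ``pred(x)`` returns a sign s iff every consistent
total labeling assigns s to x, and the undecided marker otherwise.  When
the observations are inconsistent with the graph, minimal correction sets
(MCoS) are computed first and predictions are combined across all minimal
repairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .model import (
    NodeKind,
    ObservationSet,
    Sign,
    SignedInteractionGraph,
    sign_from_int,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TotalLabeling",
    "PredictionMap",
    "McosReport",
    "is_consistent_labeling",
    "enumerate_consistent",
    "count_candidate_labelings",
    "satisfiable",
    "sample_consistent_labeling",
    "mcos",
    "predict",
    "RepairLimitError",
    "InconsistentInstanceError",
]

_SIGNS = (1, -1, 0)
_BIT = {1: 1, -1: 2, 0: 4}
_ALL = 7
_BIT_TO_SIGN = {1: 1, 2: -1, 4: 0}

TotalLabeling = Mapping[str, Sign]


class RepairLimitError(RuntimeError):
    """No repair of size <= max_k restores satisfiability."""


class InconsistentInstanceError(RuntimeError):
    """Raised when an instance expected to be satisfiable is not."""


@dataclass(frozen=True)
class McosReport:
    """Minimal correction sets: size k and every cardinality-minimal repair."""

    k: int
    repair_sets: tuple[frozenset[str], ...]

    @property
    def consistent(self) -> bool:
        return self.k == 0


@dataclass
class PredictionMap:
    """Output of ``pred``: decided signs, undecided nodes, per-kind breakdown.

    Observed nodes never appear in either set — predictions concern only
    initially unmeasured biomolecules.
    """

    predictions: dict[str, Sign]
    undecided: set[str]
    breakdown: dict[tuple[Sign, NodeKind], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.breakdown:
            counts: dict[tuple[Sign, NodeKind], int] = {}
            from .model import node_kind_of

            for node, sign in self.predictions.items():
                key = (sign, node_kind_of(node))
                counts[key] = counts.get(key, 0) + 1
            self.breakdown = counts

    def by_sign(self, sign: Sign) -> list[str]:
        return sorted(n for n, s in self.predictions.items() if s is sign)

    def __len__(self) -> int:
        return len(self.predictions)


# ---------------------------------------------------------------------------
# Compiled instance
# ---------------------------------------------------------------------------

class _Instance:
    """Integer-indexed view of a graph + observations for the solver.

    Domains are 3-bit masks (1: +, 2: -, 4: 0).  ``constrained[i]`` is True
    for nodes subject to rules 2-3 (has predecessors, not repaired).
    """

    def __init__(
        self,
        graph: SignedInteractionGraph,
        observations: Mapping[str, Sign] | None = None,
        repaired: Iterable[str] = (),
        assume: Mapping[str, int] | None = None,
    ) -> None:
        self.nodes: list[str] = graph.node_ids()
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        # in_edges[i]: list of (pred_index, sigma); pred_groups[i]: list of
        # (pred_index, tuple of sigmas) grouping parallel edges by source.
        self.in_edges: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for e in graph.iter_edges():
            self.in_edges[self.index[e.target]].append((self.index[e.source], e.sign.to_int()))
        self.pred_groups: list[list[tuple[int, tuple[int, ...]]]] = []
        for edges in self.in_edges:
            groups: dict[int, set[int]] = {}
            for p, s in edges:
                groups.setdefault(p, set()).add(s)
            self.pred_groups.append(sorted((p, tuple(sorted(ss))) for p, ss in groups.items()))
        repaired_idx = {self.index[r] for r in repaired if r in self.index}
        self.constrained = [
            bool(self.in_edges[i]) and i not in repaired_idx for i in range(n)
        ]
        self.constrained_idx = [i for i in range(n) if self.constrained[i]]
        # successors-of interest: constrained nodes whose achievability may
        # change when node j narrows
        self.watchers: list[list[int]] = [[] for _ in range(n)]
        for i in self.constrained_idx:
            for p, _ in self.pred_groups[i]:
                self.watchers[p].append(i)
        dom = [_ALL] * n
        for node, sign in (observations or {}).items():
            if node not in self.index:
                raise KeyError(f"observed node {node!r} not in graph")
            dom[self.index[node]] &= _BIT[sign.to_int()]
        for node, value in (assume or {}).items():
            dom[self.index[node]] &= _BIT[value]
        self.root = dom

    # -- achievability -------------------------------------------------
    def achievable(self, x: int, v: int, dom: list[int]) -> bool:
        """Can node x take value v under the current domains of its predecessors?

        Exact when all predecessor domains are singletons.
        """
        groups = self.pred_groups[x]
        if v != 0:
            bit_needed = _BIT[v]
            for p, sigmas in groups:
                d = dom[p]
                for s in sigmas:
                    # influence a*s == v  <=>  a == v*s
                    if d & _BIT[v * s]:
                        return True
            return False
        # v == 0: all influences zero ...
        if all(dom[p] & _BIT[0] for p, _ in groups):
            return True
        # ... or both a + and a - influence received
        plus_preds: list[int] = []
        minus_preds: list[int] = []
        for p, sigmas in groups:
            d = dom[p]
            if len(sigmas) == 2 and d & (_BIT[1] | _BIT[-1]):
                # one non-zero label a over a +edge and a -edge gives {a, -a}
                return True
            can_plus = any(d & _BIT[s] for s in sigmas)  # a == +1*s
            can_minus = any(d & _BIT[-s] for s in sigmas)
            if can_plus:
                plus_preds.append(p)
            if can_minus:
                minus_preds.append(p)
        if not plus_preds or not minus_preds:
            return False
        if len(plus_preds) > 1 or len(minus_preds) > 1:
            return True
        return plus_preds[0] != minus_preds[0]

    # -- propagation ---------------------------------------------------
    def propagate(self, dom: list[int]) -> list[int] | None:
        """Enforce generalized arc consistency on every justification constraint.

        For each constrained node x the rule couples x with its
        predecessors; values are pruned both from x (unachievable under the
        predecessors' domains) and from each predecessor p (no value of x
        remains achievable when p is pinned to that value).  Runs to
        fixpoint; returns the narrowed domains or None on a wipe-out.
        Sound: a removed value belongs to no consistent extension.
        """
        queue = list(self.constrained_idx)
        in_queue = set(queue)

        def enqueue(i: int) -> None:
            if i not in in_queue:
                queue.append(i)
                in_queue.add(i)

        while queue:
            x = queue.pop()
            in_queue.discard(x)
            d = dom[x]
            nd = 0
            for v in _SIGNS:
                if d & _BIT[v] and self.achievable(x, v, dom):
                    nd |= _BIT[v]
            if nd == 0:
                return None
            if nd != d:
                dom[x] = nd
                for w in self.watchers[x]:
                    enqueue(w)
            # support check for each predecessor value
            for p, _ in self.pred_groups[x]:
                dp = dom[p]
                if dp in (1, 2, 4):  # singleton: nothing to prune
                    continue
                np_ = 0
                for a in _SIGNS:
                    if not dp & _BIT[a]:
                        continue
                    dom[p] = _BIT[a]
                    if any(
                        dom[x] & _BIT[v] and self.achievable(x, v, dom) for v in _SIGNS
                    ):
                        np_ |= _BIT[a]
                dom[p] = dp
                if np_ != dp:
                    if np_ == 0:
                        return None
                    dom[p] = np_
                    enqueue(x)
                    for w in self.watchers[p]:
                        enqueue(w)
        if any(d == 0 for d in dom):
            return None
        return dom

    # -- search ----------------------------------------------------------
    def _select_var(self, dom: list[int]) -> int | None:
        best = None
        best_size = 4
        for i, d in enumerate(dom):
            size = bin(d).count("1")
            if size > 1 and size < best_size:
                best, best_size = i, size
                if size == 2 and self.constrained[i]:
                    break
        return best

    def solutions(
        self, dom: list[int] | None = None, rng: np.random.Generator | None = None
    ) -> Iterator[list[int]]:
        """Yield consistent total labelings (as per-node int sign lists)."""
        if dom is None:
            dom = list(self.root)
        dom = self.propagate(dom)
        if dom is None:
            return
        stack: list[list[int]] = [dom]
        while stack:
            cur = stack.pop()
            x = self._select_var(cur)
            if x is None:
                yield [_BIT_TO_SIGN[d] for d in cur]
                continue
            values = [v for v in _SIGNS if cur[x] & _BIT[v]]
            if rng is not None:
                rng.shuffle(values)
            # push in reverse so the first value is explored first
            for v in reversed(values):
                child = list(cur)
                child[x] = _BIT[v]
                narrowed = self.propagate(child)
                if narrowed is not None:
                    stack.append(narrowed)

    def satisfiable(self, assume_idx: tuple[int, int] | None = None) -> bool:
        dom = list(self.root)
        if assume_idx is not None:
            x, v = assume_idx
            dom[x] &= _BIT[v]
            if dom[x] == 0:
                return False
        return next(self.solutions(dom), None) is not None


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def is_consistent_labeling(
    graph: SignedInteractionGraph,
    labeling: TotalLabeling,
    observations: Mapping[str, Sign] | None = None,
    repaired: Iterable[str] = (),
) -> bool:
    """Direct check of the three consistency rules on a total labeling."""
    nodes = graph.node_ids()
    missing = [n for n in nodes if n not in labeling]
    if missing:
        raise ValueError(f"labeling is not total; missing {missing[:5]}")
    values = {n: labeling[n].to_int() for n in nodes}
    for node, sign in (observations or {}).items():
        if values[node] != sign.to_int():
            return False
    repaired = set(repaired)
    for node in nodes:
        if node in repaired:
            continue
        in_edges = graph.in_edges(node)
        if not in_edges:
            continue
        received = [values[e.source] * e.sign.to_int() for e in in_edges]
        v = values[node]
        if v != 0:
            if v not in received:
                return False
        else:
            if not (all(r == 0 for r in received) or (1 in received and -1 in received)):
                return False
    return True


def count_candidate_labelings(graph: SignedInteractionGraph, fixed: Mapping[str, Sign]) -> int:
    """Size of the candidate labeling space: 3 ** (number of unfixed nodes)."""
    free = [n for n in graph.node_ids() if n not in fixed]
    return 3 ** len(free)


def enumerate_consistent(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign] | None = None,
    repaired: Iterable[str] = (),
    method: str = "search",
    exhaustive_bound: int = 12,
) -> list[dict[str, Sign]]:
    """All consistent total labelings, sorted deterministically.

    ``method="search"`` uses the production solver; ``method="exhaustive"``
    filters the full ``3^|V|`` candidate space through
    :func:`is_consistent_labeling` and is kept as the independent oracle
    (node count capped by ``exhaustive_bound``).
    """
    nodes = graph.node_ids()
    observations = dict(observations or {})
    if method == "exhaustive":
        if len(nodes) > exhaustive_bound:
            raise ValueError(
                f"exhaustive enumeration capped at {exhaustive_bound} nodes, got {len(nodes)}"
            )
        choices = [
            (observations[n].to_int(),) if n in observations else _SIGNS for n in nodes
        ]
        out = []
        for combo in itertools.product(*choices):
            labeling = {n: sign_from_int(v) for n, v in zip(nodes, combo)}
            if is_consistent_labeling(graph, labeling, observations, repaired):
                out.append(labeling)
    elif method == "search":
        inst = _Instance(graph, observations, repaired)
        out = [
            {n: sign_from_int(v) for n, v in zip(inst.nodes, sol)}
            for sol in inst.solutions()
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    out.sort(key=lambda lab: tuple(lab[n].value for n in nodes))
    return out


def satisfiable(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign] | None = None,
    repaired: Iterable[str] = (),
) -> bool:
    """Does any consistent total labeling exist?"""
    return _Instance(graph, observations, repaired).satisfiable()


def sample_consistent_labeling(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign] | None = None,
    repaired: Iterable[str] = (),
    rng: np.random.Generator | None = None,
) -> dict[str, Sign]:
    """One consistent total labeling, value order randomized under ``rng``."""
    inst = _Instance(graph, observations, repaired)
    sol = next(inst.solutions(rng=rng), None)
    if sol is None:
        raise InconsistentInstanceError("no consistent labeling exists")
    return {n: sign_from_int(v) for n, v in zip(inst.nodes, sol)}


def mcos(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign],
    max_k: int = 3,
) -> McosReport:
    """Minimal correction sets restoring satisfiability.

    Each repair exempts one node from the justification rules, modeling one
    added artificial influence toward it.  The search proceeds by increasing
    cardinality and collects every repair set at the first satisfiable size.
    Exempting a node that already has no predecessor can never change
    satisfiability, so candidates are the nodes with incoming edges.
    """
    if satisfiable(graph, observations):
        return McosReport(0, (frozenset(),))
    candidates = sorted(n for n in graph.node_ids() if graph.in_degree(n) > 0)
    for k in range(1, max_k + 1):
        found = [
            frozenset(combo)
            for combo in itertools.combinations(candidates, k)
            if satisfiable(graph, observations, repaired=combo)
        ]
        if found:
            logger.info("MCoS: %d repair set(s) of size %d", len(found), k)
            return McosReport(k, tuple(sorted(found, key=sorted)))
    raise RepairLimitError(f"no repair of size <= {max_k} restores consistency")


def _predictions_under_repair(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign],
    repaired: frozenset[str],
) -> dict[str, Sign | None]:
    """pred_r over all labelings consistent under one repair set.

    For each node, a sign is entailed iff the alternative signs are
    unsatisfiable; a witness labeling bounds the queries to at most two per
    node, and a singleton propagated domain decides without search.
    """
    inst = _Instance(graph, observations, repaired)
    root = inst.propagate(list(inst.root))
    if root is None:
        raise InconsistentInstanceError(
            f"instance unsatisfiable under repair {sorted(repaired)}"
        )
    witness = next(inst.solutions(list(root)), None)
    if witness is None:
        raise InconsistentInstanceError(
            f"instance unsatisfiable under repair {sorted(repaired)}"
        )
    out: dict[str, Sign | None] = {}
    observed = set(observations)
    for i, node in enumerate(inst.nodes):
        if node in observed:
            continue
        if root[i] in _BIT_TO_SIGN:  # singleton domain: entailed
            out[node] = sign_from_int(_BIT_TO_SIGN[root[i]])
            continue
        value = witness[i]
        decided: Sign | None = sign_from_int(value)
        for v in _SIGNS:
            if v == value or not root[i] & _BIT[v]:
                continue
            if inst.satisfiable(assume_idx=(i, v)):
                decided = None
                break
        out[node] = decided
    return out


def predict(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign] | ObservationSet,
    max_k: int = 3,
) -> tuple[PredictionMap, McosReport]:
    """The prediction function pred over all minimal repairs.

    Per repair set r, ``pred_r(x) = s`` iff every labeling consistent under
    r assigns s to x.  Across repair sets, a node is reported with sign s
    iff at least one repair scenario decides it as s and no scenario
    decides a different sign; scenarios leaving it undecided do not block.
    """
    observations = dict(observations)
    report = mcos(graph, observations, max_k=max_k)
    per_repair = [
        _predictions_under_repair(graph, observations, r) for r in report.repair_sets
    ]
    predictions: dict[str, Sign] = {}
    undecided: set[str] = set()
    observed = set(observations)
    for node in graph.node_ids():
        if node in observed:
            continue
        decided = {pr[node] for pr in per_repair if pr[node] is not None}
        if len(decided) == 1:
            predictions[node] = decided.pop()
        else:
            undecided.add(node)
    return PredictionMap(predictions=predictions, undecided=undecided), report


# ---------------------------------------------------------------------------
# Brute-force reference path (test oracle)
# ---------------------------------------------------------------------------

def brute_force_mcos(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign],
    max_k: int = 3,
    exhaustive_bound: int = 12,
) -> McosReport:
    """MCoS by exhaustive labeling enumeration over exhaustive subset search."""

    def sat(repaired: Iterable[str]) -> bool:
        return bool(
            enumerate_consistent(
                graph, observations, repaired, method="exhaustive",
                exhaustive_bound=exhaustive_bound,
            )
        )

    if sat(()):
        return McosReport(0, (frozenset(),))
    candidates = sorted(n for n in graph.node_ids() if graph.in_degree(n) > 0)
    for k in range(1, max_k + 1):
        found = [
            frozenset(c)
            for c in itertools.combinations(candidates, k)
            if sat(c)
        ]
        if found:
            return McosReport(k, tuple(sorted(found, key=sorted)))
    raise RepairLimitError(f"no repair of size <= {max_k} restores consistency")


def brute_force_predict(
    graph: SignedInteractionGraph,
    observations: Mapping[str, Sign],
    max_k: int = 3,
    exhaustive_bound: int = 12,
) -> tuple[PredictionMap, McosReport]:
    """Reference pred: full enumeration + literal application of the definition.

    Independent of the search solver; used to validate ``predict`` on small
    instances.
    """
    observations = dict(observations)
    report = brute_force_mcos(graph, observations, max_k, exhaustive_bound)
    observed = set(observations)
    per_repair: list[dict[str, Sign | None]] = []
    for r in report.repair_sets:
        labelings = enumerate_consistent(
            graph, observations, r, method="exhaustive", exhaustive_bound=exhaustive_bound
        )
        decided: dict[str, Sign | None] = {}
        for node in graph.node_ids():
            if node in observed:
                continue
            signs = {lab[node] for lab in labelings}
            decided[node] = signs.pop() if len(signs) == 1 else None
        per_repair.append(decided)
    predictions: dict[str, Sign] = {}
    undecided: set[str] = set()
    for node in graph.node_ids():
        if node in observed:
            continue
        decided_signs = {pr[node] for pr in per_repair if pr[node] is not None}
        if len(decided_signs) == 1:
            predictions[node] = decided_signs.pop()
        else:
            undecided.add(node)
    return PredictionMap(predictions=predictions, undecided=undecided), report
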