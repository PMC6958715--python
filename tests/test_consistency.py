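"""The inference core: consistency rules, enumeration, MCoS repair, predictions.

Expected values for the worked examples were computed with the brute-force
enumerator (``method="exhaustive"`` / ``brute_force_predict``), which stays
independent of the search solver it checks.
"""

import pytest

from conftest import make_graph, obs, random_observations, random_protein_graph
from signpred.consistency import (
    InconsistentInstanceError,
    RepairLimitError,
    brute_force_predict,
    count_candidate_labelings,
    enumerate_consistent,
    is_consistent_labeling,
    mcos,
    predict,
    sample_consistent_labeling,
    satisfiable,
)
from signpred.model import Sign, SignedInteractionGraph

P, M, Z = Sign.PLUS, Sign.MINUS, Sign.ZERO


# ---------------------------------------------------------------------------
# is_consistent_labeling
# ---------------------------------------------------------------------------

class TestConsistencyRules:
    def test_justified_activation_chain(self):
        g = make_graph([("A", "+", "B")])
        assert is_consistent_labeling(g, {"A": P, "B": P}, {"A": P})

    def test_unjustified_sign_rejected(self):
        g = make_graph([("A", "+", "B")])
        assert not is_consistent_labeling(g, {"A": P, "B": M})

    def test_zero_balanced_by_opposing_influences(self):
        g = make_graph([("A", "+", "C"), ("B", "-", "C")])
        assert is_consistent_labeling(g, {"A": P, "B": P, "C": Z})

    def test_zero_requires_balance_or_all_zero(self):
        g = make_graph([("A", "+", "B")])
        assert not is_consistent_labeling(g, {"A": P, "B": Z})
        assert is_consistent_labeling(g, {"A": Z, "B": Z})

    def test_observation_must_be_kept(self):
        g = make_graph([("A", "+", "B")])
        assert not is_consistent_labeling(g, {"A": P, "B": P}, {"A": M})

    def test_repaired_node_exempt_from_justification_not_observation(self):
        g = make_graph([("A", "+", "B")])
        assert is_consistent_labeling(g, {"A": P, "B": M}, repaired={"B"})
        assert not is_consistent_labeling(g, {"A": P, "B": M}, {"B": P}, repaired={"B"})

    def test_partial_labeling_rejected(self):
        g = make_graph([("A", "+", "B")])
        with pytest.raises(ValueError):
            is_consistent_labeling(g, {"A": P})

    def test_inhibitory_edge_from_plus_node_balances_zero(self):
        # rule 3 reads received influences, not raw predecessor labels
        g = make_graph([("A", "+", "C"), ("A2", "-", "C")])
        assert is_consistent_labeling(g, {"A": P, "A2": P, "C": Z})


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["search", "exhaustive"])
class TestEnumeration:
    def test_chain_has_unique_labeling(self, method):
        g = make_graph([("A", "+", "B"), ("B", "+", "C")])
        labelings = enumerate_consistent(g, obs(A="+"), method=method)
        assert labelings == [{"A": P, "B": P, "C": P}]

    def test_edgeless_nodes_are_unconstrained(self, method):
        g = SignedInteractionGraph()
        g.add_node("A")
        g.add_node("B")
        assert len(enumerate_consistent(g, method=method)) == 9

    def test_fork_admits_three_labelings(self, method):
        g = make_graph([("A", "+", "C"), ("B", "-", "C")])
        labelings = enumerate_consistent(g, obs(A="+", B="+"), method=method)
        assert [lab["C"] for lab in labelings] == [P, M, Z]

    def test_empty_result_signals_inconsistency(self, method):
        g = make_graph([("A", "+", "B")])
        assert enumerate_consistent(g, obs(A="+", B="-"), method=method) == []


def test_candidate_space_of_two_free_nodes_is_nine():
    g = make_graph([("A", "+", "C"), ("B", "-", "C"), ("C", "+", "D")])
    assert count_candidate_labelings(g, obs(A="+", B="+")) == 3**2


def test_exhaustive_enumeration_is_bounded():
    g = random_protein_graph(__import__("numpy").random.default_rng(0), 13)
    with pytest.raises(ValueError):
        enumerate_consistent(g, method="exhaustive", exhaustive_bound=12)


# ---------------------------------------------------------------------------
# MCoS
# ---------------------------------------------------------------------------

class TestMcos:
    def test_consistent_instance_needs_no_repair(self):
        g = make_graph([("A", "+", "B")])
        report = mcos(g, obs(A="+", B="+"))
        assert report.k == 0 and report.repair_sets == (frozenset(),)

    def test_single_conflict_repaired_at_the_conflicting_node(self):
        g = make_graph([("A", "+", "B")])
        report = mcos(g, obs(A="+", B="-"))
        assert report.k == 1
        assert frozenset({"B"}) in report.repair_sets

    def test_repair_sets_are_minimal(self):
        # every reported set restores satisfiability and no proper subset does
        g = make_graph([("A", "+", "B"), ("A", "+", "C")])
        report = mcos(g, obs(A="+", B="-", C="-"))
        assert report.k == 2
        for repair in report.repair_sets:
            assert satisfiable(g, obs(A="+", B="-", C="-"), repaired=repair)
            for node in repair:
                assert not satisfiable(g, obs(A="+", B="-", C="-"), repaired=repair - {node})

    def test_repair_cap(self):
        g = make_graph([("A", "+", "B"), ("A", "+", "C")])
        with pytest.raises(RepairLimitError):
            mcos(g, obs(A="+", B="-", C="-"), max_k=1)


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------

class TestPredict:
    def test_chain_propagates_downstream(self):
        g = make_graph([("A", "+", "B"), ("B", "+", "C")])
        pm, report = predict(g, obs(A="+"))
        assert report.k == 0
        assert pm.predictions == {"B": P, "C": P}

    def test_opposing_influences_leave_target_undecided(self):
        g = make_graph([("A", "+", "C"), ("B", "-", "C")])
        pm, _ = predict(g, obs(A="+", B="+"))
        assert pm.predictions == {} and pm.undecided == {"C"}

    def test_inhibition_flips_the_sign(self):
        g = make_graph([("A", "-", "B")])
        pm, _ = predict(g, obs(A="+"))
        assert pm.predictions == {"B": M}

    def test_observed_nodes_are_excluded_from_predictions(self):
        g = make_graph([("A", "+", "B")])
        pm, _ = predict(g, obs(A="+", B="+"))
        assert "A" not in pm.predictions and "B" not in pm.predictions

    def test_breakdown_counts_by_sign_and_kind(self):
        g = make_graph(
            [("A_gen", "+", "A_prot"), ("A_prot", "-", "B_gen"), ("B_gen", "+", "B_prot")]
        )
        pm, _ = predict(g, obs(A_gen="+"))
        from signpred.model import NodeKind

        assert pm.breakdown == {
            (P, NodeKind.PROTEIN): 1,
            (M, NodeKind.GENE): 1,
            (M, NodeKind.PROTEIN): 1,
        }

    def test_conflicting_repair_scenarios_cancel(self, fixtures):
        fx = fixtures["two_source_inconsistent"]
        pm, report = predict(fx.graph, fx.observations)
        assert report.repair_sets == fx.expected_repairs
        assert pm.predictions == {}
        assert "C_prot" in pm.undecided


@pytest.mark.parametrize("name", [
    "chain", "inhibitor_chain", "fork", "cycle", "complex_toy",
    "two_source_consistent", "two_source_inconsistent", "insight_motif",
])
def test_fixture_motifs_match_oracle_and_expectations(fixtures, name):
    fx = fixtures[name]
    pm, report = predict(fx.graph, fx.observations)
    bm, brep = brute_force_predict(fx.graph, fx.observations)
    assert report.k == brep.k == fx.expected_k
    assert pm.predictions == bm.predictions == fx.expected_predictions
    assert pm.undecided == bm.undecided
    if fx.expected_repairs is not None:
        assert report.repair_sets == brep.repair_sets == fx.expected_repairs


# ---------------------------------------------------------------------------
# properties (seeded batteries; the full-size runs live in the acceptance suite)
# ---------------------------------------------------------------------------

def test_search_agrees_with_exhaustive_on_random_graphs(rng):
    for _ in range(100):
        g = random_protein_graph(rng, int(rng.integers(3, 8)))
        observations = random_observations(rng, g, int(rng.integers(1, 3)))
        a = enumerate_consistent(g, observations, method="search")
        b = enumerate_consistent(g, observations, method="exhaustive")
        assert a == b


def test_labelings_restate_observations(rng):
    for _ in range(30):
        g = random_protein_graph(rng, int(rng.integers(3, 7)))
        observations = random_observations(rng, g, 2)
        for lab in enumerate_consistent(g, observations, method="search"):
            assert all(lab[n] is s for n, s in observations.items())


def test_removing_an_observation_never_shrinks_the_labeling_set(rng):
    for _ in range(30):
        g = random_protein_graph(rng, int(rng.integers(3, 7)))
        observations = random_observations(rng, g, 2)
        full = enumerate_consistent(g, observations, method="search")
        node = next(iter(observations))
        relaxed = enumerate_consistent(
            g, observations.restricted_to(set(observations) - {node}), method="search"
        )
        as_sets = lambda labs: {tuple(sorted((k, v.value) for k, v in l.items())) for l in labs}
        assert as_sets(full) <= as_sets(relaxed)


def test_predictions_independent_of_construction_order(rng):
    edges = [("C", "+", "A"), ("A", "-", "B"), ("D", "+", "A"), ("B", "+", "E")]
    observations = obs(C="+", D="+")
    maps = []
    for _ in range(5):
        shuffled = list(edges)
        rng.shuffle(shuffled)
        pm, _ = predict(make_graph(shuffled), observations)
        maps.append((sorted(pm.predictions.items(), key=str), sorted(pm.undecided)))
    assert all(m == maps[0] for m in maps)


def test_sample_consistent_labeling_raises_on_contradiction():
    g = make_graph([("A", "+", "B")])
    with pytest.raises(InconsistentInstanceError):
        sample_consistent_labeling(g, obs(A="+", B="-"))
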