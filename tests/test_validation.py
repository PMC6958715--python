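"""Subsampling plans, precision scoring, stability classes, and the study loop."""

import numpy as np
import pytest

from signpred.consistency import PredictionMap
from signpred.model import ObservationSet, Sign
from signpred.synthetic import plant_consistent_labeling, random_signed_graph, reveal_observations
from signpred.validation import (
    PrecisionUndefinedError,
    SamplingPlan,
    StabilityCounts,
    precision_score,
    run_sampling_study,
    sample_observations,
    stability_classify,
    summarize,
    export_report,
)

P, M, Z = Sign.PLUS, Sign.MINUS, Sign.ZERO


def pmap(predictions, undecided=()):
    return PredictionMap(
        predictions={k: Sign.from_str(v) for k, v in predictions.items()},
        undecided=set(undecided),
    )


class TestSamplingPlan:
    def test_default_plan_is_18_fractions_by_100_replicates(self):
        plan = SamplingPlan()
        assert plan.fractions == tuple(range(10, 100, 5))
        assert plan.n_experiments == 1800

    @pytest.mark.parametrize("fractions", [(0, 50), (50, 100), (50, 40), (50, 50)])
    def test_invalid_fraction_lists_rejected(self, fractions):
        with pytest.raises(ValueError):
            SamplingPlan(fractions=fractions)

    def test_experiment_seeds_are_unique_and_order_free(self):
        plan = SamplingPlan(fractions=(10, 50), replicates=3, seed=7)
        seeds = [tuple(s) for _, _, s in plan.iter_experiments()]
        assert len(seeds) == len(set(seeds)) == 6


class TestSampleObservations:
    def setup_method(self):
        self.obs = ObservationSet(
            {f"U{i}_gen": P for i in range(10)} | {f"D{i}_gen": M for i in range(10)}
        )

    def test_half_sampling_is_stratified_five_and_five(self):
        sub = sample_observations(self.obs, 50, seed=1)
        assert len(sub.by_sign(P)) == 5 and len(sub.by_sign(M)) == 5

    def test_same_seed_same_subset(self):
        assert dict(sample_observations(self.obs, 35, seed=9)) == dict(
            sample_observations(self.obs, 35, seed=9)
        )

    def test_subset_of_original_and_round_half_up(self):
        sub = sample_observations(self.obs, 25, seed=2)
        assert set(sub) <= set(self.obs)
        # 25% of 10 = 2.5 -> 3 per stratum under round-half-up
        assert len(sub.by_sign(P)) == 3 and len(sub.by_sign(M)) == 3

    def test_tiny_fraction_may_empty_a_stratum(self):
        small = ObservationSet({"A_gen": P, "B_gen": M, "C_gen": M})
        sub = sample_observations(small, 10, seed=0)
        assert len(sub.by_sign(P)) == 0 and len(sub.by_sign(M)) == 0

    @pytest.mark.parametrize("fraction", [0, 100, -5])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ValueError):
            sample_observations(self.obs, fraction, seed=0)


class TestPrecision:
    def test_matching_ratio(self):
        predictions = pmap(
            {f"A{i}_prot": "+" for i in range(7)}  # matching: fc > 0
            | {f"B{i}_prot": "+" for i in range(3)}  # not matching: fc < 0
        )
        fc = {f"A{i}": 1.0 for i in range(7)} | {f"B{i}": -1.0 for i in range(3)}
        result = precision_score(predictions, fc)
        assert (result.m, result.t) == (7, 10)
        assert result.score == pytest.approx(0.7)

    def test_minus_predictions_match_negative_foldchanges(self):
        result = precision_score(pmap({"X_gen": "-"}), {"X": -2.0})
        assert (result.m, result.t) == (1, 1)

    def test_complexes_and_unmeasured_symbols_excluded_from_t(self):
        predictions = pmap({"A_prot::B_prot": "+", "C_prot": "+", "D_prot": "+"})
        result = precision_score(predictions, {"A": 1.0, "B": 1.0, "C": 1.0})
        assert result.t == 1  # only C maps to a measured gene

    def test_zero_predictions_reported_separately(self):
        result = precision_score(pmap({"A_prot": "0", "B_prot": "+"}), {"A": 1.0, "B": 2.0})
        assert (result.t, result.n_zero) == (1, 1)

    def test_undefined_when_nothing_comparable(self):
        with pytest.raises(PrecisionUndefinedError):
            precision_score(pmap({"A_prot::B_prot": "+"}), {"A": 1.0})


class TestStability:
    def test_identical_maps_are_all_good(self):
        ref = pmap({"X": "+", "Y": "-"})
        counts = stability_classify(ref, ref)
        assert (counts.good, counts.bad, counts.missing) == (2, 0, 0)

    def test_empty_sub_run_is_all_missing(self):
        ref = pmap({"X": "+", "Y": "-"})
        counts = stability_classify(ref, pmap({}))
        assert (counts.good, counts.bad, counts.missing) == (0, 0, 2)

    def test_sign_flip_counts_as_bad(self):
        counts = stability_classify(pmap({"X": "+", "Y": "-"}), pmap({"X": "-"}))
        assert (counts.good, counts.bad, counts.missing) == (0, 1, 1)

    def test_counts_conserve_reference_size(self):
        ref = pmap({"X": "+", "Y": "-", "Z": "0"})
        counts = stability_classify(ref, pmap({"X": "+", "Z": "-", "W": "+"}))
        assert counts.total == 3

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            stability_classify(pmap({}), pmap({}))


@pytest.fixture(scope="module")
def small_study():
    graph = random_signed_graph(n_genes=10, edge_density=0.1, complex_count=2, seed=5)
    labeling = plant_consistent_labeling(graph, seed=6)
    observations = reveal_observations(labeling, graph, fraction=90, seed=7)
    foldchanges = {
        node.removesuffix("_gen"): 1.5 * labeling[node].to_int()
        for node in labeling
        if node.endswith("_gen") and labeling[node] is not Z
    }
    plan = SamplingPlan(fractions=(20, 50, 80), replicates=4, seed=11)
    df = run_sampling_study(graph, observations, foldchanges, plan)
    return df, plan


class TestStudy:
    def test_row_count_and_reference_row(self, small_study):
        df, plan = small_study
        assert len(df) == plan.n_experiments + 1
        ref = df[df.fraction == 100]
        assert len(ref) == 1
        assert (ref.good == ref.n_predictions).all()

    def test_conservation_on_every_row(self, small_study):
        df, _ = small_study
        n_ref = df.loc[df.fraction == 100, "n_predictions"].iloc[0]
        assert ((df.good + df.bad + df.missing) == n_ref).all()

    def test_score_is_m_over_t(self, small_study):
        df, _ = small_study
        valid = df[df.t > 0]
        assert np.allclose(valid.s, valid.m / valid.t)

    def test_stratification_preserved_in_observation_counts(self, small_study):
        df, _ = small_study
        assert (df.n_observations <= df.loc[df.fraction == 100, "n_observations"].iloc[0]).all()

    def test_summary_and_report_files(self, small_study, tmp_path):
        df, _ = small_study
        stats = summarize(df)
        assert ("s", "median") in stats.columns
        paths = export_report(df, tmp_path)
        for p in paths.values():
            assert (tmp_path / p.split("/")[-1]).exists()
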