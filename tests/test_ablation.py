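import itertools
import math

import numpy as np
import pytest

from nemablate import (
    AblationStudy,
    Connectome,
    count_candidate_sets,
    expected_reduction,
    iter_candidate_sets,
    make_planted_connectome,
    summarize,
)


def conn(neurons, muscles, edges):
    kinds = {n: "neuron" for n in neurons} | {m: "muscle" for m in muscles}
    return Connectome.from_records(
        [(p, q, e, 1) for p, q, e in edges], cell_kinds=kinds, use_name_rule=False
    )


class TestEnumeration:
    def test_candidate_counts_match_whole_connectome(self):
        assert count_candidate_sets(279, 2) == 38_781
        assert count_candidate_sets(279, 3) == 3_580_779

    def test_enumerator_agrees_with_binomial_and_is_sorted(self):
        names = [f"N{i}" for i in range(7)]
        for order in (1, 2, 3):
            sets = list(iter_candidate_sets(names, order))
            assert len(sets) == math.comb(7, order)
            assert sets == sorted(sets)
            assert len(set(sets)) == len(sets)


class TestExpectedReduction:
    def test_sum_of_singles(self):
        assert expected_reduction(["a", "b", "c"], {"a": 1, "b": 0, "c": 0}) == 1

    def test_pair_excess_counts_once(self):
        singles = {"a": 0, "b": 0, "c": 0}
        pairs = {frozenset(("a", "b")): 1}
        assert expected_reduction(["a", "b", "c"], singles, pairs) == 1

    def test_two_singles_without_excess(self):
        singles = {"a": 1, "b": 1, "c": 0}
        assert expected_reduction(["a", "b", "c"], singles, {}) == 2

    def test_capped_at_baseline(self):
        singles = {"a": 2, "b": 2}
        assert expected_reduction(["a", "b"], singles, cap=3) == 3


class TestGroupFixtureScans:
    def test_group1_full_taxonomy(self, group1):
        study = AblationStudy(group1.connectome, {"drive": list(group1.inputs)}, seed=5)
        singles = study.single_scan()
        assert summarize(singles, 1)["classes"]["essential_single"] == 0
        pairs = study.pair_scan(singles)
        s2 = summarize(pairs, 2)
        assert s2["classes"]["synthetic_essential_pair"] == 0
        assert s2["classes"]["no_effect"] == 15
        triples = study.triple_scan(singles, pairs)
        s3 = summarize(triples, 3)
        assert s3["classes"]["synthetic_essential_triplet"] == 20
        # synthetic essentiality is its own category, not a negative interaction
        assert s3["negative_interactions"] == 0

    def test_group2_counts(self, group2):
        study = AblationStudy(group2.connectome, {"drive": list(group2.inputs)}, seed=5)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        triples = study.triple_scan(singles, pairs)
        assert summarize(triples, 3)["classes"]["synthetic_essential_triplet"] == 4

    def test_class_counts_conserve_totals(self, group1):
        study = AblationStudy(group1.connectome, {"drive": list(group1.inputs)}, seed=5)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        triples = study.triple_scan(singles, pairs)
        for results, order in ((pairs, 2), (triples, 3)):
            s = summarize(results, order)
            assert sum(s["classes"].values()) + s["trivial_excluded"] == count_candidate_sets(6, order)

    def test_superset_reduces_at_least_as_much(self, group1):
        study = AblationStudy(group1.connectome, {"drive": list(group1.inputs)}, seed=5)
        neurons = sorted(group1.connectome.neurons)
        for pair in itertools.combinations(neurons[:4], 2):
            for extra in neurons[4:]:
                small = study.evaluate(pair).observed_reduction
                big = study.evaluate(set(pair) | {extra}).observed_reduction
                assert big >= small


class TestTrivialExclusion:
    def test_input_pair_is_trivial_for_its_scenario(self):
        """A set containing every input of a scenario (here the posterior
        pair) is excluded from headline counts even when another scenario
        still receives signals."""
        neurons = ["PLML", "PLMR", "ALML", "AVM", "X1", "X2"]
        muscles = ["MU1", "MU2"]
        edges = [(n, m, "nmj") for n in ("X1", "X2") for m in muscles]
        edges += [(s, x, "chemical") for s in ("PLML", "PLMR", "ALML", "AVM")
                  for x in ("X1", "X2")]
        c = conn(neurons, muscles, edges)
        scenarios = {"anterior": ["ALML", "AVM"], "posterior": ["PLML", "PLMR"]}
        study = AblationStudy(c, scenarios, seed=2)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        rec, _cls = pairs[frozenset(("PLML", "PLMR"))]
        assert rec.trivial_scenarios == {"posterior"}
        assert rec.trivial
        s2 = summarize(pairs, 2)
        # the posterior input pair and the anterior input pair
        assert s2["trivial_excluded"] == 2

    def test_single_input_ablation_trivial_for_chain(self, toy_chain):
        study = AblationStudy(toy_chain, {"drive": ["a"]}, seed=0)
        singles = study.single_scan()
        rec, cls = singles["a"]
        assert rec.trivial
        assert summarize(singles, 1)["trivial_excluded"] == 1


def _two_group_network(b_sources):
    """Muscle group A (A1, A2) is fed only by X and P; muscle group B
    (B1, B2) is fed by two relay neurons u, v, which receive signals from
    ``b_sources``.  Removing X alone costs one muscle of group A; group B
    only suffers once the surviving sources drop below two."""
    neurons = ["X", "P", "u", "v"] + [s for s in b_sources if s not in ("X",)]
    muscles = ["A1", "A2", "B1", "B2"]
    edges = [(n, m, "nmj") for n in ("X", "P") for m in ("A1", "A2")]
    edges += [(s, r, "chemical") for s in b_sources for r in ("u", "v")]
    edges += [(r, m, "nmj") for r in ("u", "v") for m in ("B1", "B2")]
    c = conn(neurons, muscles, edges)
    inputs = ["X", "P"] + [s for s in b_sources if s != "X"]
    return c, inputs


class TestNegativeInteractions:
    def test_en_pair_with_negative_interaction(self):
        """An individually essential neuron plus a nonessential partner can
        lose two muscles where the single effects only explain one."""
        c, inputs = _two_group_network(("X", "Y", "D"))
        study = AblationStudy(c, {"drive": inputs}, seed=3)
        assert study.baseline == {"drive": 4}
        singles = study.single_scan()
        assert singles["X"][1].label == "essential_single"
        assert singles["Y"][1].label == "no_effect"
        pairs = study.pair_scan(singles)
        rec, cls = pairs[frozenset(("X", "Y"))]
        assert rec.observed_reduction == 2
        assert cls.label == "EN_pair"
        assert cls.expected_reduction == 1
        assert cls.negative_interaction

    def test_triple_level_negative_interaction_with_one_essential(self):
        """With four signal sources behind group B, no pair shows excess
        loss, yet removing three sources leaves a single signal: the triple
        loses two muscles with only one essential member."""
        c, inputs = _two_group_network(("X", "Y", "Z", "D"))
        study = AblationStudy(c, {"drive": inputs}, seed=3)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        for other in ("Y", "Z", "D"):
            assert singles[other][1].label == "no_effect"
            assert not pairs[frozenset(("X", other))][1].negative_interaction
        triples = study.triple_scan(singles, pairs)
        rec, cls = triples[frozenset(("X", "Y", "Z"))]
        assert rec.observed_reduction == 2
        assert cls.label == "triple_ENN"
        assert cls.expected_reduction == 1
        assert cls.negative_interaction


class TestPlantedRecovery:
    def test_zero_background_recovery_is_exact(self):
        c, truth = make_planted_connectome(12, 6, [(6, 4)], density=0.0, seed=11)
        study = AblationStudy(c, {"drive": list(truth.inputs)}, seed=11)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        triples = study.triple_scan(singles, pairs)
        found = {
            key for key, (_r, cls) in triples.items()
            if cls.label == "synthetic_essential_triplet"
        }
        assert found == set(truth.synthetic_triplets)
        assert len(found) == 20
        assert not any(
            cls.label == "synthetic_essential_pair" for _r, cls in pairs.values()
        )

    def test_small_bottleneck_recovery(self):
        c, truth = make_planted_connectome(9, 3, [(4, 2)], density=0.0, seed=7)
        study = AblationStudy(c, {"drive": list(truth.inputs)}, seed=7)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        triples = study.triple_scan(singles, pairs)
        found = {
            key for key, (_r, cls) in triples.items()
            if cls.label == "synthetic_essential_triplet"
        }
        assert found == set(truth.synthetic_triplets)
        assert len(found) == 4

    def test_noisy_background_recovers_superset(self):
        c, truth = make_planted_connectome(10, 3, [(4, 2)], density=0.08, seed=13)
        study = AblationStudy(c, {"drive": list(truth.inputs)}, seed=13)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        triples = study.triple_scan(singles, pairs)
        reducing = {key for key, (rec, _c) in triples.items() if rec.reducing}
        assert set(truth.synthetic_triplets) <= reducing
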