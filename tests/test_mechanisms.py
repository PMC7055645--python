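import itertools

import networkx as nx
import numpy as np
import pytest

from nemablate import (
    AblationStudy,
    Connectome,
    assign_layers,
    classify_pair_mechanism,
    cooccurrence_network,
    group_triplets,
    make_motif,
    muscle_loss_profile,
)
from nemablate.control import stable_seed
from conftest import random_connectome


class TestLayers:
    def test_motif_layers(self):
        m = make_motif("mechanism_m2")
        layers = assign_layers(m.connectome)
        assert layers["MU01"] == 0 and layers["MU02"] == 0
        assert layers["N1A"] == 1 and layers["N1B"] == 1
        assert all(layers[z] == 2 for z in ("N2A", "N2B", "N2C"))

    def test_isolated_neuron_unreachable(self):
        c = Connectome.from_records(
            [("a", "m1", "nmj", 1)],
            cell_kinds={"a": "neuron", "m1": "muscle", "lone": "neuron"},
            use_name_rule=False,
        )
        assert assign_layers(c)["lone"] is None

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_shortest_paths(self, seed):
        c, _ = random_connectome(np.random.default_rng(3000 + seed))
        layers = assign_layers(c)
        g = c.to_digraph()
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        for name in c.cells:
            expected = min(
                (lengths[name][m] for m in c.muscles if m in lengths.get(name, {})),
                default=None,
            )
            assert layers[name] == expected


class TestPairMechanisms:
    def test_named_motif_pairs(self):
        m1 = make_motif("mechanism_m1")
        layers = assign_layers(m1.connectome)
        assert classify_pair_mechanism(("N1A", "N1B"), layers).mechanism == "M1"
        m2 = make_motif("mechanism_m2")
        layers = assign_layers(m2.connectome)
        assert classify_pair_mechanism(("N2A", "N2B"), layers).mechanism == "M2"
        m3 = make_motif("mechanism_m3")
        layers = assign_layers(m3.connectome)
        assert classify_pair_mechanism(("N1A", "N2B"), layers).mechanism == "M3"

    def test_unreachable_member_is_other(self):
        c = Connectome.from_records(
            [("a", "m1", "nmj", 1)],
            cell_kinds={"a": "neuron", "m1": "muscle", "lone": "neuron"},
            use_name_rule=False,
        )
        layers = assign_layers(c)
        assert classify_pair_mechanism(("a", "lone"), layers).mechanism == "other"

    def test_pair_size_validated(self):
        with pytest.raises(ValueError):
            classify_pair_mechanism(("a",), {"a": 1})

    def test_m1_motif_scan_finds_the_split_pairs(self):
        """The Layer-1 groups relaying one signal each are exactly the
        synthetic essential pairs, both classified Mechanism 1."""
        m = make_motif("mechanism_m1")
        study = AblationStudy(m.connectome, {"drive": list(m.inputs)}, seed=4)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        synthetic = {
            key for key, (_r, cls) in pairs.items()
            if cls.label == "synthetic_essential_pair"
        }
        assert synthetic == {frozenset(("N1A", "N1B")), frozenset(("N1C", "N1D"))}
        layers = assign_layers(m.connectome)
        assert all(
            classify_pair_mechanism(p, layers).mechanism == "M1" for p in synthetic
        )

    def test_m2_motif_scan_finds_layer2_pairs(self):
        m = make_motif("mechanism_m2")
        study = AblationStudy(m.connectome, {"drive": list(m.inputs)}, seed=4)
        singles = study.single_scan()
        pairs = study.pair_scan(singles)
        synthetic = {
            key for key, (_r, cls) in pairs.items()
            if cls.label == "synthetic_essential_pair"
        }
        assert synthetic == {
            frozenset(p) for p in itertools.combinations(("N2A", "N2B", "N2C"), 2)
        }
        layers = assign_layers(m.connectome)
        assert all(
            classify_pair_mechanism(p, layers).mechanism == "M2" for p in synthetic
        )


def _profiles(motif, triplets, orderings=300, seed=0):
    return {
        t: muscle_loss_profile(
            motif.connectome, t, motif.inputs, orderings=orderings,
            seed=stable_seed(seed, *sorted(t)),
        )
        for t in triplets
    }


class TestTripletGroups:
    def test_group1_is_one_complete_group(self, group1):
        triplets = [frozenset(t) for t in itertools.combinations(group1.connectome.neurons, 3)]
        reports = group_triplets(group1.connectome, triplets, _profiles(group1, triplets))
        assert len(reports) == 20
        assert {r.group for r in reports} == {"G1"}
        assert all(r.complete_group for r in reports)
        assert all(
            r.affected_muscles == frozenset(("MDL09", "MDR09", "MDL10", "MDR10"))
            for r in reports
        )
        assert all(r.disconnects == frozenset() for r in reports)

    def test_group2_affected_muscles(self, group2):
        triplets = [frozenset(t) for t in itertools.combinations(group2.connectome.neurons, 3)]
        reports = group_triplets(group2.connectome, triplets, _profiles(group2, triplets))
        assert len(reports) == 4
        assert all(r.affected_muscles == frozenset(("MVL09", "MVR09")) for r in reports)
        assert all(r.complete_group for r in reports)

    def test_disconnection_flagged(self):
        """Ablating all three exclusive innervators of a muscle severs it
        from the network entirely."""
        m = make_motif("group3")
        triple = frozenset(("SMBDL", "SMDDL", "SMDDR"))
        profiles = _profiles(m, [triple], orderings=100)
        reports = group_triplets(m.connectome, [triple], profiles)
        assert reports[0].affected_muscles == frozenset(("MDR06",))
        assert reports[0].disconnects == frozenset(("MDR06",))

    def test_incomplete_partition_stays_ungrouped(self, group1):
        triplets = [frozenset(t) for t in itertools.combinations(group1.connectome.neurons, 3)]
        subset = triplets[:5]  # missing members of the C(6,3) family
        reports = group_triplets(group1.connectome, subset, _profiles(group1, subset))
        assert {r.group for r in reports} == {"ungrouped"}


class TestCooccurrence:
    def test_single_pair(self):
        g = cooccurrence_network([("a", "b")])
        assert set(g.edges) == {("a", "b")}
        assert g["a"]["b"]["weight"] == 1

    def test_group1_triplets_form_weighted_clique(self, group1):
        triplets = list(itertools.combinations(group1.connectome.neurons, 3))
        g = cooccurrence_network(triplets)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 15
        # each pair of neurons co-occurs with any one of the 4 remaining
        assert {d["weight"] for _u, _v, d in g.edges(data=True)} == {4}

    def test_empty_input(self):
        g = cooccurrence_network([])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0
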