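"""Generators for motif fixtures and planted-ground-truth connectomes.

The motifs reproduce, as standalone wiring diagrams, the layered
neuron-to-muscle bottlenecks that drive synthetic essentiality: small
groups of muscles whose only neuromuscular input comes from a small,
exclusive set of neurons.  Upstream drive is modeled directly as input
columns on the top layer (no artificial sensory chains), so each motif
comes with its canonical input set.

The planted generators embed such bottlenecks in a random background
network with known ground truth, so scan recovery can be tested exactly on
zero-noise instances and conservatively (recovered ⊇ planted) on noisy
ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .connectome import Connectome

GROUP1_NEURONS = ("AS03", "DA02", "DA03", "DB02", "DD01", "DD02")
GROUP1_MUSCLES = ("MDL09", "MDR09", "MDL10", "MDR10")
GROUP2_NEURONS = ("PVNL", "VA03", "VB02", "VD03")
GROUP2_MUSCLES = ("MVL09", "MVR09")
GROUP3_NEURONS = ("SMBDL", "SMDDL", "SMDDR")
GROUP3_MUSCLES = ("MDR06",)
VA_PAIR_NEURONS = ("VA09", "VA10", "VB08", "VD09")
VA_PAIR_MUSCLES = ("MVL18", "MVR18")

WIRINGS = (
    "complete_bipartite",
    "mechanism_m1",
    "mechanism_m2",
    "mechanism_m3",
    "group1",
    "group2",
    "group3",
    "va_pair_subnetwork",
)


@dataclass(frozen=True)
class MotifSpec:
    """Named wiring plus optional layer sizes for the generic motif."""

    wiring: str
    layer_sizes: Optional[tuple[int, ...]] = None
    input_mode: str = "drive_top_layer"


@dataclass(frozen=True)
class Motif:
    """A motif connectome together with its canonical input set."""

    name: str
    connectome: Connectome
    inputs: tuple[str, ...]


def _build(records, kinds, name, inputs) -> Motif:
    c = Connectome.from_records(
        records, cell_kinds=kinds, use_name_rule=False, provenance=f"motif:{name}"
    )
    return Motif(name, c, tuple(inputs))


def _bottleneck_motif(name: str, neurons: Sequence[str], muscles: Sequence[str]) -> Motif:
    """Independently driven neurons, complete bipartite NMJs to muscles.

    Complete wiring within the bottleneck makes the "any three" loss
    property exact: only the counts of surviving independent signals and of
    exclusively fed muscles matter for the generic rank.
    """
    kinds = {n: "neuron" for n in neurons} | {m: "muscle" for m in muscles}
    records = [(n, m, "nmj", 1) for n in neurons for m in muscles]
    return _build(records, kinds, name, neurons)


def make_motif(spec: MotifSpec | str) -> Motif:
    """Build a documented motif fixture; deterministic for a given spec."""
    if isinstance(spec, str):
        spec = MotifSpec(spec)
    w = spec.wiring
    if w == "group1":
        return _bottleneck_motif(w, GROUP1_NEURONS, GROUP1_MUSCLES)
    if w == "group2":
        return _bottleneck_motif(w, GROUP2_NEURONS, GROUP2_MUSCLES)
    if w == "group3":
        return _bottleneck_motif(w, GROUP3_NEURONS, GROUP3_MUSCLES)
    if w == "complete_bipartite":
        if not spec.layer_sizes or len(spec.layer_sizes) != 2:
            raise ValueError("complete_bipartite needs layer_sizes=(n_neurons, n_muscles)")
        n1, n0 = spec.layer_sizes
        neurons = tuple(f"N1{chr(65 + i)}" for i in range(n1))
        muscles = tuple(f"MU{i + 1:02d}" for i in range(n0))
        return _bottleneck_motif(w, neurons, muscles)
    if w == "va_pair_subnetwork":
        # MVL18/MVR18 are fed only by VA09, VA10, VB08 and VD09, which in
        # turn receive three independent upstream control signals: one each
        # for VA09 and VA10, one shared by VB08 and VD09.
        drivers = ("DRV01", "DRV02", "DRV03")
        kinds = (
            {d: "neuron" for d in drivers}
            | {n: "neuron" for n in VA_PAIR_NEURONS}
            | {m: "muscle" for m in VA_PAIR_MUSCLES}
        )
        records = [
            ("DRV01", "VA09", "chemical", 1),
            ("DRV02", "VA10", "chemical", 1),
            ("DRV03", "VB08", "chemical", 1),
            ("DRV03", "VD09", "chemical", 1),
        ] + [(n, m, "nmj", 1) for n in VA_PAIR_NEURONS for m in VA_PAIR_MUSCLES]
        return _build(records, kinds, w, drivers)
    if w == "mechanism_m1":
        # two Layer 2 drivers, four Layer 1 neurons split into two groups,
        # two muscles; removing one whole Layer-1 group cuts one signal
        l2 = ("N2A", "N2B")
        l1 = ("N1A", "N1B", "N1C", "N1D")
        mus = ("MU01", "MU02")
        kinds = {n: "neuron" for n in l2 + l1} | {m: "muscle" for m in mus}
        records = [
            ("N2A", "N1A", "chemical", 1),
            ("N2A", "N1B", "chemical", 1),
            ("N2B", "N1C", "chemical", 1),
            ("N2B", "N1D", "chemical", 1),
        ] + [(n, m, "nmj", 1) for n in l1 for m in mus]
        return _build(records, kinds, w, l2)
    if w == "mechanism_m2":
        # three Layer 2 drivers feeding two Layer 1 neurons and two muscles;
        # removing two Layer-2 drivers leaves a single signal
        l2 = ("N2A", "N2B", "N2C")
        l1 = ("N1A", "N1B")
        mus = ("MU01", "MU02")
        kinds = {n: "neuron" for n in l2 + l1} | {m: "muscle" for m in mus}
        records = [(z, n, "chemical", 1) for z in l2 for n in l1]
        records += [(n, m, "nmj", 1) for n in l1 for m in mus]
        return _build(records, kinds, w, l2)
    if w == "mechanism_m3":
        # three Layer 1 neurons over two muscles; two carry signals relayed
        # by Layer 2 drivers, the third is driven directly, so three
        # independent signals reach Layer 1 and pairs of one Layer-1 and
        # one Layer-2 cell reduce them to a single signal
        l2 = ("N2A", "N2B")
        l1 = ("N1A", "N1B", "N1C")
        mus = ("MU01", "MU02")
        kinds = {n: "neuron" for n in l2 + l1} | {m: "muscle" for m in mus}
        records = [
            ("N2A", "N1A", "chemical", 1),
            ("N2B", "N1B", "chemical", 1),
        ] + [(n, m, "nmj", 1) for n in l1 for m in mus]
        return _build(records, kinds, w, ("N2A", "N2B", "N1C"))
    raise ValueError(f"unknown wiring {spec.wiring!r}")


# ----------------------------------------------------------------------
# planted-ground-truth connectomes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth shipped with a generated connectome."""

    inputs: tuple[str, ...]
    synthetic_triplets: tuple[frozenset, ...] = ()
    synthetic_pairs: tuple[frozenset, ...] = ()
    pair_mechanisms: Optional[dict] = None
    bottlenecks: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()


def make_planted_connectome(
    n_neurons: int,
    n_muscles: int,
    bottlenecks: Sequence[tuple[int, int]],
    density: float = 0.0,
    seed: int = 0,
) -> tuple[Connectome, PlantedTruth]:
    """Random background plus exclusive (k, k-2) neuron→muscle bottlenecks.

    Each bottleneck wires k dedicated neurons, all externally driven,
    complete-bipartite onto k-2 muscles that receive no other input: any 3
    of the k neurons then leave at most k-3 independent signals for k-2
    muscles, so exactly C(k, 3) synthetic essential triplets are planted
    per bottleneck.  Background muscles are fed by all background neurons
    (also driven), which keeps them controllable under any triple ablation
    provided there are at least three more background neurons than
    background muscles.  ``density`` adds random neuron→neuron chemical
    edges, which cannot undo a planted bottleneck (the muscle exclusivity
    bounds the rank by the number of surviving bottleneck neurons).
    """
    rng = np.random.default_rng(seed)
    for k, m in bottlenecks:
        if k < 3:
            raise ValueError("bottleneck needs k >= 3")
        if m != k - 2:
            raise ValueError(f"bottleneck must be (k, k-2), got ({k}, {m})")
    used_n = sum(k for k, _m in bottlenecks)
    used_m = sum(m for _k, m in bottlenecks)
    bg_n = n_neurons - used_n
    bg_m = n_muscles - used_m
    if bg_n < 0 or bg_m < 0:
        raise ValueError("bottlenecks exceed requested network size")
    if bg_m > 0 and bg_n < bg_m + 3:
        raise ValueError(
            "need at least three more background neurons than background muscles"
        )

    records: list[tuple[str, str, str, int]] = []
    kinds: dict[str, str] = {}
    planted: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    triplets: list[frozenset] = []
    for b, (k, m) in enumerate(bottlenecks):
        neurons = tuple(f"BN{b + 1}N{i + 1:02d}" for i in range(k))
        muscles = tuple(f"BN{b + 1}M{j + 1:02d}" for j in range(m))
        kinds |= {n: "neuron" for n in neurons} | {mu: "muscle" for mu in muscles}
        records += [(n, mu, "nmj", 1) for n in neurons for mu in muscles]
        planted.append((neurons, muscles))
        triplets += [frozenset(t) for t in itertools.combinations(neurons, 3)]

    bg_neurons = tuple(f"BGN{i + 1:03d}" for i in range(bg_n))
    bg_muscles = tuple(f"BGM{j + 1:03d}" for j in range(bg_m))
    kinds |= {n: "neuron" for n in bg_neurons} | {m: "muscle" for m in bg_muscles}
    records += [(n, m, "nmj", 1) for n in bg_neurons for m in bg_muscles]

    if density > 0:
        names = sorted(n for n, kind in kinds.items() if kind == "neuron")
        for pre in names:
            for post in names:
                if pre != post and rng.random() < density:
                    records.append((pre, post, "chemical", 1))

    c = Connectome.from_records(
        records, cell_kinds=kinds, use_name_rule=False,
        provenance=f"planted:seed={seed}",
    )
    truth = PlantedTruth(
        inputs=c.neurons,
        synthetic_triplets=tuple(triplets),
        bottlenecks=tuple(planted),
    )
    return c, truth


def make_pair_planted_connectome(
    seed: int = 0,
    mechanism: str = "M1",
    n_background_neurons: int = 6,
    n_background_muscles: int = 2,
    density: float = 0.0,
) -> tuple[Connectome, PlantedTruth]:
    """Background network plus a planted pair-essential geometry.

    ``M1`` plants two Layer-2 drivers each relaying one signal to a pair of
    Layer-1 neurons over two exclusively fed muscles; the two same-relay
    Layer-1 pairs are the planted synthetic pairs (the drivers themselves
    are essential singles).  ``M3`` plants two relayed plus one directly
    driven Layer-1 neuron, whose mixed Layer-1/Layer-2 pairs are synthetic.
    Noise edges never terminate on planted cells, since extra incoming
    signals would break the planted signal counts.
    """
    if n_background_muscles > 0 and n_background_neurons < n_background_muscles + 3:
        raise ValueError(
            "need at least three more background neurons than background muscles"
        )
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str, int]] = []
    kinds: dict[str, str] = {}
    mus = ("PLM01", "PLM02")
    kinds |= {m: "muscle" for m in mus}
    if mechanism == "M1":
        l2 = ("PLZ1", "PLZ2")
        l1 = ("PLW1", "PLW2", "PLW3", "PLW4")
        kinds |= {n: "neuron" for n in l2 + l1}
        records += [
            ("PLZ1", "PLW1", "chemical", 1),
            ("PLZ1", "PLW2", "chemical", 1),
            ("PLZ2", "PLW3", "chemical", 1),
            ("PLZ2", "PLW4", "chemical", 1),
        ]
        records += [(n, m, "nmj", 1) for n in l1 for m in mus]
        inputs = list(l2)
        pairs = {
            frozenset(("PLW1", "PLW2")): "M1",
            frozenset(("PLW3", "PLW4")): "M1",
        }
    elif mechanism == "M3":
        l2 = ("PLZ1", "PLZ2")
        l1 = ("PLW1", "PLW2", "PLW3")
        kinds |= {n: "neuron" for n in l2 + l1}
        records += [
            ("PLZ1", "PLW1", "chemical", 1),
            ("PLZ2", "PLW2", "chemical", 1),
        ]
        records += [(n, m, "nmj", 1) for n in l1 for m in mus]
        inputs = ["PLZ1", "PLZ2", "PLW3"]
        pairs = {
            frozenset(("PLW1", "PLZ2")): "M3",
            frozenset(("PLW2", "PLZ1")): "M3",
            frozenset(("PLW3", "PLZ1")): "M3",
            frozenset(("PLW3", "PLZ2")): "M3",
            frozenset(("PLW1", "PLW2")): "M1",
            frozenset(("PLW1", "PLW3")): "M1",
            frozenset(("PLW2", "PLW3")): "M1",
            frozenset(("PLZ1", "PLZ2")): "M2",
        }
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    bg_neurons = tuple(f"BGN{i + 1:03d}" for i in range(n_background_neurons))
    bg_muscles = tuple(f"BGM{j + 1:03d}" for j in range(n_background_muscles))
    kinds |= {n: "neuron" for n in bg_neurons} | {m: "muscle" for m in bg_muscles}
    records += [(n, m, "nmj", 1) for n in bg_neurons for m in bg_muscles]
    inputs += list(bg_neurons)
    if density > 0:
        planted_cells = {n for n in kinds if n.startswith("PL")}
        sources = sorted(n for n, kind in kinds.items() if kind == "neuron")
        sinks = sorted(
            n for n, kind in kinds.items()
            if kind == "neuron" and n not in planted_cells
        )
        for pre in sources:
            for post in sinks:
                if pre != post and rng.random() < density:
                    records.append((pre, post, "chemical", 1))

    c = Connectome.from_records(
        records, cell_kinds=kinds, use_name_rule=False,
        provenance=f"pair_planted:{mechanism}:seed={seed}",
    )
    truth = PlantedTruth(
        inputs=tuple(sorted(inputs)),
        synthetic_pairs=tuple(p for p in pairs),
        pair_mechanisms=pairs,
    )
    return c, truth
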