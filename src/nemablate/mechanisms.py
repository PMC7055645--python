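"""Layer-based explanation of control loss.

Muscles are Layer 0; a neuron's layer is the length of the shortest
directed path from it to any muscle.  Synthetic essential pairs fall into
three mechanisms by the layers of their members — both Layer 1 (M1), both
Layer 2 (M2), one of each (M3) — all acting by cutting the number of
independent control signals that reach the motor-neuron layer.  Synthetic
essential triplets are grouped by the muscle set whose control they affect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from .connectome import Connectome, MUSCLE
from .control import LossProfile

#: Loss probabilities above this count a muscle as affected (separates
#: genuine basis rejections from Monte-Carlo noise at ~1,000 orderings).
AFFECTED_THRESHOLD = 0.01

UNREACHABLE = None


def assign_layers(c: Connectome) -> dict[str, Optional[int]]:
    """Shortest directed distance to any muscle; muscles are layer 0.

    Computed as a multi-source BFS from all muscles over the reversed
    adjacency.  Neurons with no directed path to a muscle map to ``None``.
    """
    g = c.to_digraph().reverse(copy=False)
    muscles = [m for m in c.muscles]
    lengths: dict[str, int] = {}
    if muscles:
        lengths = nx.multi_source_dijkstra_path_length(g, muscles, weight=None)
    return {name: lengths.get(name, UNREACHABLE) for name in c.cells}


@dataclass(frozen=True)
class MechanismReport:
    """Mechanism / group assignment for one synthetic essential set."""

    neurons: frozenset[str]
    mechanism: str = "other"          # pairs: M1 | M2 | M3 | other
    affected_muscles: frozenset[str] = frozenset()
    group: str = "ungrouped"          # triplets: G1, G2, ... | ungrouped
    complete_group: bool = False
    disconnects: frozenset[str] = frozenset()


def classify_pair_mechanism(
    pair: Iterable[str],
    layers: Mapping[str, Optional[int]],
    affected_muscles: Iterable[str] = (),
) -> MechanismReport:
    """Mechanism label from the layer membership of the two ablated neurons."""
    members = sorted(set(pair))
    if len(members) != 2:
        raise ValueError("a pair must contain exactly two neurons")
    lvls = sorted(
        (layers.get(n) for n in members),
        key=lambda v: (v is None, v),
    )
    if lvls == [1, 1]:
        mech = "M1"
    elif lvls == [2, 2]:
        mech = "M2"
    elif lvls == [1, 2]:
        mech = "M3"
    else:
        mech = "other"
    return MechanismReport(
        frozenset(members), mechanism=mech, affected_muscles=frozenset(affected_muscles)
    )


def group_triplets(
    c: Connectome,
    triplets: Iterable[frozenset],
    profiles: Mapping[frozenset, LossProfile],
    threshold: float = AFFECTED_THRESHOLD,
) -> list[MechanismReport]:
    """Partition synthetic essential triplets by affected-muscle set.

    Triplets with identical affected sets form a group.  A group is
    *complete* when every 3-subset of the union of its neurons is itself a
    listed synthetic essential triplet ("any three of the set" behavior);
    incomplete partitions are left ungrouped.  A triplet that leaves an
    affected muscle with no incoming connection at all is flagged as a
    disconnection.  Complete groups are named G1, G2, ... ordered by
    descending neuron-union size, then by affected-muscle names.
    """
    import itertools

    triplets = [frozenset(t) for t in triplets]
    tripset = set(triplets)
    affected = {
        t: profiles[t].affected(threshold) if t in profiles else frozenset()
        for t in triplets
    }
    partitions: dict[frozenset, list[frozenset]] = {}
    for t in triplets:
        partitions.setdefault(affected[t], []).append(t)

    meta: dict[frozenset, tuple[bool, frozenset]] = {}
    for aff, members in partitions.items():
        union = frozenset().union(*members)
        complete = all(
            frozenset(sub) in tripset for sub in itertools.combinations(sorted(union), 3)
        )
        meta[aff] = (complete, union)

    complete_parts = sorted(
        (aff for aff, (ok, union) in meta.items() if ok and aff),
        key=lambda aff: (-len(meta[aff][1]), tuple(sorted(aff))),
    )
    group_name = {aff: f"G{i + 1}" for i, aff in enumerate(complete_parts)}

    reports = []
    for t in sorted(triplets, key=lambda s: tuple(sorted(s))):
        aff = affected[t]
        complete, _union = meta[aff]
        disconnects = frozenset(m for m in aff if _in_degree_after(c, t, m) == 0)
        reports.append(
            MechanismReport(
                t,
                mechanism="other",
                affected_muscles=aff,
                group=group_name.get(aff, "ungrouped"),
                complete_group=aff in group_name,
                disconnects=disconnects,
            )
        )
    return reports


def _in_degree_after(c: Connectome, removed: frozenset, muscle: str) -> int:
    return sum(
        1
        for pre, post, _e in c.directed_edges()
        if post == muscle and pre not in removed
    )


def cooccurrence_network(sets: Iterable[Iterable[str]]) -> nx.Graph:
    """Weighted co-occurrence graph: edge weight counts shared sets."""
    g = nx.Graph()
    for s in sets:
        members = sorted(set(s))
        g.add_nodes_from(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return g


def write_cooccurrence_graphml(sets: Iterable[Iterable[str]], path) -> None:
    nx.write_graphml(cooccurrence_network(sets), path)
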