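"""Exhaustive single/double/triple ablation scans and their taxonomy.

Every candidate neuron set is ablated in silico, the number of
independently controllable muscles recomputed per input scenario, and the
set classified by how its controllability reduction relates to the effects
of its sub-parts:

* ``essential_single`` — one neuron whose removal alone costs control;
* ``synthetic_essential_pair`` — two individually nonessential neurons
  whose joint removal costs control;
* ``synthetic_essential_triplet`` — three individually nonessential
  neurons, containing no synthetic pair, whose joint removal costs control;
* a *negative interaction* is a set containing essential sub-parts whose
  observed reduction exceeds the summed, pair-corrected expectation from
  those sub-parts (synthetic essential sets are their own category and are
  not double-counted as negative).

A set is "reducing" if its reduction is at least one in any scenario (the
scenarios are run jointly and merged); a set containing the complete input
set of any scenario is flagged trivial and excluded from headline counts,
since severing every external signal trivially abolishes control.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .connectome import Connectome
from .control import build_system, generic_rank, stable_seed

log = logging.getLogger(__name__)

PAIR_LABELS = ("no_effect", "EE_pair", "EN_pair", "synthetic_essential_pair")
TRIPLE_LABELS = (
    "no_effect",
    "triple_3Epair",
    "triple_2Epair",
    "triple_EpairEsingle",
    "triple_EpairNsingle",
    "triple_EEE",
    "triple_EEN",
    "triple_ENN",
    "synthetic_essential_triplet",
)


def count_candidate_sets(n_neurons: int, order: int) -> int:
    """Number of candidate ablation sets of the given order, C(n, order)."""
    return math.comb(n_neurons, order)


def iter_candidate_sets(neurons: Iterable[str], order: int) -> Iterator[tuple[str, ...]]:
    """Candidate sets in deterministic lexicographic order."""
    return itertools.combinations(sorted(neurons), order)


@dataclass(frozen=True)
class AblationRecord:
    """Outcome of ablating one neuron set across scenarios."""

    neurons: frozenset[str]
    rank: Mapping[str, int]
    reduction: Mapping[str, int]
    trivial_scenarios: frozenset[str]

    @property
    def trivial(self) -> bool:
        """Set contains the full input set of at least one scenario."""
        return bool(self.trivial_scenarios)

    @property
    def observed_reduction(self) -> int:
        """Merged (maximum over non-trivial scenarios) reduction."""
        values = [r for sc, r in self.reduction.items() if sc not in self.trivial_scenarios]
        return max(values) if values else 0

    @property
    def reducing(self) -> bool:
        return self.observed_reduction >= 1


@dataclass(frozen=True)
class InteractionClass:
    """Taxonomy label for an ablation set."""

    label: str
    negative_interaction: bool
    expected_reduction: int
    observed_reduction: int


def expected_reduction(
    neurons: Iterable[str],
    single_reductions: Mapping[str, int],
    pair_reductions: Optional[Mapping[frozenset, int]] = None,
    cap: Optional[int] = None,
) -> int:
    """Reduction explained by sub-parts: singles plus pair excesses.

    expected(S) = sum_i r(i) + sum_{pairs p properly inside S}
    max(0, r(p) - sum_{i in p} r(i)), capped at the baseline rank.  An
    observed reduction above this is a negative interaction.
    """
    names = sorted(set(neurons))
    total = sum(single_reductions.get(n, 0) for n in names)
    if pair_reductions and len(names) > 2:
        for a, b in itertools.combinations(names, 2):
            pair = frozenset((a, b))
            if pair in pair_reductions:
                excess = pair_reductions[pair] - (
                    single_reductions.get(a, 0) + single_reductions.get(b, 0)
                )
                total += max(0, excess)
    if cap is not None:
        total = min(total, cap)
    return total


class AblationStudy:
    """Engine for systematic ablation scans on one connectome.

    Ranks are memoized by (frozen neuron set, scenario) and seeded
    deterministically from the study seed and the set's name, so repeated
    runs — and resumed runs fed a warm cache — are bit-reproducible.
    """

    def __init__(
        self,
        c: Connectome,
        scenarios: Mapping[str, Sequence[str]],
        trials: int = 3,
        seed: int = 0,
        candidate_pool: Optional[Iterable[str]] = None,
        cache: Optional[dict] = None,
    ):
        self.connectome = c
        self.scenarios = {name: tuple(inputs) for name, inputs in scenarios.items()}
        self.trials = trials
        self.seed = seed
        self.pool = tuple(sorted(candidate_pool)) if candidate_pool is not None else c.neurons
        unknown = set(self.pool) - set(c.neurons)
        if unknown:
            raise ValueError(f"candidate pool contains non-neurons: {sorted(unknown)}")
        self._cache: dict[tuple[frozenset, str], int] = cache if cache is not None else {}
        self.baseline = {
            name: self.rank(frozenset(), name) for name in self.scenarios
        }

    # -- rank plumbing ---------------------------------------------------

    def rank(self, removed: frozenset, scenario: str) -> int:
        key = (removed, scenario)
        if key not in self._cache:
            inputs = self.scenarios[scenario]
            c = self.connectome.ablate(removed) if removed else self.connectome
            sys = build_system(c, inputs, scenario=scenario)
            seed = stable_seed(self.seed, scenario, *sorted(removed))
            self._cache[key] = generic_rank(sys, trials=self.trials, seed=seed).generic_rank
        return self._cache[key]

    def evaluate(self, neurons: Iterable[str]) -> AblationRecord:
        removed = frozenset(neurons)
        trivial = frozenset(
            sc for sc, inputs in self.scenarios.items() if set(inputs) <= removed
        )
        ranks = {sc: self.rank(removed, sc) for sc in self.scenarios}
        reductions = {sc: self.baseline[sc] - ranks[sc] for sc in self.scenarios}
        return AblationRecord(removed, ranks, reductions, trivial)

    @property
    def baseline_cap(self) -> int:
        return max(self.baseline.values()) if self.baseline else 0

    # -- scans -----------------------------------------------------------

    def single_scan(self) -> dict[str, tuple[AblationRecord, InteractionClass]]:
        out = {}
        for (name,) in iter_candidate_sets(self.pool, 1):
            rec = self.evaluate([name])
            obs = rec.observed_reduction
            label = "essential_single" if (not rec.trivial and obs >= 1) else "no_effect"
            out[name] = (rec, InteractionClass(label, False, 0, obs))
        return out

    def pair_scan(
        self, singles: Mapping[str, tuple[AblationRecord, InteractionClass]]
    ) -> dict[frozenset, tuple[AblationRecord, InteractionClass]]:
        single_red = _single_reductions(singles)
        out = {}
        for pair in iter_candidate_sets(self.pool, 2):
            rec = self.evaluate(pair)
            out[frozenset(pair)] = (
                rec,
                classify_pair(rec, single_red, cap=self.baseline_cap),
            )
        return out

    def triple_scan(
        self,
        singles: Mapping[str, tuple[AblationRecord, InteractionClass]],
        pairs: Mapping[frozenset, tuple[AblationRecord, InteractionClass]],
    ) -> dict[frozenset, tuple[AblationRecord, InteractionClass]]:
        single_red = _single_reductions(singles)
        synthetic_pairs = {
            key for key, (_r, cls) in pairs.items()
            if cls.label == "synthetic_essential_pair"
        }
        pair_red = {
            key: rec.observed_reduction for key, (rec, cls) in pairs.items()
            if not rec.trivial
        }
        out = {}
        for triple in iter_candidate_sets(self.pool, 3):
            rec = self.evaluate(triple)
            out[frozenset(triple)] = (
                rec,
                classify_triple(rec, single_red, synthetic_pairs, pair_red,
                                cap=self.baseline_cap),
            )
        return out


def _single_reductions(
    singles: Mapping[str, tuple[AblationRecord, InteractionClass]]
) -> dict[str, int]:
    return {name: rec.observed_reduction for name, (rec, _c) in singles.items()}


def classify_pair(
    rec: AblationRecord,
    single_reductions: Mapping[str, int],
    cap: Optional[int] = None,
) -> InteractionClass:
    obs = rec.observed_reduction
    expected = expected_reduction(rec.neurons, single_reductions, cap=cap)
    n_ess = sum(1 for n in rec.neurons if single_reductions.get(n, 0) >= 1)
    if n_ess == 2:
        label = "EE_pair"
    elif n_ess == 1:
        label = "EN_pair"
    elif obs >= 1:
        label = "synthetic_essential_pair"
    else:
        label = "no_effect"
    if n_ess and obs == 0:
        # rank monotonicity forbids this; classify conservatively if seen
        log.warning("pair %s contains essential singles but shows no reduction",
                    sorted(rec.neurons))
    negative = obs > expected and label not in ("synthetic_essential_pair", "no_effect")
    return InteractionClass(label, negative, expected, obs)


def classify_triple(
    rec: AblationRecord,
    single_reductions: Mapping[str, int],
    synthetic_pairs: Iterable[frozenset],
    pair_reductions: Mapping[frozenset, int],
    cap: Optional[int] = None,
) -> InteractionClass:
    obs = rec.observed_reduction
    expected = expected_reduction(
        rec.neurons, single_reductions, pair_reductions, cap=cap
    )
    members = sorted(rec.neurons)
    contained = [
        frozenset(p) for p in itertools.combinations(members, 2)
        if frozenset(p) in set(synthetic_pairs)
    ]
    n_ess = sum(1 for n in members if single_reductions.get(n, 0) >= 1)
    if len(contained) == 3:
        label = "triple_3Epair"
    elif len(contained) == 2:
        label = "triple_2Epair"
    elif len(contained) == 1:
        third = next(iter(rec.neurons - contained[0]))
        label = (
            "triple_EpairEsingle"
            if single_reductions.get(third, 0) >= 1
            else "triple_EpairNsingle"
        )
    elif n_ess == 3:
        label = "triple_EEE"
    elif n_ess == 2:
        label = "triple_EEN"
    elif n_ess == 1:
        label = "triple_ENN"
    elif obs >= 1:
        label = "synthetic_essential_triplet"
    else:
        label = "no_effect"
    negative = obs > expected and label not in ("synthetic_essential_triplet", "no_effect")
    return InteractionClass(label, negative, expected, obs)


# ----------------------------------------------------------------------
# function-style convenience wrappers and summaries
# ----------------------------------------------------------------------

def run_single_scan(c, scenarios, trials=3, seed=0, candidate_pool=None):
    study = AblationStudy(c, scenarios, trials=trials, seed=seed,
                          candidate_pool=candidate_pool)
    return study.single_scan()


def run_pair_scan(c, scenarios, singles=None, trials=3, seed=0, candidate_pool=None):
    study = AblationStudy(c, scenarios, trials=trials, seed=seed,
                          candidate_pool=candidate_pool)
    if singles is None:
        singles = study.single_scan()
    return study.pair_scan(singles)


def run_triple_scan(c, scenarios, singles=None, pairs=None, trials=3, seed=0,
                    candidate_pool=None):
    study = AblationStudy(c, scenarios, trials=trials, seed=seed,
                          candidate_pool=candidate_pool)
    if singles is None:
        singles = study.single_scan()
    if pairs is None:
        pairs = study.pair_scan(singles)
    return study.triple_scan(singles, pairs)


def summarize(results: Mapping, order: int) -> dict:
    """Class counts in the double/triple-ablation table layout.

    Sets trivial in any scenario are tallied separately and excluded from
    the class counts, mirroring the published table captions.
    """
    labels = PAIR_LABELS if order == 2 else TRIPLE_LABELS if order == 3 else ("no_effect", "essential_single")
    counts = {label: 0 for label in labels}
    trivial = 0
    negative = 0
    reducing = 0
    for key, (rec, cls) in results.items():
        if rec.trivial:
            trivial += 1
            continue
        counts[cls.label] += 1
        if cls.negative_interaction:
            negative += 1
        if rec.reducing:
            reducing += 1
    return {
        "order": order,
        "classes": counts,
        "trivial_excluded": trivial,
        "negative_interactions": negative,
        "reducing": reducing,
        "total_evaluated": len(results),
    }


def records_frame(results: Mapping):
    """Flatten scan results to a tidy table (one row per set and scenario)."""
    import pandas as pd

    rows = []
    for key, (rec, cls) in sorted(
        results.items(), key=lambda kv: tuple(sorted(kv[1][0].neurons))
    ):
        names = "|".join(sorted(rec.neurons))
        for sc in sorted(rec.rank):
            rows.append(
                {
                    "neurons": names,
                    "scenario": sc,
                    "rank": rec.rank[sc],
                    "reduction": rec.reduction[sc],
                    "trivial": sc in rec.trivial_scenarios,
                    "class": cls.label,
                    "negative": cls.negative_interaction,
                    "expected": cls.expected_reduction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["neurons", "scenario", "rank", "reduction", "trivial",
                 "class", "negative", "expected"],
    )
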