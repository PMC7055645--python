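"""Target controllability of muscles from sensory inputs.

The nervous system is modeled as the linear time-invariant system

    dx/dt = A x + B u,    y = C x,

where the state x collects all N neurons and M muscles, A is the weighted
directed adjacency of the connectome plus a nodal-dynamics term a·I shared
by all cells, B injects one external control signal into each input
(touch-receptor) neuron, and C reads out the muscle states.  The number of
independently controllable muscles is the generic rank of the output
controllability matrix

    K = [CB, CAB, CA^2 B, ..., CA^(N+M-1) B],

i.e. the rank attained for almost every assignment of the free weights.

Because the nodal term is shared, A = W + a·I commutes with W and the
column space of K equals span{C W^k B : k >= 0}: the rank is decided by the
walk structure of the wiring diagram, so ablating neurons can only remove
independent control signals, never create them.  (If instead every node
carried an independent self-loop weight, distinct poles would render every
reachable muscle controllable and ablations would only matter through
disconnection — a regime in which none of the layered loss mechanisms seen
in real connectome ablation studies can arise.)

``generic_rank`` evaluates the rank numerically via a block-Krylov basis of
the reachable subspace; ``exact_rank_oracle`` forms K explicitly over the
rationals on small systems and is the independent ground truth the numeric
path is validated against.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .connectome import Connectome, ConnectomeError, MUSCLE

log = logging.getLogger(__name__)

#: Weights are drawn uniformly from this interval: positive, away from zero,
#: so random cancellations are measure-zero and powers of A stay well scaled.
WEIGHT_LOW, WEIGHT_HIGH = 0.5, 1.5

#: Singular values below max_dim * eps * sigma_max * RANK_TOL_FACTOR count as
#: zero.  The standard SVD cutoff is inflated to absorb accumulated Krylov
#: round-off; the factor is validated against the exact rational oracle.
RANK_TOL_FACTOR = 1e3

#: Relative residual below which a candidate Krylov direction is considered
#: linearly dependent on the basis built so far.
KRYLOV_DROP_TOL = 1e-9

ORACLE_STATE_CAP = 15


def stable_seed(*parts: object) -> int:
    """Deterministic 31-bit seed derived from arbitrary labeled parts."""
    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class StructuredSystem:
    """Zero pattern of (A, B, C) for one input scenario and target set.

    ``nodes`` orders the states (neurons first, then muscles, each sorted by
    name); ``a_pattern`` holds the off-diagonal adjacency with entry (i, j)
    marking an edge j -> i.  The shared nodal-dynamics diagonal is implicit.
    """

    nodes: tuple[str, ...]
    a_pattern: sp.csr_matrix
    input_idx: tuple[int, ...]
    target_idx: tuple[int, ...]
    scenario: str = ""

    @property
    def n_state(self) -> int:
        return len(self.nodes)

    @property
    def n_inputs(self) -> int:
        return len(self.input_idx)

    @property
    def n_targets(self) -> int:
        return len(self.target_idx)

    @property
    def trivial(self) -> bool:
        """True when every input neuron has been ablated (S = 0)."""
        return self.n_inputs == 0


@dataclass(frozen=True)
class RankResult:
    """Generic rank of the output controllability matrix."""

    generic_rank: int
    trials_used: int
    per_trial_ranks: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.per_trial_ranks and self.generic_rank != max(self.per_trial_ranks):
            raise ValueError("generic_rank must be the maximum over trials")

    def to_json(self) -> str:
        return json.dumps(
            {
                "generic_rank": self.generic_rank,
                "trials_used": self.trials_used,
                "per_trial_ranks": list(self.per_trial_ranks),
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class LossProfile:
    """Per-muscle probability of ablation-induced loss of control."""

    probabilities: Mapping[str, float]
    orderings_used: int

    def affected(self, threshold: float = 0.01) -> frozenset[str]:
        return frozenset(m for m, p in self.probabilities.items() if p > threshold)

    def to_json(self) -> str:
        return json.dumps(
            {
                "probabilities": dict(sorted(self.probabilities.items())),
                "orderings_used": self.orderings_used,
            },
            sort_keys=True,
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("muscle,probability\n")
            for muscle, p in sorted(self.probabilities.items()):
                fh.write(f"{muscle},{p}\n")


def build_system(
    c: Connectome,
    inputs: Iterable[str],
    targets: Optional[Iterable[str]] = None,
    scenario: str = "",
) -> StructuredSystem:
    """Assemble the structured (A, B, C) pattern for a connectome.

    ``inputs`` are neuron names; names absent from the connectome are
    treated as ablated inputs (dropping the corresponding B column), so a
    fully ablated input set yields a trivial S = 0 system rather than an
    error.  ``targets`` defaults to every muscle.
    """
    neurons = c.neurons
    muscles = c.muscles
    nodes = neurons + muscles
    index = {name: i for i, name in enumerate(nodes)}

    surviving = []
    for name in sorted(set(inputs)):
        if name in c.cells:
            if c.cells[name].kind == MUSCLE:
                raise ConnectomeError(f"input {name!r} is a muscle")
            surviving.append(name)
    input_idx = tuple(index[n] for n in surviving)

    if targets is None:
        target_names: tuple[str, ...] = muscles
    else:
        target_names = tuple(sorted(set(targets)))
        for name in target_names:
            if name not in c.cells or c.cells[name].kind != MUSCLE:
                raise ConnectomeError(f"target {name!r} is not a muscle of this connectome")
    target_idx = tuple(index[m] for m in target_names)

    rows, cols = [], []
    for pre, post, _etype in c.directed_edges():
        rows.append(index[post])
        cols.append(index[pre])
    n = len(nodes)
    a_pattern = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    a_pattern.sum_duplicates()
    a_pattern.data[:] = 1  # structural pattern only; multiplicities ignored
    return StructuredSystem(nodes, a_pattern, input_idx, target_idx, scenario)


# ----------------------------------------------------------------------
# numeric generic rank
# ----------------------------------------------------------------------

def _instantiate(sys: StructuredSystem, rng: np.random.Generator) -> tuple[sp.csr_matrix, np.ndarray]:
    w = sys.a_pattern.astype(np.float64).copy()
    w.data = rng.uniform(WEIGHT_LOW, WEIGHT_HIGH, size=w.nnz)
    b = np.zeros((sys.n_state, sys.n_inputs))
    b[list(sys.input_idx), np.arange(sys.n_inputs)] = rng.uniform(
        WEIGHT_LOW, WEIGHT_HIGH, size=sys.n_inputs
    )
    return w, b


def _spectral_radius(w: sp.csr_matrix, iters: int = 50) -> float:
    """Power-iteration estimate of the spectral radius of |W|."""
    n = w.shape[0]
    if w.nnz == 0 or n == 0:
        return 0.0
    absw = abs(w)
    v = np.ones(n) / np.sqrt(n)
    radius = 0.0
    for _ in range(iters):
        v = absw @ v
        nrm = float(np.linalg.norm(v))
        if nrm == 0.0 or not np.isfinite(nrm):
            return nrm if np.isfinite(nrm) else np.inf
        radius, v = nrm, v / nrm
    return radius


def _krylov_basis(w: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of span{B, WB, W^2 B, ...}.

    Blocks are orthogonalized against the accumulated basis twice (classical
    Gram–Schmidt with reorthogonalization) and expansion stops as soon as a
    step contributes no new direction, at which point the span is
    W-invariant and equals the full reachable subspace.
    """
    n = w.shape[0]
    if b.size == 0:
        return np.zeros((n, 0))
    block, _ = np.linalg.qr(b)
    keep = [i for i in range(block.shape[1]) if np.linalg.norm(b[:, i]) > 0]
    block = block[:, : len(keep)] if keep else np.zeros((n, 0))
    basis = block
    while basis.shape[1] < n and block.shape[1] > 0:
        cand = w @ block
        new_cols = []
        for j in range(cand.shape[1]):
            v = cand[:, j]
            norm0 = np.linalg.norm(v)
            if norm0 == 0.0:
                continue
            for _ in range(2):
                v = v - basis @ (basis.T @ v)
                if new_cols:
                    nc = np.column_stack(new_cols)
                    v = v - nc @ (nc.T @ v)
            norm1 = np.linalg.norm(v)
            if norm1 > KRYLOV_DROP_TOL * norm0:
                new_cols.append(v / norm1)
        if not new_cols:
            break
        block = np.column_stack(new_cols)
        basis = np.column_stack([basis, block])
    return basis


def _numeric_rank(mat: np.ndarray) -> int:
    if mat.size == 0:
        return 0
    s = np.linalg.svd(mat, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = max(mat.shape) * np.finfo(np.float64).eps * s[0] * RANK_TOL_FACTOR
    return int(np.sum(s > tol))


def generic_rank(sys: StructuredSystem, trials: int = 3, seed: int = 0) -> RankResult:
    """Generic rank of K = [CB, CAB, ...] over random weight draws.

    Each trial instantiates the free entries independently; the result is
    the maximum over trials (the generic rank is attained almost surely per
    draw, so the maximum over a few trials is a robust estimator).  Trials
    producing non-finite intermediates are redrawn; S = 0 systems report
    rank 0 without sampling.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if sys.trivial:
        return RankResult(0, 0, (0,), seed)

    ranks: list[int] = []
    draws = 0
    max_draws = trials * 5
    while len(ranks) < trials and draws < max_draws:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, draws]))
        draws += 1
        w, b = _instantiate(sys, rng)
        radius = _spectral_radius(w)
        if not np.isfinite(radius):
            log.warning("discarding trial %d: non-finite spectral radius", draws)
            continue
        if radius > 0:
            w = w / (1.1 * radius)
        basis = _krylov_basis(w, b)
        if not np.all(np.isfinite(basis)):
            log.warning("discarding trial %d: non-finite Krylov basis", draws)
            continue
        ranks.append(_numeric_rank(basis[list(sys.target_idx), :]))
    if not ranks:
        raise RuntimeError("all generic-rank trials degenerate")
    return RankResult(max(ranks), len(ranks), tuple(ranks), seed)


# ----------------------------------------------------------------------
# exact rational oracle
# ----------------------------------------------------------------------

def _fraction_rank(rows: list[list[Fraction]]) -> int:
    """Rank over the rationals by fraction-free Gaussian elimination."""
    rows = [list(r) for r in rows]
    ncols = len(rows[0]) if rows else 0
    rank = 0
    col = 0
    while rank < len(rows) and col < ncols:
        pivot = next((i for i in range(rank, len(rows)) if rows[i][col] != 0), None)
        if pivot is None:
            col += 1
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pr = rows[rank]
        for i in range(rank + 1, len(rows)):
            if rows[i][col] != 0:
                factor = rows[i][col] / pr[col]
                rows[i] = [a - factor * b for a, b in zip(rows[i], pr)]
        rank += 1
        col += 1
    return rank


def exact_rank_oracle(sys: StructuredSystem, assignments: int = 3, seed: int = 0) -> int:
    """Exact rank of K over the rationals, maximized over weight assignments.

    Free off-diagonal entries and B weights receive distinct random
    rationals; the shared nodal-dynamics diagonal receives one rational per
    assignment.  K = [CB, CAB, ..., CA^(n-1)B] is formed explicitly with
    Fraction arithmetic, so the result is immune to floating-point rank
    decisions.  Only feasible for small systems (n_state <= 15).
    """
    if sys.n_state > ORACLE_STATE_CAP:
        raise ValueError(f"oracle limited to {ORACLE_STATE_CAP} states, got {sys.n_state}")
    if assignments < 1:
        raise ValueError("assignments must be >= 1")
    if sys.trivial:
        return 0

    n = sys.n_state
    coo = sys.a_pattern.tocoo()
    entries = list(zip(coo.row.tolist(), coo.col.tolist()))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xACE]))
    best = 0
    for _ in range(assignments):
        seen: set[Fraction] = set()

        def draw() -> Fraction:
            # distinct random rationals; exact arithmetic makes any generic
            # assignment as good as symbolic indeterminates
            while True:
                f = Fraction(int(rng.integers(1, 999_983)), int(rng.integers(1, 999_983)))
                if f not in seen:
                    seen.add(f)
                    return f

        a = [[Fraction(0)] * n for _ in range(n)]
        diag = draw()  # shared nodal dynamics; rank is invariant to it
        for i in range(n):
            a[i][i] = diag
        for i, j in entries:
            a[i][j] += draw()
        cols = [
            [Fraction(0)] * sys.n_inputs for _ in range(n)
        ]
        for k, idx in enumerate(sys.input_idx):
            cols[idx][k] = draw()

        k_rows: list[list[Fraction]] = [[] for _ in sys.target_idx]
        x = cols
        for _power in range(n):
            for r, t in enumerate(sys.target_idx):
                k_rows[r].extend(x[t])
            x = [
                [sum(a[i][j] * x[j][k] for j in range(n) if a[i][j] != 0)
                 for k in range(sys.n_inputs)]
                for i in range(n)
            ]
        best = max(best, _fraction_rank(k_rows))
        if best == sys.n_targets:
            break
    return best


# ----------------------------------------------------------------------
# convenience compositions
# ----------------------------------------------------------------------

def controllable_muscle_count(
    c: Connectome,
    inputs: Iterable[str],
    scenario: str = "",
    trials: int = 3,
    seed: int = 0,
) -> int:
    """Number of independently controllable muscles for an input set."""
    sys = build_system(c, inputs, scenario=scenario)
    return generic_rank(sys, trials=trials, seed=seed).generic_rank


def reachable_muscles(c: Connectome, inputs: Iterable[str]) -> frozenset[str]:
    """Muscles reachable by a directed path from any input neuron."""
    import networkx as nx

    g = c.to_digraph()
    seen: set[str] = set()
    for src in inputs:
        if src in g:
            seen |= {src}
            seen |= set(nx.descendants(g, src))
    return frozenset(m for m in c.muscles if m in seen)


def muscle_loss_profile(
    c: Connectome,
    removed: Iterable[str],
    inputs: Iterable[str],
    orderings: int = 1000,
    seed: int = 0,
) -> LossProfile:
    """Probability, per muscle, that the ablation costs its control.

    The reachable-output spaces of the healthy and ablated systems are built
    from one shared weight draw (the ablated system inherits the surviving
    weights).  For each random muscle ordering, muscle output rows are added
    greedily to a basis, accepted when they raise the numeric rank; a muscle
    "lost" in an ordering is one rejected under ablation but accepted in the
    healthy network, so muscles uncontrollable at baseline are never charged
    to the ablation.  Probabilities are rejection frequencies over orderings.
    """
    if orderings < 1:
        raise ValueError("orderings must be >= 1")
    removed = sorted(set(removed))
    inputs = sorted(set(inputs))
    healthy_sys = build_system(c, inputs)
    ablated = c.ablate(removed)
    ablated_sys = build_system(ablated, inputs)
    muscles = list(c.muscles)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x1055]))
    w, b = _instantiate(healthy_sys, rng)
    radius = _spectral_radius(w)
    if radius > 0:
        w = w / (1.1 * radius)
    # restrict the same weights to the surviving subnetwork
    gone = set(removed)
    keep = [i for i, name in enumerate(healthy_sys.nodes) if name not in gone]
    w_abl = sp.csr_matrix(w[keep, :][:, keep])
    b_abl = b[keep][:, [k for k, idx in enumerate(healthy_sys.input_idx)
                       if healthy_sys.nodes[idx] not in gone]]

    def muscle_rows(sys: StructuredSystem, wmat, bmat) -> np.ndarray:
        basis = _krylov_basis(wmat, bmat)
        g = basis[list(sys.target_idx), :]
        # compress to the row space so greedy passes are cheap
        if g.size == 0:
            return np.zeros((len(sys.target_idx), 0))
        u, s, _ = np.linalg.svd(g, full_matrices=False)
        tol = max(g.shape) * np.finfo(np.float64).eps * (s[0] if s.size else 0.0) * RANK_TOL_FACTOR
        r = int(np.sum(s > tol))
        return u[:, :r] * s[:r]

    g_healthy = muscle_rows(healthy_sys, w, b)
    g_ablated = muscle_rows(ablated_sys, sp.csr_matrix(w_abl), b_abl)

    name_to_row_h = {m: i for i, m in enumerate(c.muscles)}
    name_to_row_a = {m: i for i, m in enumerate(ablated.muscles)}

    def rejected(order: Sequence[str], g: np.ndarray, row_of: Mapping[str, int]) -> set[str]:
        basis: list[np.ndarray] = []
        out: set[str] = set()
        for m in order:
            v = g[row_of[m]].astype(np.float64).copy()
            norm0 = np.linalg.norm(v)
            if norm0 <= 1e-12:
                out.add(m)
                continue
            for q in basis:
                v -= q * (q @ v)
            norm1 = np.linalg.norm(v)
            if norm1 > 1e-8 * norm0:
                basis.append(v / norm1)
            else:
                out.add(m)
        return out

    counts = {m: 0 for m in muscles}
    for _ in range(orderings):
        order = list(muscles)
        rng.shuffle(order)
        lost = rejected(order, g_ablated, name_to_row_a) - rejected(order, g_healthy, name_to_row_h)
        for m in lost:
            counts[m] += 1
    probs = {m: counts[m] / orderings for m in muscles}
    return LossProfile(probs, orderings)
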