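# Methods

## The control model

A wiring diagram over N neurons and M muscles is mapped to the structured
linear system dx/dt = A x + B u, y = C x. The state collects every cell;
A is the directed adjacency (chemical synapses as stored, gap junctions
expanded to both directions, neuromuscular junctions neuron → muscle) plus
a nodal-dynamics diagonal a·I *shared by all cells*; B has one column per
surviving input neuron with a single nonzero; C selects the muscle rows.
Edge multiplicities are retained in files but ignored by the control
computation: the generic rank depends only on the zero pattern.

The number of independently controllable muscles is the generic rank of
K = [CB, CAB, …, CA^(N+M−1)B] — the rank attained for almost every
assignment of the free weights. Because the nodal term is shared, A = W + a·I
commutes with the adjacency W and col K = span{C Wᵏ B}: the rank counts the
linearly independent control signals that walks of the network can deliver
to the muscles, and is invariant to a.

The shared nodal term is a modeling decision with teeth. If instead every
cell carried an *independent* self-dynamics weight, distinct poles would let
a single signal steer any number of downstream first-order units, every
accessible system would be fully controllable (a PBH argument; with
self-loops on all nodes, accessibility implies structural controllability),
and ablation effects would reduce to mere disconnection. None of the layered
loss mechanisms this package exists to detect — e.g. two muscles fed by four
neurons that share only three independent upstream signals — can occur in
that regime. The shared-dynamics model is the one under which the worked
bottleneck examples (Group 1/2, the VA09–VA10 pair) behave as observed in
connectome ablation analyses, and it is the model the exact oracle and all
tests verify.

## Numerical rank computation

`generic_rank` draws the free entries of W and B i.i.d. uniform on
[0.5, 1.5] (positive, bounded away from zero: cancellations are
measure-zero and powers stay well scaled), rescales W by 1.1 × a
power-iteration estimate of its spectral radius, and builds an orthonormal
block-Krylov basis of span{B, WB, W²B, …}. Each block is orthogonalized
twice against the accumulated basis; directions whose residual falls below
1e−9 of their pre-projection norm are dropped; expansion stops as soon as a
step contributes no new direction (the span is then W-invariant, so later
powers add nothing) or the basis reaches N+M. The rank is the number of
singular values of C·Q above max_dim · ε · σ_max · 10³ — the standard SVD
cutoff inflated by 10³ to absorb accumulated Krylov round-off, a factor
validated against the exact oracle. Three trials are drawn and the maximum
taken (the generic rank is an almost-sure maximum); trials with non-finite
intermediates are redrawn and logged, and a system whose inputs are all
ablated reports rank 0 without sampling. Explicitly forming K is hopeless at
N+M ≈ 374 (powers of A overflow or underflow long before N+M terms); the
Krylov route needs only matrix–block products.

`exact_rank_oracle` is the independent ground truth: it instantiates the
free entries with distinct random rationals (shared diagonal per
assignment), forms K explicitly with Fraction arithmetic, takes the rank
over ℚ by Gaussian elimination, and maximizes over ≥3 assignments. It is
capped at 15 states. The suite checks numeric–exact agreement on 200 random
structured systems of up to 12 states.

## Ablation scans and taxonomy

`AblationStudy` evaluates every candidate set (all neurons, including the
sensory inputs, by default) in deterministic lexicographic order, memoizing
ranks by (neuron set, scenario) with seeds derived stably from the study
seed and the set's names, so runs and resumed runs are bit-reproducible.
Scenarios (anterior {ALML, ALMR, AVM}, posterior {PLML, PLMR} by default)
are run jointly; a set is *reducing* when its reduction is ≥1 in any
scenario. A set containing the complete input set of any scenario is
flagged trivial and excluded from headline counts — severing all external
signals trivially abolishes control and says nothing about network
structure.

Classification: a single is essential iff its reduction is ≥1. A pair of
nonessential members with reduction ≥1 is a synthetic essential pair; pairs
are otherwise EE/EN/no-effect by member essentiality. Triples are labeled
first by how many contained synthetic pairs they hold (3, 2, 1 — with the
third member's essentiality splitting the 1-pair case), then by essential-
single count (EEE/EEN/ENN), and an NNN triple with no contained synthetic
pair and reduction ≥1 is a synthetic essential triplet. The *expected*
reduction of a set is Σ single reductions + Σ max(0, pair excess) over
proper sub-pairs, capped at the baseline rank; an essential-containing set
whose observed reduction exceeds this is a negative interaction (synthetic
essential sets are their own category and are not double-counted).

## Loss profiles and mechanisms

`muscle_loss_profile` quantifies *which* muscles lose control. One weight
draw instantiates the healthy system; the ablated system inherits the
surviving weights. For each of (default) 1,000 random muscle orderings,
muscle output rows are added greedily to a basis of the reachable-output
space, accepted when they raise the numeric rank; a muscle is charged to
the ablation in an ordering when it is rejected under ablation but accepted
in the healthy network, so muscles already uncontrollable at baseline are
never charged. Probabilities are rejection frequencies; their sum equals
the rank deficit up to Monte-Carlo error (≈ 2/√orderings), and a muscle
with probability > 0.01 counts as *affected* (separating genuine rejections
from Monte-Carlo noise at the default orderings).

Layers: muscles are Layer 0; a neuron's layer is its shortest directed
path length to any muscle (multi-source reverse BFS); unreachable neurons
are flagged, never numbered. Synthetic pairs classify by member layers —
both Layer 1 → M1, both Layer 2 → M2, one of each → M3, anything else
"other" (logged). Layer membership is the observable surrogate for the
local signal-count geometry of the three mechanisms; every named example in
the test motifs classifies correctly under it. Synthetic triplets are
partitioned by identical affected-muscle sets; a partition is a *complete
group* (named G1, G2, … by descending neuron-union size) when every
3-subset of its neuron union is itself a listed triplet, otherwise its
members stay "ungrouped"; a triplet leaving an affected muscle with
in-degree 0 is additionally flagged as a disconnection.

## Synthetic data

The motif generators are first-class, deterministic constructors of the
geometries that produce synthetic essentiality:

* `group1` / `group2` / `group3` — k independently driven neurons as the
  sole (complete-bipartite) innervators of k−2 muscles (k = 6, 4, 3).
  Complete wiring inside the bottleneck is deliberate: only exclusivity
  and counts matter for the rank, and it makes the "any three of the set"
  property exact.
* `va_pair_subnetwork` — two muscles fed only by four neurons that receive
  three independent upstream signals (one shared relay); the upstream wiring
  is abstracted as three driver cells since only the signal count matters.
* `mechanism_m1` / `mechanism_m2` / `mechanism_m3` — the minimal layered motifs for each pair
  mechanism. The M3 motif drives one Layer-1 neuron directly so that three
  independent signals reach Layer 1 from only two Layer-2 relays.

Upstream drive is modeled directly as input columns on the top layer — no
artificial sensory chains. `make_planted_connectome` embeds (k, k−2)
bottlenecks in a random background whose muscles are fed by all background
neurons (requiring three more background neurons than muscles, so no
background triple can cost control); ground truth is exactly C(k, 3)
triplets per bottleneck, exact at zero noise density and a guaranteed
subset of the recovered sets under neuron→neuron noise (exclusive NMJs
bound the rank by surviving bottleneck neurons). `make_pair_planted_connectome`
plants M1/M3 pair geometries; its noise edges never terminate on planted
cells, because planted pair essentiality depends on upstream signal counts
that incoming edges would alter.

What the generators do not emulate: realistic degree distributions,
synapse multiplicities, neuron classes and left/right symmetry, or the
dense recurrent core of a real connectome. Passing tests therefore
demonstrate correctness of the rank machinery, the taxonomy and the
recovery logic on known ground truth — not that any particular biological
connectome has a given number of essential sets; real-data scans use
`load_connectome` on the published edge lists.

## Problem sizes and defaults

Tests and the acceptance script run desk-scale problems: motifs of ≤ 12
cells, planted connectomes of ≤ 18 cells, 200 random systems of ≤ 12
states for the oracle comparison, 1,000 orderings for loss profiles, 3
rank trials. A full 279-neuron connectome pair scan (38,781 pairs × 2
scenarios × 3 trials) is an hours-scale batch job; triple scans (3,580,779
sets) run overnight — the CLI streams results, checkpoints every 10,000
ranks and resumes from its cache.

## Known limitations

* The generic rank is an almost-sure property estimated from finitely many
  draws; three trials with the inflated SVD cutoff matched the exact oracle
  on every random system tested, but pathological weight patterns could in
  principle need more trials.
* Negative/expected accounting caps pair excess at the baseline rank; other
  consistent conventions exist for deeply redundant networks.
* Mechanism labels use layer membership only; a synthetic pair whose
  members sit outside Layers 1–2 is reported "other" rather than analyzed.
* Group naming (G1, G2, …) is deterministic but synthetic; it does not try
  to reproduce any particular published group numbering beyond the
  complete/ungrouped distinction.
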