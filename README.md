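# nemablate

Target-controllability ablation analysis of neural wiring diagrams.

`nemablate` asks a systems-level question about a connectome such as that of
*C. elegans*: if external stimuli drive a small set of sensory neurons (the
touch receptors ALML/ALMR/AVM for anterior gentle touch, PLML/PLMR for
posterior touch), how many body-wall muscles can be steered independently —
and which neuron ablations, singly or in combination, destroy that control?
It is aimed at computational neuroscientists and network scientists who want
systematic, falsifiable predictions of *synthetic essentiality*: pairs or
triplets of individually dispensable neurons whose joint ablation costs
muscle control, the neural analogue of synthetic lethality in genetics.

## Model

The nervous system (N neurons + M muscles) is the structured linear system

    dx/dt = A x + B u,      y = C x,

where A is the weighted directed adjacency of the wiring diagram (chemical
synapses directed, gap junctions reciprocal, neuromuscular junctions
neuron → muscle) plus a nodal-dynamics term a·I shared by all cells, B
injects one independent control signal into each input neuron, and C reads
out the muscle states. By Kalman's criterion the number of independently
controllable muscles equals the generic rank of the output controllability
matrix

    K = [CB, CAB, CA²B, …, CA^(N+M−1)B],

the rank attained for almost every assignment of the free weights. With a
shared nodal term, rank K is decided purely by the walk structure of the
graph — by how many linearly independent control signals can reach the
muscles — so ablating neurons can only remove independent signals, never
create them. The package computes this rank numerically via a block-Krylov
basis of the reachable subspace (validated against an exact
rational-arithmetic oracle), enumerates all single, double and triple
ablations, classifies every set (essential singles, synthetic essential
pairs/triplets, negative interactions), and explains losses through layer
mechanisms (M1/M2/M3) and affected-muscle groups.

## Worked example

The classic joint-loss geometry: muscles MVL18 and MVR18 are innervated
only by VA09, VA10, VB08 and VD09, which receive three independent
upstream control signals.

```python
from nemablate import controllable_muscle_count, make_motif, muscle_loss_profile

motif = make_motif("va_pair_subnetwork")
c, inputs = motif.connectome, motif.inputs
print(controllable_muscle_count(c, inputs, seed=1))                            # 2
print(controllable_muscle_count(c.ablate(["VA09"]), inputs, seed=1))           # 2
print(controllable_muscle_count(c.ablate(["VA09", "VA10"]), inputs, seed=1))   # 1

profile = muscle_loss_profile(c, ["VA09", "VA10"], inputs, orderings=1000, seed=1)
print(sorted(profile.probabilities.items()))
# [('MVL18', 0.499), ('MVR18', 0.501)]
```

Both muscles stay controllable when either VA09 or VA10 is removed alone,
but the double ablation leaves a single independent signal for two muscles:
{VA09, VA10} is a synthetic essential pair, and exactly one of MVL18/MVR18
(each with probability ≈ 1/2) loses control. The same pipeline scales to
whole wiring diagrams through `AblationStudy` or the `nemablate` command
line (`fixtures`, `scan`, `report`, `mechanisms`, `loss-map`); for example
a triple scan over the Group-1 bottleneck motif (six driven neurons, the
sole innervators of four muscles) reports 20 synthetic essential triplets —
every choice of three of the six.

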