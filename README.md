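# logicscape

Energy landscapes of logical gene regulatory networks.

`logicscape` maps a signed gene regulatory network (GRN) plus a
configuration of three-valued logical operators onto a discrete energy
landscape over all 2^N binary cell states, and provides the analysis
tools that make that landscape useful: attractor and basin detection,
exact multilinear interpolation to a continuous energy, stochastic
"marble" random walks that probe basin strengths and simulate
reprogramming, flattened-hypercube visualisation, and exhaustive or
stochastic search of the operator-configuration space against
experimental attractor constraints.

It is aimed at systems biologists modelling cell-fate decisions —
pluripotency maintenance, reprogramming, lineage commitment — who have
a curated GRN topology and binarized expression profiles of known
stable states, and want a global view of *all* stable states the
network supports rather than the trajectory-by-trajectory view of rate
equations or synchronous Boolean updating.

## The model

Each of the N genes is ON (1) or OFF (0); a cell state is the joint
assignment, indexed by `s = Σ_i 2^i g_i`.  A regulatory input acts
through the *effect* space {−1, 0, +1} (repressive / neutral /
activating): an OFF input always has neutral effect, an ON input has
effect +1 through an activating edge and −1 through a repressing one.
Multiple inputs are combined by binary operators on the effect space;
demanding idempotence, commutativity and associativity leaves exactly
nine of the 3^9 = 19683 possible operators, six of them non-trivial
(`AND_HI`, `AND_LO`, `OR_HI`, `OR_LO`, `MAX`, `MIN`).  An assignment of
one operator expression tree per multi-input gene is a *configuration*;
with p operators a gene with k inputs admits
`N(p,k) = p(3p−2)^(k−2)` distinct trees.

The energy of a state sums one term per gene: L = −1 if the gene's
expression agrees with the value its net input signal forces, H = +1 if
it disagrees, and (L+H)/2 = 0 if the signal is neutral.  Attractors are
equal-energy plateaus with no lower Hamming-1 neighbor; their basins
are the states connected to them by non-increasing-energy paths.  A
Boltzmann-weighted random walk (move probabilities ∝ `exp(−β ΔE)`,
including a stay option) turns the landscape into reach probabilities
between states and attractors.  The discrete landscape also has a
unique multilinear extension `E(s) = Σ_b ω_b Π_{i∈b} s_i` with
`ω = M⁻¹T`, which combined with the mixing entropy yields a free energy
with sigmoid gain functions.

## Worked example

Three networks ship with the package: a 5-gene toy network (`"toy"`,
32 states), a 15-node pluripotency-maintenance network
(`"pluripotency"`, 32768 states) and a 14-node MEF→iPSC reprogramming
network (`"mef_ipsc"`, 16384 states).

```python
from logicscape import fixture, operator_set, search_configurations
from logicscape.landscape import compute_landscape, find_attractors
from logicscape.marble import MarbleConfig, reprogramming_matrix
from logicscape.network import state_string

grn, constraints = fixture("toy")
result = search_configurations(grn, operator_set("bar"), constraints,
                               mode="exhaustive")
print(result.n_tested, len(result.valid))   # 16 3

config = result.valid[1]
land = compute_landscape(grn, config)
for att in find_attractors(land):
    print([state_string(s, 5) for s in sorted(att.states)], att.energy)
```

The exhaustive search over the {`AND_HI`, `OR_HI`} pair tests all 16
distinct configurations and finds 3 whose landscapes contain both
constraint states.  The chosen configuration yields three attractors:

```
['10110'] -3.0     # constraint state "blue" (index 22)
['11101'] -3.0     # constraint state "red"  (index 29)
['01010'] -2.0     # a surplus attractor predicted by the model
```

The two required states are attractors and the search additionally
predicts a stable state with only genes B and D ON.  Releasing 10,000
marbles from each attractor at noise level β = 1.0 gives the
reprogramming matrix:

```python
mean, std = reprogramming_matrix(land, find_attractors(land),
                                 MarbleConfig(beta=1.0, n_marbles=10000, seed=1))
print(mean.round(3))
#        A0     A1     A2  Other
# A0  0.672  0.230  0.032  0.067
# A1  0.230  0.653  0.036  0.081
# A2  0.243  0.262  0.412  0.082
```

Rows are initial attractors, columns the probability of ending in each
attractor (or elsewhere): the two deep attractors retain two thirds of
their cells, while the shallower surplus attractor (A2) loses more than
half of its population to them — it is the easiest state to reprogram
away from.

The same workflow is available from the shell:

```sh
logicscape count-configs --network mef_ipsc       # 26142282979403407520956416
logicscape search --network toy --operators bar --mode exhaustive --out search_out
logicscape marbles --network toy --config config.json --seed 7 --out marbles_out
logicscape plot --network toy --config config.json --out plot_out
```

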