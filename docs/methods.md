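# Methods

## State space and encoding

A network of N genes defines 2^N binary cell states.  The gene at list
position i owns bit i (least significant) of the state index
`s = Σ_i 2^i g_i`; gene order is file order, fixed at load time, so the
encoding is deterministic.  Reports print bit strings most-significant
bit first, so the 5-gene state (g_0..g_4) = (0,1,1,0,1) prints as
`10110` and indexes to 22.  The data model allows self-loops (a gene
may regulate itself); the random-network generator excludes them by
default.

## Three-valued regulatory logic

Expression lives in {0,1}, regulatory effect in {−1,0,+1}.  An OFF
input is always neutral; an ON input contributes +1 (activating edge)
or −1 (repressing edge).  This decoupling removes the symmetry artifact
of plain Boolean logic with NOT, where a repressor influences its
target as strongly when absent as when present: in the single-edge
motif, activation B→A gives the landscape T = (0,0,1,−1) and repression
its exact negative, both properly directed.

Effects are combined by binary operators on the effect space.  Of the
3^9 = 19683 possible tables, requiring idempotence, commutativity and
associativity leaves nine (verified by brute force in the test suite);
the six non-constant ones are packaged as `AND_HI`, `AND_LO`, `OR_HI`,
`OR_LO`, `MAX`, `MIN` (the suffix says where different-sign inputs
land).  Dropping idempotence yields 63 tables; the same constraints on
the 16 two-valued operators leave exactly AND and OR.  n-ary
combination is a left fold, safe because only associative operators are
admitted as tree labels.  The forcing function maps effect +1 to
expression 1 and −1 to 0; it is deliberately undefined at 0 (an
explicit error), and every caller branches on neutrality first.

## Energy

With agreement energy L = −1, disagreement H = +1 and neutral (L+H)/2 =
0 (defaults used throughout; both are configurable), the energy of a
state is the sum over genes of the per-gene term.  All energies are
integers in [−N, +N]; −N means every gene agrees with its input signal.
The implementation evaluates each target's tree once over all 2^N
states with vectorised table lookups (O(2^N · tree size) per gene); an
independent scalar per-state reimplementation serves as the oracle in
the tests.

## Attractors and basins

An attractor is a maximal connected equal-energy plateau none of whose
members has a strictly lower-energy neighbor.  Plateau semantics (rather
than strict minima) are required because degenerate attractors —
plateaus whose free genes do not change the energy — are biologically
meaningful stable states.  Basins are computed by reverse BFS from the
attractor: a state belongs if a path of equal-or-decreasing-energy
steps leads into the attractor.  Flat steps are traversable in both
directions by default; a strict variant (`allow_flat=False`) is
flag-gated and provably yields subsets.  Constraint checking accepts a
landscape when every named pattern state is a member of some attractor
(membership in a degenerate attractor counts); surplus attractors are
reported, never grounds for rejection.  Partial patterns (not every
gene pinned) match any attractor containing an agreeing state.

## Configuration counting and enumeration

With p operators and k inputs the number of distinct trees is
N(p,1) = 1, N(p,2) = p, N(p,k) = p(3p−2)^(k−2), computed in exact
integer arithmetic (the packaged 14-node network has ≈ 2.6·10^25
configurations).  The exhaustive enumerator realises this count
constructively: trees over the first k−1 inputs are each extended by
the next input in exactly 3p−2 ways — appended to the root's operator
run, or joined by each differing operator to the whole tree, to the
root's first child, or to the root's last child.  Enumeration starts
from the maximally left-heavy single-operator tree and cycles operators
before leaf rearrangements (the cheapest change first).  Distinctness
is verified against a canonical form (flatten maximal same-operator
runs, sort children) exhaustively for p ∈ {2..6}, k ∈ {1..5}.

A caveat worth recording: the closed form undercounts the *full* set of
canonically distinct trees for k ≥ 4 (for p = 2, k = 4 there are 52
distinct canonical forms but N = 32).  The enumerator therefore
deliberately targets the closed-form count — the quantity all reported
configuration-space sizes are built on — rather than exhausting every
canonical form; its guarantees are exactly "count equals the closed
form" and "no duplicates".

The network-level search space is the Cartesian product of per-target
enumerations, streamed with the smallest trees outermost, and guarded
at 10^7 landscapes (overridable) since exhaustion beyond that scale is
impractical.  The stochastic sampler draws, per target, a uniformly
random split point recursively (giving the tree shape), a uniform leaf
permutation, and iid uniform operator labels.  No reference
distribution exists for this sampler, so prevalence statistics from
stochastic searches are reproducible only under a fixed seed, not
across implementations.

## Continuous interpolation

The multilinear extension's coefficients solve Mω = T with
M_ab = 1 iff b ⊆ a (bitwise).  ω is computed by the in-place subset
Möbius transform in O(n·2^n) — exact integers for integer T — rather
than dense inversion, which a 15-gene landscape could not afford; the
dense Kronecker construction (`build_M`, guarded at n ≤ 14) exists for
verification and agrees with the transform on all tested sizes.
Entropy uses the natural logarithm (a base change only rescales the
temperature) with the continuous-extension convention 0·log 0 = 0, so
corners have zero entropy.  Free energy F = E − T·S has stationary
points at s_i = logistic(−∂E/∂s_i / T), the sigmoid gain property
checked numerically in the tests.  Path finding on the continuous
landscape is out of scope.

## Marble walks

From state s the walk moves to one of the N neighbors or stays, with
probabilities softmax(−β·ΔE) (stay has ΔE = 0).  β ≥ 0 is the noise
level: smaller β means more uphill moves.  Frozen genes (media
components a cell cannot switch) are removed *before* normalisation —
the walker has fewer admissible moves, not a rescaled stay probability.
Move selection uses the smallest index whose cumulative probability
exceeds a uniform draw; moves are ordered by bit, stay last.  A walk
arrives when the state is unchanged for 3 consecutive updates
(configurable, ≥ 2).  Because flat regions could stall indefinitely, a
safeguard of 10·N·stop_repeats steps censors runaway walks; censored
walks are counted under "Other" alongside terminations outside any
named attractor.  Ensembles credit terminal states inside a degenerate
attractor to that attractor (members pooled), and marbles initialised
"in" a degenerate attractor are split evenly over its member states.
Each (initial state, replicate) pair draws from its own RNG stream
derived from the master seed by a spawn-key counter, so tables are
byte-identical under a fixed seed regardless of execution order.
Defaults (β = 1, 100 marbles, 3 replicates) match small exploratory
runs; the packaged examples use 10^4 marbles where probabilities are
quoted.

## Visualisation

The layout of an N-cube is recursive: two copies of the (N−1)-layout,
the outer scaled by a constant factor (2.2), corresponding corners
joined; the base case is a square.  The exact flattening is otherwise
unconstrained, so concentric placement was chosen for determinism and
simplicity.  Layouts are refused above seven dimensions; larger systems
are handled by slicing fixed hyperplanes or merging gene groups into
shared dimensions.  Merged landscapes keep only full states where each
group is internally uniform — their reduced neighbors are *not*
Hamming-1 neighbors of the full landscape, so apparent minima may
differ; this caveat is attached to every merged result and is mandatory
in rendered captions.  Landscape plots draw states as energy-colored
pie glyphs (one sector per gene, filled = ON, diverging colormap
symmetric about zero so agreement/disagreement is visually signed),
downhill arrows with width ∝ |ΔE|, dashed flat segments, and optional
basin rings.

## Packaged networks and what the tests show

The 14-node reprogramming network is transcribed from a published
curated interaction table (38 signed edges; exact).  The 15-node
pluripotency network's diagram is published only graphically; the
packaged 26-edge reconstruction follows the textual description of its
interactions, and its in-degree sequence reproduces the published exact
configuration count, which is the quantity the tests assert.  The toy
network is synthetic: a 5-gene topology chosen so that the exhaustive
two-operator search exhibits the reference behaviour (both constraint
states as attractors plus one surplus attractor).  The constraint
patterns packaged for the two biological networks are likewise partial,
synthetic stand-ins for binarized expression profiles published only
in figure form; they exercise the constraint machinery and example
workflows but are not treated as exact reference data.  Consequently,
passing tests demonstrate the correctness of the algebra, counting,
energy map, attractor semantics and walk statistics — not the
biological fidelity of any particular fixture landscape.

## Known limitations

Non-commutative and non-associative operators are enumerable but not
admitted as tree labels (the enumerator's redundancy elimination relies
on both properties).  Cyclic attractors and asynchronous update
dynamics are out of scope, as is path finding on the continuous
landscape.  Stochastic-search prevalence percentages depend on the
sampler's tree distribution and are not comparable across
implementations.
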