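# Methods

## Model

A synchronous Boolean network has `N` binary nodes; node `i` has an
ordered list of `k_i` inputs and a truth table of `2^{k_i}` entries. All
nodes update in parallel from the same global state, so the dynamics are
a deterministic map `F` on the `2^N` global states. Global states are
encoded as integers with the little-endian convention (bit `i` of the
integer is the state of node `i`); input configurations are encoded the
same way over a node's input list (input `j` contributes bit `j`). Every
module of the package shares these conventions, as does the on-disk
BoolNet rule format.

Every trajectory of a finite deterministic map ends on a cycle: a fixed
point (`ℓ = 1`) or a limit cycle (`ℓ > 1`). The basin of an attractor is
the set of states whose trajectories reach it; normalized basin sizes
`b_α` sum to 1.

## Noise model

Local noise is a single-node flip applied to an attractor state. The
model assumes noise is rare: between events the system has relaxed back
onto an attractor, so perturbations of transient states never arise and
dwell time in transients is negligible. Under that assumption the noisy
system is exactly a Markov jump chain over attractors with the
transition probabilities

    m_αβ = ν_αβ / (N ℓ_α),

obtained by flipping each of the `N` nodes once in each of the `ℓ_α`
states of attractor `α` and relaxing deterministically. Relaxation uses
the precomputed basin map, which is exact — identical to re-simulating
the trajectory of every flipped state — because the dynamics between
noise events are deterministic. Flip counts are kept as integers and
divided only at matrix assembly, so row-stochasticity holds at machine
precision.

The global-randomization baseline replaces the flip by a uniform reset
of the entire state. The landing basin is then independent of the
source, every row of the baseline matrix equals `b`, its stationary
distribution is `b`, and its trace is exactly `Σ_α b_α = 1`. This is the
reference point against which `Tr M` is read.

## Attractor enumeration

The full successor array (`2^N` entries, `uint32`) is built with
vectorised bit arithmetic, one node at a time. Pointer doubling —
squaring the map `N` times — advances every state by `2^N` steps at cost
`O(N·2^N)`, which is guaranteed to land on its cycle since no transient
can exceed the state-space size. The image of that map is exactly the
set of on-cycle states; walking the successor array groups them into
cycles. Cycles are canonicalised by rotating to start at their smallest
state integer and attractors are sorted by that state, so indices are
reproducible across runs. Scanning candidate states in ascending order
makes the first unseen member of each cycle its minimum, so
canonicalisation is free.

Exhaustive work is refused above a configurable cap (default `N = 24`,
about 16.8M states, ~130 MB of transient arrays). No sampling-based
search is provided for larger networks; all ensemble experiments here
use `N ≤ 20`.

## Stationary distribution

With the row-stochastic convention the stationary law is the *left*
principal eigenvector, `v M = v`. The attractor chain is frequently
reducible (several closed communicating classes) and often periodic —
even the two-node swap example has period 2 — so plain power iteration
need not converge. The implementation computes the well-defined limit of
the uniform-start time-average occupancy directly:

1. strongly connected components of the positive-entry graph
   (`scipy.sparse.csgraph`), identifying closed classes as those with no
   outgoing probability;
2. the stationary law inside each closed class by a dense linear solve
   (the `(P^T − I)` system with one row replaced by the normalisation);
3. absorption probabilities into each closed class from the uniform
   initial distribution via the fundamental matrix of the transient
   block.

The mixture of class laws weighted by absorption probabilities satisfies
`v M = v` exactly; the implementation verifies `‖vM − v‖∞ ≤ 1e-10` and
raises if violated. For an irreducible chain this reduces to the unique
stationary distribution, and time averages of periodic chains are
handled correctly (the swap network yields (1/4, 1/2, 1/4)). A
`return_info` flag reports reducibility.

## Similarity, entropy, transition bias

`σ_α` (pair-count form) is the probability that two distinct cycle
states agree at a uniformly random position:
`mean_i [C(n0,2)+C(n1,2)] / C(ℓ,2)` with `n0`, `n1` the per-position
symbol counts; fixed points are assigned `σ = 1` (all positions trivially
agree). The frequency-squared approximation `mean_i [μ_i² + (1−μ_i)²]`
is bounded below by 1/2 and differs from the pair-count form by `O(1/ℓ)`.
Landscape-level similarity is the unweighted mean over attractors (no
basin or length weighting). For i.i.d. uniform cycle states the
approximation tends to 1/2, the "random states" floor.

Normalized entropy is `H = −Σ p log2 p / log2 n` with `0·log 0 = 0`; a
single-outcome distribution is defined to have `H = 0` (it is fully
localized, and the usual normaliser `log2 1` vanishes). The entropy gap
is reported as `ΔH = H(b) − H(v)`, so positive values mean the noisy
dynamics occupy a narrower set of attractors than basin sizes predict;
the opposite sign is available via `convention="signed_terms"`.

Transition bias normalizes each off-diagonal rate by the *target* basin,
`r_αβ = m_αβ / b_β`, the unique convention under which every pair gives
exactly 1 for the global-randomization baseline — making `R>` (mean over
pairs into larger basins), `R<` (into smaller) and their ratio directly
interpretable as deviations from basin-neutral hopping. Pairs with equal
basins are excluded; with no qualifying pairs (single attractor, or all
basins equal) the bias is reported as undefined rather than as a number,
and ensemble aggregation averages only over networks where it is
defined and finite. Source-basin normalization is available as a switch.

## Noisy simulation

`simulate_attractor_hopping` realises the jump chain directly: starting
from a uniformly random attractor state, each noise event picks a
uniform phase of the current cycle and a uniform node, flips it, and
relaxes via the basin map. Dwell time is counted in noise events charged
to the source attractor — precisely the chain whose stationary law is
`v`, which is what the event-count convention is chosen to match; raw
step counts including transients would differ only by `O(transient /
mean dwell)` corrections outside the rare-noise regime. One seeded
generator (NumPy PCG64) drives the run; phases and node choices are
pre-drawn as arrays, so runs are bit-reproducible given the seed.

## Random ensembles

The generator produces in-degree-regular networks: each node gets `k`
distinct inputs sampled uniformly without replacement (self-inputs
allowed by default; a switch forbids them), and each truth-table entry
is independently 0 with probability `p`. Distinct inputs keep tables at
exactly `2^k` entries, and "degree" means in-degree because the
sensitivity formula `s = 2p(1−p)k` counts a function's inputs. Sweeps
are parameterised by `s`, inverted to the `p ≤ 1/2` branch
`p = (1 − √(1 − 2s/k))/2`; cells with `s > k/2` are unattainable and
skipped with a warning. Per-replicate seeds are a 31-bit BLAKE2 hash of
`(base_seed, k, s, replicate)`, so enlarging a sweep never reshuffles
existing cells.

Default problem sizes are chosen for a desk machine: `N = 20` with 20
replicates per cell for trace sweeps (a few hundred milliseconds per
network), `N = 15` with 50–1000 replicates for similarity and bias
sweeps (milliseconds per network). The transition-bias ratio deserves a
note: the per-network ratio distribution is heavy-tailed (a single
network's `R<` can be nearly zero, inflating its ratio a hundredfold),
so the mean of per-network ratios does not stabilize at desk-scale
ensemble sizes. Two aggregations are therefore provided: `run_ensemble`
reports the mean over networks where the ratio is defined and finite,
while `ensemble_bias_ratio` pools the pair-level rates across the whole
ensemble and forms a single `R>/R<` from the pooled means — the robust
estimator of the ensemble-level bias, and the one the acceptance script
reports (over 1000 networks).

## What the synthetic ensembles do and do not show

Random regular networks with bias-`p` tables probe the framework across
the ordered-to-chaotic spectrum via `s`, but they lack the degree
heterogeneity, canalizing functions, modularity and redundancy of real
regulatory networks. Passing tests on these ensembles demonstrates the
correctness of the machinery and the qualitative phenomena (traces above
the basin baseline, similarity above the random floor, bias toward
smaller basins at low sensitivity) for this model class — not
quantitative predictions for any particular biological network. Real
models can be analysed through the BoolNet importer; curated model
collections are not bundled.

## Degenerate inputs and edge cases

- A node with zero inputs is a constant (one-entry table); the BoolNet
  constant forms `A, 0` / `A, 1` round-trip to it.
- A single-attractor landscape gives `M = [[1]]`, `v = (1)`, `H = 0` and
  undefined transition bias.
- `bias_for_sensitivity` clamps a slightly negative discriminant at
  `s = k/2` (maximum sensitivity) to 0 before the square root.
- BoolNet expressions are validated against a strict token grammar
  (names, `! & | ( ) 0 1`) before compilation, and parse errors carry
  line numbers.

## Limitations

Exhaustive enumeration limits networks to `N ≤ 24`; no SAT/BDD symbolic
attractor search is provided. The noise model is single-node,
uniform-rate, uncorrelated and applied only to attractor states;
multi-node flips, biased or correlated noise, noise during transients
and asynchronous update schemes are out of scope. Probabilistic update
rules (as opposed to deterministic rules plus external noise) are a
different modelling framework and are not covered.
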