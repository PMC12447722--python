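# boolstab

Attractor stability and noise-induced attractor transitions in
synchronous Boolean networks.

Boolean networks are a standard coarse-grained model of gene regulatory
and signalling systems: each node carries a binary state updated in
parallel by a fixed logical function of its inputs, and every trajectory
settles into an attractor — a fixed point or a limit cycle — commonly
identified with a stable cellular phenotype. Real cells are noisy,
though: a stray fluctuation can flip a single gene's state and kick the
system out of its attractor into another one. `boolstab` quantifies that
process.

## The framework

For a network with `N` nodes and attractors `α = 1..n_att` (attractor
`α` a cycle of `ℓ_α` states), local noise is modelled as a single-node
flip applied to an attractor state. Flipping each of the `N` nodes once
in every state of attractor `α` gives `N·ℓ_α` trials; if `ν_αβ` of them
relax (deterministically) into the basin of attractor `β`, the transition
probability is

    m_αβ = ν_αβ / (N ℓ_α),

a row-stochastic matrix `M` defining a Markov chain over attractors.
From `M` the package computes:

- **Stability** `Tr M` — the summed probabilities of returning to the
  same attractor after a flip. The baseline is *global randomization*
  (noise resets the whole state uniformly at random), whose matrix has
  every row equal to the basin-size vector `b` and hence trace exactly 1;
  `Tr M > 1` means attractors hold on to the system more strongly than
  their basin sizes predict. `Tr M / n_att` is the average per-attractor
  stability.
- **Dominance** — the stationary distribution `v` of the chain
  (`v M = v`), the long-run fraction of time spent in each attractor
  under rare noise; validated against direct noisy simulation.
- **Within-attractor similarity** `σ_α` — the probability that two
  distinct cycle states agree at a random position (pair-count form, with
  `σ = 1` for fixed points, and a frequency-squared approximation whose
  floor for random states is 1/2).
- **Entropy** `H` — normalized Shannon entropy of `v`, and the gap
  `ΔH = H(b) − H(v)`; positive values mean noise localizes the dynamics
  on fewer attractors than basin sizes suggest.
- **Transition bias** `R>/R<` — basin-normalized rates `m_αβ/b_β`
  averaged over transitions into larger (`R>`) versus smaller (`R<`)
  basins; the ratio is exactly 1 under global randomization.

Random regular ensembles (every node with in-degree `k`, truth-table
entries 0 with bias probability `p`) are swept using the average
sensitivity `s = 2p(1−p)k` as the control parameter.

## Worked example

The two-node swap network (`A` copies `B`, `B` copies `A`) has three
attractors: the fixed points 00 and 11 and the 2-cycle {01, 10}, with
basin sizes 1/4, 1/2, 1/4 (attractors are ordered by their smallest
state, so the cycle is index 1).

```bash
$ cat toy.bnet
targets, factors
A, B
B, A

$ boolstab matrix toy.bnet
0,1,0
0.5,0,0.5
0,1,0
```

Every flip of a fixed-point state lands on a cycle state, and the two
flips of each cycle state land on the two fixed points — so the diagonal
is zero (`Tr M = 0`: under single-node noise these attractors never
retain the system, far below the basin-size baseline of 1).

```bash
$ boolstab report toy.bnet
{
  ...
  "trace": 0.0,
  "stationary": [0.25, 0.5, 0.25],
  "basin_sizes": [0.25, 0.5, 0.25],
  "similarity_exact": 0.666666666667,
  ...
}
```

The stationary distribution (1/4, 1/2, 1/4) says the noisy system spends
half its time on the cycle; `similarity_exact` is the mean of σ = 1 for
each fixed point and σ = 0 for the maximally dissimilar cycle. A direct
simulation agrees:

```bash
$ boolstab simulate toy.bnet --events 100000 --seed 3
{
  "n_events": 100000,
  "seed": 3,
  "time_fractions": [0.24962, 0.5, 0.25038],
  "n_jumps": 99999
}
```

(with `Tr M = 0` every single event is a jump).

Ensemble sweeps run from a config file:

```bash
$ boolstab ensemble --config sweep.json -o grid.csv   # {"n_nodes": 15,
  "degrees": [2, 3], "sensitivities": [0.5, 1.0], "replicates": 100,
  "base_seed": 0}
```

giving per-cell means and standard errors of `n_att`, `Tr M`,
`Tr M/n_att`, σ, `H`, `ΔH` and `R>/R<`.

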