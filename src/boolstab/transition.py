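"""Attractor transition matrices under single-node flips.

Local noise flips one randomly chosen node of an attractor state; the
deterministic dynamics then relax the flipped state to some attractor.
Exhausting all ``N * l_a`` (state, node) flips of attractor ``a`` yields
flip counts ``nu[a, b]`` and the row-stochastic transition probabilities
``m[a, b] = nu[a, b] / (N * l_a)``.

The global-randomization baseline resets the whole state uniformly at
random instead; there every row of the matrix equals the basin-size
distribution, and its trace is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractors import AttractorLandscape
from .network import BooleanNetwork, synchronous_update

__all__ = [
    "TransitionMatrix",
    "single_flip_neighbors",
    "build_transition_matrix",
    "global_randomization_matrix",
]


class LandscapeMismatchError(ValueError):
    """The supplied landscape was not computed from the supplied network."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix of attractor-to-attractor transition probabilities.

    Attributes
    ----------
    m:
        ``n_att x n_att`` probabilities; row ``a`` sums to 1.
    counts:
        Integer flip-outcome counts ``nu[a, b]``; ``None`` for analytic
        (basin-based) matrices that involve no finite trials.
    trials:
        Flip attempts per source attractor (``N * l_a``); ``None`` for
        analytic matrices.
    """

    m: np.ndarray = field(repr=False)
    counts: np.ndarray | None = field(default=None, repr=False)
    trials: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_att(self) -> int:
        return self.m.shape[0]

    @property
    def is_analytic(self) -> bool:
        return self.counts is None

    @property
    def trace(self) -> float:
        return float(np.trace(self.m))

    def to_dict(self) -> dict:
        out = {"n_att": self.n_att, "m": self.m.tolist()}
        if self.counts is not None:
            out["counts"] = self.counts.tolist()
            out["trials"] = self.trials.tolist()
        return out


def single_flip_neighbors(state: int, n_nodes: int) -> list[int]:
    """The ``N`` states at Hamming distance 1 from ``state``, in node order."""
    if not 0 <= state < (1 << n_nodes):
        raise ValueError(f"state {state} out of range for N={n_nodes}")
    return [state ^ (1 << i) for i in range(n_nodes)]


def _check_consistency(net: BooleanNetwork, landscape: AttractorLandscape) -> None:
    if landscape.n_nodes != net.n_nodes:
        raise LandscapeMismatchError(
            f"landscape has N={landscape.n_nodes}, network has N={net.n_nodes}"
        )
    # cheap spot check: every attractor cycle must close under the network map
    for a in landscape.attractors:
        for j, s in enumerate(a.states):
            if synchronous_update(net, s) != a.states[(j + 1) % a.length]:
                raise LandscapeMismatchError(
                    "attractor cycle does not close under the network update"
                )


def build_transition_matrix(
    net: BooleanNetwork, landscape: AttractorLandscape
) -> TransitionMatrix:
    """Exhaustive single-flip transition matrix of a network.

    For every state of every attractor, each of the ``N`` single-node
    flips is relaxed to its attractor through the precomputed basin map
    (exact, since the dynamics are deterministic).  Counts are integers;
    probabilities are formed only at assembly, so row sums are exact.
    """
    _check_consistency(net, landscape)
    n_att = landscape.n_att
    n = net.n_nodes
    counts = np.zeros((n_att, n_att), dtype=np.int64)
    trials = np.zeros(n_att, dtype=np.int64)
    basin = landscape.basin_of
    for alpha, attr in enumerate(landscape.attractors):
        states = np.asarray(attr.states, dtype=np.int64)
        flips = states[:, None] ^ (np.int64(1) << np.arange(n, dtype=np.int64))
        dest = basin[flips.ravel()]
        counts[alpha] = np.bincount(dest, minlength=n_att)
        trials[alpha] = n * attr.length
    m = counts / trials[:, None]
    return TransitionMatrix(m=m, counts=counts, trials=trials)


def global_randomization_matrix(landscape: AttractorLandscape) -> TransitionMatrix:
    """Baseline matrix for noise that rerandomises the entire state.

    A global reset lands in basin ``b`` with probability equal to the
    basin size, regardless of the source attractor, so every row equals
    the basin-size vector.  Consequently the stationary distribution is
    the basin-size distribution and the trace is exactly 1.
    """
    b = np.asarray(landscape.basin_sizes, dtype=float)
    m = np.tile(b, (landscape.n_att, 1))
    return TransitionMatrix(m=m, counts=None, trials=None)
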