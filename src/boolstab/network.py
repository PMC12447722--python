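"""Synchronous Boolean networks and random regular ensembles.

A Boolean network is a set of ``N`` binary nodes, each updated in parallel
by a fixed Boolean function of its inputs.  Global states are encoded as
integers in ``[0, 2**N)`` with the little-endian convention: bit ``i`` of
the integer is the state of node ``i``.  Every module in this package
shares that encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "synchronous_update",
    "successor_table",
    "random_regular_network",
    "sensitivity",
    "bias_for_sensitivity",
]

#: Largest node count for which exhaustive state-space work is permitted
#: by default (2**24 ~ 16.8M states).
DEFAULT_STATE_CAP = 24


class InvalidStateError(ValueError):
    """A state integer lies outside ``[0, 2**N)``."""


class StateSpaceTooLargeError(ValueError):
    """Exhaustive enumeration was requested above the node-count cap."""


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``.
    inputs:
        Per-node ordered tuple of in-neighbour indices.  The order fixes
        how input configurations are encoded: input ``j`` of node ``i``
        contributes bit ``j`` of the truth-table index.
    tables:
        Per-node truth table: a tuple of ``2**k_i`` entries in ``{0, 1}``,
        indexed by the integer-encoded input configuration.  A node with
        no inputs has a single-entry table (a constant).
    meta:
        Optional provenance record (generator parameters or source file).
    """

    n_nodes: int
    inputs: tuple[tuple[int, ...], ...]
    tables: tuple[tuple[int, ...], ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("network must have at least one node")
        if len(self.inputs) != self.n_nodes or len(self.tables) != self.n_nodes:
            raise ValueError("inputs and tables must have one entry per node")
        object.__setattr__(self, "inputs", tuple(tuple(t) for t in self.inputs))
        object.__setattr__(self, "tables", tuple(tuple(t) for t in self.tables))
        for i, (inp, tab) in enumerate(zip(self.inputs, self.tables)):
            if len(tab) != 1 << len(inp):
                raise ValueError(
                    f"node {i}: table has {len(tab)} entries, "
                    f"expected {1 << len(inp)} for {len(inp)} inputs"
                )
            if any(j < 0 or j >= self.n_nodes for j in inp):
                raise ValueError(f"node {i}: input index out of range")
            if any(v not in (0, 1) for v in tab):
                raise ValueError(f"node {i}: table entries must be 0 or 1")

    @property
    def n_states(self) -> int:
        return 1 << self.n_nodes

    def validate_state(self, state: int) -> None:
        if not 0 <= state < self.n_states:
            raise InvalidStateError(
                f"state {state} out of range for N={self.n_nodes}"
            )

    def state_to_bits(self, state: int) -> tuple[int, ...]:
        """Decode a state integer into the tuple ``(x_0, ..., x_{N-1})``."""
        self.validate_state(state)
        return tuple((state >> i) & 1 for i in range(self.n_nodes))

    @staticmethod
    def bits_to_state(bits: Sequence[int]) -> int:
        """Encode a bit sequence (node 0 first) into a state integer."""
        return sum((int(b) & 1) << i for i, b in enumerate(bits))


def synchronous_update(net: BooleanNetwork, state: int) -> int:
    """Apply one parallel update step: every node reads the same input state.

    Pure and deterministic: the successor of a state never changes.
    """
    net.validate_state(state)
    nxt = 0
    for i in range(net.n_nodes):
        idx = 0
        for j, src in enumerate(net.inputs[i]):
            idx |= ((state >> src) & 1) << j
        nxt |= net.tables[i][idx] << i
    return nxt


def successor_table(net: BooleanNetwork, cap: int = DEFAULT_STATE_CAP) -> np.ndarray:
    """Successor of every state, as a ``uint32`` array of length ``2**N``.

    The table is built node-by-node with vectorised bit arithmetic, so the
    cost is ``O(N * 2**N)`` with small constants.  Exhaustive work is
    refused above ``cap`` nodes.
    """
    if net.n_nodes > cap:
        raise StateSpaceTooLargeError(
            f"N={net.n_nodes} exceeds the exhaustive-enumeration cap of {cap}"
        )
    states = np.arange(net.n_states, dtype=np.uint32)
    succ = np.zeros(net.n_states, dtype=np.uint32)
    for i in range(net.n_nodes):
        idx = np.zeros(net.n_states, dtype=np.uint32)
        for j, src in enumerate(net.inputs[i]):
            idx |= ((states >> np.uint32(src)) & np.uint32(1)) << np.uint32(j)
        bits = np.asarray(net.tables[i], dtype=np.uint32)[idx]
        succ |= bits << np.uint32(i)
    return succ


def random_regular_network(
    n_nodes: int,
    k: int,
    p: float,
    seed: int,
    allow_self_inputs: bool = True,
) -> BooleanNetwork:
    """Generate a random in-degree-regular Boolean network.

    Every node receives exactly ``k`` distinct inputs drawn uniformly at
    random (self-inputs permitted unless ``allow_self_inputs`` is False),
    and each truth-table entry is independently 0 with probability ``p``
    (the bias).  One seed drives both topology and table sampling, so
    identical arguments reproduce the network bit for bit.
    """
    if not 0 < k < n_nodes:
        raise ValueError(f"in-degree k={k} must satisfy 0 < k < N={n_nodes}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bias p={p} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    inputs = []
    tables = []
    for i in range(n_nodes):
        if allow_self_inputs:
            pool = np.arange(n_nodes)
        else:
            pool = np.delete(np.arange(n_nodes), i)
        inp = rng.choice(pool, size=k, replace=False)
        # entry is 0 with probability p, 1 otherwise
        tab = (rng.random(1 << k) >= p).astype(np.uint8)
        inputs.append(tuple(int(x) for x in inp))
        tables.append(tuple(int(x) for x in tab))
    meta = {
        "generator": "random_regular_network",
        "k": k,
        "p": p,
        "seed": seed,
        "allow_self_inputs": allow_self_inputs,
    }
    return BooleanNetwork(n_nodes, tuple(inputs), tuple(tables), meta)


def sensitivity(p: float, k: int) -> float:
    """Average sensitivity ``s = 2 p (1 - p) k`` of bias-``p`` functions.

    ``s`` is the expected number of output changes caused by flipping a
    single input of a random ``k``-input Boolean function with output bias
    ``p``; it is the standard order parameter separating ordered (s < 1)
    from chaotic (s > 1) random Boolean networks.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bias p={p} must lie in [0, 1]")
    if k < 1:
        raise ValueError(f"in-degree k={k} must be >= 1")
    return 2.0 * p * (1.0 - p) * k


class UnattainableSensitivityError(ValueError):
    """Requested sensitivity exceeds the maximum ``k/2`` at the given degree."""


def bias_for_sensitivity(s: float, k: int) -> float:
    """Invert ``s = 2 p (1 - p) k`` on the branch ``p <= 1/2``.

    The two roots ``p`` and ``1 - p`` give the same sensitivity; the lower
    branch is returned so that ``p`` keeps its meaning as the probability
    of output 0.
    """
    if k < 1:
        raise ValueError(f"in-degree k={k} must be >= 1")
    if s < 0:
        raise ValueError(f"sensitivity s={s} must be >= 0")
    disc = 1.0 - 2.0 * s / k
    if disc < -1e-12:
        raise UnattainableSensitivityError(
            f"s={s} exceeds the maximum k/2={k / 2} at k={k}"
        )
    return (1.0 - math.sqrt(max(disc, 0.0))) / 2.0
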