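"""Exhaustive attractor enumeration and basin analysis.

For networks small enough to enumerate (``N`` up to a configurable cap),
the full successor map is built and every state is assigned to the
attractor its trajectory reaches.  Attractors are canonicalised by
rotating each cycle to start at its smallest state integer and sorting
attractors by that state, so indices are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    DEFAULT_STATE_CAP,
    BooleanNetwork,
    successor_table,
    synchronous_update,
)

__all__ = ["Attractor", "AttractorLandscape", "enumerate_landscape", "attractor_of"]


@dataclass(frozen=True)
class Attractor:
    """An ordered cycle of states; a fixed point has length 1.

    ``states[j]`` maps to ``states[(j+1) % length]`` under one synchronous
    update, and ``states[0]`` is the smallest state integer in the cycle.
    """

    states: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @staticmethod
    def from_cycle(cycle: tuple[int, ...]) -> "Attractor":
        """Canonicalise a cycle: rotate so the minimal state comes first."""
        j = min(range(len(cycle)), key=lambda i: cycle[i])
        return Attractor(tuple(cycle[j:]) + tuple(cycle[:j]))


@dataclass(frozen=True)
class AttractorLandscape:
    """All attractors of a network plus the basin partition of state space.

    Attributes
    ----------
    n_nodes:
        Node count of the underlying network.
    attractors:
        Canonically ordered attractors, indexed ``0 .. n_att - 1``.
    basin_of:
        ``int32`` array of length ``2**N`` mapping every state to the
        index of the attractor its trajectory reaches.
    basin_sizes:
        Normalised basin sizes ``b`` (fractions of state space, sum 1).
    """

    n_nodes: int
    attractors: tuple[Attractor, ...]
    basin_of: np.ndarray = field(repr=False)
    basin_sizes: np.ndarray = field(repr=False)

    @property
    def n_att(self) -> int:
        return len(self.attractors)

    @property
    def n_states(self) -> int:
        return 1 << self.n_nodes

    def to_dict(self) -> dict:
        """JSON-ready summary (attractor states and basin sizes)."""
        return {
            "n_nodes": self.n_nodes,
            "n_att": self.n_att,
            "attractors": [list(a.states) for a in self.attractors],
            "lengths": [a.length for a in self.attractors],
            "basin_sizes": [float(b) for b in self.basin_sizes],
        }


def enumerate_landscape(
    net: BooleanNetwork, cap: int = DEFAULT_STATE_CAP
) -> AttractorLandscape:
    """Enumerate all attractors and assign every state to its basin.

    The successor map ``succ`` is iterated by pointer doubling: after
    ``N`` squarings each state has advanced ``2**N`` steps, which is
    guaranteed to land on its attractor cycle (no transient is longer
    than the state-space size).  The image of that map is exactly the set
    of on-cycle states, which are then grouped into cycles by walking
    ``succ``.  Total cost ``O(N * 2**N)``.
    """
    succ = successor_table(net, cap=cap)
    n_states = net.n_states

    reach = succ.copy()
    for _ in range(net.n_nodes):
        reach = reach[reach]

    cycle_states = np.unique(reach)  # sorted ascending
    attr_index = np.full(n_states, -1, dtype=np.int32)
    attractors: list[Attractor] = []
    for s in cycle_states:
        s = int(s)
        if attr_index[s] >= 0:
            continue
        cycle = [s]
        t = int(succ[s])
        while t != s:
            cycle.append(t)
            t = int(succ[t])
        idx = len(attractors)
        # ascending scan means the first unseen state of a cycle is its minimum
        attractors.append(Attractor(tuple(cycle)))
        attr_index[cycle] = idx

    basin_of = attr_index[reach]
    counts = np.bincount(basin_of, minlength=len(attractors))
    basin_sizes = counts / n_states
    return AttractorLandscape(
        n_nodes=net.n_nodes,
        attractors=tuple(attractors),
        basin_of=basin_of,
        basin_sizes=basin_sizes,
    )


def attractor_of(
    net: BooleanNetwork,
    start: int,
    landscape: AttractorLandscape | None = None,
) -> tuple[int, int]:
    """Follow the trajectory from ``start`` until its attractor recurs.

    Returns ``(attractor_index, transient_length)`` where the transient
    length is the number of steps taken before the trajectory first enters
    the cycle.  Indices refer to ``landscape`` (enumerated on demand if
    not supplied), so the result is consistent with ``basin_of``.
    """
    net.validate_state(start)
    if landscape is None:
        landscape = enumerate_landscape(net)

    seen: dict[int, int] = {}
    path: list[int] = []
    state = start
    while state not in seen:
        seen[state] = len(path)
        path.append(state)
        state = synchronous_update(net, state)
    transient = seen[state]  # position of the first on-cycle state
    idx = int(landscape.basin_of[start])
    cycle = set(path[transient:])
    if cycle != set(landscape.attractors[idx].states):
        raise ValueError("landscape does not match the supplied network")
    return idx, transient
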