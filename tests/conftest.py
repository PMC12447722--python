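"""Shared fixtures: tiny hand-analysable networks and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from boolstab import BooleanNetwork, synchronous_update

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def swap_net() -> BooleanNetwork:
    """2-node swap: x0' = x1, x1' = x0.

    Attractors (canonical order): fixed point 0b00, the 2-cycle
    {0b01, 0b10}, fixed point 0b11; basin sizes (1/4, 1/2, 1/4).
    """
    return BooleanNetwork(2, ((1,), (0,)), ((0, 1), (0, 1)))


@pytest.fixture
def negation_net() -> BooleanNetwork:
    """1-node negation: x' = !x; sole attractor is the 2-cycle {0, 1}."""
    return BooleanNetwork(1, ((0,),), ((1, 0),))


def constant_zero_net(n: int) -> BooleanNetwork:
    """Every node's function is the constant 0 (one self-input, all-zero table)."""
    return BooleanNetwork(
        n, tuple((i,) for i in range(n)), tuple((0, 0) for _ in range(n))
    )


def identity_net(n: int) -> BooleanNetwork:
    """Every node copies itself: every state is a fixed point."""
    return BooleanNetwork(
        n, tuple((i,) for i in range(n)), tuple((0, 1) for _ in range(n))
    )


def naive_landscape(net: BooleanNetwork):
    """Brute-force oracle: follow every state's trajectory independently.

    Returns (attractors, basin_of) with attractors as canonically rotated
    state tuples sorted by first state, and basin_of a list over all
    states.  Independent of the package's pointer-doubling enumeration.
    """
    n_states = 1 << net.n_nodes
    cycles: dict[tuple[int, ...], int] = {}
    basin = [-1] * n_states
    raw = []
    for s0 in range(n_states):
        seen: dict[int, int] = {}
        path = []
        s = s0
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = synchronous_update(net, s)
        cyc = path[seen[s]:]
        j = min(range(len(cyc)), key=lambda i: cyc[i])
        canon = tuple(cyc[j:]) + tuple(cyc[:j])
        if canon not in cycles:
            cycles[canon] = len(cycles)
        raw.append(cycles[canon])
    order = sorted(cycles, key=lambda c: c[0])
    remap = {cycles[c]: i for i, c in enumerate(order)}
    basin = [remap[r] for r in raw]
    return order, basin


def naive_flip_matrix(net: BooleanNetwork, attractors, basin) -> np.ndarray:
    """Oracle transition matrix: re-simulate the full trajectory per flip."""
    n_att = len(attractors)
    counts = np.zeros((n_att, n_att), dtype=np.int64)
    for alpha, cyc in enumerate(attractors):
        for s in cyc:
            for i in range(net.n_nodes):
                t = s ^ (1 << i)
                seen = set()
                while t not in seen:
                    seen.add(t)
                    t = synchronous_update(net, t)
                counts[alpha, basin[t]] += 1
    trials = np.array([net.n_nodes * len(c) for c in attractors], dtype=float)
    return counts / trials[:, None]
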