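"""Direct simulation of noisy attractor hopping.

In the rare-noise regime the system sits on an attractor essentially all
the time; the relevant stochastic process is the jump chain over
attractors.  Each noise event picks a uniformly random phase of the
current cycle, flips one uniformly random node, and lets the
deterministic dynamics relax the flipped state to its attractor.  Dwell
time is counted in noise events charged to the source attractor, which
is exactly the Markov chain whose stationary law is the transition
matrix's principal left eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .attractors import AttractorLandscape
from .network import BooleanNetwork
from .transition import _check_consistency

__all__ = ["NoisyTrajectory", "simulate_attractor_hopping", "compare_occupancy"]


@dataclass(frozen=True)
class NoisyTrajectory:
    """Outcome of an event-driven noisy simulation.

    ``visits`` is a run-length encoding: consecutive ``(attractor index,
    dwell events)`` pairs.  ``time_fractions`` is the empirical occupancy
    ``t_a / t_tot`` over all attractors of the landscape (events charged
    to the source attractor of each jump).
    """

    visits: tuple[tuple[int, int], ...]
    n_events: int
    time_fractions: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(float(self.time_fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("time fractions must sum to 1")


def simulate_attractor_hopping(
    net: BooleanNetwork,
    landscape: AttractorLandscape,
    n_events: int,
    seed: int,
) -> NoisyTrajectory:
    """Run ``n_events`` single-node-flip noise events and track occupancy.

    Starts from a uniformly random attractor state (uniform over the union
    of all cycle states).  Relaxation after each flip is instantaneous via
    the basin map; transients carry zero dwell time.  Fully reproducible
    for a given seed.
    """
    _check_consistency(net, landscape)
    if landscape.n_att < 1:
        raise ValueError("landscape has no attractors")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")

    rng = np.random.default_rng(seed)
    n = net.n_nodes
    cycles = [np.asarray(a.states, dtype=np.int64) for a in landscape.attractors]
    all_states = np.concatenate(cycles)
    state_owner = np.concatenate(
        [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(cycles)]
    )

    start = int(rng.integers(len(all_states)))
    current = int(state_owner[start])

    phase_u = rng.random(n_events)
    nodes = rng.integers(0, n, size=n_events)
    basin = landscape.basin_of

    counts = np.zeros(landscape.n_att, dtype=np.int64)
    visits: list[list[int]] = [[current, 0]]
    for e in range(n_events):
        cyc = cycles[current]
        phase = int(phase_u[e] * len(cyc))
        flipped = int(cyc[phase]) ^ (1 << int(nodes[e]))
        counts[current] += 1
        visits[-1][1] += 1
        nxt = int(basin[flipped])
        if nxt != current:
            visits.append([nxt, 0])
            current = nxt
    if visits[-1][1] == 0:
        visits.pop()

    return NoisyTrajectory(
        visits=tuple((a, d) for a, d in visits),
        n_events=n_events,
        time_fractions=counts / n_events,
        seed=seed,
    )


class OccupancyDiscrepancy(NamedTuple):
    max_abs_diff: float
    tv_distance: float


def compare_occupancy(traj: NoisyTrajectory, v) -> OccupancyDiscrepancy:
    """Max absolute difference and total-variation distance to a prediction."""
    v = np.asarray(v, dtype=float)
    t = traj.time_fractions
    if v.shape != t.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {v.shape}")
    diff = np.abs(t - v)
    return OccupancyDiscrepancy(float(diff.max()), float(diff.sum() / 2.0))
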