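"""Stability, dominance, similarity, entropy and transition-bias metrics.

The single-flip transition matrix defines a Markov chain over attractors.
Its trace aggregates per-attractor return probabilities (the global-
randomization baseline pins this at exactly 1, so ``Tr M > 1`` means
attractors are more stable than basin sizes alone predict).  Its
stationary distribution ``v`` gives the long-run fraction of time the
noisy system spends in each attractor; comparing the Shannon entropy of
``v`` with that of the basin-size distribution, and the basin-normalised
transition rates into larger versus smaller basins, characterises how
local noise reshapes the landscape relative to the static basin picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .attractors import Attractor, AttractorLandscape
from .network import BooleanNetwork
from .transition import TransitionMatrix

__all__ = [
    "trace_stability",
    "stationary_distribution",
    "attractor_similarity_exact",
    "attractor_similarity_approx",
    "landscape_similarity",
    "normalized_entropy",
    "entropy_difference",
    "transition_bias",
    "TransitionBias",
    "StabilityReport",
    "build_report",
]

_ROW_TOL = 1e-9


def _as_matrix(M) -> np.ndarray:
    m = M.m if isinstance(M, TransitionMatrix) else np.asarray(M, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(m < -1e-12):
        raise ValueError("transition matrix has negative entries")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > _ROW_TOL:
        raise ValueError("transition matrix rows must sum to 1")
    return m


def trace_stability(M) -> float:
    """Trace of the transition matrix: summed return probabilities.

    Lies in ``[0, n_att]``; equals 1 for the global-randomization
    baseline, so larger values indicate attractors that retain the system
    more strongly than their basin sizes would suggest.
    """
    return float(np.trace(_as_matrix(M)))


def _closed_class_stationary(sub: np.ndarray) -> np.ndarray:
    """Stationary law of an irreducible row-stochastic matrix (left eigvec)."""
    n = sub.shape[0]
    if n == 1:
        return np.ones(1)
    a = sub.T - np.eye(n)
    a[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        v = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError:
        v = np.linalg.lstsq(a, rhs, rcond=None)[0]
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_distribution(M, *, return_info: bool = False):
    """Long-run attractor occupancy ``v`` with ``v @ M = v``.

    The matrix is row-stochastic, so the stationary law is the *left*
    principal eigenvector.  The chain may be reducible (several closed
    communicating classes) or periodic; the returned vector is the
    limiting time-average occupancy of a chain started uniformly over
    attractors, which is always well defined:

    * each closed class contributes its internal stationary law,
    * weighted by the probability of absorption into that class from the
      uniform start (transient attractors carry zero mass).

    For an irreducible chain this is the unique stationary distribution.
    With ``return_info=True`` also returns a dict flagging reducibility.
    """
    m = _as_matrix(M)
    n = m.shape[0]
    if n == 1:
        v = np.ones(1)
        return (v, {"reducible": False, "n_closed_classes": 1}) if return_info else v

    n_comp, labels = connected_components(
        csr_matrix(m > 0), directed=True, connection="strong"
    )
    # a class is closed iff no probability leaks to a different class
    closed = []
    for c in range(n_comp):
        idx = np.where(labels == c)[0]
        if np.allclose(m[np.ix_(idx, idx)].sum(axis=1), 1.0, atol=1e-12):
            closed.append(c)

    recurrent = np.isin(labels, closed)
    transient_idx = np.where(~recurrent)[0]

    # absorption probabilities from the uniform start into each closed class
    weights = {}
    if transient_idx.size:
        q = m[np.ix_(transient_idx, transient_idx)]
        inv = np.linalg.inv(np.eye(transient_idx.size) - q)
    for c in closed:
        idx = np.where(labels == c)[0]
        w = idx.size / n
        if transient_idx.size:
            r_c = m[np.ix_(transient_idx, idx)].sum(axis=1)
            w += inv.dot(r_c).sum() / n
        weights[c] = w

    v = np.zeros(n)
    for c in closed:
        idx = np.where(labels == c)[0]
        v[idx] = weights[c] * _closed_class_stationary(m[np.ix_(idx, idx)])
    v = np.clip(v, 0.0, None)
    v /= v.sum()

    resid = float(np.max(np.abs(v @ m - v)))
    if resid > 1e-10:
        raise RuntimeError(f"stationary residual {resid:.2e} exceeds 1e-10")
    if return_info:
        return v, {"reducible": len(closed) > 1 or transient_idx.size > 0,
                   "n_closed_classes": len(closed)}
    return v


def _bit_counts(attr: Attractor, n_nodes: int) -> np.ndarray:
    """Number of ones at each position across the cycle's states."""
    states = np.asarray(attr.states, dtype=np.int64)
    bits = (states[:, None] >> np.arange(n_nodes, dtype=np.int64)) & 1
    return bits.sum(axis=0)


def attractor_similarity_exact(attr: Attractor, n_nodes: int) -> float:
    """Probability that two distinct cycle states agree at a random position.

    Averages ``[C(n0,2) + C(n1,2)] / C(l,2)`` over positions, where ``n0``
    and ``n1`` count zeros and ones at a position across the ``l`` cycle
    states.  Fixed points are defined to have similarity 1.
    """
    ell = attr.length
    if ell == 1:
        return 1.0
    n1 = _bit_counts(attr, n_nodes)
    n0 = ell - n1
    pairs_same = n1 * (n1 - 1) / 2 + n0 * (n0 - 1) / 2
    return float(np.mean(pairs_same / (ell * (ell - 1) / 2)))


def attractor_similarity_approx(attr: Attractor, n_nodes: int) -> float:
    """Large-cycle approximation: mean of ``mu**2 + (1-mu)**2`` over positions.

    ``mu`` is the fraction of cycle states with value 1 at a position;
    the value lies in ``[1/2, 1]`` and equals 1 for fixed points.  For
    cycles with i.i.d. uniform positions it tends to 1/2, the
    random-state floor.
    """
    if attr.length == 1:
        return 1.0
    mu = _bit_counts(attr, n_nodes) / attr.length
    return float(np.mean(mu**2 + (1.0 - mu) ** 2))


def landscape_similarity(landscape: AttractorLandscape, mode: str = "exact") -> float:
    """Unweighted mean of per-attractor similarity over all attractors."""
    if mode == "exact":
        f = attractor_similarity_exact
    elif mode == "approx":
        f = attractor_similarity_approx
    else:
        raise ValueError(f"mode must be 'exact' or 'approx', got {mode!r}")
    return float(
        np.mean([f(a, landscape.n_nodes) for a in landscape.attractors])
    )


def normalized_entropy(dist) -> float:
    """Shannon entropy of a distribution, normalised by ``log2`` of its length.

    ``0 * log 0`` is treated as 0, and a single-outcome distribution has
    entropy 0 by convention (it is fully localised; the usual normaliser
    ``log2 1`` vanishes).  The result lies in ``[0, 1]``.
    """
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1:
        raise ValueError("distribution must be a vector")
    if np.any(p < -1e-12):
        raise ValueError("distribution has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution sums to {p.sum()}, not 1")
    n = p.size
    if n == 1:
        return 0.0
    pos = p[p > 0]
    h = -np.sum(pos * np.log2(pos))
    return float(h / math.log2(n))


def entropy_difference(v, b, *, convention: str = "localization") -> float:
    """Entropy gap between the basin-size and stationary distributions.

    With the default ``localization`` convention the value is
    ``H(b) - H(v)``: positive when the noisy dynamics concentrate on a
    narrower subset of attractors than basin sizes alone would predict.
    ``convention='signed_terms'`` returns the opposite sign,
    ``H(v) - H(b)``.
    """
    v = np.asarray(v, dtype=float)
    b = np.asarray(b, dtype=float)
    if v.shape != b.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {b.shape}")
    dh = normalized_entropy(b) - normalized_entropy(v)
    if convention == "localization":
        return dh
    if convention == "signed_terms":
        return -dh
    raise ValueError(f"unknown convention {convention!r}")


class TransitionBias(NamedTuple):
    """Basin-normalised transition rates into larger vs. smaller basins.

    Fields are ``None`` when no qualifying attractor pair exists (single
    attractor, or all basins equal); ``ratio`` is additionally ``None``
    when ``r_lt`` is zero.
    """

    r_gt: float | None
    r_lt: float | None
    ratio: float | None


def transition_bias(
    M, b, *, normalization: str = "target"
) -> TransitionBias:
    """Directionality of noise-induced transitions across basin sizes.

    For every ordered pair ``a != b`` of attractors the rate
    ``r = m[a, b] / basin[b]`` (target normalisation, the default) is
    exactly 1 under global randomization, making deviations directly
    interpretable.  ``R>`` averages ``r`` over pairs into larger basins,
    ``R<`` over pairs into smaller ones; their ratio quantifies the bias.
    ``normalization='source'`` divides by the source basin instead.
    """
    m = _as_matrix(M)
    b = np.asarray(b, dtype=float)
    if b.size != m.shape[0]:
        raise ValueError("basin vector length does not match matrix")
    if normalization == "target":
        r = np.divide(m, b[None, :], out=np.zeros_like(m), where=b[None, :] > 0)
    elif normalization == "source":
        r = np.divide(m, b[:, None], out=np.zeros_like(m), where=b[:, None] > 0)
    else:
        raise ValueError(f"normalization must be 'target' or 'source'")
    larger = b[None, :] > b[:, None]
    smaller = b[None, :] < b[:, None]
    r_gt = float(np.mean(r[larger])) if larger.any() else None
    r_lt = float(np.mean(r[smaller])) if smaller.any() else None
    ratio = None
    if r_gt is not None and r_lt is not None and r_lt > 0:
        ratio = r_gt / r_lt
    return TransitionBias(r_gt, r_lt, ratio)


@dataclass(frozen=True)
class StabilityReport:
    """All scalar and vector stability summaries for one network."""

    n_att: int
    trace: float
    mean_stability: float
    stationary: np.ndarray = field(repr=False)
    basin_sizes: np.ndarray = field(repr=False)
    similarity_exact_per: tuple[float, ...] = field(repr=False)
    similarity_exact: float = 0.0
    similarity_approx: float = 0.0
    entropy: float = 0.0
    entropy_basin: float = 0.0
    delta_entropy: float = 0.0
    bias_r_gt: float | None = None
    bias_r_lt: float | None = None
    bias_ratio: float | None = None
    reducible: bool = False

    def to_dict(self) -> dict:
        return {
            "n_att": self.n_att,
            "trace": self.trace,
            "mean_stability": self.mean_stability,
            "stationary": [float(x) for x in self.stationary],
            "basin_sizes": [float(x) for x in self.basin_sizes],
            "similarity_exact_per": list(self.similarity_exact_per),
            "similarity_exact": self.similarity_exact,
            "similarity_approx": self.similarity_approx,
            "entropy": self.entropy,
            "entropy_basin": self.entropy_basin,
            "delta_entropy": self.delta_entropy,
            "bias_r_gt": self.bias_r_gt,
            "bias_r_lt": self.bias_r_lt,
            "bias_ratio": self.bias_ratio,
            "reducible": self.reducible,
        }


def build_report(
    net: BooleanNetwork,
    landscape: AttractorLandscape,
    M: TransitionMatrix,
) -> StabilityReport:
    """Aggregate every stability metric for one (network, landscape, matrix)."""
    v, info = stationary_distribution(M, return_info=True)
    b = np.asarray(landscape.basin_sizes, dtype=float)
    sim_per = tuple(
        attractor_similarity_exact(a, net.n_nodes) for a in landscape.attractors
    )
    h_v = normalized_entropy(v)
    h_b = normalized_entropy(b)
    bias = transition_bias(M, b)
    return StabilityReport(
        n_att=landscape.n_att,
        trace=trace_stability(M),
        mean_stability=trace_stability(M) / landscape.n_att,
        stationary=v,
        basin_sizes=b,
        similarity_exact_per=sim_per,
        similarity_exact=float(np.mean(sim_per)),
        similarity_approx=landscape_similarity(landscape, mode="approx"),
        entropy=h_v,
        entropy_basin=h_b,
        delta_entropy=h_b - h_v,
        bias_r_gt=bias.r_gt,
        bias_r_lt=bias.r_lt,
        bias_ratio=bias.ratio,
        reducible=info["reducible"],
    )
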