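"""Ensemble sweeps over random regular Boolean networks.

Sweeps a grid of in-degrees ``k`` and average sensitivities ``s`` (the
unified control parameter ``s = 2 p (1 - p) k``), generating
``replicates`` independent networks per cell, analysing each one
exhaustively, and aggregating means and standard errors of the stability
metrics.  Per-cell seeds are derived from a stable hash of
``(base_seed, k, s, replicate)`` so adding cells or replicates never
reshuffles existing ones.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attractors import enumerate_landscape
from .metrics import build_report
from .network import bias_for_sensitivity, random_regular_network
from .transition import build_transition_matrix

__all__ = [
    "EnsembleSpec",
    "cell_seed",
    "ensemble_records",
    "run_ensemble",
    "ensemble_bias_ratio",
]

logger = logging.getLogger(__name__)

_METRICS = [
    "n_att",
    "trace",
    "mean_stability",
    "similarity_exact",
    "similarity_approx",
    "entropy",
    "delta_entropy",
    "bias_ratio",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of one ensemble sweep.

    ``sensitivities`` values above the attainable maximum ``k/2`` for a
    given ``k`` are skipped (with a logged warning) rather than failing
    the whole sweep.
    """

    n_nodes: int
    degrees: tuple[int, ...]
    sensitivities: tuple[float, ...]
    replicates: int
    base_seed: int = 0
    allow_self_inputs: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "degrees", tuple(int(k) for k in self.degrees))
        object.__setattr__(
            self, "sensitivities", tuple(float(s) for s in self.sensitivities)
        )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.degrees or not self.sensitivities:
            raise ValueError("degrees and sensitivities must be non-empty")


def cell_seed(base_seed: int, k: int, s: float, replicate: int) -> int:
    """Stable per-replicate seed below 2**31."""
    key = f"{base_seed}|{k}|{s:.12g}|{replicate}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (
        1 << 31
    )


def ensemble_records(spec: EnsembleSpec) -> pd.DataFrame:
    """One row per analysed replicate, with all scalar metrics.

    The bias ratio column is NaN where undefined (single attractor or all
    basins equal); aggregation must exclude those rows for that column.
    """
    rows = []
    for k in spec.degrees:
        for s in spec.sensitivities:
            if s > k / 2 + 1e-12:
                logger.warning(
                    "skipping cell k=%d, s=%g: sensitivity above maximum k/2=%g",
                    k, s, k / 2,
                )
                continue
            p = bias_for_sensitivity(s, k)
            for r in range(spec.replicates):
                seed = cell_seed(spec.base_seed, k, s, r)
                net = random_regular_network(
                    spec.n_nodes, k, p, seed,
                    allow_self_inputs=spec.allow_self_inputs,
                )
                landscape = enumerate_landscape(net)
                matrix = build_transition_matrix(net, landscape)
                rep = build_report(net, landscape, matrix)
                rows.append(
                    {
                        "k": k,
                        "s": s,
                        "p": p,
                        "replicate": r,
                        "seed": seed,
                        "n_att": rep.n_att,
                        "trace": rep.trace,
                        "mean_stability": rep.mean_stability,
                        "similarity_exact": rep.similarity_exact,
                        "similarity_approx": rep.similarity_approx,
                        "entropy": rep.entropy,
                        "delta_entropy": rep.delta_entropy,
                        "bias_ratio": (
                            rep.bias_ratio
                            if rep.bias_ratio is not None
                            and math.isfinite(rep.bias_ratio)
                            else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)


def ensemble_bias_ratio(
    spec: EnsembleSpec, *, normalization: str = "target"
) -> pd.DataFrame:
    """Pooled transition-bias ratio per (k, s) cell.

    Accumulates the basin-normalised rates ``r = m[a, b] / basin[b]`` of
    every qualifying ordered attractor pair across all replicates of a
    cell, then forms ``R> / R<`` once from the pooled means.  Unlike the
    mean of per-network ratios (``bias_ratio_mean`` in
    :func:`run_ensemble`), the pooled estimator is insensitive to the
    heavy upper tail of per-network ratios, whose ``R<`` denominator can
    be arbitrarily small in a single network.
    """
    from .metrics import _as_matrix  # row-stochasticity validation

    rows = []
    for k in spec.degrees:
        for s in spec.sensitivities:
            if s > k / 2 + 1e-12:
                continue
            p = bias_for_sensitivity(s, k)
            gts: list[float] = []
            lts: list[float] = []
            for r in range(spec.replicates):
                seed = cell_seed(spec.base_seed, k, s, r)
                net = random_regular_network(
                    spec.n_nodes, k, p, seed,
                    allow_self_inputs=spec.allow_self_inputs,
                )
                landscape = enumerate_landscape(net)
                m = _as_matrix(build_transition_matrix(net, landscape))
                b = np.asarray(landscape.basin_sizes)
                if normalization == "target":
                    rate = np.divide(
                        m, b[None, :], out=np.zeros_like(m), where=b[None, :] > 0
                    )
                elif normalization == "source":
                    rate = np.divide(
                        m, b[:, None], out=np.zeros_like(m), where=b[:, None] > 0
                    )
                else:
                    raise ValueError("normalization must be 'target' or 'source'")
                larger = b[None, :] > b[:, None]
                smaller = b[None, :] < b[:, None]
                gts.extend(rate[larger].tolist())
                lts.extend(rate[smaller].tolist())
            r_gt = float(np.mean(gts)) if gts else math.nan
            r_lt = float(np.mean(lts)) if lts else math.nan
            ratio = r_gt / r_lt if gts and lts and r_lt > 0 else math.nan
            rows.append(
                {"k": k, "s": s, "p": p, "r_gt": r_gt, "r_lt": r_lt,
                 "ratio": ratio, "n_pairs": len(gts) + len(lts)}
            )
    return pd.DataFrame(rows)


def run_ensemble(spec: EnsembleSpec) -> pd.DataFrame:
    """Aggregate an ensemble sweep into per-(k, s) means and standard errors.

    Returns one row per grid cell with ``<metric>_mean``, ``<metric>_sem``
    and defined-replicate counts; quantities that are undefined for some
    replicates (the bias ratio) are averaged only over replicates where
    they exist, with the count reported in ``bias_ratio_n``.
    """
    records = ensemble_records(spec)
    if records.empty:
        return records
    out = []
    for (k, s), grp in records.groupby(["k", "s"], sort=True):
        row: dict = {"k": k, "s": s, "p": grp["p"].iloc[0],
                     "replicates": len(grp)}
        for mname in _METRICS:
            vals = grp[mname].dropna().to_numpy(dtype=float)
            row[f"{mname}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{mname}_sem"] = (
                vals.std(ddof=1) / math.sqrt(vals.size) if vals.size > 1 else np.nan
            )
            if mname == "bias_ratio":
                row["bias_ratio_n"] = int(vals.size)
        out.append(row)
    return pd.DataFrame(out)
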