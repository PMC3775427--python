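"""Degree-based hub comparison between two networks.

Weight-level similarity of two networks can be high while their hubs
differ: node degree depends on which edges survive the sparsity threshold,
not on overall weight agreement.  This module quantifies that dissociation
with (a) degree correlations across sparsity, (b) per-node degree
differences with top/bottom-k hub tables, and (c) a sorted
degree-difference curve compared against an edge-exchange permutation
envelope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import as_seed_sequence
from .compare import edge_exchange
from .graph import degree, threshold_sparsity
from .matrices import ConnectivityMatrix
from .roi import RoiSet

logger = logging.getLogger("netshift.hubs")

__all__ = [
    "Envelope",
    "degree_correlation",
    "degree_difference_table",
    "degree_envelope",
    "top_bottom_k",
]


def degree_correlation(
    w1: ConnectivityMatrix,
    w2: ConnectivityMatrix,
    s: float,
    method: str = "pearson",
) -> float:
    """Correlation of the two networks' node-degree vectors at sparsity s.

    Pearson by default (``method="spearman"`` available).  A constant
    degree vector leaves the correlation undefined; NaN is returned and a
    warning logged.
    """
    if not w1.same_labels(w2):
        raise ValueError("matrices have different node labels")
    k1 = degree(threshold_sparsity(w1, s))
    k2 = degree(threshold_sparsity(w2, s))
    if np.ptp(k1) == 0 or np.ptp(k2) == 0:
        logger.warning("constant degree vector at sparsity %.3f; correlation undefined", s)
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(k1, k2).statistic)
    if method == "spearman":
        return float(stats.spearmanr(k1, k2).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def degree_difference_table(
    w1: ConnectivityMatrix,
    w2: ConnectivityMatrix,
    s: float,
    rois: RoiSet | None = None,
) -> pd.DataFrame:
    """Per-node degree differences (network 1 − network 2), sorted descending.

    Ties keep the input node order.  With an ROI set, MNI coordinates are
    attached.  Columns: label [, x, y, z], degree_a, degree_b, diff, rank.
    """
    if not w1.same_labels(w2):
        raise ValueError("matrices have different node labels")
    k1 = degree(threshold_sparsity(w1, s))
    k2 = degree(threshold_sparsity(w2, s))
    df = pd.DataFrame(
        {
            "label": w1.labels,
            "degree_a": k1,
            "degree_b": k2,
            "diff": k1.astype(int) - k2.astype(int),
        }
    )
    if rois is not None:
        if list(rois.labels) != list(w1.labels):
            raise ValueError("ROI labels do not match matrix labels")
        df.insert(1, "x", rois.centers[:, 0])
        df.insert(2, "y", rois.centers[:, 1])
        df.insert(3, "z", rois.centers[:, 2])
    df = df.sort_values("diff", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_bottom_k(table: pd.DataFrame, k: int = 5):
    """Top-k (largest, most positive) and bottom-k (most negative) rows.

    The bottom list is ordered most-negative first.  Returns
    ``(top, bottom)`` DataFrames in the hub-table layout.
    """
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n}-node table")
    top = table.head(k).reset_index(drop=True)
    bottom = table.tail(k).iloc[::-1].reset_index(drop=True)
    return top, bottom


@dataclass
class Envelope:
    """Sorted degree-difference curve against its permutation envelope.

    ``observed`` is the descending-sorted per-node degree difference;
    the null band is the per-rank min/max (and percentile band) over
    ``n_perm`` edge-exchange permutations; ``exceed`` flags ranks where the
    observed curve lies outside the min/max band.
    """

    sparsity: float
    observed: np.ndarray
    null_min: np.ndarray
    null_max: np.ndarray
    null_lower: np.ndarray
    null_upper: np.ndarray
    percentiles: tuple[float, float]
    exceed: np.ndarray
    n_perm: int
    seed: object

    def __post_init__(self) -> None:
        if np.any(self.null_min > self.null_max):
            raise ValueError("envelope lower bound exceeds upper bound")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.observed.size + 1),
                "observed": self.observed,
                "null_min": self.null_min,
                "null_max": self.null_max,
                "null_lower": self.null_lower,
                "null_upper": self.null_upper,
                "exceed": self.exceed,
            }
        )


def degree_envelope(
    w1: ConnectivityMatrix,
    w2: ConnectivityMatrix,
    s: float,
    n_perm: int = 1000,
    seed=0,
    frac: float = 0.5,
    percentiles: tuple[float, float] = (0.05, 99.95),
) -> Envelope:
    """Sorted degree-difference curve vs. the edge-exchange null band.

    Each permutation mixes the two thresholded networks, recomputes the
    per-node degree difference, and sorts it descending; the envelope is
    the per-rank min/max (plus the requested percentile band, by default
    0.05/99.95, matching a 0.001 two-sided level).
    """
    if not w1.same_labels(w2):
        raise ValueError("matrices have different node labels")
    g1 = threshold_sparsity(w1, s)
    g2 = threshold_sparsity(w2, s)
    observed = np.sort(degree(g1).astype(int) - degree(g2).astype(int))[::-1]
    root = as_seed_sequence(seed)
    null = np.empty((n_perm, g1.n_nodes))
    for i, child in enumerate(root.spawn(n_perm)):
        rng = np.random.default_rng(child)
        mixed = edge_exchange(g1, g2, frac=frac, rng=rng)
        diff = degree(mixed.g1).astype(int) - degree(mixed.g2).astype(int)
        null[i] = np.sort(diff)[::-1]
    lo, hi = np.percentile(null, percentiles, axis=0)
    null_min = null.min(axis=0)
    null_max = null.max(axis=0)
    return Envelope(
        sparsity=float(s),
        observed=observed,
        null_min=null_min,
        null_max=null_max,
        null_lower=lo,
        null_upper=hi,
        percentiles=percentiles,
        exceed=(observed < null_min) | (observed > null_max),
        n_perm=n_perm,
        seed=seed,
    )
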