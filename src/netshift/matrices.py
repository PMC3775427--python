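"""Labeled symmetric connectivity matrices — the pipeline's common currency.

Both the meta-analytic coactivation matrix and the group resting-state
correlation matrix are carried in this form.  Node order is the join key
between every stage: two matrices are comparable only when their ordered
label lists are identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConnectivityMatrix", "weight_correlation"]

# asymmetry beyond this is a programming error; builders symmetrize explicitly
_SYMMETRY_ATOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """A symmetric weighted matrix over a fixed, ordered set of node labels.

    Parameters
    ----------
    values
        Square symmetric array of edge weights.  The diagonal carries the
        builder's convention (1 for correlation matrices, ln 2 for the
        coactivation matrix) and is ignored by thresholding.
    labels
        Unique node labels, one per row/column, in matrix order.
    """

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a "
                f"{self.values.shape[0]}-node matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix has non-finite entries")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=_SYMMETRY_ATOL):
            raise ValueError("matrix is not symmetric; symmetrize it explicitly")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.values.copy(), list(self.labels))

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle weights in row-major pair order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def same_labels(self, other: "ConnectivityMatrix") -> bool:
        return self.labels == other.labels


def weight_correlation(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation of edge weights over all node pairs.

    This is the weight-level similarity of the two networks, computed over
    the n(n-1)/2 unordered off-diagonal pairs (9730 pairs for 140 nodes).
    """
    if not a.same_labels(b):
        raise ValueError("matrices have different node labels")
    return float(np.corrcoef(a.upper_values(), b.upper_values())[0, 1])
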