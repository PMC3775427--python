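"""Region-of-interest bookkeeping.

Nodes are spherical ROIs at MNI millimetre coordinates (10 mm radius in the
reference analysis, 140 ROIs).  The ordered label list defined here fixes
matrix row/column order for the whole pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RoiSet"]


@dataclass
class RoiSet:
    """Ordered set of labeled spherical ROIs in MNI mm space.

    Attributes
    ----------
    labels
        Unique ROI labels in matrix order.
    centers
        (N, 3) array of MNI mm coordinates.
    radius_mm
        Per-ROI sphere radii (scalar input is broadcast).
    affiliation
        Network affiliation name per ROI (used only for reporting).
    """

    labels: list[str]
    centers: np.ndarray
    radius_mm: np.ndarray = 10.0
    affiliation: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        n = len(self.labels)
        if n < 2:
            raise ValueError("an ROI set needs at least 2 ROIs")
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        if self.centers.shape != (n, 3):
            raise ValueError("centers must be an (N, 3) array of MNI mm coordinates")
        self.radius_mm = np.broadcast_to(
            np.asarray(self.radius_mm, dtype=float), (n,)
        ).copy()
        if np.any(self.radius_mm <= 0):
            raise ValueError("sphere radii must be positive")
        if not self.affiliation:
            self.affiliation = ["unknown"] * n
        self.affiliation = [str(x) for x in self.affiliation]
        if len(self.affiliation) != n:
            raise ValueError("one affiliation per ROI required")

    def __len__(self) -> int:
        return len(self.labels)

    def extend(self, other: "RoiSet") -> "RoiSet":
        """Append another ROI set (e.g. extra ROIs added to a base atlas)."""
        return RoiSet(
            self.labels + other.labels,
            np.vstack([self.centers, other.centers]),
            np.concatenate([self.radius_mm, other.radius_mm]),
            self.affiliation + other.affiliation,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "radius_mm": self.radius_mm,
                "network": self.affiliation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiSet":
        required = ["label", "x", "y", "z", "radius_mm", "network"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"ROI table is missing columns: {missing}")
        return cls(
            list(df["label"]),
            df[["x", "y", "z"]].to_numpy(dtype=float),
            df["radius_mm"].to_numpy(dtype=float),
            list(df["network"]),
        )
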