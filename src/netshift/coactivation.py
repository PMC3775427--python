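"""Build the meta-analytic coactivation matrix.

Each ROI, used as a seed inquiry against a coordinate database, yields one
whole-brain coactivation value map.  Extracting all ROI values from all
maps gives an asymmetric N×N raw matrix (one row per seed).  The builder
then applies, in order:

1. row normalization by the diagonal (seed self-coactivation), removing
   the per-seed study-count bias and forcing the diagonal to 1;
2. log(1 + x), to de-skew the value distribution;
3. symmetrization by averaging with the transpose.

The result is a :class:`~netshift.matrices.ConnectivityMatrix` whose
diagonal equals ln 2 by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import ConnectivityMatrix
from .roi import RoiSet
from .synthetic import VolumeGrid, _sphere_mask

__all__ = [
    "RawCoactivationMatrix",
    "extract_roi_values",
    "build_raw_from_maps",
    "normalize_by_diagonal",
    "log_transform",
    "symmetrize",
    "build_coactivation_matrix",
]


@dataclass
class RawCoactivationMatrix:
    """Asymmetric non-negative seed×target value matrix.

    Rows are indexed by seed ROI (one map per seed), columns by target ROI.
    Diagonal entries must be strictly positive: a seed coactivates with
    itself, and the diagonal is the row normalizer.
    """

    values: np.ndarray
    labels: list[str]
    row_provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("raw coactivation matrix must be square")
        if len(self.labels) != n or len(set(self.labels)) != n:
            raise ValueError("need one unique label per ROI")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raw coactivation values must be finite")
        if np.any(self.values < 0):
            raise ValueError("raw coactivation values must be non-negative")
        bad = np.flatnonzero(np.diag(self.values) <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive diagonal for seed ROI(s): {[self.labels[i] for i in bad]}"
            )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def extract_roi_values(volume, rois: RoiSet, statistic: str = "mean") -> np.ndarray:
    """One value per ROI from a value map: statistic over in-sphere voxels.

    A voxel is in an ROI sphere when its mm center lies within the ROI
    radius of the ROI center (closed ball).  ``statistic`` is ``"mean"``
    (default), ``"max"``, or ``"center"`` (value at the voxel nearest the
    ROI center).
    """
    if hasattr(volume, "get_fdata"):  # nibabel image
        data = np.asarray(volume.get_fdata(), dtype=float)
        affine = np.asarray(volume.affine, dtype=float)
    else:
        data, affine = volume.data, volume.affine
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("volume affine is not invertible")
    inv = np.linalg.inv(affine)
    out = np.empty(len(rois))
    for idx, label in enumerate(rois.labels):
        mask = _sphere_mask(data.shape, affine, inv, rois.centers[idx], rois.radius_mm[idx])
        if not mask.any():
            raise ValueError(f"ROI {label!r}: sphere contains no voxels of the map")
        if statistic == "mean":
            out[idx] = data[mask].mean()
        elif statistic == "max":
            out[idx] = data[mask].max()
        elif statistic == "center":
            vc = (inv @ np.append(rois.centers[idx], 1.0))[:3]
            vox = tuple(np.clip(np.round(vc).astype(int), 0, np.array(data.shape) - 1))
            out[idx] = data[vox]
        else:
            raise ValueError(f"unknown extraction statistic {statistic!r}")
    return out


def build_raw_from_maps(maps, rois: RoiSet, statistic: str = "mean") -> RawCoactivationMatrix:
    """Stack per-seed map extractions into the raw seed×target matrix.

    ``maps`` is a sequence of value maps (``VolumeGrid`` or nibabel image),
    one per seed ROI, in ROI order.
    """
    maps = list(maps)
    if len(maps) != len(rois):
        raise ValueError(f"need one map per seed ROI ({len(rois)}), got {len(maps)}")
    rows = [extract_roi_values(vol, rois, statistic=statistic) for vol in maps]
    return RawCoactivationMatrix(
        np.vstack(rows),
        list(rois.labels),
        row_provenance=[f"map {i}" for i in range(len(maps))],
    )


def normalize_by_diagonal(raw: RawCoactivationMatrix) -> np.ndarray:
    """Divide each row by its diagonal entry; the diagonal becomes exactly 1.

    Removes the per-seed scale bias (different seed inquiries return
    different numbers of studies).
    """
    diag = np.diag(raw.values)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"cannot normalize: non-positive diagonal for {[raw.labels[i] for i in bad]}"
        )
    return raw.values / diag[:, None]


def log_transform(m: np.ndarray) -> np.ndarray:
    """Elementwise ln(1 + x) for non-negative x (de-skews the values)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("log transform requires non-negative entries")
    return np.log1p(m)


def symmetrize(m: np.ndarray) -> np.ndarray:
    """Average a square matrix with its transpose; diagonal is unchanged."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("symmetrize requires a square matrix")
    return (m + m.T) / 2.0


def build_coactivation_matrix(raw: RawCoactivationMatrix) -> ConnectivityMatrix:
    """Full recipe: normalize by diagonal → ln(1+x) → symmetrize.

    The diagonal of the result equals ln 2 exactly (1 after normalization,
    then ln(1+1)); off-diagonal weights are invariant to any positive
    per-seed rescaling of the raw rows.
    """
    return ConnectivityMatrix(
        symmetrize(log_transform(normalize_by_diagonal(raw))),
        list(raw.labels),
    )
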