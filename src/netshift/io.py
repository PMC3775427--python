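"""Plain-text I/O: labeled matrix TSV, ROI tables, panels, NIfTI volumes.

Matrices round-trip bitwise (pandas writes shortest round-trip float
repr).  A matrix file asymmetric beyond 1e-10 is symmetrized with a
logged warning; ROI tables may carry an ``in_mask`` column whose zero
rows are dropped (and counted) on read, mirroring atlas bookkeeping where
ROIs outside the database mask are removed.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix
from .roi import RoiSet
from .synthetic import SubjectPanel, VolumeGrid

logger = logging.getLogger("netshift.io")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_roiset",
    "write_roiset",
    "read_panel",
    "write_panel",
    "load_volume",
    "save_volume",
]

_ASYM_TOL = 1e-10


def write_matrix(m: ConnectivityMatrix, path) -> None:
    """Labeled TSV with row and column headers, full float precision."""
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.to_csv(path, sep="\t", index_label="label")


def read_matrix(path) -> ConnectivityMatrix:
    """Read a labeled matrix TSV written by :func:`write_matrix`.

    Row and column labels must agree; non-numeric cells are reported with
    their location; asymmetry beyond 1e-10 is symmetrized with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}×{df.shape[1]}, not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = [
            (str(df.index[i]), str(df.columns[j]))
            for i in range(df.shape[0])
            for j in range(df.shape[1])
            if not _is_number(df.iat[i, j])
        ]
        raise ValueError(f"{path}: non-numeric cells at (row, column) {bad[:5]}") from exc
    asym = np.abs(values - values.T).max()
    if asym > _ASYM_TOL:
        logger.warning("%s: asymmetric by %.3g; symmetrizing on read", path, asym)
        values = (values + values.T) / 2.0
    return ConnectivityMatrix(values, [str(x) for x in df.index])


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_roiset(rois: RoiSet, path) -> None:
    rois.to_frame().to_csv(path, sep="\t", index=False)


def read_roiset(path):
    """Read an ROI table (label, x, y, z, radius_mm, network [, in_mask]).

    Returns ``(roiset, n_dropped)`` where rows with ``in_mask == 0`` were
    dropped (logged).  Duplicate labels are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    n_dropped = 0
    if "in_mask" in df.columns:
        keep = df["in_mask"].astype(int) != 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropping %d ROI(s) flagged outside the mask", path, n_dropped)
        df = df.loc[keep]
    return RoiSet.from_frame(df), n_dropped


def save_volume(vol: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine))


def write_panel(panel: SubjectPanel, directory) -> None:
    """Panel directory: per-subject TSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tr_seconds": panel.tr_seconds,
        "n_subjects": panel.n_subjects,
        "labels": panel.labels,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for idx in range(panel.n_subjects):
        pd.DataFrame(panel.series[idx], columns=panel.labels).to_csv(
            directory / f"sub{idx:03d}_series.tsv", sep="\t", index=False
        )
        for name, arr in [
            ("motion", panel.motion[idx]),
            ("wm", panel.wm_eigs[idx]),
            ("csf", panel.csf_eigs[idx]),
        ]:
            pd.DataFrame(arr).to_csv(
                directory / f"sub{idx:03d}_{name}.tsv", sep="\t", index=False
            )


def read_panel(directory) -> SubjectPanel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    series, motion, wm, csf = [], [], [], []
    for idx in range(int(manifest["n_subjects"])):
        series.append(
            pd.read_csv(directory / f"sub{idx:03d}_series.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=float)
        )
        motion.append(
            pd.read_csv(directory / f"sub{idx:03d}_motion.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=float)
        )
        wm.append(pd.read_csv(directory / f"sub{idx:03d}_wm.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=float))
        csf.append(pd.read_csv(directory / f"sub{idx:03d}_csf.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=float))
    return SubjectPanel(
        series,
        float(manifest["tr_seconds"]),
        motion,
        wm,
        csf,
        labels=list(manifest["labels"]),
    )
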