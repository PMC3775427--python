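"""Synthetic study inputs.

The real study draws on two data sources that cannot ship with a package:
per-seed meta-analytic coactivation maps (an online database of published
activation coordinates) and a multi-subject resting-state fMRI sample.
This module generates statistical stand-ins for both, with controllable
modular structure, hub placement and noise, so that every downstream stage
is testable end to end:

* a weighted modular "ground truth" connectivity matrix (blocks along the
  diagonal, as network-ordered brain matrices show);
* an asymmetric non-negative seed×target count matrix with per-seed scale
  biases (each seed inquiry returns a different number of studies);
* multi-subject ROI time-series panels whose population covariance is the
  planted matrix, with motion traces and WM/CSF nuisance regressors;
* volumetric value maps with spherical ROIs painted in, for testing sphere
  extraction.

Every generator is a pure function of its parameters and seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seeds import as_seed_sequence
from .matrices import ConnectivityMatrix
from .roi import RoiSet

logger = logging.getLogger("netshift.synthetic")

__all__ = [
    "ModularSpec",
    "MotionSpec",
    "SubjectPanel",
    "VolumeGrid",
    "gen_modular_matrix",
    "gen_seed_count_matrix",
    "gen_subject_panel",
    "plant_hub",
    "boost_between_module",
    "gen_volume_with_spheres",
    "make_task_rest_pair",
    "default_study_spec",
]


@dataclass
class ModularSpec:
    """Parameters of a planted-block weighted connectivity matrix.

    ``mu_in`` / ``mu_out`` are the mean edge weights within / between
    modules; ``sigma`` is the Gaussian weight-noise SD (clipped at zero so
    weights stay non-negative, like z-values).
    """

    n_nodes: int
    module_sizes: list[int]
    mu_in: float = 0.6
    mu_out: float = 0.2
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = [int(s) for s in self.module_sizes]
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (self.mu_in > self.mu_out >= 0):
            raise ValueError("require mu_in > mu_out >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def membership(self) -> np.ndarray:
        """Module id per node (0-based, block order)."""
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass
class MotionSpec:
    """Random-walk head-motion traces (3 translations mm, 3 rotations deg).

    ``violator_index`` plants one subject whose peak absolute translation is
    rescaled to ``violator_peak_mm`` so the >3 mm screen removes exactly
    that subject.
    """

    step_sd_mm: float = 0.02
    step_sd_deg: float = 0.02
    violator_index: int | None = None
    violator_peak_mm: float = 3.5


@dataclass
class SubjectPanel:
    """Per-subject ROI time series plus nuisance material.

    All subjects share T (frames) and N (ROIs); ``tr_seconds`` is the
    repetition time (1.8 s in the reference acquisition, 240 analyzed
    frames per subject).
    """

    series: list[np.ndarray]  # each T×N
    tr_seconds: float
    motion: list[np.ndarray]  # each T×6
    wm_eigs: list[np.ndarray]  # each T×5
    csf_eigs: list[np.ndarray]  # each T×5
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("panel has no subjects")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        t, n = self.series[0].shape
        for name, group, ncol in [
            ("series", self.series, n),
            ("motion", self.motion, 6),
            ("wm_eigs", self.wm_eigs, 5),
            ("csf_eigs", self.csf_eigs, 5),
        ]:
            if len(group) != len(self.series):
                raise ValueError(f"{name}: one array per subject required")
            for arr in group:
                if arr.shape != (t, ncol):
                    raise ValueError(f"{name}: expected shape {(t, ncol)}, got {arr.shape}")
        if not self.labels:
            self.labels = [f"roi{i:03d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_frames(self) -> int:
        return self.series[0].shape[0]

    @property
    def n_rois(self) -> int:
        return self.series[0].shape[1]


@dataclass
class VolumeGrid:
    """A 3-D value map with a voxel-to-MNI-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4×4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")


def _module_labels(spec: ModularSpec) -> list[str]:
    mem = spec.membership
    return [f"m{m}_n{i:03d}" for i, m in enumerate(mem)]


def gen_modular_matrix(spec: ModularSpec, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Weighted matrix with planted modules (blocks along the diagonal).

    Off-diagonal weights are Gaussian around ``mu_in`` within blocks and
    ``mu_out`` between blocks, clipped at zero; the diagonal is 1.
    """
    n = spec.n_nodes
    rng = np.random.default_rng(as_seed_sequence(spec.seed))
    mem = spec.membership
    same = mem[:, None] == mem[None, :]
    iu = np.triu_indices(n, k=1)
    mu = np.where(same[iu], spec.mu_in, spec.mu_out)
    vals = mu + spec.sigma * rng.standard_normal(iu[0].size)
    vals = np.clip(vals, 0.0, None)
    w = np.zeros((n, n))
    w[iu] = vals
    w += w.T
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(w, labels if labels is not None else _module_labels(spec))


def gen_seed_count_matrix(
    base: ConnectivityMatrix,
    per_seed_scale,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Asymmetric seed×target value matrix with per-seed scale biases.

    Row i is ``base`` row i times ``per_seed_scale[i]`` plus non-negative
    noise — emulating that each seed inquiry returns a different number of
    studies, the bias the diagonal normalization later removes.

    Returns a :class:`netshift.coactivation.RawCoactivationMatrix`.
    """
    from .coactivation import RawCoactivationMatrix

    scale = np.asarray(per_seed_scale, dtype=float)
    n = base.n_nodes
    if scale.shape != (n,):
        raise ValueError(f"per_seed_scale must have length {n}")
    if np.any(scale <= 0):
        raise ValueError("per-seed scales must be strictly positive")
    rng = np.random.default_rng(as_seed_sequence(seed))
    values = base.values * scale[:, None]
    if noise_sd > 0:
        values = values + np.abs(noise_sd * rng.standard_normal((n, n)))
    return RawCoactivationMatrix(
        values,
        list(base.labels),
        row_provenance=[f"synthetic seed row {lbl}" for lbl in base.labels],
    )


def _repair_psd(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues so the matrix is usable as a covariance."""
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() >= floor:
        return cov
    logger.warning(
        "covariance not PSD (min eigenvalue %.3g); clipping at %.1g",
        evals.min(),
        floor,
    )
    evals = np.clip(evals, floor, None)
    return (evecs * evals) @ evecs.T


def _smooth_series(rng: np.random.Generator, t: int, k: int) -> np.ndarray:
    """Standardized random walks — smooth, slowly varying regressors."""
    walk = np.cumsum(rng.standard_normal((t, k)), axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk / sd


def gen_subject_panel(
    cov: ConnectivityMatrix,
    n_subjects: int = 20,
    t: int = 240,
    tr_seconds: float = 1.8,
    noise_sd: float = 0.5,
    motion_spec: MotionSpec | None = None,
    seed: int = 0,
) -> SubjectPanel:
    """Multi-subject panel whose population covariance is ``cov``.

    Each subject's series is drawn as Gaussian with covariance ``cov``
    (repaired to PSD by eigenvalue clipping if needed, logged) plus
    independent white noise of SD ``noise_sd``.  Per-subject streams are
    derived from one root seed, so the panel is reproducible and subject k
    is unchanged when ``n_subjects`` grows.
    """
    if t < 10:
        raise ValueError("need at least 10 frames per subject")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    motion_spec = motion_spec or MotionSpec()
    n = cov.n_nodes
    chol = np.linalg.cholesky(_repair_psd(cov.values))
    children = as_seed_sequence(seed).spawn(n_subjects)
    series, motion, wm, csf = [], [], [], []
    for s_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        x = rng.standard_normal((t, n)) @ chol.T
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal((t, n))
        trans = np.cumsum(motion_spec.step_sd_mm * rng.standard_normal((t, 3)), axis=0)
        rot = np.cumsum(motion_spec.step_sd_deg * rng.standard_normal((t, 3)), axis=0)
        if s_idx == motion_spec.violator_index:
            peak = np.abs(trans).max()
            if peak == 0:
                trans[-1, 0] = motion_spec.violator_peak_mm
            else:
                trans = trans * (motion_spec.violator_peak_mm / peak)
        series.append(x)
        motion.append(np.hstack([trans, rot]))
        wm.append(_smooth_series(rng, t, 5))
        csf.append(_smooth_series(rng, t, 5))
    return SubjectPanel(series, tr_seconds, motion, wm, csf, labels=list(cov.labels))


def plant_hub(matrix: ConnectivityMatrix, node_index: int, boost: float) -> ConnectivityMatrix:
    """Increase every off-diagonal weight incident to one node by ``boost``.

    Used to plant a known hub (a node that will dominate the degree ranking
    after thresholding) in one network only.
    """
    if boost <= 0:
        raise ValueError("boost must be strictly positive")
    n = matrix.n_nodes
    if not 0 <= node_index < n:
        raise ValueError(f"node index {node_index} out of range for {n} nodes")
    w = matrix.values.copy()
    d = w[node_index, node_index]
    w[node_index, :] += boost
    w[:, node_index] += boost
    w[node_index, node_index] = d
    return ConnectivityMatrix(w, list(matrix.labels))


def boost_between_module(
    matrix: ConnectivityMatrix,
    membership: np.ndarray,
    boost: float,
    fraction: float = 1.0,
    seed: int = 0,
) -> ConnectivityMatrix:
    """Add ``boost`` to a random fraction of between-module edge weights.

    Emulates the task regime: extra long-range, between-system coupling on
    top of a resting modular backbone.
    """
    if boost <= 0:
        raise ValueError("boost must be strictly positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mem = np.asarray(membership)
    n = matrix.n_nodes
    if mem.shape != (n,):
        raise ValueError("membership must give one module id per node")
    rng = np.random.default_rng(as_seed_sequence(seed))
    iu = np.triu_indices(n, k=1)
    between = np.flatnonzero(mem[iu[0]] != mem[iu[1]])
    k = int(round(fraction * between.size))
    chosen = rng.choice(between, size=k, replace=False) if k < between.size else between
    w = matrix.values.copy()
    w[iu[0][chosen], iu[1][chosen]] += boost
    w[iu[1][chosen], iu[0][chosen]] += boost
    return ConnectivityMatrix(w, list(matrix.labels))


def gen_volume_with_spheres(
    grid_shape,
    affine: np.ndarray,
    rois: RoiSet,
    values,
) -> VolumeGrid:
    """Paint one constant-valued sphere per ROI into a zero volume.

    A voxel belongs to a sphere when its mm center is within the ROI
    radius.  On overlap the later ROI wins (overlap voxel count logged); a
    sphere containing no voxel centers is an error naming the ROI.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(rois),):
        raise ValueError(f"need one value per ROI ({len(rois)})")
    data = np.zeros(tuple(int(s) for s in grid_shape))
    affine = np.asarray(affine, dtype=float)
    painted = np.zeros(data.shape, dtype=bool)
    inv = np.linalg.inv(affine)
    for idx, label in enumerate(rois.labels):
        mask = _sphere_mask(data.shape, affine, inv, rois.centers[idx], rois.radius_mm[idx])
        if not mask.any():
            raise ValueError(f"ROI {label!r}: sphere contains no voxel centers in the grid")
        overlap = int((mask & painted).sum())
        if overlap:
            logger.info("ROI %s overlaps %d already-painted voxels (later wins)", label, overlap)
        data[mask] = values[idx]
        painted |= mask
    return VolumeGrid(data, affine)


def _sphere_mask(shape, affine, inv_affine, center_mm, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose mm centers lie within the sphere."""
    vc = (inv_affine @ np.append(center_mm, 1.0))[:3]
    # worst-case voxel-index extent of an mm ball under this affine
    half = np.ceil(radius_mm * np.linalg.norm(inv_affine[:3, :3], axis=1)).astype(int) + 1
    lo = np.maximum(np.floor(vc).astype(int) - half, 0)
    hi = np.minimum(np.ceil(vc).astype(int) + half + 1, np.asarray(shape))
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ijk = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = ijk @ affine.T
    dist2 = ((mm[..., :3] - np.asarray(center_mm)) ** 2).sum(axis=-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = dist2 <= radius_mm**2
    return mask


def default_study_spec(seed: int = 0) -> ModularSpec:
    """Study-scale modular template: 140 nodes in four 35-node modules.

    Mirrors the reference analysis (140 ROIs; four modules visible in the
    resting network) with weight levels chosen so that within- and
    between-module weights are well separated relative to the noise SD.
    """
    return ModularSpec(
        n_nodes=140,
        module_sizes=[35, 35, 35, 35],
        mu_in=0.6,
        mu_out=0.2,
        sigma=0.1,
        seed=seed,
    )


def make_task_rest_pair(
    spec: ModularSpec | None = None,
    seed: int = 0,
    between_boost: float = 0.5,
    between_fraction: float = 0.15,
    hub_node: int = 0,
    hub_boost: float = 0.5,
):
    """Planted task/rest matrix pair with known differences.

    ``rest`` is a modular matrix; ``task`` is the same matrix with a random
    subset of between-module weights boosted (more between-system
    integration) and one node's weights boosted everywhere (a planted
    task hub).  Returns ``(task, rest, info)`` where ``info`` records the
    planted hub label and module membership.
    """
    if spec is None:
        spec = default_study_spec(seed)
    rest = gen_modular_matrix(spec)
    task = boost_between_module(
        rest, spec.membership, boost=between_boost, fraction=between_fraction, seed=seed + 1
    )
    task = plant_hub(task, hub_node, hub_boost)
    info = {
        "hub_node": hub_node,
        "hub_label": rest.labels[hub_node],
        "membership": spec.membership,
        "spec": spec,
    }
    return task, rest, info
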