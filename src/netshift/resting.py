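"""Build the group resting-state connectivity matrix from ROI time series.

The chain, per the reference analysis: screen out subjects with head
motion greater than 3 mm; regress out 23 nuisance regressors (six motion
parameters and their first-order backward-difference derivatives, the
first five WM eigenvectors, the first five CSF eigenvectors, and an
intercept); band-pass 0.01–0.1 Hz; compute the N×N Kendall rank
correlation (tau-b) per subject; Fisher-z transform, average across
subjects, and transform back.

The default band-pass is an ideal (hard-mask) filter on the real FFT with
inclusive band edges; a 4th-order zero-phase Butterworth is available.
Nuisance regression runs before filtering by default (configurable).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .matrices import ConnectivityMatrix
from .synthetic import SubjectPanel

logger = logging.getLogger("netshift.resting")

__all__ = [
    "BandSpec",
    "NuisanceMatrix",
    "motion_screen",
    "build_nuisance",
    "regress_nuisance",
    "bandpass",
    "kendall_matrix",
    "fisher_z",
    "fisher_inv",
    "group_average",
    "build_resting_matrix",
]

_CLIP = 1.0 - 1e-7  # |tau| clip before atanh


@dataclass
class BandSpec:
    """Pass band in Hz plus the repetition time that fixes Nyquist."""

    low_hz: float = 0.01
    high_hz: float = 0.1
    tr_seconds: float = 1.8

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) "
                f"< Nyquist ({nyquist:.4g} Hz at TR={self.tr_seconds} s)"
            )

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class NuisanceMatrix:
    """T×K design of nuisance columns with role labels (K = 23 full model)."""

    columns: np.ndarray
    column_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("nuisance design must be 2-D")
        if not self.column_roles:
            self.column_roles = [f"col{i}" for i in range(self.columns.shape[1])]
        if len(self.column_roles) != self.columns.shape[1]:
            raise ValueError("one role label per column required")

    @property
    def k(self) -> int:
        return self.columns.shape[1]


def motion_screen(panel: SubjectPanel, threshold_mm: float = 3.0):
    """Keep subjects whose peak absolute translation is <= threshold.

    Exclusion is strict (">3 mm" excludes, exactly 3.0 mm is kept) and uses
    the three translation columns only; rotations are logged, not
    thresholded.  Returns ``(kept_indices, exclusion_log)`` where the log
    holds ``(subject_index, peak_translation_mm)`` pairs.
    """
    kept, excluded = [], []
    for idx, mot in enumerate(panel.motion):
        if mot is None:
            raise ValueError(f"subject {idx} has no motion trace")
        peak = float(np.abs(mot[:, :3]).max())
        peak_rot = float(np.abs(mot[:, 3:]).max())
        if peak > threshold_mm:
            excluded.append((idx, peak))
            logger.info(
                "subject %d excluded: peak translation %.2f mm (> %.2f); peak rotation %.2f",
                idx, peak, threshold_mm, peak_rot,
            )
        else:
            kept.append(idx)
    return kept, excluded


def build_nuisance(motion: np.ndarray, wm_eigs: np.ndarray, csf_eigs: np.ndarray) -> NuisanceMatrix:
    """Assemble the 23-column design: motion, its derivatives, WM, CSF, intercept.

    Derivatives are backward differences with a zero first row; any
    constant offset they miss is absorbed by the intercept.
    """
    motion = np.asarray(motion, dtype=float)
    wm_eigs = np.asarray(wm_eigs, dtype=float)
    csf_eigs = np.asarray(csf_eigs, dtype=float)
    t = motion.shape[0]
    if motion.shape != (t, 6) or wm_eigs.shape != (t, 5) or csf_eigs.shape != (t, 5):
        raise ValueError(
            "expected motion T×6, wm T×5, csf T×5 with a common T; got "
            f"{motion.shape}, {wm_eigs.shape}, {csf_eigs.shape}"
        )
    dmotion = np.zeros_like(motion)
    dmotion[1:] = np.diff(motion, axis=0)
    cols = np.hstack([motion, dmotion, wm_eigs, csf_eigs, np.ones((t, 1))])
    roles = (
        [f"motion{i+1}" for i in range(6)]
        + [f"dmotion{i+1}" for i in range(6)]
        + [f"wm{i+1}" for i in range(5)]
        + [f"csf{i+1}" for i in range(5)]
        + ["intercept"]
    )
    return NuisanceMatrix(cols, roles)


def regress_nuisance(series: np.ndarray, nuisance: NuisanceMatrix) -> np.ndarray:
    """OLS residuals of every ROI column against the nuisance design.

    Rank deficiency is handled by the least-squares pseudoinverse and
    logged; residuals are orthogonal to every design column.
    """
    series = np.asarray(series, dtype=float)
    x = nuisance.columns
    t = series.shape[0]
    if x.shape[0] != t:
        raise ValueError("series and nuisance design must share T")
    if t <= nuisance.k:
        raise ValueError(f"need more frames ({t}) than nuisance columns ({nuisance.k})")
    beta, _, rank, _ = np.linalg.lstsq(x, series, rcond=None)
    if rank < nuisance.k:
        logger.warning("nuisance design rank %d < %d columns; pseudoinverse fit", rank, nuisance.k)
    return series - x @ beta


def bandpass(series: np.ndarray, band: BandSpec, method: str = "ideal") -> np.ndarray:
    """Band-pass every column; DC (the mean) is always outside the band.

    ``"ideal"`` zeroes rFFT bins outside [low_hz, high_hz] (inclusive
    edges), giving exact pass/stop behaviour on bin frequencies.
    ``"butterworth"`` applies a 4th-order zero-phase Butterworth.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    if t < 32:
        raise ValueError("band-pass needs at least 32 frames")
    if method == "ideal":
        freqs = np.fft.rfftfreq(t, d=band.tr_seconds)
        spec = np.fft.rfft(series, axis=0)
        mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
        spec[~mask] = 0.0
        return np.fft.irfft(spec, n=t, axis=0)
    if method == "butterworth":
        nyq = band.nyquist_hz
        b, a = signal.butter(4, [band.low_hz / nyq, band.high_hz / nyq], btype="bandpass")
        return signal.filtfilt(b, a, series - series.mean(axis=0), axis=0)
    raise ValueError(f"unknown band-pass method {method!r}")


def kendall_matrix(series: np.ndarray, labels: list[str] | None = None,
                   variant: str = "b") -> np.ndarray:
    """N×N Kendall rank correlation (tie-corrected tau-b by default).

    A constant column has no rank ordering and is an error naming the ROI.
    """
    series = np.asarray(series, dtype=float)
    t, n = series.shape
    if t < 3:
        raise ValueError("Kendall correlation needs at least 3 frames")
    flat = np.ptp(series, axis=0) == 0
    if flat.any():
        names = [labels[i] if labels else f"column {i}" for i in np.flatnonzero(flat)]
        raise ValueError(f"constant time series for ROI(s): {names}")
    tau = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            tau[i, j] = tau[j, i] = stats.kendalltau(
                series[:, i], series[:, j], variant=variant
            ).statistic
    return tau


def fisher_z(r) -> np.ndarray:
    """atanh of a correlation; |r| within 1e-7 of 1 is clipped (logged)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) > _CLIP):
        logger.warning("clipping %d correlation(s) at |r|=%.7f before atanh",
                       int((np.abs(r) > _CLIP).sum()), _CLIP)
        r = np.clip(r, -_CLIP, _CLIP)
    return np.arctanh(r)


def fisher_inv(z) -> np.ndarray:
    """Inverse Fisher transform (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def group_average(matrices, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Average correlation matrices across subjects in Fisher-z space.

    Off-diagonal entries are atanh-transformed, averaged, and mapped back
    with tanh; the diagonal is set to 1 without transformation.
    """
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    if not matrices:
        raise ValueError("need at least one subject matrix")
    shape = matrices[0].shape
    if any(m.shape != shape for m in matrices):
        raise ValueError("subject matrices must share one shape")
    n = shape[0]
    off = ~np.eye(n, dtype=bool)
    zsum = np.zeros(shape)
    for m in matrices:
        zsum[off] += fisher_z(m[off])
    out = np.eye(n)
    out[off] = fisher_inv(zsum[off] / len(matrices))
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return ConnectivityMatrix(out, labels if labels is not None else [f"roi{i:03d}" for i in range(n)])


def build_resting_matrix(
    panel: SubjectPanel,
    threshold_mm: float = 3.0,
    band: BandSpec | None = None,
    order: str = "regress-then-filter",
    filter_method: str = "ideal",
    tau_variant: str = "b",
):
    """Full chain: motion screen → nuisance → band-pass → tau → group average.

    Returns ``(group_matrix, report)``; the report records kept/excluded
    subjects so no data is dropped silently.  ``order`` may be
    ``"regress-then-filter"`` (default, the listed order) or
    ``"filter-then-regress"``.
    """
    band = band or BandSpec(tr_seconds=panel.tr_seconds)
    if order not in ("regress-then-filter", "filter-then-regress"):
        raise ValueError(f"unknown processing order {order!r}")
    kept, excluded = motion_screen(panel, threshold_mm)
    if not kept:
        raise ValueError("motion screen excluded every subject")
    per_subject = []
    for idx in kept:
        nuis = build_nuisance(panel.motion[idx], panel.wm_eigs[idx], panel.csf_eigs[idx])
        x = panel.series[idx]
        if order == "regress-then-filter":
            x = bandpass(regress_nuisance(x, nuis), band, method=filter_method)
        else:
            x = regress_nuisance(bandpass(x, band, method=filter_method), nuis)
        per_subject.append(kendall_matrix(x, labels=panel.labels, variant=tau_variant))
    group = group_average(per_subject, labels=panel.labels)
    report = {
        "n_subjects_in": panel.n_subjects,
        "n_subjects_kept": len(kept),
        "kept": kept,
        "excluded": excluded,
        "order": order,
        "filter_method": filter_method,
        "band": (band.low_hz, band.high_hz),
        "tr_seconds": band.tr_seconds,
    }
    return group, report
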