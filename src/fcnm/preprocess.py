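"""Time-series preparation on already-normalized 4-D data.

Covers initial-volume discard, head-motion quality control, framewise
displacement (Power variant: sum of absolute frame-to-frame translation
differences plus rotation differences scaled by an assumed 50 mm head
radius), the Friston-24 motion expansion, per-spike one-hot regressors for
frames with FD above threshold, simultaneous least-squares nuisance
regression, and an ideal (rectangular, zero-phase) FFT bandpass.

Processing order in the pipeline: discard -> motion QC gate -> nuisance
regression with all regressors at once (including the linear trend) ->
bandpass. Regressing everything simultaneously avoids reintroducing
variance that a sequential scheme would leave behind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volumes import BinaryMask, Volume4D

__all__ = [
    "MotionTrace",
    "NuisanceDesign",
    "load_motion_trace",
    "discard_initial_volumes",
    "motion_qc",
    "framewise_displacement",
    "friston24",
    "spike_regressors",
    "build_nuisance_design",
    "nuisance_regress",
    "bandpass",
]


@dataclass
class MotionTrace:
    """Rigid-body motion estimates: T x 3 translations (mm), T x 3 rotations (radians)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be T x 3")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]

    @property
    def params(self) -> np.ndarray:
        """T x 6 matrix [tx, ty, tz, rx, ry, rz]."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class NuisanceDesign:
    matrix: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("design matrix columns must match labels")
        if not np.isfinite(self.matrix).all():
            raise ValueError("design matrix contains non-finite values")


def load_motion_trace(path: str | Path) -> MotionTrace:
    """Read a 6-column text file: 3 translations (mm), 3 rotations (radians)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns, got {arr.shape[1]}")
    return MotionTrace(arr[:, :3], arr[:, 3:])


def discard_initial_volumes(data: Volume4D, n_discard: int = 10) -> Volume4D:
    """Drop the first ``n_discard`` volumes (scanner equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if data.n_volumes <= n_discard:
        raise ValueError(f"T={data.n_volumes} <= n_discard={n_discard}")
    return Volume4D(data.data[..., n_discard:], data.affine, data.tr_seconds, data.space_label)


def motion_qc(
    motion: MotionTrace, max_trans_mm: float = 2.0, max_rot_deg: float = 2.0
) -> tuple[bool, np.ndarray]:
    """Gross-motion gate: fail iff any axis strictly exceeds the limits.

    Returns (passed, offending frame indices). The rotation limit is given
    in degrees and compared against the radian trace after conversion; a
    value exactly at the limit passes (strict "exceeding").
    """
    bad_t = np.abs(motion.translations) > max_trans_mm
    bad_r = np.abs(motion.rotations) > np.deg2rad(max_rot_deg)
    offending = np.where(bad_t.any(axis=1) | bad_r.any(axis=1))[0]
    return offending.size == 0, offending


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD: FD_t = sum|d trans| + r * sum|d rot| (radians); FD[0] = 0."""
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    return np.r_[0.0, dt + head_radius_mm * dr]


def friston24(motion: MotionTrace) -> np.ndarray:
    """Friston motion expansion: [p, p_{t-1}, p^2, p_{t-1}^2] for 6 parameters.

    The lagged row 0 is set to 0. Output is T x 24, columns grouped as
    6 params, 6 lags, 6 squares, 6 lagged squares.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames")
    p = motion.params
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def spike_regressors(fd: np.ndarray, threshold_mm: float = 0.5) -> np.ndarray:
    """One one-hot column per frame with FD strictly above threshold (T x s)."""
    fd = np.asarray(fd, dtype=float)
    flagged = np.where(fd > threshold_mm)[0]
    out = np.zeros((fd.size, flagged.size))
    for j, t in enumerate(flagged):
        out[t, j] = 1.0
    return out


def build_nuisance_design(
    motion: MotionTrace,
    fd: np.ndarray,
    global_sig: np.ndarray,
    wm_sig: np.ndarray,
    csf_sig: np.ndarray,
    include_gsr: bool = True,
    fd_threshold_mm: float = 0.5,
) -> NuisanceDesign:
    """Assemble [constant, linear trend, Friston-24, spikes, (global), wm, csf]."""
    T = motion.n_frames
    series = {"fd": fd, "global": global_sig, "wm": wm_sig, "csf": csf_sig}
    for name, s in series.items():
        if np.asarray(s).shape != (T,):
            raise ValueError(f"{name} signal length {np.asarray(s).shape} != T={T}")
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    labels = ["constant", "linear_trend"]
    f24 = friston24(motion)
    cols.extend(f24.T)
    labels.extend(f"friston24_{i}" for i in range(24))
    spikes = spike_regressors(np.asarray(fd, dtype=float), fd_threshold_mm)
    cols.extend(spikes.T)
    labels.extend(f"spike_{int(t)}" for t in np.where(np.asarray(fd) > fd_threshold_mm)[0])
    if include_gsr:
        cols.append(np.asarray(global_sig, dtype=float))
        labels.append("global")
    cols.append(np.asarray(wm_sig, dtype=float))
    labels.append("wm")
    cols.append(np.asarray(csf_sig, dtype=float))
    labels.append("csf")
    return NuisanceDesign(np.column_stack(cols), labels)


def nuisance_regress(
    data: Volume4D, design: NuisanceDesign, mask: BinaryMask | None = None
) -> Volume4D:
    """Per-voxel least-squares residuals against the nuisance design.

    Uses the pseudoinverse projection, so a rank-deficient design (warned)
    behaves as if dependent columns were dropped; residuals are orthogonal
    to every design column.
    """
    X = design.matrix
    T = data.n_volumes
    if X.shape[0] != T:
        raise ValueError(f"design rows {X.shape[0]} != T={T}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; dependent columns are ignored",
                      stacklevel=2)
    if mask is not None:
        if not mask.same_geometry(data):
            raise ValueError("mask geometry does not match data")
        sel = mask.data.astype(bool)
    else:
        sel = np.ones(data.shape[:3], dtype=bool)
    Y = data.data[sel].T  # T x V
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    out = np.array(data.data, dtype=float, copy=True)
    out[sel] = resid.T
    return Volume4D(out, data.affine, data.tr_seconds, data.space_label)


def bandpass(data: Volume4D, low_hz: float = 0.01, high_hz: float = 0.1) -> Volume4D:
    """Ideal rectangular bandpass in the frequency domain, per voxel.

    Keeps Fourier bins with low_hz <= f <= high_hz; the DC component is
    always removed. Zero-phase and idempotent by construction.
    """
    T, tr = data.n_volumes, data.tr_seconds
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz={high_hz} exceeds Nyquist={nyquist:.4f} at TR={tr}")
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    keep[0] = False
    spec = np.fft.rfft(data.data, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=-1)
    return Volume4D(out, data.affine, data.tr_seconds, data.space_label)
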