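"""Functional preprocessing chain for homotopic-connectivity analysis.

Stage order (recorded in provenance): drop initial volumes -> motion-trace
alignment bookkeeping -> linear detrend -> nuisance + spike regression
(24 motion regressors, CSF mean, one indicator column per high-motion frame)
-> band-pass filter (ideal rectangular FFT filter) -> Gaussian smoothing
restricted to a tissue mask.

Framewise displacement follows Power's convention: the sum of absolute
backward differences of the six rigid-body parameters, with rotations
converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

__all__ = [
    "drop_initial",
    "detrend_linear",
    "compute_fd",
    "friston24",
    "spike_regressors",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "masked_smooth",
    "preprocess_subject",
    "STAGE_ORDER",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("drop", "align_motion", "detrend", "nuisance_regression", "bandpass", "masked_smooth")


def drop_initial(arr: np.ndarray, k: int = 5, time_axis: int = -1) -> np.ndarray:
    """Discard the first ``k`` frames along ``time_axis`` (signal
    stabilization); apply with ``time_axis=0`` to truncate a motion trace
    identically."""
    T = arr.shape[time_axis]
    if not 0 <= k < T:
        raise ValueError(f"cannot drop k={k} of T={T} frames")
    index = [slice(None)] * arr.ndim
    index[time_axis] = slice(k, None)
    return arr[tuple(index)]


def detrend_linear(series: np.ndarray, time_axis: int = -1) -> np.ndarray:
    """Remove the per-voxel least-squares line (intercept + slope); the
    output is orthogonal to both the constant and the linear ramp."""
    series = np.moveaxis(np.asarray(series, float), time_axis, -1)
    T = series.shape[-1]
    if T < 3:
        raise ValueError(f"detrend needs T >= 3, got {T}")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    Y = series.reshape(-1, T).T
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    return np.moveaxis(resid.T.reshape(series.shape), -1, time_axis)


def compute_fd(motion: np.ndarray, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Per-frame framewise displacement (mm); FD[0] = 0."""
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be T x 6, got {motion.shape}")
    if motion.shape[0] < 1:
        raise ValueError("motion trace needs at least one frame")
    diff = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = diff[:, :3].sum(axis=1) + sphere_radius_mm * diff[:, 3:].sum(axis=1)
    return fd


def friston24(motion: np.ndarray) -> np.ndarray:
    """24 motion regressors: the 6 parameters, their one-frame lags (zero at
    the first frame), and the squares of both sets."""
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be T x 6, got {motion.shape}")
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.column_stack([motion, lag, motion**2, lag**2])


def spike_regressors(fd: np.ndarray, threshold_mm: float = 1.0) -> np.ndarray:
    """T x S indicator matrix with one column per frame whose FD exceeds the
    threshold; S = 0 yields a (T, 0) matrix."""
    fd = np.asarray(fd, float)
    frames = np.flatnonzero(fd > threshold_mm)
    out = np.zeros((fd.shape[0], frames.size))
    out[frames, np.arange(frames.size)] = 1.0
    return out


def build_nuisance_design(
    motion: np.ndarray,
    csf_mean: np.ndarray | None = None,
    fd: np.ndarray | None = None,
    fd_threshold_mm: float = 1.0,
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept | 24 motion regressors | CSF mean | spike
    indicators]; returns the design and its column names."""
    m24 = friston24(motion)
    T = m24.shape[0]
    cols = [np.ones((T, 1)), m24]
    names = ["intercept"] + [f"motion{j}" for j in range(24)]
    if csf_mean is not None:
        csf_mean = np.asarray(csf_mean, float).reshape(-1)
        if csf_mean.shape[0] != T:
            raise ValueError("CSF regressor length does not match motion trace")
        cols.append(csf_mean[:, None])
        names.append("csf")
    if fd is not None:
        spikes = spike_regressors(fd, fd_threshold_mm)
        cols.append(spikes)
        names += [f"spike_t{f}" for f in np.flatnonzero(np.asarray(fd) > fd_threshold_mm)]
    return np.column_stack(cols), names


def regress_nuisance(bold: np.ndarray, design: np.ndarray, time_axis: int = -1) -> np.ndarray:
    """Per-voxel OLS residuals against the design; collinear columns are
    dropped (pivoted QR) with a logged warning.  Residuals are orthogonal to
    every retained column; frames owned by a spike indicator come out exactly
    zero."""
    design = np.asarray(design, float)
    if design.ndim != 2:
        raise ValueError("design must be a T x K matrix")
    bold = np.moveaxis(np.asarray(bold, float), time_axis, -1)
    T = bold.shape[-1]
    if design.shape[0] != T:
        raise ValueError(f"design has {design.shape[0]} rows but series has {T} frames")
    from scipy.linalg import qr

    _, R, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = np.sort(piv[: int((diag > tol).sum())])
    if keep.size < design.shape[1]:
        logger.warning(
            "nuisance design rank-deficient: dropping %d collinear column(s)",
            design.shape[1] - keep.size,
        )
    X = design[:, keep]
    Y = bold.reshape(-1, T).T
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    return np.moveaxis(resid.T.reshape(bold.shape), -1, time_axis)


def bandpass(series: np.ndarray, low_hz: float = 0.01, high_hz: float = 0.1, tr_s: float = 2.2,
             time_axis: int = -1) -> np.ndarray:
    """Ideal rectangular band-pass: discrete-Fourier bins with frequency in
    [low_hz, high_hz] are kept, all others (including DC) zeroed."""
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got [{low_hz}, {high_hz}]")
    if high_hz >= nyquist:
        raise ValueError(f"high={high_hz} Hz reaches the Nyquist frequency {nyquist:.4f} Hz")
    series = np.moveaxis(np.asarray(series, float), time_axis, -1)
    T = series.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=-1)
    return np.moveaxis(out, -1, time_axis)


def _gaussian_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def masked_smooth(
    series: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_size_mm: float = 3.0,
    truncate: float = 4.0,
) -> np.ndarray:
    """Normalized Gaussian smoothing restricted to a binary mask:
    ``smooth(data * mask) / smooth(mask)`` inside the mask, zero outside, so
    values outside the mask never leak in and a constant field stays exactly
    constant.  Accepts a 3D volume or a 4D series (time last)."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    series = np.asarray(series, float)
    sigma = _gaussian_sigma_vox(fwhm_mm, voxel_size_mm)
    denom = ndimage.gaussian_filter(mask.astype(float), sigma, mode="constant", truncate=truncate)
    valid = mask & (denom > 1e-6)

    def one(vol: np.ndarray) -> np.ndarray:
        num = ndimage.gaussian_filter(np.where(mask, vol, 0.0), sigma, mode="constant", truncate=truncate)
        out = np.zeros_like(vol, dtype=float)
        out[valid] = num[valid] / denom[valid]
        return out

    if series.ndim == 3:
        return one(series)
    if series.ndim == 4:
        out = np.empty_like(series, dtype=float)
        for t in range(series.shape[-1]):
            out[..., t] = one(series[..., t])
        return out
    raise ValueError("series must be 3D or 4D")


def preprocess_subject(
    bold: np.ndarray,
    motion: np.ndarray,
    csf_mask: np.ndarray,
    tissue_masks: dict[str, np.ndarray],
    drop: int = 5,
    fd_threshold_mm: float = 1.0,
    band: tuple[float, float] = (0.01, 0.1),
    tr_s: float = 2.2,
    fwhm_mm: float = 4.0,
    voxel_size_mm: float = 3.0,
    smooth: bool = True,
) -> dict:
    """Run the full chain on one subject.

    Returns a dict with per-tissue preprocessed 4D series (smoothed when
    ``smooth`` is true), the band-passed unsmoothed series, the FD trace,
    flagged spike frames, and a provenance record of stages and parameters.
    The CSF nuisance regressor is the mean detrended signal inside
    ``csf_mask`` (extracted after volume dropping and detrending).
    """
    if motion.shape[0] != bold.shape[-1]:
        raise ValueError("motion trace and BOLD series disagree on frame count")
    bold_d = drop_initial(bold, drop)
    motion_d = drop_initial(motion, drop, time_axis=0)
    detrended = detrend_linear(bold_d)
    fd = compute_fd(motion_d)
    csf_mean = detrended[np.asarray(csf_mask, bool)].mean(axis=0)
    design, names = build_nuisance_design(motion_d, csf_mean=csf_mean, fd=fd,
                                          fd_threshold_mm=fd_threshold_mm)
    resid = regress_nuisance(detrended, design)
    filtered = bandpass(resid, band[0], band[1], tr_s)
    out: dict = {
        "filtered": filtered,
        "fd": fd,
        "spike_frames": np.flatnonzero(fd > fd_threshold_mm).tolist(),
        "design_columns": names,
        "tissue": {},
        "provenance": {
            "stages": list(STAGE_ORDER if smooth else STAGE_ORDER[:-1]),
            "drop": drop,
            "fd_threshold_mm": fd_threshold_mm,
            "band_hz": list(band),
            "tr_s": tr_s,
            "fwhm_mm": fwhm_mm if smooth else None,
            "voxel_size_mm": voxel_size_mm,
        },
    }
    for tissue, mask in tissue_masks.items():
        if smooth:
            out["tissue"][tissue] = masked_smooth(filtered, mask, fwhm_mm, voxel_size_mm)
        else:
            out["tissue"][tissue] = np.where(np.asarray(mask, bool)[..., None], filtered, 0.0)
    return out
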