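"""Single-tensor diffusion fitting and scalar metrics (AD, MD, FA).

The tensor is estimated per voxel by log-linear least squares on
``ln S = ln S0 - b * g^T D g`` (exact on noiseless signals).  Axial
diffusivity is the largest eigenvalue, mean diffusivity the eigenvalue mean,
and fractional anisotropy the usual normalized eigenvalue dispersion

    FA = sqrt(3/2) * sqrt(sum((lambda_i - MD)^2)) / sqrt(sum(lambda_i^2)),

which lies in [0, 1].  ROI mean metrics are compared between groups with
two-sample t-tests at a Bonferroni-divided alpha (0.05/9 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TensorField", "fit_tensor", "tensor_metrics", "roi_dti_compare"]


@dataclass
class TensorField:
    """Voxelwise tensor estimates: the symmetric 3x3 tensors (mm^2/s),
    eigenvalues sorted descending, S0, and QA flags for voxels whose signals
    had to be clamped positive before taking logs."""

    tensor: np.ndarray  # (..., 3, 3)
    eigvals: np.ndarray  # (..., 3), descending
    s0: np.ndarray  # (...)
    clamped: np.ndarray  # (...) bool


def _design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx**2,
            -bvals * gy**2,
            -bvals * gz**2,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )


def fit_tensor(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
               mask: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares tensor fit.

    ``dwi`` has one volume per (b-value, direction) along the last axis.
    Requires at least six diffusion-weighted directions spanning the tensor
    space plus one b=0 volume.  Non-positive signals are clamped to a tiny
    positive value and flagged.
    """
    dwi = np.asarray(dwi, float)
    bvals = np.asarray(bvals, float).ravel()
    bvecs = np.asarray(bvecs, float)
    if dwi.shape[-1] != bvals.size or bvecs.shape != (bvals.size, 3):
        raise ValueError("dwi volumes, bvals and bvecs disagree in length")
    if (bvals > 0).sum() < 6 or (bvals == 0).sum() < 1:
        raise ValueError("need >= 6 diffusion-weighted volumes and >= 1 b=0 volume")
    X = _design(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme does not span the tensor space (collinear directions?)")

    spatial_shape = dwi.shape[:-1]
    Y = dwi.reshape(-1, bvals.size)
    if mask is not None:
        mask = np.asarray(mask).astype(bool).ravel()
    else:
        mask = np.ones(Y.shape[0], dtype=bool)
    clamped = (Y <= 0).any(axis=1) & mask
    logY = np.log(np.maximum(Y[mask], 1e-12)).T
    beta = np.linalg.pinv(X) @ logY

    tensor = np.zeros(Y.shape[0:1] + (3, 3))
    s0 = np.zeros(Y.shape[0])
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1], beta[2], beta[3], beta[4], beta[5], beta[6]
    t = np.zeros((mask.sum(), 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = dxx, dyy, dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    tensor[mask] = t
    s0[mask] = np.exp(beta[0])
    eigvals = np.linalg.eigvalsh(tensor)[:, ::-1]
    return TensorField(
        tensor=tensor.reshape(spatial_shape + (3, 3)),
        eigvals=eigvals.reshape(spatial_shape + (3,)),
        s0=s0.reshape(spatial_shape),
        clamped=clamped.reshape(spatial_shape),
    )


def tensor_metrics(eigvals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(AD, MD, FA) from eigenvalues.

    Slightly negative eigenvalues (noise) are clamped to zero; the all-zero
    tensor gets FA = 0 rather than 0/0.
    """
    lam = np.maximum(np.asarray(eigvals, float), 0.0)
    lam = np.sort(lam, axis=-1)[..., ::-1]
    ad = lam[..., 0]
    md = lam.mean(axis=-1)
    num = np.sqrt(((lam - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return ad, md, np.clip(fa, 0.0, 1.0)


def roi_dti_compare(
    metric_maps: dict[str, dict[str, np.ndarray]],
    rois: dict[str, np.ndarray],
    groups: dict[str, str],
    m_comparisons: int = 9,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of ROI-mean tensor metrics.

    Parameters
    ----------
    metric_maps : metric name -> {subject_id -> 3D map} (e.g. "FA", "MD", "AD").
    rois : roi name -> boolean mask on the metric grid.
    groups : subject_id -> group label.
    m_comparisons : Bonferroni divisor for the family of tests.

    Returns one row per (roi, metric, group pair) with the ROI-mean
    difference, t, two-tailed p, and significance at ``alpha / m``.
    """
    if m_comparisons <= 0:
        raise ValueError("m_comparisons must be positive")
    for name, mask in rois.items():
        if not np.asarray(mask).any():
            raise ValueError(f"ROI {name!r} is empty")
    levels = sorted(set(groups.values()))
    rows = []
    for roi_name, mask in rois.items():
        mask = np.asarray(mask).astype(bool)
        for metric, per_subject in metric_maps.items():
            means = {sid: float(np.asarray(vol)[mask].mean()) for sid, vol in per_subject.items()}
            for ga, gb in combinations(levels, 2):
                a = np.array([means[s] for s in means if groups[s] == ga])
                b = np.array([means[s] for s in means if groups[s] == gb])
                t, p = stats.ttest_ind(a, b)
                rows.append(
                    {
                        "roi": roi_name,
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "mean_diff": a.mean() - b.mean(),
                        "t": float(t),
                        "p": float(p),
                        "significant": bool(p < alpha / m_comparisons),
                    }
                )
    return pd.DataFrame(rows)
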