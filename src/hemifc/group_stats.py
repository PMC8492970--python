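"""Mass-univariate group comparison of homotopic-connectivity maps.

Per voxel, a covariate-adjusted one-way ANOVA (partial F for the group
factor in the GLM ``y ~ group dummies + age + sex + education + 1``),
Benjamini-Hochberg FDR control across in-mask voxels, post-hoc
covariate-adjusted two-sample t-tests at a Bonferroni-divided alpha
(0.05/6 for the GM family, 0.05/9 for the WM family by default), and
suprathreshold cluster extraction with left-right mirrored cluster pairs
merged into single bilateral records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .symmetry import mirror_volume

__all__ = [
    "StatMap",
    "encode_covariates",
    "glm_group_f",
    "fdr_bh",
    "posthoc_t",
    "extract_clusters",
]


@dataclass
class StatMap:
    """Voxelwise statistics: the statistic values (F or t), uncorrected
    p-values, degrees of freedom, and (after correction) rejection flags."""

    stat: np.ndarray
    p: np.ndarray
    df: tuple[float, float]
    reject: np.ndarray | None = None
    kind: str = "F"


def encode_covariates(covariates: pd.DataFrame, columns=("age", "sex", "education")) -> np.ndarray:
    """Numeric covariate matrix; 'sex' is encoded M=1, F=0."""
    cols = []
    for name in columns:
        col = covariates[name]
        if name == "sex":
            col = col.map({"M": 1.0, "F": 0.0}) if col.dtype == object else col.astype(float)
        cols.append(np.asarray(col, float))
    return np.column_stack(cols) if cols else np.empty((len(covariates), 0))


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = np.sort(piv[: int((diag > tol).sum())])
    if keep.size < X.shape[1]:
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d collinear design column(s)", X.shape[1] - keep.size
        )
    return X[:, keep]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    return (resid**2).sum(axis=0)


def glm_group_f(maps: np.ndarray, groups, covariates: np.ndarray | None = None) -> StatMap:
    """Partial F for the group factor, per voxel.

    Parameters
    ----------
    maps : (n_subjects, n_voxels) array of map values.
    groups : length-n sequence of group labels (>= 2 distinct, each n >= 2).
    covariates : optional (n_subjects, c) numeric matrix (e.g. age, sex,
        education); adjusted for in both the full and the reduced model.

    With no covariates this reduces exactly to the classical one-way ANOVA F
    with df = (g - 1, n - g).
    """
    Y = np.asarray(maps, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    n = Y.shape[0]
    if groups.shape[0] != n:
        raise ValueError("groups length does not match number of map rows")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    dummies = np.column_stack([(groups == lev).astype(float) for lev in levels[1:]])
    C = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    X_reduced = _drop_collinear(np.column_stack([np.ones(n), C]))
    X_full = _drop_collinear(np.column_stack([np.ones(n), dummies, C]))
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = n - X_full.shape[1]
    if df1 < 1 or df2 < 1:
        raise ValueError("not enough subjects for the requested model")
    rss_full = _rss(X_full, Y)
    rss_reduced = _rss(X_reduced, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    F = np.where(np.isfinite(F), np.maximum(F, 0.0), 0.0)
    p = stats.f.sf(F, df1, df2)
    return StatMap(stat=F, p=p, df=(float(df1), float(df2)), kind="F")


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure: reject the k smallest p-values
    where k = max{i : p_(i) <= i q / m}; returns boolean rejection flags."""
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    below = p[order] <= (np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1
        reject[order[:k]] = True
    return reject.reshape(np.asarray(pvals).shape)


def posthoc_t(
    maps: np.ndarray,
    groups,
    group_a: str,
    group_b: str,
    covariates: np.ndarray | None = None,
    m_comparisons: int = 9,
    alpha: float = 0.05,
) -> StatMap:
    """Covariate-adjusted two-sample t (group-indicator coefficient in the
    GLM on the two groups' rows); two-tailed p; significant iff
    p < alpha / m_comparisons."""
    if m_comparisons <= 0:
        raise ValueError("m_comparisons must be positive")
    groups = np.asarray(groups)
    sel = (groups == group_a) | (groups == group_b)
    if (groups == group_a).sum() < 2 or (groups == group_b).sum() < 2:
        raise ValueError("both groups need n >= 2")
    Y = np.asarray(maps, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y[sel]
    ind = (groups[sel] == group_a).astype(float)
    C = np.empty((sel.sum(), 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))[sel]
    X = _drop_collinear(np.column_stack([np.ones(sel.sum()), ind, C]))
    n, p_cols = X.shape
    df = n - p_cols
    if df < 1:
        raise ValueError("not enough subjects for the requested model")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return StatMap(stat=t, p=p, df=(1.0, float(df)),
                   reject=p < alpha / m_comparisons, kind="t")


def extract_clusters(
    reject_map: np.ndarray,
    stat_map: np.ndarray,
    voxel_size_mm: float = 3.0,
    connectivity: int = 26,
    merge_mirrored: bool = True,
    tissue: str = "",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of the rejection map, with peak statistics and
    sizes in mm^3.

    Returns a table (one row per cluster; exact left-right mirrored pairs
    merged into one bilateral record whose x coordinate carries a ±) and the
    integer label map (mirrored pairs share a label).  Coordinates are in mm
    relative to the grid centre, so the midline is x = 0.
    """
    reject_map = np.asarray(reject_map).astype(bool)
    stat_map = np.asarray(stat_map, float)
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labels, n = ndimage.label(reject_map, structure=structure)
    voxel_volume = voxel_size_mm**3
    shape = np.asarray(reject_map.shape, float)
    offset = -(shape - 1) / 2.0 * voxel_size_mm

    comp_masks = {lab: labels == lab for lab in range(1, n + 1)}
    merged_with: dict[int, int] = {}
    if merge_mirrored:
        mirrored = {lab: mirror_volume(m) for lab, m in comp_masks.items()}
        for a in range(1, n + 1):
            if a in merged_with:
                continue
            for b in range(a + 1, n + 1):
                if b in merged_with:
                    continue
                if np.array_equal(mirrored[a], comp_masks[b]):
                    merged_with[b] = a
                    break

    rows = []
    out_labels = np.zeros_like(labels)
    new_id = 0
    for lab in range(1, n + 1):
        if lab in merged_with:
            continue
        partner = next((b for b, a in merged_with.items() if a == lab), None)
        members = comp_masks[lab] | (comp_masks[partner] if partner else False)
        new_id += 1
        out_labels[members] = new_id
        idx = np.argwhere(members)
        vals = stat_map[tuple(idx.T)]
        peak = idx[int(np.argmax(np.abs(vals)))]
        peak_mm = peak * voxel_size_mm + offset
        rows.append(
            {
                "cluster_id": new_id,
                "tissue": tissue,
                "n_voxels": int(members.sum()),
                "size_mm3": float(members.sum() * voxel_volume),
                "peak_stat": float(vals[int(np.argmax(np.abs(vals)))]),
                "bilateral": partner is not None,
                "peak_x_mm": float(abs(peak_mm[0])) if partner is not None else float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "tissue", "n_voxels", "size_mm3", "peak_stat",
            "bilateral", "peak_x_mm", "peak_y_mm", "peak_z_mm",
        ],
    )
    if len(table):
        table = table.sort_values("size_mm3", ascending=False, ignore_index=True)
    return table, out_labels
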