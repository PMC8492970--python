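"""Voxel-mirrored homotopic connectivity (VMHC).

For every pair of left-right mirrored voxels inside a symmetric tissue mask,
the Pearson correlation of their preprocessed time series is computed and
assigned to both voxels of the pair, then variance-stabilized with Fisher's
z transform (z = atanh r).  The resulting z map is exactly mirror-symmetric
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symmetry import MirrorMap

__all__ = ["fisher_z", "homotopic_correlation", "VmhcMap", "vmhc_subject"]

#: correlations are clipped to 1 - FISHER_EPS in magnitude before atanh so
#: degenerate (perfectly correlated) phantom inputs stay finite.
FISHER_EPS = 1e-7


def fisher_z(r, eps: float = FISHER_EPS):
    """Fisher z = atanh(r) with clipping to ``|r| <= 1 - eps``; odd and
    strictly increasing.  Rejects |r| > 1 (beyond float slack)."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
    return z if z.ndim else float(z)


def homotopic_correlation(bold: np.ndarray, mirror_map: MirrorMap) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between mirrored time series for every pair in the map.

    Returns ``(r_map, degenerate_map)``: both 3D, with the pair's r written
    to both voxels.  Pairs where either series has zero variance get r = 0
    and a True flag in ``degenerate_map`` (QA, not fatal).
    """
    bold = np.asarray(bold, float)
    if bold.ndim != 4:
        raise ValueError("bold must be 4D (x, y, z, t)")
    T = bold.shape[-1]
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    x = bold[tuple(mirror_map.left.T)]
    y = bold[tuple(mirror_map.right.T)]
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((y**2).sum(axis=1))
    bad = (sx == 0) | (sy == 0)
    denom = np.where(bad, 1.0, sx * sy)
    r = np.clip((x * y).sum(axis=1) / denom, -1.0, 1.0)
    r[bad] = 0.0
    return mirror_map.scatter(r), mirror_map.scatter(bad.astype(float)) > 0


@dataclass
class VmhcMap:
    """Per-subject homotopic connectivity map: Fisher-z values over the mask
    (zero outside), the companion raw-r map, a QA flag map for degenerate
    (zero-variance) pairs, and provenance."""

    subject_id: str
    tissue: str
    z: np.ndarray
    r: np.ndarray
    degenerate: np.ndarray
    provenance: dict = field(default_factory=dict)


def vmhc_subject(
    bold: np.ndarray,
    mirror_map: MirrorMap,
    subject_id: str = "",
    tissue: str = "",
    provenance: dict | None = None,
) -> VmhcMap:
    """Full VMHC map for one preprocessed subject series."""
    r_map, degenerate = homotopic_correlation(bold, mirror_map)
    z_map = np.zeros_like(r_map)
    sel = np.zeros(mirror_map.shape, dtype=bool)
    sel[tuple(mirror_map.left.T)] = True
    sel[tuple(mirror_map.right.T)] = True
    z_map[sel] = fisher_z(r_map[sel])
    return VmhcMap(
        subject_id=subject_id,
        tissue=tissue,
        z=z_map,
        r=r_map,
        degenerate=degenerate,
        provenance=dict(provenance or {}),
    )
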