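"""Symmetric templates, binary group GM/WM masks, and the voxel mirror map.

The mirror axis is the first voxel axis of the canonical grid (left-right);
phantom grids are midline-aligned by construction, so mirroring is a pure
index flip ``i -> N_x - 1 - i``.  On a grid with an odd left-right extent the
midsagittal plane mirrors onto itself; those voxels are excluded from the
mirror map (their homotopic correlation would be trivially 1) with a log
message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "mirror_volume",
    "symmetric_average",
    "group_symmetric_mask",
    "exclude_region",
    "MirrorMap",
    "build_mirror_map",
]

logger = logging.getLogger(__name__)


def mirror_volume(vol: np.ndarray) -> np.ndarray:
    """Flip a 3D volume along the left-right axis; an involution."""
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    return vol[::-1, :, :]


def symmetric_average(vol: np.ndarray) -> np.ndarray:
    """(vol + mirror(vol)) / 2; the output is exactly mirror-invariant."""
    vol = np.asarray(vol, float)
    return (vol + mirror_volume(vol)) / 2.0


def group_symmetric_mask(prob_maps: list[np.ndarray], threshold: float) -> np.ndarray:
    """Binary group mask: average the subjects' tissue probability maps,
    symmetrize by flip-averaging, then binarize at ``>= threshold`` (0.2 for
    GM, 0.8 for WM in the default configuration)."""
    if len(prob_maps) == 0:
        raise ValueError("need at least one probability map")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    stack = np.stack([np.asarray(p, float) for p in prob_maps])
    if stack.min() < 0 or stack.max() > 1:
        raise ValueError("probability maps must take values in [0, 1]")
    return symmetric_average(stack.mean(axis=0)) >= threshold


def exclude_region(mask: np.ndarray, exclusion_mask: np.ndarray) -> np.ndarray:
    """Remove a (possibly asymmetric) exclusion region, then re-symmetrize by
    intersecting the result with its own mirror."""
    mask = np.asarray(mask).astype(bool)
    exclusion_mask = np.asarray(exclusion_mask).astype(bool)
    if mask.shape != exclusion_mask.shape:
        raise ValueError(f"grid mismatch: {mask.shape} vs {exclusion_mask.shape}")
    out = mask & ~exclusion_mask
    return out & mirror_volume(out)


@dataclass(frozen=True)
class MirrorMap:
    """Pairing of every in-mask voxel with its left-right counterpart.

    ``left`` and ``right`` are (n_pairs, 3) integer index arrays with
    ``right = (N_x - 1 - left_i, left_j, left_k)``; each in-mask voxel
    appears in exactly one pair."""

    shape: tuple[int, int, int]
    left: np.ndarray
    right: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.left.shape[0])

    def scatter(self, pair_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Write one value per pair to both voxels of the pair."""
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.left.T)] = pair_values
        out[tuple(self.right.T)] = pair_values
        return out


def build_mirror_map(mask: np.ndarray) -> MirrorMap:
    """Mirror map of a mirror-symmetric binary mask.

    Raises on an asymmetric mask, listing the unmatched voxels.  Midplane
    voxels of an odd-extent grid are excluded (logged)."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    unmatched = np.argwhere(mask & ~mirror_volume(mask))
    if unmatched.size:
        shown = unmatched[:10].tolist()
        raise ValueError(
            f"mask is not mirror-symmetric: {len(unmatched)} unmatched voxel(s), e.g. {shown}"
        )
    nx = mask.shape[0]
    work = mask.copy()
    if nx % 2 == 1:
        mid = nx // 2
        n_mid = int(work[mid].sum())
        if n_mid:
            logger.info("excluding %d midsagittal-plane voxel(s) from the mirror map", n_mid)
        work[mid] = False
    left = np.argwhere(work[: nx // 2, :, :])
    right = left.copy()
    right[:, 0] = nx - 1 - left[:, 0]
    return MirrorMap(shape=tuple(mask.shape), left=left, right=right)
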