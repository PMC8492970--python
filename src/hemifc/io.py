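"""File I/O helpers: NIfTI-1 volumes, TSV tables, FSL-style bval/bvec text.

Every writer can drop a JSON provenance sidecar (``<file>.json``) next to the
file it writes; the pipeline uses this to stamp outputs with the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def centered_affine(shape, voxel_size_mm: float) -> np.ndarray:
    """RAS affine with the origin at the grid centre (midline between the two
    central slices on the left-right axis when the extent is even)."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape[:3], float) - 1) / 2.0 * voxel_size_mm
    return aff


def save_nifti(data: np.ndarray, path, affine: np.ndarray, sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        write_sidecar(path, sidecar)
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_tsv(df: pd.DataFrame, path, sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        write_sidecar(path, sidecar)
    return path


def load_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_bvals_bvecs(bvals, bvecs, prefix) -> tuple[Path, Path]:
    """FSL layout: one row of b-values; three rows (x, y, z) of directions."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, np.asarray(bvals, float)[None, :], fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs, float).T, fmt="%.8f")
    return bval_path, bvec_path


def load_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def write_sidecar(path, payload: dict) -> Path:
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return side


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]
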