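"""Synthetic cohort generator ("phantom") for homotopic-connectivity analysis.

Generates, on a midline-aligned voxel grid, everything the pipeline consumes:
4D BOLD series with planted homotopic correlations, GM/WM/CSF tissue
probability maps (concentric compartments, mirror-symmetric up to an optional
perturbation), 6-parameter rigid-body motion traces with optional >1 mm
spikes, single-tensor DWI signals, and a covariate table (group, age, sex,
education, MMSE).

Planted correlation model
-------------------------
For every mirrored voxel pair inside a parcel with target correlation ``rho``
and BOLD noise scale ``sigma = noise_sd``::

    x(t) = s(t)              + sigma * e1(t)
    y(t) = rho * s(t) + sqrt(1 - rho**2) * e2(t) + sigma * e3(t)

with ``s, e1, e2, e3`` independent unit-variance Gaussian series.  The
population correlation of the pair is therefore attenuated to

    rho_eff = rho / (1 + sigma**2)

which :func:`effective_rho` exposes; recovery tests target
``atanh(rho_eff)``.  Voxels inside the brain but outside every parcel carry
independent noise, so their homotopic correlation is zero in expectation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParcelSpec",
    "PhantomSpec",
    "GroundTruth",
    "Subject",
    "Cohort",
    "effective_rho",
    "default_parcels",
    "default_dwi_scheme",
    "tissue_compartments",
    "parcel_masks",
    "generate_tissue_probs",
    "generate_bold",
    "generate_motion",
    "generate_dwi",
    "generate_cohort",
    "fibonacci_directions",
]

GROUPS = ("NC", "VMCI", "MCI")

# Cohort demographics emulated by the covariate generator: mean/SD of age and
# education (years), MMSE, and the fraction of male subjects, per group.
COVARIATE_DISTRIBUTIONS = {
    "NC": {"age": (74.41, 8.227), "education": (14.32, 1.757), "mmse": (28.86, 1.318), "p_male": 0.50},
    "VMCI": {"age": (74.76, 7.668), "education": (14.59, 3.016), "mmse": (25.99, 2.882), "p_male": 48 / 90},
    "MCI": {"age": (75.89, 8.554), "education": (14.75, 3.204), "mmse": (22.08, 4.057), "p_male": 33 / 53},
}

# Baseline single-tensor eigenvalues per tissue (mm^2/s), principal axis +y.
TISSUE_TENSOR_EIGVALS = {
    "wm": (1.7e-3, 0.3e-3, 0.3e-3),
    "gm": (0.8e-3, 0.8e-3, 0.8e-3),
    "csf": (3.0e-3, 3.0e-3, 3.0e-3),
}


@dataclass(frozen=True)
class ParcelSpec:
    """A mirrored parcel: a box on the left side of the grid (voxel index
    bounds, half-open) intersected with one tissue compartment, plus its
    mirror image.  ``rho`` maps group name -> planted homotopic correlation;
    ``dwi_eigval_scale`` maps group name -> per-eigenvalue multipliers
    applied to the diffusion tensor inside the parcel."""

    name: str
    tissue: str  # "wm" or "gm"
    box: tuple[int, int, int, int, int, int]  # i0, i1, j0, j1, k0, k1 (left side)
    rho: dict[str, float] = field(default_factory=dict)
    dwi_eigval_scale: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def default_parcels() -> list[ParcelSpec]:
    """Three WM parcels and two GM parcels echoing the study conditions:
    homotopic correlation ordered NC > VMCI > MCI in most parcels, one WM
    parcel altered only in MCI (both in connectivity and in tensor shape)."""
    return [
        ParcelSpec("occipital_wm", "wm", (4, 9, 4, 10, 9, 15), {"NC": 0.8, "VMCI": 0.6, "MCI": 0.4}),
        ParcelSpec(
            "sublobar_wm", "wm", (5, 10, 12, 18, 8, 13),
            {"NC": 0.8, "VMCI": 0.78, "MCI": 0.5},
            {"MCI": (1.5, 1.0, 1.0)},
        ),
        ParcelSpec(
            "parietal_wm", "wm", (4, 9, 18, 24, 10, 15),
            {"NC": 0.75, "VMCI": 0.6, "MCI": 0.45},
            {"MCI": (1.25, 1.25, 1.25)},
        ),
        ParcelSpec("occipital_gm", "gm", (2, 8, 2, 9, 8, 16), {"NC": 0.8, "VMCI": 0.6, "MCI": 0.4}),
        ParcelSpec("parietal_gm", "gm", (2, 8, 19, 26, 8, 16), {"NC": 0.75, "VMCI": 0.6, "MCI": 0.45}),
    ]


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` unit vectors spread on the sphere by the golden-angle spiral;
    deterministic and pairwise non-collinear."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    vec = np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    return vec / np.linalg.norm(vec, axis=1, keepdims=True)


def default_dwi_scheme(n_directions: int = 24, b: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """One b=0 volume followed by ``n_directions`` diffusion-weighted volumes
    at b-value ``b`` (s/mm^2) along non-collinear unit directions."""
    bvals = np.concatenate([[0.0], np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros(3), fibonacci_directions(n_directions)])
    return bvals, bvecs


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cohort.  Defaults emulate the acquisition
    this pipeline targets (164 time points at TR 2.2 s; 24-direction DWI at
    b=1000 plus one b=0) on a desk-scale 24x28x24 grid of 3 mm voxels."""

    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 164
    tr_s: float = 2.2
    groups: dict[str, int] = field(default_factory=lambda: {"NC": 10, "VMCI": 10, "MCI": 10})
    parcels: list[ParcelSpec] = field(default_factory=default_parcels)
    noise_sd: float = 0.2
    motion_spike_frames: dict[str, list[int]] | None = None
    spike_mm: float = 2.0
    tissue_asym_sd: float = 0.02
    tissue_noise_sd: float = 0.02
    subject_eigval_jitter_sd: float = 0.04
    dwi_bvals: np.ndarray = field(default_factory=lambda: default_dwi_scheme()[0])
    dwi_bvecs: np.ndarray = field(default_factory=lambda: default_dwi_scheme()[1])
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive voxel counts, got {self.grid_shape}")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError(
                f"grid_shape[0]={self.grid_shape[0]} is odd: an even left-right extent is "
                "required so the mirror map has no self-paired midline voxels"
            )
        if self.n_timepoints < 10:
            raise ValueError(f"n_timepoints must be >= 10, got {self.n_timepoints}")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise ValueError(f"each requested group needs >= 1 subject, got {self.groups}")
        for parcel in self.parcels:
            if parcel.tissue not in ("wm", "gm"):
                raise ValueError(f"parcel {parcel.name}: tissue must be 'wm' or 'gm'")
            for group, rho in parcel.rho.items():
                if not 0.0 <= rho <= 1.0:
                    raise ValueError(f"parcel {parcel.name}: rho[{group}]={rho} outside [0, 1]")
            if parcel.box[1] > self.grid_shape[0] // 2:
                raise ValueError(f"parcel {parcel.name}: box crosses the midline")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bvals = np.asarray(self.dwi_bvals, float)
        if np.any(bvals < 0):
            raise ValueError("b-values must be >= 0")

    def subject_ids(self) -> list[str]:
        return [f"{g}{i + 1:02d}" for g in self.groups for i in range(self.groups[g])]

    def group_of(self, subject_id: str) -> str:
        for g in self.groups:
            if subject_id.startswith(g) and subject_id[len(g):].isdigit():
                return g
        raise ValueError(f"cannot infer group of subject {subject_id!r}")


def effective_rho(rho: float, noise_sd: float) -> float:
    """Population correlation of a planted pair after additive voxel noise:
    ``rho / (1 + noise_sd**2)`` (see module docstring for the derivation)."""
    return rho / (1.0 + noise_sd**2)


def _rng(spec: PhantomSpec, subject_id: str, stream: int) -> np.random.Generator:
    # Stable per-(seed, subject, stream) generator; crc32 keeps ids portable.
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, zlib.crc32(subject_id.encode()), stream])


def tissue_compartments(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Binary compartments on the grid: concentric ellipsoids with a CSF core,
    a WM shell and a GM rind, mirror-symmetric by construction.  Also returns
    the union under key ``"brain"``."""
    nx, ny, nz = spec.grid_shape
    centre = (np.array([nx, ny, nz], float) - 1) / 2.0
    semi = np.array([nx, ny, nz], float) / 2.0 - 1.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r = np.sqrt(
        ((ii - centre[0]) / semi[0]) ** 2
        + ((jj - centre[1]) / semi[1]) ** 2
        + ((kk - centre[2]) / semi[2]) ** 2
    )
    csf = r < 0.30
    wm = (r >= 0.30) & (r < 0.72)
    gm = (r >= 0.72) & (r < 0.95)
    return {"csf": csf, "wm": wm, "gm": gm, "brain": csf | wm | gm}


def parcel_masks(spec: PhantomSpec) -> dict[str, dict[str, np.ndarray]]:
    """Per parcel: ``left`` (box ∩ tissue, left hemisphere) and ``full``
    (left ∪ its mirror) boolean masks."""
    comps = tissue_compartments(spec)
    nx = spec.grid_shape[0]
    out: dict[str, dict[str, np.ndarray]] = {}
    for parcel in spec.parcels:
        i0, i1, j0, j1, k0, k1 = parcel.box
        box = np.zeros(spec.grid_shape, dtype=bool)
        box[i0:i1, j0:j1, k0:k1] = True
        left = box & comps[parcel.tissue]
        left[nx // 2:, :, :] = False
        if not left.any():
            raise ValueError(f"parcel {parcel.name}: box does not intersect its tissue compartment")
        full = left | left[::-1, :, :]
        out[parcel.name] = {"left": left, "full": full}
    return out


def generate_tissue_probs(spec: PhantomSpec, subject_id: str) -> dict[str, np.ndarray]:
    """Per-subject GM/WM/CSF probability maps: 0.92 inside the compartment,
    0.04 elsewhere in the brain, 0 outside, plus symmetric per-subject noise
    and an optional small asymmetric perturbation (exercises the flip-average
    symmetrization downstream)."""
    spec.validate()
    comps = tissue_compartments(spec)
    rng = _rng(spec, subject_id, 3)
    probs = {}
    for tissue in ("gm", "wm", "csf"):
        p = np.where(comps[tissue], 0.92, np.where(comps["brain"], 0.04, 0.0))
        noise = rng.normal(0.0, spec.tissue_noise_sd, size=spec.grid_shape)
        sym_noise = (noise + noise[::-1, :, :]) / 2.0
        asym = rng.normal(0.0, spec.tissue_asym_sd, size=spec.grid_shape)
        p = np.clip(p + sym_noise + asym, 0.0, 1.0)
        p[~comps["brain"]] = 0.0
        probs[tissue] = p.astype(np.float32)
    return probs


def generate_bold(spec: PhantomSpec, subject_id: str, group: str) -> np.ndarray:
    """4D BOLD series (nx, ny, nz, T) for one subject.

    Brain voxels get a 1000-unit baseline, a per-voxel linear drift, and unit
    Gaussian noise; CSF voxels share a common fluctuation (so the CSF-mean
    nuisance regressor has something to remove); parcel voxel pairs receive
    the shared-latent construction described in the module docstring; frames
    listed in ``motion_spike_frames`` receive a global additive artifact.
    """
    spec.validate()
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}; spec has {sorted(spec.groups)}")
    nx, ny, nz = spec.grid_shape
    T = spec.n_timepoints
    rng = _rng(spec, subject_id, 0)
    comps = tissue_compartments(spec)
    brain = comps["brain"]

    bold = np.zeros((nx, ny, nz, T), dtype=np.float64)
    n_brain = int(brain.sum())
    bold[brain] = rng.normal(0.0, 1.0, size=(n_brain, T))

    csf_sig = rng.normal(0.0, 1.0, size=T)
    bold[comps["csf"]] += csf_sig[None, :]

    sigma = spec.noise_sd
    for parcel, masks in zip(spec.parcels, parcel_masks(spec).values()):
        rho = parcel.rho.get(group)
        if rho is None:
            continue
        left_idx = np.argwhere(masks["left"])
        n = len(left_idx)
        s = rng.normal(0.0, 1.0, size=(n, T))
        e1 = rng.normal(0.0, 1.0, size=(n, T))
        e2 = rng.normal(0.0, 1.0, size=(n, T))
        e3 = rng.normal(0.0, 1.0, size=(n, T))
        x = s + sigma * e1
        y = rho * s + np.sqrt(1.0 - rho**2) * e2 + sigma * e3
        li, lj, lk = left_idx.T
        bold[li, lj, lk, :] = x
        bold[nx - 1 - li, lj, lk, :] = y

    drift = rng.uniform(-0.02, 0.02, size=n_brain)
    t = np.arange(T, dtype=float)
    bold[brain] += 1000.0 + drift[:, None] * t[None, :]

    spikes = (spec.motion_spike_frames or {}).get(subject_id, [])
    for f in spikes:
        if not 0 <= f < T:
            raise ValueError(f"spike frame {f} out of range [0, {T})")
        bold[..., f][brain] += rng.normal(5.0, 1.0, size=n_brain)

    return bold.astype(np.float32)


def generate_motion(spec: PhantomSpec, subject_id: str) -> np.ndarray:
    """T x 6 rigid-body trace (3 translations mm, 3 rotations rad): a clipped
    random walk whose framewise displacement stays well under 1 mm, plus a
    persistent ``spike_mm`` x-translation step at each requested spike frame
    (guaranteeing FD >= spike_mm there)."""
    spec.validate()
    T = spec.n_timepoints
    rng = _rng(spec, subject_id, 1)
    # Step scales chosen so mean Power-FD is ~0.3 mm; clipping bounds max FD
    # at 3*0.15 + 50*3*0.0015 = 0.675 mm in the spike-free case.
    dt = np.clip(rng.normal(0.0, 0.08, size=(T, 3)), -0.15, 0.15)
    dr = np.clip(rng.normal(0.0, 8e-4, size=(T, 3)), -1.5e-3, 1.5e-3)
    dt[0] = dr[0] = 0.0
    motion = np.cumsum(np.concatenate([dt, dr], axis=1), axis=0)
    for f in (spec.motion_spike_frames or {}).get(subject_id, []):
        if not 0 <= f < T:
            raise ValueError(f"spike frame {f} out of range [0, {T})")
        motion[f:, 0] += spec.spike_mm
    return motion


def generate_dwi(
    spec: PhantomSpec,
    tensor_field: np.ndarray,
    s0: np.ndarray | float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-tensor DWI signals ``S(b, g) = S0 * exp(-b * g^T D g)``, one
    volume per (b-value, direction); noiseless unless ``noise_sd`` > 0
    (additive Gaussian on the signal)."""
    tensor_field = np.asarray(tensor_field, float)
    if tensor_field.shape[-2:] != (3, 3):
        raise ValueError("tensor_field must have trailing shape (3, 3)")
    bvals = np.asarray(spec.dwi_bvals, float)
    bvecs = np.asarray(spec.dwi_bvecs, float)
    if np.any(bvals < 0):
        raise ValueError("b-values must be >= 0")
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
        raise ValueError("gradient directions for b > 0 must be unit-norm")
    # g^T D g for every voxel and direction in one contraction.
    quad = np.einsum("...ab,na,nb->...n", tensor_field, bvecs, bvecs)
    signal = np.asarray(s0, float)[..., None] if np.ndim(s0) else float(s0)
    dwi = signal * np.exp(-bvals * quad)
    if noise_sd > 0:
        gen = rng if rng is not None else np.random.default_rng(spec.seed)
        dwi = dwi + gen.normal(0.0, noise_sd, size=dwi.shape)
    return dwi


def base_tensor_field(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel baseline diffusion tensor: anisotropic in WM (principal axis
    along y, mirror-invariant), isotropic in GM and CSF, zero outside."""
    comps = tissue_compartments(spec)
    field_ = np.zeros(spec.grid_shape + (3, 3), dtype=float)
    for tissue, (l1, l2, l3) in TISSUE_TENSOR_EIGVALS.items():
        # principal axis +y => eigvals on the diagonal as (l2, l1, l3)
        field_[comps[tissue]] = np.diag([l2, l1, l3])
    return field_


@dataclass
class GroundTruth:
    """What was planted: per-parcel, per-group target and effective
    correlations; the baseline tensor field with per-subject eigenvalue
    jitter and per-parcel group scalings; true labels; injected spike
    frames."""

    parcel_rho: dict[str, dict[str, float]]
    parcel_rho_effective: dict[str, dict[str, float]]
    tensor_base: np.ndarray
    subject_eigval_jitter: dict[str, np.ndarray]
    labels: dict[str, str]
    spike_frames: dict[str, list[int]]


@dataclass
class Subject:
    subject_id: str
    group: str
    bold: np.ndarray  # (nx, ny, nz, T) float32
    motion: np.ndarray  # (T, 6)
    tissue_probs: dict[str, np.ndarray]
    dwi: np.ndarray  # (nx, ny, nz, n_volumes)
    tensor_true: np.ndarray  # (nx, ny, nz, 3, 3)


@dataclass
class Cohort:
    spec: PhantomSpec
    subjects: list[Subject]
    covariates: pd.DataFrame  # subject, group, age, sex, education, mmse
    ground_truth: GroundTruth

    def by_group(self) -> dict[str, list[Subject]]:
        out: dict[str, list[Subject]] = {g: [] for g in self.spec.groups}
        for s in self.subjects:
            out[s.group].append(s)
        return out


def _subject_tensor(spec: PhantomSpec, base: np.ndarray, group: str, jitter: np.ndarray) -> np.ndarray:
    tensor = base.copy()
    pm = parcel_masks(spec)
    for parcel in spec.parcels:
        scale = parcel.dwi_eigval_scale.get(group)
        if scale is None:
            continue
        mask = pm[parcel.name]["full"]
        vals, vecs = np.linalg.eigh(tensor[mask])
        vals = vals[:, ::-1] * np.asarray(scale, float)[None, :]  # descending
        vecs = vecs[:, :, ::-1]
        tensor[mask] = np.einsum("nab,nb,ncb->nac", vecs, vals, vecs)
    # Global per-subject eigenvalue jitter (between-subject variability).
    vals, vecs = np.linalg.eigh(tensor.reshape(-1, 3, 3))
    vals = vals[:, ::-1] * jitter[None, :]
    vecs = vecs[:, :, ::-1]
    return np.einsum("nab,nb,ncb->nac", vecs, vals, vecs).reshape(base.shape)


def generate_covariates(spec: PhantomSpec) -> pd.DataFrame:
    """Covariate table drawn from the emulated demographic distributions;
    MMSE clipped to [0, 30]."""
    spec.validate()
    rows = []
    for sid in spec.subject_ids():
        group = spec.group_of(sid)
        dist = COVARIATE_DISTRIBUTIONS[group]
        rng = _rng(spec, sid, 2)
        rows.append(
            {
                "subject": sid,
                "group": group,
                "age": round(float(rng.normal(*dist["age"])), 1),
                "sex": "M" if rng.random() < dist["p_male"] else "F",
                "education": round(float(rng.normal(*dist["education"])), 1),
                "mmse": float(np.clip(round(rng.normal(*dist["mmse"])), 0, 30)),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """All subjects' BOLD, tissue maps, motion, DWI, the covariate table and
    the ground truth, deterministically from ``spec.seed``."""
    spec.validate()
    base = base_tensor_field(spec)
    covariates = generate_covariates(spec)
    subjects = []
    jitters: dict[str, np.ndarray] = {}
    for sid in spec.subject_ids():
        group = spec.group_of(sid)
        jitter = np.exp(_rng(spec, sid, 4).normal(0.0, spec.subject_eigval_jitter_sd, size=3))
        jitters[sid] = jitter
        tensor = _subject_tensor(spec, base, group, jitter)
        subjects.append(
            Subject(
                subject_id=sid,
                group=group,
                bold=generate_bold(spec, sid, group),
                motion=generate_motion(spec, sid),
                tissue_probs=generate_tissue_probs(spec, sid),
                dwi=generate_dwi(spec, tensor).astype(np.float32),
                tensor_true=tensor,
            )
        )
    truth = GroundTruth(
        parcel_rho={p.name: dict(p.rho) for p in spec.parcels},
        parcel_rho_effective={
            p.name: {g: effective_rho(r, spec.noise_sd) for g, r in p.rho.items()} for p in spec.parcels
        },
        tensor_base=base,
        subject_eigval_jitter=jitters,
        labels={s.subject_id: s.group for s in subjects},
        spike_frames=dict(spec.motion_spike_frames or {}),
    )
    return Cohort(spec=spec, subjects=subjects, covariates=covariates, ground_truth=truth)


def with_groups(spec: PhantomSpec, groups: dict[str, int], seed: int | None = None) -> PhantomSpec:
    """Copy of ``spec`` with different group sizes (and optionally seed)."""
    return replace(spec, groups=dict(groups), seed=spec.seed if seed is None else seed)
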