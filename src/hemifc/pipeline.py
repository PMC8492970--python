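"""End-to-end orchestration: phantom -> preprocessing -> symmetric masks ->
VMHC -> group statistics -> DTI -> classification, from a single config,
with deterministic seeding and a provenance-stamped output manifest.

Defaults are the analysis constants this pipeline is built around: drop 5
volumes, FD spike threshold 1 mm, band 0.01-0.1 Hz, 4 mm FWHM tissue-
restricted smoothing, GM/WM mask thresholds 0.2/0.8, FDR q = 0.05,
Bonferroni families of 6 (GM) and 9 (WM), SVM cost grid 2^-8..2^3 in 2^0.25
steps.  Cohort sizes are desk-scale (see docs/methods.md).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import dti as dti_mod
from . import group_stats as gs
from . import io as hio
from . import phantom as ph
from . import preprocess as pp
from . import symmetry as sym
from . import vmhc as vm

__all__ = ["RunConfig", "run", "compute_vmhc_maps", "group_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run; serialized verbatim into
    every output's provenance sidecar.  Unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "hemifc_out"
    # phantom
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 164
    tr_s: float = 2.2
    noise_sd: float = 0.2
    train_groups: dict = field(default_factory=lambda: {"NC": 10, "VMCI": 10, "MCI": 10})
    val_groups: dict = field(default_factory=lambda: {"NC": 6, "VMCI": 6, "MCI": 6})
    # preprocessing
    drop: int = 5
    fd_threshold_mm: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 4.0
    # masks
    gm_threshold: float = 0.2
    wm_threshold: float = 0.8
    # statistics
    fdr_q: float = 0.05
    bonferroni_m_gm: int = 6
    bonferroni_m_wm: int = 9
    cluster_connectivity: int = 26
    # classification
    c_grid_exponents: tuple[float, float, float] = (-8.0, 3.0, 0.25)
    cv_folds: int = 5

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_s)
        low, high = self.band_hz
        if not 0 <= low < high:
            raise ValueError(f"invalid band {self.band_hz}")
        if high >= nyquist:
            raise ValueError(
                f"band high {high} Hz reaches the Nyquist frequency {nyquist:.4f} Hz at TR {self.tr_s}"
            )
        if not 0 < self.gm_threshold < 1 or not 0 < self.wm_threshold < 1:
            raise ValueError("mask thresholds must lie in (0, 1)")
        if self.fdr_q <= 0 or self.fdr_q >= 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.bonferroni_m_gm <= 0 or self.bonferroni_m_wm <= 0:
            raise ValueError("Bonferroni m must be positive")
        if self.drop < 0 or self.drop >= self.n_timepoints:
            raise ValueError("drop must satisfy 0 <= drop < n_timepoints")
        # delegate the rest to the phantom spec
        self.phantom_spec(self.train_groups, self.seed).validate()

    def phantom_spec(self, groups: dict, seed: int) -> ph.PhantomSpec:
        return ph.PhantomSpec(
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=self.voxel_size_mm,
            n_timepoints=self.n_timepoints,
            tr_s=self.tr_s,
            groups=dict(groups),
            noise_sd=self.noise_sd,
            seed=seed,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("grid_shape", "band_hz", "c_grid_exponents"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def compute_vmhc_maps(cohort: ph.Cohort, masks: dict[str, np.ndarray], config: RunConfig,
                      smooth: bool = True) -> dict[str, dict[str, vm.VmhcMap]]:
    """Preprocess every subject and compute per-tissue VMHC maps.

    Returns tissue -> subject_id -> VmhcMap.  ``smooth=False`` skips the
    masked smoothing stage (used for planted-correlation recovery, where
    smoothing's partial-volume mixing at parcel borders is a known bias).
    """
    mirror_maps = {t: sym.build_mirror_map(m) for t, m in masks.items()}
    out: dict[str, dict[str, vm.VmhcMap]] = {t: {} for t in masks}
    for subject in cohort.subjects:
        csf_mask = subject.tissue_probs["csf"] >= 0.5
        res = pp.preprocess_subject(
            subject.bold,
            subject.motion,
            csf_mask,
            masks,
            drop=config.drop,
            fd_threshold_mm=config.fd_threshold_mm,
            band=tuple(config.band_hz),
            tr_s=config.tr_s,
            fwhm_mm=config.fwhm_mm,
            voxel_size_mm=config.voxel_size_mm,
            smooth=smooth,
        )
        for tissue in masks:
            out[tissue][subject.subject_id] = vm.vmhc_subject(
                res["tissue"][tissue],
                mirror_maps[tissue],
                subject_id=subject.subject_id,
                tissue=tissue,
                provenance=res["provenance"],
            )
    return out


def _stack_maps(maps: dict[str, vm.VmhcMap], mask: np.ndarray, order: list[str]) -> np.ndarray:
    idx = np.asarray(mask).astype(bool)
    return np.stack([maps[sid].z[idx] for sid in order])


def group_analysis(
    maps: dict[str, vm.VmhcMap],
    mask: np.ndarray,
    covariates: pd.DataFrame,
    config: RunConfig,
    tissue: str,
) -> dict:
    """Covariate-adjusted ANOVA + BH-FDR over the mask, cluster extraction,
    and post-hoc pairwise t-tests on ROI-mean z values."""
    order = list(covariates["subject"])
    groups = np.asarray(covariates["group"])
    Y = _stack_maps(maps, mask, order)
    cov = gs.encode_covariates(covariates)
    stat = gs.glm_group_f(Y, groups, cov)
    stat.reject = gs.fdr_bh(stat.p, config.fdr_q)

    mask_idx = np.asarray(mask).astype(bool)
    reject_vol = np.zeros(mask_idx.shape, dtype=bool)
    reject_vol[mask_idx] = stat.reject
    f_vol = np.zeros(mask_idx.shape)
    f_vol[mask_idx] = stat.stat
    table, labels_vol = gs.extract_clusters(
        reject_vol, f_vol, config.voxel_size_mm, config.cluster_connectivity, tissue=tissue
    )

    m = config.bonferroni_m_gm if tissue == "gm" else config.bonferroni_m_wm
    posthoc_rows = []
    roi_means = {}
    for _, row in table.iterrows():
        roi_mask = labels_vol == row["cluster_id"]
        roi_means[int(row["cluster_id"])] = np.array(
            [maps[sid].z[roi_mask].mean() for sid in order]
        )
    for cid, means in roi_means.items():
        for ga, gb in (("NC", "VMCI"), ("NC", "MCI"), ("VMCI", "MCI")):
            if ga not in set(groups) or gb not in set(groups):
                continue
            res = gs.posthoc_t(means[:, None], groups, ga, gb, cov, m_comparisons=m)
            posthoc_rows.append(
                {
                    "tissue": tissue,
                    "cluster_id": cid,
                    "group_a": ga,
                    "group_b": gb,
                    "t": float(res.stat[0]),
                    "p": float(res.p[0]),
                    "alpha": 0.05 / m,
                    "significant": bool(res.reject[0]),
                }
            )
    return {
        "stat": stat,
        "f_vol": f_vol,
        "reject_vol": reject_vol,
        "clusters": table,
        "labels_vol": labels_vol,
        "posthoc": pd.DataFrame(posthoc_rows),
        "roi_means": roi_means,
    }


def _dti_analysis(cohort: ph.Cohort, rois: dict[str, np.ndarray], config: RunConfig) -> dict:
    spec = cohort.spec
    metric_maps: dict[str, dict[str, np.ndarray]] = {"AD": {}, "MD": {}, "FA": {}}
    brain = ph.tissue_compartments(spec)["brain"]
    fields = {}
    for subject in cohort.subjects:
        tf = dti_mod.fit_tensor(subject.dwi, spec.dwi_bvals, spec.dwi_bvecs, mask=brain)
        ad, md, fa = dti_mod.tensor_metrics(tf.eigvals)
        metric_maps["AD"][subject.subject_id] = ad
        metric_maps["MD"][subject.subject_id] = md
        metric_maps["FA"][subject.subject_id] = fa
        fields[subject.subject_id] = tf
    groups = cohort.ground_truth.labels
    table = (
        dti_mod.roi_dti_compare(metric_maps, rois, groups, m_comparisons=config.bonferroni_m_wm)
        if rois
        else pd.DataFrame()
    )
    return {"metric_maps": metric_maps, "tensor_fields": fields, "table": table}


def _classification(
    train_maps: dict[str, vm.VmhcMap],
    val_maps: dict[str, vm.VmhcMap],
    train_cov: pd.DataFrame,
    val_cov: pd.DataFrame,
    roi_mask: np.ndarray,
    config: RunConfig,
) -> dict:
    idx = np.asarray(roi_mask).astype(bool)
    if idx.any():
        X_train_vox = np.stack([train_maps[s].z[idx] for s in train_cov["subject"]])
        X_val_vox = np.stack([val_maps[s].z[idx] for s in val_cov["subject"]])
    else:
        logger.warning("no abnormal-connectivity ROI voxels found; using covariates only")
        X_train_vox = np.empty((len(train_cov), 0))
        X_val_vox = np.empty((len(val_cov), 0))
    X_train = np.column_stack([X_train_vox, clf.covariate_features(train_cov)])
    X_val = np.column_stack([X_val_vox, clf.covariate_features(val_cov)])
    y_train = np.asarray(train_cov["group"])
    y_val = np.asarray(val_cov["group"])

    keep = clf.select_features(X_train, y_train)
    if not keep.any():
        logger.warning("t-test filter kept no features; falling back to all features")
        keep = np.ones(X_train.shape[1], dtype=bool)
    Xtr, Xva, scaling = clf.scale_unit_variance(X_train[:, keep], X_val[:, keep])
    exp_min, exp_max, exp_step = config.c_grid_exponents
    grid = clf.default_c_grid(exp_min, exp_max, exp_step)
    C = clf.tune_c(Xtr, y_train, grid, n_folds=config.cv_folds, seed=config.seed)
    y_pred = clf.train_predict(Xtr, y_train, Xva, C)
    rep = clf.report(y_val, y_pred)
    return {
        "C": C,
        "n_features_total": int(X_train.shape[1]),
        "n_features_kept": int(keep.sum()),
        "keep_mask": keep,
        "scaling": scaling,
        "y_pred": y_pred,
        "report": rep,
    }


def run(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns the manifest (also written to ``manifest.json``): file list with
    SHA-256 hashes, the config, its hash, and headline results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # hash the scientific parameters only: where outputs land must not change
    # their provenance identity
    cfg_hash = hio.config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})
    sidecar = {"config_hash": cfg_hash, "seed": config.seed}
    affine = hio.centered_affine(config.grid_shape, config.voxel_size_mm)
    files: list[Path] = []

    def _nifti(data, rel):
        files.append(hio.save_nifti(data, out / rel, affine, sidecar))

    def _tsv(df, rel):
        files.append(hio.save_tsv(df, out / rel, sidecar))

    logger.info("stage phantom: generating train/validation cohorts")
    train = ph.generate_cohort(config.phantom_spec(config.train_groups, config.seed))
    val = ph.generate_cohort(config.phantom_spec(config.val_groups, config.seed + 1))
    _tsv(train.covariates, "train_covariates.tsv")
    _tsv(val.covariates, "val_covariates.tsv")

    logger.info("stage masks: group symmetric GM/WM masks")
    masks = {
        "gm": sym.group_symmetric_mask([s.tissue_probs["gm"] for s in train.subjects], config.gm_threshold),
        "wm": sym.group_symmetric_mask([s.tissue_probs["wm"] for s in train.subjects], config.wm_threshold),
    }
    for tissue, mask in masks.items():
        _nifti(mask.astype(np.float32), f"mask_{tissue}.nii")

    logger.info("stage vmhc: per-subject homotopic connectivity maps")
    train_maps = compute_vmhc_maps(train, masks, config)
    val_maps = compute_vmhc_maps(val, masks, config)
    for tissue in masks:
        for sid, vmap in train_maps[tissue].items():
            _nifti(vmap.z, f"vmhc/{tissue}/{sid}_z.nii")

    logger.info("stage group-stats: ANOVA + FDR + clusters + post-hoc")
    analyses = {}
    for tissue in ("gm", "wm"):
        res = group_analysis(train_maps[tissue], masks[tissue], train.covariates, config, tissue)
        analyses[tissue] = res
        _nifti(res["f_vol"], f"stats/{tissue}_F.nii")
        _nifti(res["reject_vol"].astype(np.float32), f"stats/{tissue}_reject.nii")
        _nifti(res["labels_vol"].astype(np.float32), f"stats/{tissue}_clusters.nii")
        _tsv(res["clusters"], f"stats/{tissue}_clusters.tsv")
        _tsv(res["posthoc"], f"stats/{tissue}_posthoc.tsv")

    logger.info("stage dti: tensor metrics in abnormal-connectivity ROIs")
    wm_labels = analyses["wm"]["labels_vol"]
    rois = {
        f"wm_cluster_{int(cid)}": wm_labels == int(cid)
        for cid in analyses["wm"]["clusters"]["cluster_id"]
    }
    dti_res = _dti_analysis(train, rois, config)
    if len(dti_res["table"]):
        _tsv(dti_res["table"], "dti/roi_comparisons.tsv")

    logger.info("stage classify: multiclass linear SVM with external validation")
    roi_mask = wm_labels > 0
    cls = _classification(train_maps["wm"], val_maps["wm"], train.covariates, val.covariates,
                          roi_mask, config)
    rep = cls["report"]
    _tsv(rep.to_frame(), "classify/report.tsv")
    _tsv(
        pd.DataFrame(rep.confusion, index=list(rep.labels), columns=list(rep.labels)).reset_index(
            names="true"
        ),
        "classify/confusion.tsv",
    )
    model_prov = {
        "C": cls["C"],
        "n_features_total": cls["n_features_total"],
        "n_features_kept": cls["n_features_kept"],
        "accuracy": rep.accuracy,
        "baseline": rep.baseline,
        "config_hash": cfg_hash,
    }
    model_path = out / "classify" / "model_provenance.json"
    model_path.parent.mkdir(parents=True, exist_ok=True)
    model_path.write_text(json.dumps(model_prov, indent=2, sort_keys=True))
    files.append(model_path)

    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "files": {
            str(f.relative_to(out)): hio.sha256_file(f) for f in sorted(files, key=str)
        },
        "results": {
            "n_train": len(train.subjects),
            "n_val": len(val.subjects),
            "gm_clusters": len(analyses["gm"]["clusters"]),
            "wm_clusters": len(analyses["wm"]["clusters"]),
            "svm_C": cls["C"],
            "svm_accuracy": rep.accuracy,
            "svm_baseline": rep.baseline,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
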