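"""End-to-end orchestration: phantom -> features -> reference -> train -> eval.

A pipeline run generates a cohort of synthetic patients, extracts every
quantitative feature group (1D CUDI, 4D CUDI incl. similarity and velocity
entropy, SWE elasticity), builds the kriged probabilistic reference with
confidence weights, trains the CNN-MLP classifier (and the location-only
control) under repeated stratified cross-validation, and reports
confidence-weighted ROC AUCs for the whole prostate and per zone.

A single global seed fans out to per-stage, per-patient and per-repeat seeds
through a fixed derivation, so any stage can be reproduced in isolation; the
run directory carries a manifest with the config echo, derived seeds and
per-output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    ArchitectureSpec,
    PatientRecord,
    TrainConfig,
    VoxelTable,
    control_location_model,
    make_folds,
    standardize_features,
    train_full_model,
)
from .cudi_dispersion import estimate_convective_dispersion
from .cudi_entropy import velocity_entropy_maps, velocity_field_from_delays
from .cudi_similarity import tic_coherence_map, tic_correlation_map, tic_mutual_information_map
from .cudi_temporal import TICVolume, fit_mldrw_volume, derive_temporal_features, mldrw_curve
from .classifier import compute_location_channels
from .evaluation import repeated_cv_aggregate, zone_stratified_eval
from .phantom import PhantomConfig, generate_study
from .reference import build_reference
from .swe import stack_planes, sws_crosscorr

__all__ = ["PipelineConfig", "run_pipeline", "extract_features", "study_to_record"]


def _derive_seed(*parts: int) -> int:
    h = hashlib.sha256(np.array(parts, dtype=np.int64).tobytes()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Study conditions of one phantom experiment.

    The cohort mirrors the clinical setting at desk scale: ~30% of patients
    have no csPCa lesions and the malignant voxel fraction among lesion
    patients targets ~5%.  Defaults keep a 40-patient run on one CPU core in
    minutes; all sizes are configurable.
    """

    n_patients: int = 40
    fraction_no_cspca: float = 0.3
    k_folds: int = 7
    n_repeats: int = 2
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    groups: tuple[str, ...] = ("CUDI_1D", "CUDI_4D", "SWE")
    arch: dict = field(
        default_factory=lambda: {
            "conv_widths": (6, 6), "embedding": 8, "mlp_hidden": (32, 16),
            "patch_size": 5,
        }
    )
    train: dict = field(
        default_factory=lambda: {
            "batch_size": 640, "max_epochs": 8, "patience": 3,
            "val_subsample": 6000,
        }
    )
    stats_scope: str = "entire_dataset"
    max_voxels_per_patient: int = 300
    with_swe: bool = True
    with_control: bool = True
    # feature-extraction windows
    dispersion_window_vox: int = 5
    entropy_window_vox: int = 5
    similarity_ring_mm: float = 2.0
    out_dir: str | None = None
    save_volumes: bool = False


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

def extract_features(study, config: PipelineConfig | None = None) -> dict[str, np.ndarray]:
    """All quantitative feature maps for one study, named per feature group."""
    config = config or PipelineConfig()
    loop = study.ceus_loop
    pcfg = study.config

    fits = fit_mldrw_volume(loop)
    feats = dict(derive_temporal_features(fits, loop.time_s, arrival_threshold=0.5))
    tau = feats.pop("arrival_time")

    # model-smoothed loop for the dispersion regression where fits converged
    conv = fits["converged"]
    smooth = loop.data.copy()
    if conv.any():
        smooth[conv] = mldrw_curve(
            loop.time_s, fits["kappa"][conv], fits["mu"][conv],
            fits["t0"][conv], fits["auc"][conv],
        )
    smooth_vol = TICVolume(smooth, loop.time_s, mask=loop.mask,
                           voxel_size_mm=loop.voxel_size_mm)
    disp = estimate_convective_dispersion(
        smooth_vol, window_vox=config.dispersion_window_vox
    )
    feats["cd_v_mag"] = disp.v_mag
    feats["cd_D"] = disp.D

    ring = max(config.similarity_ring_mm, pcfg.voxel_size_mm)
    feats["sa_corr"] = tic_correlation_map(loop, ring)
    feats["sa_coh"] = tic_coherence_map(loop, ring)
    feats["sa_mi"] = tic_mutual_information_map(loop, ring)

    vf = velocity_field_from_delays(
        tau, window_vox=config.entropy_window_vox, voxel_size_mm=pcfg.voxel_size_mm
    )
    ent = velocity_entropy_maps(vf, window_vox=config.entropy_window_vox)
    feats["ve_H"] = ent.H
    feats["ve_H_cond"] = ent.H_cond

    if config.with_swe and study.swe_planes:
        maps = [sws_crosscorr(p) for p in study.swe_planes]
        stacked = stack_planes(
            maps, study.swe_planes, pcfg.grid_shape, pcfg.voxel_size_mm,
            pcfg.probe_standoff_mm,
        )
        feats["swe_sws"] = stacked["sws"]
        feats["swe_E"] = stacked["E"]
        feats["swe_quality"] = stacked["quality"]

    m = study.prostate_mask
    return {k: np.where(m, v, np.nan) for k, v in feats.items()}


def study_to_record(study, pid: int, config: PipelineConfig | None = None) -> PatientRecord:
    """Features + location + reference + clinical for one phantom patient."""
    config = config or PipelineConfig()
    pcfg = study.config
    feats = extract_features(study, config)
    ref = build_reference(
        study.histology_slices, study.prostate_mask, study.pz_mask, study.tz_mask,
        pcfg.voxel_size_mm,
    )
    loc = compute_location_channels(
        study.prostate_mask, study.pz_mask, pcfg.voxel_size_mm, pcfg.probe_standoff_mm
    )
    vol = study.clinical["volume_cc"]
    clinical = {
        "volume_cc": vol,
        "psa_density": study.clinical["psa_ng_ml"] / vol,
    }
    lesion_mm3 = float(study.lesion_mask.sum()) * pcfg.voxel_size_mm**3
    return PatientRecord(
        pid=pid, features=feats, location=loc, clinical=clinical,
        reference=ref, lesion_size_mm3=lesion_mm3,
    )


# --------------------------------------------------------------------------
# cohort, training, evaluation
# --------------------------------------------------------------------------

def _patient_config(config: PipelineConfig, i: int, rng) -> PhantomConfig:
    no_cspca = rng.random() < config.fraction_no_cspca
    overrides = dict(config.phantom)
    overrides.setdefault("n_lesions", 0 if no_cspca else int(rng.integers(1, 3)))
    if no_cspca:
        overrides["n_lesions"] = 0
    overrides["seed"] = _derive_seed(config.seed, 1, i)
    return PhantomConfig(**overrides)


def _make_cohort_records(config: PipelineConfig) -> list[PatientRecord]:
    """Generate each study, extract its record, free the raw acquisitions.

    A full study (4D CEUS loop + 25 shear-wave movies) is ~100 MB; only the
    derived feature maps and reference are kept per patient.
    """
    rng = np.random.default_rng([config.seed, 11])
    records = []
    for i in range(config.n_patients):
        study = generate_study(_patient_config(config, i, rng),
                               with_swe=config.with_swe)
        records.append(study_to_record(study, pid=i, config=config))
        study.ceus_loop = None
        study.swe_planes = None
    return records


def _spec_for_groups(config: PipelineConfig, groups) -> ArchitectureSpec:
    from .classifier import DEFAULT_FEATURE_GROUPS

    branches = {g: list(DEFAULT_FEATURE_GROUPS[g]) for g in groups}
    if not config.with_swe:
        branches.pop("SWE", None)
    return ArchitectureSpec(branches=branches, **config.arch)


def _run_cv(
    patients: list[PatientRecord],
    spec: ArchitectureSpec,
    config: PipelineConfig,
    label: str,
) -> dict:
    plan = make_folds(
        [p.pid for p in patients],
        {p.pid: p.lesion_size_mm3 for p in patients},
        k=config.k_folds, seed=config.seed,
    )
    results = {"whole": [], "pz": [], "tz": []}
    for rep in range(config.n_repeats):
        for fold in range(config.k_folds):
            train_pids, val_pids = plan.split(fold)
            tr = [p for p in patients if p.pid in set(train_pids)]
            va = [p for p in patients if p.pid in set(val_pids)]
            seed = _derive_seed(config.seed, 2, rep, fold)
            tcfg = TrainConfig(**{**config.train, "seed": seed})
            tr_table = VoxelTable(tr, spec, config.max_voxels_per_patient, seed=seed)
            va_table = VoxelTable(va, spec, config.max_voxels_per_patient, seed=seed)
            if not (tr_table.label.any() and va_table.label.any()):
                continue
            model, _ = train_full_model(spec, tr_table, va_table, tcfg)
            from .classifier import _val_scores_full  # scoring helper

            scores = _val_scores_full(model, va_table, np.arange(len(va_table)))
            per_zone = zone_stratified_eval(
                scores, va_table.label.astype(bool), va_table.weight,
                np.ones(len(va_table), dtype=bool), va_table.pz, va_table.tz,
            )
            for zone, roc in per_zone.items():
                if roc is not None:
                    results[zone].append(roc.auc)
    out = {"label": label, "auc_per_fold": results}
    for zone, aucs in results.items():
        out[zone] = repeated_cv_aggregate(aucs) if len(aucs) >= 2 else None
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the results dict and (optionally) writes a
    run directory with a provenance manifest and a Table-style CSV."""
    t0 = time.time()
    patients = _make_cohort_records(config)
    stats = standardize_features(patients, stats_scope=config.stats_scope)

    spec = _spec_for_groups(config, config.groups)
    results = {"full": _run_cv(patients, spec, config, label="+".join(config.groups))}
    if config.with_control:
        results["control"] = _run_cv(
            patients, control_location_model(spec), config, label="LOCATION"
        )
    results["elapsed_s"] = time.time() - t0
    results["n_patients"] = config.n_patients
    results["stats_scope"] = config.stats_scope

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for key, res in results.items():
            if not isinstance(res, dict) or "whole" not in res:
                continue
            for zone in ("whole", "pz", "tz"):
                agg = res[zone]
                if agg:
                    rows.append({
                        "feature_group": res["label"], "zone": zone,
                        "auc": agg["mean"], "ci_low": agg["ci_low"],
                        "ci_high": agg["ci_high"], "sd": agg["sd"], "n": agg["n"],
                    })
        pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
        manifest = {
            "config": _jsonable(asdict(config)),
            "seed": config.seed,
            "derived_seeds": {
                "patients": [_derive_seed(config.seed, 1, i) for i in range(config.n_patients)],
                "cv": [
                    _derive_seed(config.seed, 2, r, f)
                    for r in range(config.n_repeats) for f in range(config.k_folds)
                ],
            },
            "checksums": {
                "results.csv": hashlib.sha256((out / "results.csv").read_bytes()).hexdigest(),
            },
            "elapsed_s": results["elapsed_s"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "results.json").write_text(json.dumps(_jsonable(results), indent=2))
        if config.save_volumes:
            from .io import save_feature_maps

            vox = config.phantom.get("voxel_size_mm", PhantomConfig().voxel_size_mm)
            for p in patients:
                save_feature_maps(out / f"patient_{p.pid:03d}", p.features, vox)
    results["stats"] = stats
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
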