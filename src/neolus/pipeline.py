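"""End-to-end orchestration: cohort -> ROIs -> features -> evaluation.

One run executes, for a synthetic or manifest-loaded cohort: pleural traces,
constant-area ROIs at each configured size, first-order statistics and the
per-patient mean-intensity score, the 44-dimensional texture vectors, visual
score sums, Spearman correlations of both scores with both oxygenation
indices, interobserver kappa, ROC/AUC for the direct scores, LOPO-SVR
per-feature-group AUC tables and (optionally) a PCA sweep. All randomness
descends from one seed; rerunning an identical config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, glcm
from .cohort import CohortConfig, generate_cohort
from .exceptions import NeolusError
from .first_order import first_order_stats, patient_mean_intensity_score
from .io import read_cohort_manifest
from .model import SVRConfig, group_analysis, pca_sweep
from .roi import auto_trace, build_roi, extract_pixels


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run; every protocol constant is a field."""

    mode: str = "synthetic"                  # "synthetic" or "manifest"
    manifest_path: str | None = None
    n_patients: int = 75
    views_per_patient: int = 8
    roi_areas: tuple[int, ...] = (50_000, 100_000)
    glcm_distance: int = 2
    glcm_levels: int = 256
    pf_cutoff: float = 200.0
    aa_cutoff: float = 150.0
    groups: tuple[str, ...] = ("1", "2", "3", "all")
    pca_max_k: int = 0                        # 0 disables the sweep
    rater_error_rate: float = 0.05
    seed: int = 0
    svr: SVRConfig = field(default_factory=SVRConfig)

    def __post_init__(self):
        if not self.roi_areas:
            raise NeolusError("at least one ROI area is required")
        if self.pf_cutoff <= 0 or self.aa_cutoff <= 0:
            raise NeolusError("cutoffs must be positive")


@dataclass
class RunResult:
    features: pd.DataFrame            # per frame x roi: 44 named features
    first_order: pd.DataFrame         # per patient x roi: mean-intensity score
    patients: pd.DataFrame            # per patient: grades, gases, indices
    clinical: dict                    # correlations, kappa, direct-score AUCs
    group_auc: pd.DataFrame           # LOPO SVR AUC per feature group/index/roi
    pca: dict                         # per roi/index sweep summaries (may be empty)
    log: list[str]


def _load_patients(config: RunConfig):
    """Yield (patient_id, frames, rater_grades, fio2, pao2, paco2) tuples."""
    if config.mode == "synthetic":
        cohort = generate_cohort(CohortConfig(
            n_patients=config.n_patients, views_per_patient=config.views_per_patient,
            rater_error_rate=config.rater_error_rate, seed=config.seed))
        return [(r.patient_id, r.frames, r.rater_grades, r.fio2, r.pao2, r.paco2)
                for r in cohort]
    if config.manifest_path is None:
        raise NeolusError("manifest mode requires manifest_path")
    records = read_cohort_manifest(config.manifest_path, config.views_per_patient)
    out = []
    for r in records:
        try:
            frames = r.load_frames()
        except FileNotFoundError as e:
            raise NeolusError(
                f"stage=load patient={r.patient_id}: missing frame file {e.filename}"
            ) from None
        out.append((r.patient_id, frames, r.rater_grades, r.fio2, r.pao2, r.paco2))
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full analysis; optionally write the result bundle to disk."""
    log: list[str] = [f"config: {json.dumps(asdict(config), default=str, sort_keys=True)}"]
    patients = _load_patients(config)

    feature_rows, fo_rows, patient_rows = [], [], []
    fnames = glcm.feature_names()
    for pid, frames, raters, fio2, pao2, paco2 in patients:
        oxy = clinical.OxygenationRecord.from_gases(fio2, pao2, paco2)
        frame_means = {area: [] for area in config.roi_areas}
        for frame in frames:
            try:
                trace = auto_trace(frame)
                for area in config.roi_areas:
                    mask = build_roi(trace, area, frame.shape)
                    pixels = extract_pixels(frame, mask)
                    fos = first_order_stats(pixels)
                    frame_means[area].append(fos.mean)
                    vec = glcm.feature_vector(frame, mask,
                                              distance=config.glcm_distance,
                                              levels=config.glcm_levels)
                    row = {"patient_id": pid, "view": frame.view, "roi_area": area,
                           "frame_mean": fos.mean, "frame_variance": fos.variance}
                    row.update(dict(zip(fnames, vec)))
                    feature_rows.append(row)
            except NeolusError as e:
                raise NeolusError(
                    f"stage=features patient={pid} view={frame.view}: {e}") from e
        for area in config.roi_areas:
            fo_rows.append({
                "patient_id": pid, "roi_area": area,
                "mean_intensity_score": patient_mean_intensity_score(
                    frame_means[area], config.views_per_patient),
                **{f"frame_mean_{k}": m for k, m in enumerate(frame_means[area])}})
        patient_rows.append({
            "patient_id": pid,
            "visual_sum_r1": clinical.visual_score_sum(raters[0], config.views_per_patient),
            "visual_sum_r2": clinical.visual_score_sum(raters[1], config.views_per_patient),
            "fio2": fio2, "pao2": pao2, "paco2": paco2,
            "pf_ratio": oxy.pf_ratio, "aa_gradient": oxy.aa_gradient})

    features = pd.DataFrame(feature_rows)
    first_order_df = pd.DataFrame(fo_rows)
    patient_df = pd.DataFrame(patient_rows)
    log.append(f"frames analyzed: {len(features) // len(config.roi_areas)}")

    # --- clinical evaluation layer -------------------------------------------
    r1 = np.concatenate([list(p[2][0]) for p in patients])
    r2 = np.concatenate([list(p[2][1]) for p in patients])
    kappa_frames = clinical.cohen_kappa(r1, r2)
    kappa_sums = clinical.cohen_kappa(
        patient_df["visual_sum_r1"], patient_df["visual_sum_r2"],
        categories=sorted(set(patient_df["visual_sum_r1"])
                          | set(patient_df["visual_sum_r2"])))

    pf = patient_df["pf_ratio"].to_numpy()
    aa = patient_df["aa_gradient"].to_numpy()
    pf_labels = clinical.dichotomize_pf(pf, config.pf_cutoff)
    aa_labels = clinical.dichotomize_aa(aa, config.aa_cutoff)

    def _score_block(scores: np.ndarray) -> dict:
        block = {}
        for index, vals in (("pf_ratio", pf), ("aa_gradient", aa)):
            sp = clinical.spearman_ci(scores, vals)
            block[index] = {"rho": sp.rho, "ci": [sp.ci_low, sp.ci_high],
                            "p": sp.p_value, "n": sp.n}
        if len(set(pf_labels)) == 2:
            block["auc_pf"] = clinical.roc_auc(scores, pf_labels).auc
        if len(set(aa_labels)) == 2:
            block["auc_aa"] = clinical.roc_auc(scores, aa_labels).auc
        return block

    visual = patient_df["visual_sum_r1"].to_numpy(dtype=float)
    clin = {"kappa_frames": kappa_frames, "kappa_patient_sums": kappa_sums,
            "visual_score": _score_block(visual), "mean_intensity": {}}
    for area in config.roi_areas:
        scores = first_order_df.loc[first_order_df["roi_area"] == area,
                                    "mean_intensity_score"].to_numpy()
        clin["mean_intensity"][str(area)] = _score_block(scores)

    # --- texture + machine-learning layer ------------------------------------
    targets = {"pf_ratio": dict(zip(patient_df["patient_id"], pf)),
               "aa_gradient": dict(zip(patient_df["patient_id"], aa))}
    group_tables, pca_out = [], {}
    for area in config.roi_areas:
        sub = features[features["roi_area"] == area]
        X = sub[fnames].to_numpy()
        pids = sub["patient_id"].to_numpy()
        group_tables.append(group_analysis(X, pids, targets, roi_label=str(area),
                                           groups=config.groups, svr=config.svr))
        if config.pca_max_k > 0:
            for index in ("pf_ratio", "aa_gradient"):
                sweep = pca_sweep(X, pids, targets[index], index=index,
                                  k_range=range(1, config.pca_max_k + 1),
                                  svr=config.svr)
                pca_out[f"{area}_{index}"] = {
                    "explained_variance_ratio": sweep.explained_variance_ratio.tolist(),
                    "cumulative_variance": sweep.cumulative_variance.tolist(),
                    "auc_by_k": {str(k): v for k, v in sweep.auc_by_k.items()}}
    group_auc = pd.concat(group_tables, ignore_index=True)

    result = RunResult(features=features, first_order=first_order_df,
                       patients=patient_df, clinical=clin, group_auc=group_auc,
                       pca=pca_out, log=log)
    if outdir is not None:
        _write_bundle(result, config, Path(outdir))
    return result


def _write_bundle(result: RunResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.csv", index=False)
    result.first_order.to_csv(outdir / "first_order.csv", index=False)
    result.patients.to_csv(outdir / "patients.csv", index=False)
    result.group_auc.to_csv(outdir / "group_auc.csv", index=False)
    with open(outdir / "clinical.json", "w") as fh:
        json.dump(result.clinical, fh, indent=2, sort_keys=True)
    with open(outdir / "pca.json", "w") as fh:
        json.dump(result.pca, fh, indent=2, sort_keys=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
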