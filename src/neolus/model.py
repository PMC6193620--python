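"""Severity regression: SVR with leave-one-patient-out cross-validation.

Frames carry their patient's oxygenation index as regression target; each
fold trains an RBF support-vector regressor on every other patient's frames
and predicts the held-out patient's frames, which are averaged into one
per-patient prediction. Standardization (features and target) is fitted
inside each training fold, so no information from the held-out patient
leaks into training. Feature-group restrictions and PCA feature-reduction
sweeps reuse the same fold structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import glcm as glcm_mod
from .clinical import dichotomize_aa, dichotomize_pf, roc_auc
from .exceptions import ValidationError


@dataclass(frozen=True)
class SVRConfig:
    """RBF-SVR hyperparameters; epsilon is on the standardized target scale,
    so 0.1 equals one tenth of the training targets' SD."""

    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"


@dataclass
class CVResult:
    """One per-patient prediction per leave-one-patient-out fold."""

    patient_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    label: str = ""


@dataclass
class PCASweep:
    """Explained-variance curve plus LOPO AUC as a function of kept components."""

    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray
    k_values: list[int]
    auc_by_k: dict[int, float] = field(default_factory=dict)
    results_by_k: dict[int, CVResult] = field(default_factory=dict)


def standardize(train_features: np.ndarray,
                apply_to: np.ndarray | None = None) -> np.ndarray:
    """Per-feature z-score using training mean/SD; zero-SD features map to 0."""
    scaler = StandardScaler().fit(np.asarray(train_features, dtype=float))
    target = train_features if apply_to is None else apply_to
    return scaler.transform(np.asarray(target, dtype=float))


def _check_inputs(X: np.ndarray, patient_ids: np.ndarray, y_by_patient: dict):
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X).all(axis=1)).ravel()
        raise ValidationError(f"non-finite features in frame row(s) {bad.tolist()}")
    unique = list(dict.fromkeys(patient_ids.tolist()))
    if len(unique) < 3:
        raise ValidationError("leave-one-patient-out needs at least 3 patients")
    missing = [p for p in unique if p not in y_by_patient]
    if missing:
        raise ValidationError(f"no target for patient(s) {missing}")
    return unique


def lopo_cv(X: np.ndarray, patient_ids, y_by_patient: dict[str, float],
            svr: SVRConfig = SVRConfig(), columns=None, n_components: int | None = None,
            label: str = "") -> CVResult:
    """Leave-one-patient-out SVR with optional column subset and in-fold PCA.

    Frame-level training (every frame inherits its patient's index),
    per-patient aggregation of the held-out frames' predictions by mean.
    """
    X = np.asarray(X, dtype=float)
    patient_ids = np.asarray(patient_ids)
    unique = _check_inputs(X, patient_ids, y_by_patient)
    if columns is not None:
        X = X[:, columns]
    if n_components is not None and n_components > X.shape[1]:
        raise ValidationError(
            f"n_components={n_components} exceeds feature count {X.shape[1]}")

    y_frame = np.array([y_by_patient[p] for p in patient_ids], dtype=float)
    preds = np.empty(len(unique))
    for f, pid in enumerate(unique):
        held = patient_ids == pid
        Xtr, ytr = X[~held], y_frame[~held]
        xscaler = StandardScaler().fit(Xtr)
        Xtr_s, Xte_s = xscaler.transform(Xtr), xscaler.transform(X[held])
        if n_components is not None:
            pca = PCA(n_components=n_components, svd_solver="full").fit(Xtr_s)
            Xtr_s, Xte_s = pca.transform(Xtr_s), pca.transform(Xte_s)
        y_mean, y_sd = ytr.mean(), ytr.std()
        y_sd = y_sd if y_sd > 0 else 1.0
        reg = SVR(kernel="rbf", C=svr.C, epsilon=svr.epsilon, gamma=svr.gamma)
        reg.fit(Xtr_s, (ytr - y_mean) / y_sd)
        preds[f] = reg.predict(Xte_s).mean() * y_sd + y_mean

    y_true = np.array([y_by_patient[p] for p in unique], dtype=float)
    return CVResult(patient_ids=unique, y_true=y_true, y_pred=preds, label=label)


def _auc_for_index(result: CVResult, index: str) -> float:
    """AUC of LOPO predictions against the dichotomized true index.

    For PaO2/FiO2 (positive = below cutoff) scores are negated so that a
    higher score indicates the positive class.
    """
    if index == "pf_ratio":
        labels = dichotomize_pf(result.y_true)
        scores = -result.y_pred
    elif index == "aa_gradient":
        labels = dichotomize_aa(result.y_true)
        scores = result.y_pred
    else:
        raise ValidationError(f"unknown index {index!r}")
    if len(set(labels.tolist())) < 2:
        return float("nan")  # cutoff leaves a single class; AUC undefined
    return roc_auc(scores, labels).auc


def group_analysis(X: np.ndarray, patient_ids, targets: dict[str, dict[str, float]],
                   roi_label: str, groups=("1", "2", "3", "all"),
                   svr: SVRConfig = SVRConfig()) -> pd.DataFrame:
    """Per-feature-group LOPO AUC table for one ROI size.

    ``targets`` maps index name ("pf_ratio", "aa_gradient") to per-patient
    values. Returns a tidy frame: feature_group x index x roi x auc.
    """
    rows = []
    for group in groups:
        cols = glcm_mod.group_columns(group)
        for index, y in targets.items():
            res = lopo_cv(X, patient_ids, y, svr=svr, columns=cols,
                          label=f"group={group},index={index},roi={roi_label}")
            rows.append({"feature_group": str(group), "index": index,
                         "roi": roi_label, "auc": _auc_for_index(res, index)})
    return pd.DataFrame(rows)


def pca_sweep(X: np.ndarray, patient_ids, y_by_patient: dict[str, float],
              index: str, k_range=None, svr: SVRConfig = SVRConfig()) -> PCASweep:
    """AUC as a function of the number of principal components kept.

    The explained-variance curve comes from a PCA fit on all standardized
    frames (descriptive, matching a single-curve report); the predictive
    sweep keeps standardization and PCA inside each training fold. Within a
    fold the PCA basis is fitted once at max(k) and truncated, since the
    leading components do not depend on how many are kept.
    """
    X = np.asarray(X, dtype=float)
    patient_ids = np.asarray(patient_ids)
    d = X.shape[1]
    k_values = list(k_range) if k_range is not None else list(range(1, d + 1))
    if any(k < 1 or k > d for k in k_values):
        raise ValidationError(f"components must lie in 1..{d}")
    unique = _check_inputs(X, patient_ids, y_by_patient)

    full = PCA(svd_solver="full").fit(standardize(X))
    evr = full.explained_variance_ratio_

    kmax = max(k_values)
    y_frame = np.array([y_by_patient[p] for p in patient_ids], dtype=float)
    pred_by_k = {k: np.empty(len(unique)) for k in k_values}
    for f, pid in enumerate(unique):
        held = patient_ids == pid
        Xtr, ytr = X[~held], y_frame[~held]
        xscaler = StandardScaler().fit(Xtr)
        Xtr_s, Xte_s = xscaler.transform(Xtr), xscaler.transform(X[held])
        pca = PCA(n_components=kmax, svd_solver="full").fit(Xtr_s)
        Ztr, Zte = pca.transform(Xtr_s), pca.transform(Xte_s)
        y_mean, y_sd = ytr.mean(), ytr.std()
        y_sd = y_sd if y_sd > 0 else 1.0
        for k in k_values:
            reg = SVR(kernel="rbf", C=svr.C, epsilon=svr.epsilon, gamma=svr.gamma)
            reg.fit(Ztr[:, :k], (ytr - y_mean) / y_sd)
            pred_by_k[k][f] = reg.predict(Zte[:, :k]).mean() * y_sd + y_mean

    y_true = np.array([y_by_patient[p] for p in unique], dtype=float)
    sweep = PCASweep(explained_variance_ratio=evr,
                     cumulative_variance=np.cumsum(evr), k_values=k_values)
    for k in k_values:
        res = CVResult(patient_ids=unique, y_true=y_true, y_pred=pred_by_k[k],
                       label=f"pca_k={k},index={index}")
        sweep.results_by_k[k] = res
        sweep.auc_by_k[k] = _auc_for_index(res, index)
    return sweep
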