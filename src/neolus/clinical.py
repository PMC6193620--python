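"""Oxygenation indices, visual LUS scoring and evaluation statistics.

Oxygenation indices (mmHg): the oxygenation ratio PaO2/FiO2 (lower = worse,
dichotomized at < 200) and the alveolar-arterial gradient
A-a = PA - PaO2 with PA = FiO2*(760 - 47) - PaCO2/0.8 (higher = worse,
dichotomized at > 150). The visual LUS score sums the per-frame 0-3 grades
over the 8 standard views (range 0-24).

Evaluation statistics: Spearman rank correlation with Fisher-z 95% CI,
Cohen's kappa for interobserver agreement, and ROC/AUC by the Mann-Whitney
pair-counting estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import ValidationError

PF_CUTOFF = 200.0   # PaO2/FiO2 below this = worse respiratory status
AA_CUTOFF = 150.0   # A-a gradient above this = worse respiratory status

_BAROMETRIC_MINUS_WATER = 760.0 - 47.0  # mmHg at sea level, body temperature
_RESPIRATORY_QUOTIENT = 0.8


def pf_ratio(pao2: float, fio2: float) -> float:
    """Oxygenation ratio PaO2/FiO2 in mmHg."""
    if not 0.0 < fio2 <= 1.0:
        raise ValidationError(f"fio2 must lie in (0, 1], got {fio2}")
    return pao2 / fio2


def alveolar_po2(fio2: float, paco2: float) -> float:
    """Alveolar oxygen tension PA = FiO2*(760 - 47) - PaCO2/0.8 (mmHg)."""
    return fio2 * _BAROMETRIC_MINUS_WATER - paco2 / _RESPIRATORY_QUOTIENT


def aa_gradient(fio2: float, pao2: float, paco2: float) -> float:
    """Alveolar-arterial gradient PA - PaO2 (mmHg); may be negative."""
    if not 0.0 < fio2 <= 1.0:
        raise ValidationError(f"fio2 must lie in (0, 1], got {fio2}")
    if pao2 <= 0 or paco2 <= 0:
        raise ValidationError("pao2 and paco2 must be positive")
    return alveolar_po2(fio2, paco2) - pao2


@dataclass
class OxygenationRecord:
    """Blood gases with the two derived severity indices."""

    fio2: float
    pao2: float
    paco2: float
    pf_ratio: float
    pa_alveolar: float
    aa_gradient: float

    @classmethod
    def from_gases(cls, fio2: float, pao2: float, paco2: float) -> "OxygenationRecord":
        return cls(fio2=fio2, pao2=pao2, paco2=paco2,
                   pf_ratio=pf_ratio(pao2, fio2),
                   pa_alveolar=alveolar_po2(fio2, paco2),
                   aa_gradient=aa_gradient(fio2, pao2, paco2))


def visual_score_sum(grades, views_per_patient: int = 8) -> int:
    """Per-patient visual LUS score: sum of the 8 per-frame grades (0-24)."""
    grades = list(grades)
    if len(grades) != views_per_patient:
        raise ValidationError(f"expected {views_per_patient} grades, got {len(grades)}")
    if any(g not in (0, 1, 2, 3) for g in grades):
        raise ValidationError(f"grades must be in {{0,1,2,3}}, got {grades}")
    return int(sum(grades))


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def spearman_ci(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Spearman rho with two-sided p and a Fisher-z confidence interval.

    The CI transforms rho with arctanh, uses SE = 1/sqrt(n - 3) and maps the
    normal-quantile band back with tanh.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 4:
        raise ValidationError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(x.size - 3)
    return SpearmanResult(rho=float(rho), ci_low=float(np.tanh(z - half)),
                          ci_high=float(np.tanh(z + half)), p_value=float(p),
                          n=int(x.size))


def cohen_kappa(rater1, rater2, categories=(0, 1, 2, 3),
                weights: str | None = None) -> float:
    """Chance-corrected agreement between two raters' categorical grades.

    Unweighted by default; ``weights`` in {"linear", "quadratic"} enables
    weighted kappa. When both raters are constant and identical (expected
    agreement 1), kappa is defined as 1.
    """
    r1 = np.asarray(rater1)
    r2 = np.asarray(rater2)
    if r1.shape != r2.shape or r1.size == 0:
        raise ValidationError("rater grade lists must be equal-length and non-empty")
    cats = list(categories)
    lookup = {c: k for k, c in enumerate(cats)}
    try:
        i1 = np.array([lookup[v] for v in r1.tolist()])
        i2 = np.array([lookup[v] for v in r2.tolist()])
    except KeyError as e:
        raise ValidationError(f"grade {e.args[0]!r} outside categories {cats}") from None
    k = len(cats)
    confusion = np.zeros((k, k))
    np.add.at(confusion, (i1, i2), 1.0)
    confusion /= confusion.sum()

    if weights is None:
        w = 1.0 - np.eye(k)
    else:
        d = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :]).astype(float)
        w = d if weights == "linear" else d ** 2
    expected = np.outer(confusion.sum(axis=1), confusion.sum(axis=0))
    we = float((w * expected).sum())
    if we == 0.0:
        return 1.0  # both raters constant and equal: perfect agreement
    return float(1.0 - (w * confusion).sum() / we)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC with higher score indicating the positive class.

    AUC is the Mann-Whitney pair-counting estimator: the fraction of
    (positive, negative) pairs where the positive scores higher, ties
    counting one half. Curve points come from all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present to compute an ROC curve")
    diff = pos[:, None] - neg[None, :]
    auc = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


def dichotomize_pf(pf_values, cutoff: float = PF_CUTOFF) -> np.ndarray:
    """Positive (1) = worse status = PaO2/FiO2 below the cutoff."""
    return (np.asarray(pf_values, dtype=float) < cutoff).astype(int)


def dichotomize_aa(aa_values, cutoff: float = AA_CUTOFF) -> np.ndarray:
    """Positive (1) = worse status = A-a gradient above the cutoff."""
    return (np.asarray(aa_values, dtype=float) > cutoff).astype(int)
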