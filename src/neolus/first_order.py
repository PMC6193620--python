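"""First-order gray-scale statistics and the per-patient mean-intensity score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError


@dataclass
class FirstOrderStats:
    """Histogram, mean and population variance of ROI gray values."""

    histogram: np.ndarray  # counts over the 256 native 8-bit levels
    mean: float
    variance: float
    n: int


def first_order_stats(pixels) -> FirstOrderStats:
    """256-bin histogram, arithmetic mean and population variance (divide by n)."""
    values = np.asarray(pixels).ravel()
    if values.size == 0:
        raise ValidationError("cannot compute first-order statistics of an empty ROI")
    if values.min() < 0 or values.max() > 255:
        raise ValidationError("gray values must lie in [0, 255]")
    hist = np.bincount(values.astype(np.int64), minlength=256)
    mean = float(values.mean())
    variance = float(values.astype(np.float64).var())  # population variance
    return FirstOrderStats(histogram=hist, mean=mean, variance=variance, n=values.size)


def patient_mean_intensity_score(frame_means, views_per_patient: int = 8) -> float:
    """Pool the per-frame ROI means of one patient into a single score.

    The eight per-view mean intensities are averaged into the patient's
    gray-scale mean intensity score.
    """
    means = np.asarray(frame_means, dtype=float)
    if means.size != views_per_patient:
        raise ValidationError(
            f"expected {views_per_patient} frame means, got {means.size}")
    return float(means.mean())
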