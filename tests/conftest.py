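"""Shared fixtures: the default synthetic cohort, analyzed once per session."""

import numpy as np
import pytest

from neolus import (CohortConfig, auto_trace, build_roi, extract_pixels,
                    feature_names, feature_vector, first_order_stats,
                    generate_cohort, patient_mean_intensity_score)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 75 patients x 8 views, seed 0."""
    return generate_cohort(CohortConfig(n_patients=75, views_per_patient=8, seed=0))


@pytest.fixture(scope="session")
def cohort_analysis(default_cohort):
    """Per-frame 44-dim features and per-patient scores at the 50K-pixel ROI.

    Computed once per session; several end-to-end checks share it.
    """
    area = 50_000
    X, frame_pids, rows = [], [], []
    for rec in default_cohort:
        means = []
        for frame in rec.frames:
            mask = build_roi(auto_trace(frame), area, frame.shape)
            pixels = extract_pixels(frame, mask)
            means.append(first_order_stats(pixels).mean)
            X.append(feature_vector(frame, mask))
            frame_pids.append(rec.patient_id)
        rows.append({
            "patient_id": rec.patient_id,
            "severity": rec.severity,
            "mean_intensity": patient_mean_intensity_score(means),
            "visual_sum_r1": sum(rec.rater_grades[0]),
            "visual_sum_r2": sum(rec.rater_grades[1]),
            "mean_true_grade": float(np.mean(rec.true_grades)),
            "fio2": rec.fio2, "pao2": rec.pao2, "paco2": rec.paco2,
        })
    return {
        "X": np.array(X),
        "frame_patient_ids": np.array(frame_pids),
        "patients": rows,
        "feature_names": feature_names(),
        "roi_area": area,
    }
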