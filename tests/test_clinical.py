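"""Oxygenation indices, visual scoring and the evaluation statistics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from neolus import (aa_gradient, cohen_kappa, pf_ratio, roc_auc, spearman_ci,
                    visual_score_sum)
from neolus.clinical import (OxygenationRecord, alveolar_po2, dichotomize_aa,
                             dichotomize_pf)
from neolus.exceptions import ValidationError


class TestIndices:
    @pytest.mark.parametrize("pao2, fio2, expected", [
        (100, 0.5, 200.0),
        (100, 1.0, 100.0),
        (90, 0.21, 428.5714),
    ])
    def test_pf_ratio(self, pao2, fio2, expected):
        assert pf_ratio(pao2, fio2) == pytest.approx(expected, abs=1e-3)

    def test_pf_ratio_domain(self):
        with pytest.raises(ValidationError):
            pf_ratio(100, 0.0)

    @pytest.mark.parametrize("fio2, paco2, pao2, pa, grad", [
        (1.0, 40, 663, 663.0, 0.0),
        (0.21, 40, 90, 99.73, 9.73),
        (0.40, 48, 60, 225.2, 165.2),
    ])
    def test_aa_gradient(self, fio2, paco2, pao2, pa, grad):
        assert alveolar_po2(fio2, paco2) == pytest.approx(pa)
        assert aa_gradient(fio2, pao2, paco2) == pytest.approx(grad)

    def test_aa_gradient_linear_in_fio2(self):
        # slope 713 mmHg per unit FiO2 at fixed PaO2/PaCO2
        points = [aa_gradient(f, 80, 40) for f in (0.3, 0.5, 0.7)]
        diffs = np.diff(points)
        np.testing.assert_allclose(diffs, 713 * 0.2, rtol=1e-12)

    def test_record_invariants(self):
        rec = OxygenationRecord.from_gases(0.5, 120, 40)
        assert rec.pf_ratio == pytest.approx(240)
        assert rec.aa_gradient == pytest.approx(rec.pa_alveolar - 120)

    def test_dichotomization_rules(self):
        np.testing.assert_array_equal(dichotomize_pf([150, 200, 250]), [1, 0, 0])
        np.testing.assert_array_equal(dichotomize_aa([100, 150, 200]), [0, 0, 1])


class TestVisualScore:
    @pytest.mark.parametrize("grades, expected", [
        ([3] * 8, 24), ([0] * 8, 0), ([1, 2, 0, 3, 1, 2, 2, 1], 12)])
    def test_sum(self, grades, expected):
        assert visual_score_sum(grades) == expected

    def test_out_of_range_grade(self):
        with pytest.raises(ValidationError):
            visual_score_sum([0, 1, 2, 3, 4, 0, 1, 2])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_ci([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman_ci([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)): d^2 sums to 4 and 6 respectively
        assert spearman_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]).rho == pytest.approx(0.8)
        assert spearman_ci([1, 2, 3, 4, 5], [2, 3, 1, 4, 5]).rho == pytest.approx(0.7)

    def test_ci_brackets_rho_and_is_ordered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = spearman_ci(x, x + rng.normal(scale=0.7, size=30))
        assert res.ci_low < res.rho < res.ci_high

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman_ci(x, y).rho
        assert spearman_ci(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_ci(x, y ** 3).rho == pytest.approx(base)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 2, 3, 1], [0, 1, 2, 3, 1]) == pytest.approx(1.0)

    def test_binary_confusion_table(self):
        # confusion [[20, 5], [10, 15]] -> p_o 0.7, p_e 0.5, kappa 0.4
        r1 = [0] * 25 + [1] * 25
        r2 = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert cohen_kappa(r1, r2, categories=(0, 1)) == pytest.approx(0.4)

    def test_matches_sklearn_on_random_grades(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            r1 = rng.integers(0, 4, 100)
            r2 = rng.integers(0, 4, 100)
            assert cohen_kappa(r1, r2) == pytest.approx(
                cohen_kappa_score(r1, r2, labels=[0, 1, 2, 3]), abs=1e-12)

    def test_independent_raters_null_centers_at_zero(self):
        rng = np.random.default_rng(3)
        kappas = [cohen_kappa(rng.integers(0, 4, 600), rng.integers(0, 4, 600))
                  for _ in range(200)]
        assert abs(np.mean(kappas)) <= 0.05

    def test_both_constant_and_equal(self):
        assert cohen_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = cohen_kappa(rng.integers(0, 4, 40), rng.integers(0, 4, 40))
            assert -1.0 <= k <= 1.0

    def test_weighted_variants(self):
        r1 = [0, 1, 2, 3, 0, 1, 2, 3, 3, 0]
        r2 = [0, 2, 2, 3, 1, 1, 3, 3, 2, 0]
        for w in ("linear", "quadratic"):
            assert cohen_kappa(r1, r2, weights=w) == pytest.approx(
                cohen_kappa_score(r1, r2, labels=[0, 1, 2, 3], weights=w), abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_pair_enumeration(self):
        # positives {2, 4} vs negatives {1, 3}: 3 of 4 pairs concordant
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_complement_identity(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = rng.normal(size=40).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_curve_endpoints(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
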