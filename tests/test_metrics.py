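from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import beta

from cxrnlp.metrics import (
    AgreementResult,
    ConfusionMatrix,
    cohens_kappa,
    confusion,
    likelihood_ratio_ci,
    metrics,
    percent,
    proportion_ci,
    reconstruct_confusion,
)

# Validation-set confusion matrices reconstructed from published rounded
# marginals (n=1350, 185 reference-positive). These are fixtures derived
# from printed sensitivity/specificity/PPV/NPV, not printed counts.
RECONSTRUCTED = {
    "word_embedding": ConfusionMatrix(36, 57, 149, 1108),
    "xgboost": ConfusionMatrix(113, 14, 72, 1151),
    "svm": ConfusionMatrix(104, 22, 81, 1143),
    "naive_bayes": ConfusionMatrix(173, 300, 12, 865),
    "logistic_regression": ConfusionMatrix(10, 52, 175, 1113),
    "lightgbm": ConfusionMatrix(49, 2, 136, 1163),
}


class TestPercent:
    def test_half_away_from_zero(self):
        assert percent(0.72425) == 72.4
        assert percent(0.0005) == 0.1
        assert percent(0.93625) == 93.6
        assert percent(None) is None


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 1)

    def test_total_disagreement(self):
        cm = confusion([1, 0, 1], [0, 1, 0])
        assert cm.tp == 0 and cm.tn == 0

    def test_loop_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.integers(0, 2, size=50)
            truth = rng.integers(0, 2, size=50)
            cm = confusion(pred, truth)
            tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
            fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
            fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
            tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert cm.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_xgboost_row(self):
        ms = metrics(RECONSTRUCTED["xgboost"])
        assert percent(ms.accuracy) == 93.6
        assert percent(ms.f1) == 72.4

    def test_naive_bayes_row(self):
        ms = metrics(RECONSTRUCTED["naive_bayes"])
        assert percent(ms.sensitivity) == 93.5
        assert percent(ms.f1) == 52.6

    def test_zero_denominator_flagged_not_zero(self):
        ms = metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert ms.ppv is None
        assert "ppv" in ms.not_applicable
        assert ms.sensitivity == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(0, 0, 0, 0)

    def test_f1_identity_exact_rational(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp == 0:
                continue
            direct = Fraction(2 * tp, 2 * tp + fp + fn)
            p = Fraction(tp, tp + fp) if tp + fp else None
            r = Fraction(tp, tp + fn)
            harmonic = 2 * p * r / (p + r)
            assert direct == harmonic
            ms = metrics(ConfusionMatrix(tp, fp, fn, max(tn, 1)))
            assert ms.f1 == pytest.approx(float(direct), abs=1e-12)

    def test_accuracy_between_sens_and_spec(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 40, size=4))
            ms = metrics(ConfusionMatrix(tp, fp, fn, tn))
            lo, hi = sorted((ms.sensitivity, ms.specificity))
            assert lo - 1e-12 <= ms.accuracy <= hi + 1e-12


class TestProportionCI:
    def test_zero_successes(self):
        lo, hi = proportion_ci(0, 10)
        assert lo == 0.0
        assert hi < 1.0

    def test_all_successes(self):
        lo, hi = proportion_ci(10, 10)
        assert hi == 1.0

    def test_published_sensitivity_interval(self):
        lo, hi = proportion_ci(113, 185)
        assert round(lo * 100, 1) == 53.7
        assert round(hi * 100, 1) == 68.1

    def test_beta_quantile_oracle(self):
        lo, hi = proportion_ci(5, 10)
        assert lo == pytest.approx(float(beta.ppf(0.025, 5, 6)), abs=1e-9)
        assert hi == pytest.approx(float(beta.ppf(0.975, 6, 5)), abs=1e-9)

    def test_statsmodels_oracle_many(self):
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = proportion_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(float(slo), abs=1e-10)
            assert hi == pytest.approx(float(shi), abs=1e-10)

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (20, 80, 320, 1280):
            lo, hi = proportion_ci(n // 4, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_k_gt_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(11, 10)

    def test_wilson_variant(self):
        lo, hi = proportion_ci(5, 10, method="wilson")
        assert 0 < lo < 0.5 < hi < 1


class TestLikelihoodRatios:
    def test_published_lr_pos(self):
        ms = metrics(RECONSTRUCTED["xgboost"])
        # sens/(1-spec) from the reconstructed counts: 50.8 as printed
        assert round(ms.lr_pos, 1) == 50.8
        lo, hi = ms.ci["lr_pos"]
        assert round(lo, 1) == 29.8
        assert round(hi, 1) == 86.6

    def test_uninformative_test(self):
        ms = metrics(ConfusionMatrix(tp=5, fp=5, fn=5, tn=5))
        assert ms.lr_pos == pytest.approx(1.0)
        assert ms.lr_neg == pytest.approx(1.0)

    def test_zero_cell_correction_flagged(self):
        out = likelihood_ratio_ci(ConfusionMatrix(tp=10, fp=0, fn=5, tn=20))
        assert "lr_pos" in out["corrected"]
        lo, hi = out["lr_pos_ci"]
        assert 0 < lo < out["lr_pos"] < hi


class TestKappa:
    def test_perfect_agreement(self):
        res = cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0])
        assert res.kappa == pytest.approx(1.0)

    def test_hand_arithmetic_table(self):
        r1 = [1] * 50 + [0] * 50
        r2 = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        res = cohens_kappa(r1, r2)
        assert res.observed_agreement == pytest.approx(0.8)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        r1 = rng.integers(0, 2, 100)
        r2 = rng.integers(0, 2, 100)
        assert cohens_kappa(r1, r2).kappa == pytest.approx(cohens_kappa(r2, r1).kappa)

    def test_sklearn_oracle_random(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 200))
            r1 = rng.integers(0, 2, n)
            r2 = rng.integers(0, 2, n)
            res = cohens_kappa(r1, r2)
            if res.undefined:
                continue
            assert res.kappa == pytest.approx(float(cohen_kappa_score(r1, r2)), abs=1e-10)

    def test_both_constant_identical_undefined(self):
        res = cohens_kappa([1, 1, 1], [1, 1, 1])
        assert res.undefined
        assert res.kappa is None


class TestReconstruction:
    @pytest.mark.parametrize(
        "name,marginals",
        [
            ("word_embedding", (19.5, 95.1, 38.7, 88.1)),
            ("xgboost", (61.1, 98.8, 89.0, 94.1)),
            ("svm", (56.2, 98.1, 82.5, 93.4)),
            ("naive_bayes", (93.5, 74.2, 36.6, 98.6)),
            ("logistic_regression", (5.4, 95.5, 16.1, 86.4)),
            ("lightgbm", (26.5, 99.8, 96.1, 89.5)),
        ],
    )
    def test_recovers_unique_integer_matrix(self, name, marginals):
        sens, spec, ppv, npv = marginals
        cm = reconstruct_confusion(1350, 185, sens, spec, ppv, npv)
        assert cm == RECONSTRUCTED[name]

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ValueError, match="no integer confusion matrix"):
            reconstruct_confusion(10, 5, 50.0, 50.0, 99.9)
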