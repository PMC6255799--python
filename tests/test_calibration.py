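"""pH calibration, correlation and ROC statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcest.calibration import (
    CalibrationModel,
    fit_ph_calibration,
    linear_correlation,
    ph_from_ksw,
    roc_analysis,
)


def auc_pair_counting(scores, labels):
    """Independent oracle: AUC = P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCalibrationFit:
    def test_noiseless_recovery_of_printed_coefficients(self):
        ph = np.arange(6.0, 7.41, 0.2)
        model = CalibrationModel(a=1.3, b=248.2)
        fit = fit_ph_calibration(ph, np.asarray(model.ksw(ph)))
        assert fit.a == pytest.approx(1.3, abs=1e-9)
        assert fit.b == pytest.approx(248.2, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_ksw_rejected(self):
        with pytest.raises(ValueError):
            fit_ph_calibration(np.array([6.0, 6.5, 7.0]), np.full(3, 300.0))

    def test_narrow_ph_span_rejected(self):
        with pytest.raises(ValueError):
            fit_ph_calibration(
                np.array([7.0, 7.1, 7.2]), np.array([250.0, 260.0, 270.0]))

    def test_noisy_monte_carlo_offset_recovery(self):
        rng = np.random.default_rng(9)
        errs = []
        for _ in range(200):
            ph = rng.uniform(5.8, 7.4, 50)
            k = 1.3 * 10 ** (8 - ph) + 248.2 + rng.normal(0, 20, 50)
            fit = fit_ph_calibration(ph, k)
            errs.append(abs(fit.b - 248.2))
        assert np.median(errs) < 15


class TestInversion:
    def test_printed_value_at_ph_7_2(self):
        model = CalibrationModel(a=1.3, b=248.2)
        assert model.ksw(7.2) == pytest.approx(256.4, abs=0.1)

    def test_round_trip_identity(self):
        model = CalibrationModel(a=1.3, b=248.2)
        k = float(model.ksw(6.5))
        assert ph_from_ksw(model, k) == pytest.approx(6.5, abs=1e-12)

    def test_at_or_below_offset_floor_rejected(self):
        model = CalibrationModel(a=1.3, b=248.2)
        for k in (248.2, 100.0):
            with pytest.raises(ValueError, match="floor"):
                ph_from_ksw(model, k)

    def test_strictly_decreasing_in_ksw(self):
        model = CalibrationModel(a=1.3, b=248.2)
        ks = np.linspace(250.0, 450.0, 50)
        phs = [ph_from_ksw(model, k) for k in ks]
        assert np.all(np.diff(phs) < 0)


class TestLinearCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r, r2, p = linear_correlation(x, 2 * x + 1)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(1.0))
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(10.0)
        _, _, r, _, _ = linear_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        _, _, r, _, _ = linear_correlation(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_raised(self):
        with pytest.raises(ValueError):
            linear_correlation(np.ones(5), np.arange(5.0))

    def test_pvalue_matches_permutation_test(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(size=12)
        *_, p = linear_correlation(x, y)
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        perm = np.mean([
            abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= r_obs
            for _ in range(4000)
        ])
        assert p == pytest.approx(perm, abs=0.02)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis(np.array([1, 2, 3, 10, 11, 12.0]),
                           np.array([0, 0, 0, 1, 1, 1]))
        assert res.auc == pytest.approx(1.0)
        assert res.youden_sensitivity == 1.0 and res.youden_specificity == 1.0

    def test_interleaved_example(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        assert roc_analysis(scores, np.array([0, 0, 1, 1])).auc == pytest.approx(1.0)
        assert roc_analysis(scores, np.array([0, 1, 0, 1])).auc == pytest.approx(0.75)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = np.arange(2000) % 2 == 0
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_raised(self):
        with pytest.raises(ValueError):
            roc_analysis(np.array([1.0, 2.0]), np.array([1, 1]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.normal(size=200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100).astype(bool)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
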