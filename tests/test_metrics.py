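"""Overlap metrics, regression, and ICC against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmhkit import metrics
from tmhkit.errors import DegenerateFitError, InputError

counts_strategy = st.builds(
    metrics.ConfusionCounts,
    tp=st.integers(0, 10**6),
    fp=st.integers(0, 10**6),
    fn=st.integers(0, 10**6),
    tn=st.integers(0, 10**6),
)


class TestConfusion:
    def test_perfect_prediction(self):
        m = (np.arange(25).reshape(5, 5) % 3 == 0).astype(np.uint8)
        c = metrics.confusion(m, m)
        assert c.fp == c.fn == 0
        assert c.tp == int(m.sum())

    def test_all_background_prediction(self):
        true = np.zeros((4, 4), dtype=np.uint8)
        true[1:3, 1:3] = 1
        c = metrics.confusion(np.zeros_like(true), true)
        assert (c.tp, c.fn) == (0, 4)

    def test_hand_tallied_4x4(self):
        true = np.array([[1, 1, 0, 0],
                         [1, 1, 0, 0],
                         [0, 0, 0, 0],
                         [0, 0, 0, 0]], dtype=np.uint8)
        pred = np.array([[1, 0, 0, 0],
                         [1, 1, 1, 0],
                         [0, 1, 1, 0],
                         [0, 0, 0, 0]], dtype=np.uint8)
        c = metrics.confusion(pred, true)
        # tally: overlap {00,10,11}=3; pred-only {12,21,22}=3; true-only {01}=1
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 3, 1, 9)
        assert c.total == 16
        assert c.as_matrix().tolist() == [[9, 3], [1, 3]]  # rows=truth, cols=pred
        assert metrics.iou(c) == pytest.approx(3 / 7)
        assert metrics.dice(c) == pytest.approx(6 / 10)
        assert metrics.sensitivity(c) == pytest.approx(3 / 4)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            metrics.confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestOverlapMetrics:
    def test_identical_masks_score_one(self):
        c = metrics.ConfusionCounts(tp=10, fp=0, fn=0, tn=90)
        assert metrics.iou(c) == metrics.dice(c) == metrics.sensitivity(c) == 1.0

    def test_disjoint_masks_score_zero(self):
        c = metrics.ConfusionCounts(tp=0, fp=5, fn=7, tn=88)
        assert metrics.iou(c) == metrics.dice(c) == 0.0

    def test_both_empty_convention(self):
        c = metrics.ConfusionCounts(tp=0, fp=0, fn=0, tn=100)
        assert metrics.iou(c) == metrics.dice(c) == 1.0
        with pytest.raises(InputError):
            metrics.sensitivity(c)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(counts_strategy)
    def test_dice_iou_identity_and_bounds(self, c):
        i, d = metrics.iou(c), metrics.dice(c)
        assert 0.0 <= i <= 1.0 and 0.0 <= d <= 1.0
        assert d == pytest.approx(2 * i / (1 + i))

    def test_symmetry_of_iou_and_dice_but_not_sensitivity(self):
        rng = np.random.default_rng(3)
        a = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        b = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        cab, cba = metrics.confusion(a, b), metrics.confusion(b, a)
        assert metrics.iou(cab) == metrics.iou(cba)
        assert metrics.dice(cab) == metrics.dice(cba)
        assert metrics.sensitivity(cab) != metrics.sensitivity(cba)


class TestSegMetrics:
    def test_identical_masks_all_means_one(self):
        m = (np.arange(64).reshape(8, 8) % 5 == 0).astype(np.uint8)
        sm = metrics.seg_metrics(m, m)
        assert sm.mean_iou == sm.mean_dice == sm.mean_sensitivity == 1.0

    def test_class_mean_is_unweighted(self):
        sm = metrics.SegMetrics(
            iou_per_class=(0.999, 0.8),
            dice_per_class=(0.999, 0.8),
            sensitivity_per_class=(0.999, 0.8),
            precision_per_class=(0.999, 0.8),
        )
        assert sm.mean_iou == pytest.approx(0.8995)

    def test_against_per_class_recount(self):
        rng = np.random.default_rng(9)
        pred = (rng.random((30, 30)) < 0.4).astype(np.uint8)
        true = (rng.random((30, 30)) < 0.4).astype(np.uint8)
        sm = metrics.seg_metrics(pred, true)
        for cls in (0, 1):
            p, t = pred == cls, true == cls
            inter = np.sum(p & t)
            union = np.sum(p | t)
            assert sm.iou_per_class[cls] == pytest.approx(inter / union)
            assert sm.dice_per_class[cls] == pytest.approx(
                2 * inter / (p.sum() + t.sum())
            )
            assert sm.sensitivity_per_class[cls] == pytest.approx(inter / t.sum())


class TestRegression:
    def test_perfect_agreement(self):
        t = np.array([0.2, 0.3, 0.4, 0.55])
        fit = metrics.tmh_regression(t, t)
        assert (fit.slope, fit.intercept, fit.r_squared) == pytest.approx((1, 0, 1))

    def test_constant_offset(self):
        t = np.array([0.2, 0.3, 0.4, 0.55])
        fit = metrics.tmh_regression(t, t + 0.1)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-0.1)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(17)
        pred = rng.uniform(0.1, 0.7, size=10)
        true = 0.95 * pred + 0.02 + rng.normal(0, 0.02, size=10)
        fit = metrics.tmh_regression(true, pred)
        # closed-form OLS of true on pred
        sxx = np.sum((pred - pred.mean()) ** 2)
        sxy = np.sum((pred - pred.mean()) * (true - true.mean()))
        slope = sxy / sxx
        intercept = true.mean() - slope * pred.mean()
        r2 = sxy**2 / (sxx * np.sum((true - true.mean()) ** 2))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_degenerate_predictor(self):
        with pytest.raises(DegenerateFitError):
            metrics.tmh_regression([0.1, 0.2, 0.3], [0.4, 0.4, 0.4])


def icc21_anova_oracle(x: np.ndarray) -> float:
    """Explicit two-way ANOVA variance-component oracle for ICC(2,1)."""
    n, k = x.shape
    grand = x.mean()
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        t = np.array([0.2, 0.3, 0.4, 0.55, 0.6])
        assert metrics.icc_agreement(t, t).icc == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            t = rng.uniform(0.1, 0.7, size=30)
            p = rng.permutation(t)
            assert abs(metrics.icc_agreement(t, p).icc) < 0.3

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(29)
        t = rng.uniform(0.1, 0.7, size=12)
        p = t + rng.normal(0, 0.05, size=12)
        res = metrics.icc_agreement(t, p)
        assert res.icc == pytest.approx(icc21_anova_oracle(np.column_stack([t, p])),
                                        abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(31)
        t = rng.uniform(0.1, 0.7, size=15)
        p = t + rng.normal(0, 0.04, size=15)
        res = metrics.icc_agreement(t, p)
        frame = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["a", "b"], 15),
            "score": np.column_stack([t, p]).ravel(),
        })
        icc_table = pingouin.intraclass_corr(
            data=frame, targets="subject", raters="rater", ratings="score"
        )
        # ICC(A,1): single-rater absolute agreement = ICC(2,1)
        ref = float(icc_table.loc[icc_table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert res.icc == pytest.approx(ref, abs=1e-8)

    def test_constant_ratings_degenerate(self):
        with pytest.raises(DegenerateFitError):
            metrics.icc_agreement([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
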