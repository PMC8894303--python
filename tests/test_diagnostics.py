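"""ROC/Youden layer, bootstrap comparison, CV error, and agreement statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from pleuratex import (
    ValidationError,
    YoudenCutoffClassifier,
    compare_auc_bootstrap,
    cv_error,
    icc_agreement,
    roc_curve,
)


class TestRocCurve:
    def test_perfect_separation(self):
        r = roc_curve([0.1, 0.2, 0.9, 1.0], ["n", "n", "p", "p"],
                      positive="p", ci="none")
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 0.2 < r.cutoff < 0.9

    def test_four_point_example(self):
        r = roc_curve([1, 2, 3, 4], ["n", "n", "p", "p"], positive="p", ci="none")
        assert r.auc == 1.0
        assert r.cutoff == 2.5

    def test_null_scores_give_half_auc(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        r = roc_curve(scores, labels, positive=1, ci="none")
        assert r.auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_mann_whitney_u(self, seed):
        """Trapezoidal empirical AUC equals U/(n+ n-) with ties counted half."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        auc_mw = u / ((labels == 1).sum() * (labels == 0).sum())
        r = roc_curve(scores, labels, positive=1, ci="none")
        expected = max(auc_mw, 1.0 - auc_mw)  # direction chosen so auc >= 0.5
        assert r.auc == pytest.approx(expected, abs=1e-12)

    def test_direction_flips_for_lower_positive_feature(self):
        r = roc_curve([5, 4, 1, 2], ["n", "n", "p", "p"], positive="p", ci="none")
        assert r.direction == "lower-positive"
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        a = roc_curve(scores, labels, positive=1, ci="none").auc
        b = roc_curve(np.exp(scores), labels, positive=1, ci="none").auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self, rng):
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
        labels = np.r_[np.zeros(40), np.ones(40)]
        r1 = roc_curve(scores, labels, positive=1, n_boot=200, seed=5)
        r2 = roc_curve(scores, labels, positive=1, n_boot=200, seed=5)
        assert r1 == r2
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_delong_ci(self, rng):
        scores = np.r_[rng.normal(0, 1, 60), rng.normal(1.0, 1, 60)]
        labels = np.r_[np.zeros(60), np.ones(60)]
        r = roc_curve(scores, labels, positive=1, ci="delong")
        assert r.ci_low <= r.auc <= r.ci_high
        assert r.ci_high - r.ci_low < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1, 2, 3], ["p", "p", "p"], positive="p")

    def test_missing_scores_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1.0, np.nan], ["p", "n"], positive="p")


class TestCompareAucBootstrap:
    def test_identical_features_give_p_one(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert compare_auc_bootstrap(scores, scores, labels, positive=1,
                                     seed=0) == 1.0

    def test_separating_vs_random_feature_significant(self, rng):
        n = 100
        labels = np.r_[np.zeros(n), np.ones(n)]
        good = np.r_[rng.normal(0, 1, n), rng.normal(3, 1, n)]
        noise = rng.normal(size=2 * n)
        p = compare_auc_bootstrap(good, noise, labels, positive=1, seed=1)
        assert p < 0.01

    def test_seed_reproducibility(self, rng):
        labels = np.r_[np.zeros(30), np.ones(30)]
        a = rng.normal(size=60) + labels
        b = rng.normal(size=60)
        p1 = compare_auc_bootstrap(a, b, labels, positive=1, n_boot=300, seed=9)
        p2 = compare_auc_bootstrap(a, b, labels, positive=1, n_boot=300, seed=9)
        assert p1 == p2

    def test_small_n_boot_warns(self, rng):
        labels = np.r_[np.zeros(20), np.ones(20)]
        a = rng.normal(size=40)
        with pytest.warns(UserWarning):
            compare_auc_bootstrap(a, a + 0.1, labels, positive=1, n_boot=50, seed=0)


class TestYoudenClassifier:
    def test_fit_predict_on_separable(self):
        X = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = YoudenCutoffClassifier().fit(X, y)
        assert clf.direction_ == "higher-positive"
        assert 3 < clf.cutoff_ < 10
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_lower_positive_direction(self):
        X = np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = YoudenCutoffClassifier().fit(X, y)
        assert clf.direction_ == "lower-positive"
        np.testing.assert_array_equal(clf.predict(X), y)


class TestCvError:
    def test_zero_on_separable(self):
        scores = np.r_[np.arange(20.0), np.arange(100.0, 120.0)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        for seed in (0, 1, 2):
            assert cv_error(scores, labels, k=4, seed=seed) == 0.0

    def test_half_on_permuted_labels(self, rng):
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n // 2)])
        err = cv_error(scores, labels, k=4, seed=3)
        assert err == pytest.approx(0.5, abs=0.05)

    def test_small_minority_falls_back_to_loo(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0])
        labels = np.array([0, 0, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="leave-one-out"):
            err = cv_error(scores, labels, k=4, seed=0)
        assert err == 0.0

    def test_bounds(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:8] = [0, 0, 0, 0, 1, 1, 1, 1]
        err = cv_error(scores, labels, k=4, seed=0)
        assert 0.0 <= err <= 1.0


def icc21_anova_oracle(x):
    """ICC(2,1) from the two-way ANOVA table, transcribed independently."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - grand) ** 2).sum() \
        - k * ((x.mean(axis=1) - grand) ** 2).sum() \
        - n * ((x.mean(axis=0) - grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAgreement:
    def test_duplicated_raters_give_perfect_agreement(self, rng):
        a = rng.normal(size=12)
        res = icc_agreement(np.column_stack([a, a]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.cronbach_alpha == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_rater_gives_low_icc(self, rng):
        a = rng.normal(size=500)
        b = a + rng.normal(scale=50.0, size=500)
        res = icc_agreement(np.column_stack([a, b]))
        assert abs(res.icc) < 0.15

    def test_six_by_two_fixture_matches_anova_oracle(self):
        x = np.array(
            [[9.0, 10.0], [8.0, 7.5], [6.0, 6.5], [4.0, 5.0], [7.0, 7.0], [2.0, 3.0]]
        )
        res = icc_agreement(x)
        assert res.icc == pytest.approx(icc21_anova_oracle(x), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_icc2_and_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1)) * 2
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        ref = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
        res = icc_agreement(x)
        assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-9)
        ci_col = "CI95" if "CI95" in ref.index else "CI95%"
        lo, hi = ref[ci_col]
        # pingouin rounds the interval to 2 decimals
        assert res.ci_low == pytest.approx(float(lo), abs=6e-3)
        assert res.ci_high == pytest.approx(float(hi), abs=6e-3)

    def test_matches_pingouin_cronbach(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
        alpha = pingouin.cronbach_alpha(data=pd.DataFrame(x))[0]
        assert icc_agreement(x).cronbach_alpha == pytest.approx(alpha, abs=1e-9)

    def test_zero_between_subject_variance_warns(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning):
            res = icc_agreement(x)
        assert res.icc == 0.0

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValidationError):
            icc_agreement(np.array([[1.0, np.nan], [2.0, 3.0]]))
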