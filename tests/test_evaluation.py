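"""ROC/AUC, bootstrap CI, operating points, McNemar, image quality."""

import numpy as np
import pytest
from scipy.stats import binom

from mbdwi.evaluation import (
    auc_ci,
    bonferroni_alpha,
    image_quality,
    mcnemar_paired,
    operating_point,
    roc_auc,
)


def _brute_force_auc(scores, y):
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        s = np.r_[np.full(5, 2.0), np.full(5, 1.0)]
        assert roc_auc(s, y) == 1.0

    def test_all_tied_scores_give_half(self):
        y = np.r_[np.ones(6, int), np.zeros(4, int)]
        assert roc_auc(np.ones(10), y) == 0.5

    def test_matches_pair_enumeration_oracle_on_50_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n1 = rng.integers(3, 18)
            y = np.zeros(20, int)
            y[rng.choice(20, n1, replace=False)] = 1
            s = np.round(rng.normal(size=20), 1)  # rounding forces ties
            assert roc_auc(s, y) == pytest.approx(
                _brute_force_auc(s, y), abs=1e-12)

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = rng.normal(size=20)  # continuous, tie-free
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.ones(5, int))


class TestAUCConfidenceInterval:
    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        s = np.r_[rng.normal(0.8, 1, 30), rng.normal(0, 1, 30)]
        lo, hi = auc_ci(s, y, seed=3)
        assert lo <= roc_auc(s, y) <= hi

    def test_perfect_separation_upper_bound_one(self):
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        s = np.r_[np.full(40, 5.0), np.zeros(40)]
        lo, hi = auc_ci(s, y, seed=1)
        assert hi == 1.0

    def test_small_class_warns(self):
        y = np.r_[np.ones(3, int), np.zeros(30, int)]
        s = np.arange(33.0)
        with pytest.warns(UserWarning):
            auc_ci(s, y, seed=0, n_boot=50)


class TestOperatingPoint:
    def test_perfect_separation_all_ones(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = np.r_[np.full(10, 1.0), np.zeros(10)]
        op = operating_point(s, y)
        assert (op["sensitivity"], op["specificity"],
                op["ppv"], op["npv"]) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_counted_interleaved_toy(self):
        # 10 malignant scoring high except one, 10 benign scoring low
        # except one: the Youden threshold leaves one error on each side.
        s_mal = [0.9, 0.85, 0.8, 0.78, 0.75, 0.7, 0.65, 0.6, 0.55, 0.05]
        s_ben = [0.95, 0.3, 0.28, 0.25, 0.2, 0.18, 0.15, 0.1, 0.08, 0.02]
        s = np.r_[s_mal, s_ben]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        op = operating_point(s, y)
        assert op["sensitivity"] == pytest.approx(0.9)
        assert op["specificity"] == pytest.approx(0.9)

    def test_ppv_npv_satisfy_bayes_identity(self):
        rng = np.random.default_rng(4)
        y = (rng.random(60) < 0.4).astype(int)
        y[:2] = [0, 1]  # both classes guaranteed
        s = rng.normal(size=60) + y
        op = operating_point(s, y)
        prev = y.mean()
        se, sp = op["sensitivity"], op["specificity"]
        ppv = se * prev / (se * prev + (1 - sp) * (1 - prev))
        npv = sp * (1 - prev) / (sp * (1 - prev) + (1 - se) * prev)
        assert op["ppv"] == pytest.approx(ppv, rel=1e-12)
        assert op["npv"] == pytest.approx(npv, rel=1e-12)


class TestMcNemar:
    def test_identical_predictions_give_p_one(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        preds = 1 - y
        assert mcnemar_paired(preds, preds, y) == 1.0

    def test_discordant_12_2_matches_binomial_tail_oracle(self):
        y = np.zeros(40, int)
        y[:20] = 1
        a, b = y.copy(), y.copy()
        b[:12] = 1 - b[:12]      # a right / b wrong: 12
        a[25:27] = 1 - a[25:27]  # b right / a wrong: 2
        p = mcnemar_paired(a, b, y)
        # oracle: two-sided exact binomial tail sum
        oracle = 2.0 * binom.cdf(2, 14, 0.5)
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(0.0129, abs=5e-5)

    def test_large_discordant_count_uses_chi_square(self):
        y = np.zeros(200, int)
        y[:100] = 1
        a, b = y.copy(), y.copy()
        b[:40] = 1 - b[:40]
        a[150:170] = 1 - a[150:170]
        p = mcnemar_paired(a, b, y)
        # continuity-corrected chi-square on (40, 20)
        stat = (abs(40 - 20) - 1) ** 2 / 60
        from scipy.stats import chi2
        assert p == pytest.approx(chi2.sf(stat, 1), rel=1e-9)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 23, 0.05 / 23),
        (0.05, 1, 0.05),
        (0.05, 10, 0.005),
    ])
    def test_threshold_values(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_printed_value_to_paper_precision(self):
        assert round(bonferroni_alpha(0.05, 23), 5) == 0.00217

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestImageQuality:
    def test_direct_arithmetic(self):
        vol = np.zeros((10, 10, 2))
        les = np.zeros_like(vol, bool)
        bg = np.zeros_like(vol, bool)
        les[0, :5, 0] = True
        bg[5:, :, :] = True
        vol[les] = 100.0
        rng = np.random.default_rng(0)
        bg_vals = rng.normal(20, 10, bg.sum())
        vol[bg] = bg_vals
        q = image_quality(vol, les, bg)
        mb, sb = bg_vals.mean(), bg_vals.std()
        assert q["snr"] == pytest.approx(100.0 / sb)
        assert q["cnr"] == pytest.approx((100.0 - mb) / sb)
        assert q["contrast"] == pytest.approx(100.0 / mb)

    def test_noiseless_background_is_an_error(self):
        vol = np.ones((4, 4, 2))
        les = np.zeros_like(vol, bool)
        bg = np.zeros_like(vol, bool)
        les[0, 0, 0] = True
        bg[2:, :, :] = True
        with pytest.raises(ValueError, match="SNR undefined"):
            image_quality(vol, les, bg)

    def test_overlapping_regions_rejected(self):
        vol = np.ones((4, 4, 2))
        region = np.ones_like(vol, bool)
        with pytest.raises(ValueError):
            image_quality(vol, region, region)

    def test_synthetic_cohort_snr_near_generator_target(self, scheme):
        """Measured b=0 SNR of a noisy phantom is within 20% of the
        generator's target of 30."""
        from mbdwi.synthetic import (
            LesionPhantomSpec, add_rician_noise, make_lesion_phantom,
        )

        spec = LesionPhantomSpec(label="malignant")
        vol, mask, _ = make_lesion_phantom(spec, scheme, seed=6)
        noisy = add_rician_noise(vol, 30.0, seed=7, mask=mask)
        bg = np.zeros(vol.shape, bool)
        bg[:4, :4, :] = True  # air corner
        q = image_quality(noisy.volume_at(0.0), mask, bg)
        # Rayleigh background SD = sigma * sqrt(2 - pi/2)
        expected_snr = 30.0 / np.sqrt(2 - np.pi / 2)
        assert q["snr"] == pytest.approx(expected_snr, rel=0.2)
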