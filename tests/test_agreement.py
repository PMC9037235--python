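"""Bland–Altman agreement, acceptance rules, consensus maps, paired t,
Pearson — each checked against direct-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitcount.agreement import (
    AcceptanceSpec,
    BAResult,
    PairedMeasurements,
    bland_altman,
    check_loa_acceptance,
    consensus_map,
    paired_t_test,
    pearson_r,
)

from _oracles import bland_altman_oracle, paired_t_oracle, pearson_oracle


def _pairs(manual, automated):
    manual = np.asarray(manual, dtype=float)
    return PairedMeasurements(
        [f"s{i}" for i in range(len(manual))], manual, np.asarray(automated, dtype=float)
    )


class TestBlandAltman:
    def test_identical_pairs_degenerate(self):
        ba = bland_altman(_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert ba.loa_lower == ba.loa_upper == 0.0
        assert ba.n_outside_loa == 0
        assert ba.bias_ci == (0.0, 0.0)  # zero variance: width-0 CIs

    def test_differences_one_two_three(self):
        ba = bland_altman(_pairs([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_upper == pytest.approx(3.96)
        assert ba.loa_lower == pytest.approx(0.04)

    def test_matches_formula_oracle_on_large_sample(self):
        rng = np.random.default_rng(17)
        manual = rng.uniform(0, 40, 1000)
        automated = manual + rng.normal(0.5, 2.0, 1000)
        ba = bland_altman(_pairs(manual, automated))
        oracle = bland_altman_oracle(manual, automated)
        assert ba.bias == pytest.approx(oracle["bias"], abs=1e-10)
        assert ba.sd_diff == pytest.approx(oracle["sd"], abs=1e-10)
        assert ba.loa_lower == pytest.approx(oracle["loa_lower"], abs=1e-10)
        assert ba.loa_upper == pytest.approx(oracle["loa_upper"], abs=1e-10)
        assert ba.bias_ci == pytest.approx(oracle["bias_ci"], abs=1e-10)
        assert ba.loa_lower_ci == pytest.approx(oracle["loa_lower_ci"], abs=1e-10)
        assert ba.loa_upper_ci == pytest.approx(oracle["loa_upper_ci"], abs=1e-10)
        assert ba.n_outside_loa == oracle["n_outside"]

    def test_loa_identities_hold(self):
        rng = np.random.default_rng(3)
        ba = bland_altman(_pairs(rng.uniform(0, 30, 25), rng.uniform(0, 30, 25)))
        assert ba.loa_upper == pytest.approx(ba.bias + 1.96 * ba.sd_diff, abs=1e-12)
        assert ba.loa_lower == pytest.approx(ba.bias - 1.96 * ba.sd_diff, abs=1e-12)
        assert ba.loa_lower <= ba.bias <= ba.loa_upper

    def test_swapping_methods_negates_bias_and_loas(self):
        rng = np.random.default_rng(6)
        manual = rng.uniform(0, 30, 40)
        automated = manual + rng.normal(1, 2, 40)
        ba = bland_altman(_pairs(manual, automated))
        swapped = bland_altman(_pairs(automated, manual))
        assert swapped.bias == pytest.approx(-ba.bias, abs=1e-12)
        assert swapped.loa_upper == pytest.approx(-ba.loa_lower, abs=1e-12)
        assert swapped.loa_lower == pytest.approx(-ba.loa_upper, abs=1e-12)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, derandomize=True)
    def test_pair_order_invariance(self, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        manual = rng.uniform(0, 30, 15)
        automated = manual + rng.normal(0, 1, 15)
        ba = bland_altman(_pairs(manual, automated))
        perm = rng.permutation(15)
        ba_perm = bland_altman(_pairs(manual[perm], automated[perm]))
        assert ba_perm.bias == pytest.approx(ba.bias, abs=1e-12)
        assert ba_perm.loa_upper == pytest.approx(ba.loa_upper, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            _pairs([1.0], [1.0])


class TestLOAAcceptance:
    def test_published_overall_loas_fail_five_percent_bound(self):
        # LOAs of -4.86 / +6.00: the upper limit exceeds the ±5 aim
        ba = BAResult(58, 0.57, 2.77, -4.86, 6.00, (0, 0), (0, 0), (0, 0), np.array([]), np.array([]))
        verdict = check_loa_acceptance(ba, AcceptanceSpec(), "overall")
        assert not verdict.passed
        assert verdict.max_abs_loa == 6.00

    def test_low_stratum_loas_fail_one_point_five_bound(self):
        ba = BAResult(10, 0.99, 0.49, 0.03, 1.95, (0, 0), (0, 0), (0, 0), np.array([]), np.array([]))
        assert not check_loa_acceptance(ba, AcceptanceSpec(), "low").passed

    def test_tight_loas_pass(self):
        ba = BAResult(10, 0.0, 0.51, -1.0, 1.0, (0, 0), (0, 0), (0, 0), np.array([]), np.array([]))
        assert check_loa_acceptance(ba, AcceptanceSpec(), "low").passed

    def test_verdict_monotone_in_bound(self):
        ba = BAResult(10, 0.0, 1.0, -1.96, 1.96, (0, 0), (0, 0), (0, 0), np.array([]), np.array([]))
        passes = [
            check_loa_acceptance(ba, AcceptanceSpec(overall_bound=b), "overall").passed
            for b in (0.5, 1.0, 1.96, 3.0, 5.0)
        ]
        assert passes == sorted(passes)  # shrinking never flips fail→pass

    def test_low_stratum_subset(self):
        pairs = _pairs([1.0, 2.0, 30.0, 4.0], [1.5, 2.5, 33.0, 4.5])
        low = pairs.subset_low(5.0)
        assert len(low) == 3
        assert all(m < 5.0 for m in low.manual)


class TestConsensusMap:
    def test_three_identical_masks(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        cm = consensus_map([mask, mask, mask])
        assert (cm.counts[mask] == 3).all()
        assert (cm.counts[~mask] == 0).all()
        assert cm.summary()[3] == int(mask.sum())

    def test_disjoint_masks_never_exceed_one(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4], b[4:] = True, True
        assert consensus_map([a, b]).counts.max() == 1

    def test_matches_per_pixel_addition(self):
        rng = np.random.default_rng(12)
        masks = [rng.random((20, 20)) > 0.5 for _ in range(3)]
        cm = consensus_map(masks)
        oracle = sum(m.astype(int) for m in masks)
        assert np.array_equal(cm.counts, oracle)

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            consensus_map([np.zeros((8, 8), bool), np.zeros((8, 9), bool)])


class TestPairedT:
    def test_symmetric_differences_give_t_zero(self):
        t, p = paired_t_test(_pairs([0.0, 0.0], [-1.0, 1.0]))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_differences_one_two_three(self):
        t, p = paired_t_test(_pairs([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))
        assert t == pytest.approx(2.0 * np.sqrt(3.0))

    def test_matches_oracle_and_scipy(self):
        rng = np.random.default_rng(23)
        manual = rng.uniform(0, 30, 50)
        automated = manual + rng.normal(0.3, 1.0, 50)
        t, p = paired_t_test(_pairs(manual, automated))
        t_o, p_o = paired_t_oracle(manual, automated)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        from scipy import stats

        res = stats.ttest_rel(automated, manual)
        assert t == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(_pairs([1.0, 2.0], [2.0, 3.0]))

    def test_type_one_error_calibrated(self):
        # 5000 null replicates of n=20: rejection rate at alpha=.05
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 5000
        for _ in range(reps):
            d = rng.normal(0.0, 1.0, 20)
            _, p = paired_t_test(_pairs(np.zeros(20), d))
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_anti_linearity(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle_and_scipy(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        from scipy import stats

        res = stats.pearsonr(x, y)
        assert r == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            pearson_r([1.0, 2.0], [1.0, 2.0])
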