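"""Efficacy engine: Hedges' g, direction normalization, significance tiers."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cdti.efficacy import (
    EfficacyConsistencyError,
    SignificanceTier,
    TIER_MULTIPLIERS,
    TierLabel,
    adjusted_efficacy,
    compute_hedges_g,
    hedges_correction,
    normalize_direction,
    score_efficacy,
    significance_tier,
)
from cdti.records import BenefitDirection, EfficacyEvidence, SignificanceInference


def brute_force_hedges_g(mean_a, mean_b, sd_a, sd_b, n_a, n_b):
    """Independent textbook computation: Cohen's d on the pooled SD, then the
    small-sample correction factor — written out step by step."""
    pooled_var = ((n_a - 1) * sd_a * sd_a + (n_b - 1) * sd_b * sd_b) / (n_a + n_b - 2)
    cohens_d = (mean_a - mean_b) / math.sqrt(pooled_var)
    correction = 1.0 - 3.0 / (4.0 * (n_a + n_b - 2) - 1.0)
    return cohens_d * correction


class TestHedgesG:
    def test_zero_mean_difference(self):
        assert compute_hedges_g(10, 10, 3, 5, 20, 20) == 0.0

    def test_hand_computed_example(self):
        # d = 2/4 = 0.5, J = 1 - 3/151, g = 0.5 * (1 - 3/151)
        g = compute_hedges_g(10, 8, 4, 4, 20, 20)
        assert g == pytest.approx(0.5 * (1 - 3 / 151), abs=1e-12)
        assert g == pytest.approx(0.4901, abs=5e-5)

    def test_antisymmetry_under_group_swap(self):
        g = compute_hedges_g(12.3, 9.1, 2.5, 3.1, 30, 45)
        assert compute_hedges_g(9.1, 12.3, 3.1, 2.5, 45, 30) == pytest.approx(-g, abs=1e-15)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_hedges_g(1, 0, 0, 0, 10, 10)

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            compute_hedges_g(1, 0, 1, 1, 1, 10)

    @settings(max_examples=1000, derandomize=True)
    @given(
        mean_a=st.floats(-50, 50),
        mean_b=st.floats(-50, 50),
        sd_a=st.floats(0.1, 20),
        sd_b=st.floats(0.1, 20),
        n_a=st.integers(2, 500),
        n_b=st.integers(2, 500),
    )
    def test_matches_independent_brute_force(self, mean_a, mean_b, sd_a, sd_b, n_a, n_b):
        expected = brute_force_hedges_g(mean_a, mean_b, sd_a, sd_b, n_a, n_b)
        assert compute_hedges_g(mean_a, mean_b, sd_a, sd_b, n_a, n_b) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(derandomize=True)
    @given(
        delta=st.floats(0.01, 30),
        sd=st.floats(0.1, 20),
        n_a=st.integers(2, 200),
        n_b=st.integers(2, 200),
    )
    def test_bias_correction_shrinks_magnitude(self, delta, sd, n_a, n_b):
        g = compute_hedges_g(delta, 0.0, sd, sd, n_a, n_b)
        d = delta / sd  # equal SDs: pooled SD equals sd
        assert abs(g) < abs(d)
        assert 0 < hedges_correction(n_a + n_b - 2) < 1


class TestDirectionNormalization:
    def test_lower_better_endpoint_flips_sign(self):
        # fewer migraine days on treatment: raw SMD -0.300 -> benefit +0.300
        assert normalize_direction(-0.300, BenefitDirection.lower_better) == 0.300

    def test_higher_better_endpoint_unchanged(self):
        assert normalize_direction(0.179, BenefitDirection.higher_better) == 0.179

    @pytest.mark.parametrize("direction", list(BenefitDirection))
    def test_zero_is_a_fixed_point(self, direction):
        assert normalize_direction(0.0, direction) == 0.0


class TestSignificanceTier:
    @pytest.mark.parametrize(
        "p,label,multiplier",
        [
            (0.0009, TierLabel.very_high, 1.15),
            (0.0, TierLabel.very_high, 1.15),
            (0.001, TierLabel.high, 1.10),  # half-open boundary
            (0.005, TierLabel.high, 1.10),
            (0.01, TierLabel.significant, 1.00),  # half-open boundary
            (0.049, TierLabel.significant, 1.00),
            (0.05, TierLabel.not_significant, 0.50),  # half-open boundary
            (0.214, TierLabel.not_significant, 0.50),
            (1.0, TierLabel.not_significant, 0.50),
        ],
    )
    def test_tier_boundaries(self, p, label, multiplier):
        tier = significance_tier(p)
        assert tier.label is label
        assert tier.multiplier == multiplier

    @pytest.mark.parametrize(
        "inference,multiplier",
        [
            (SignificanceInference.ci_excludes_null, 1.00),
            (SignificanceInference.reported_significant, 1.00),
            (SignificanceInference.unknown, 0.50),
            (None, 0.50),
        ],
    )
    def test_missing_p_value_falls_back_to_inference(self, inference, multiplier):
        assert significance_tier(None, inference).multiplier == multiplier

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            significance_tier(1.5)

    def test_multiplier_is_non_increasing_in_p(self):
        grid = [i / 2000 for i in range(2001)]
        multipliers = [significance_tier(p).multiplier for p in grid]
        assert all(a >= b for a, b in zip(multipliers, multipliers[1:]))

    def test_tier_label_multiplier_pairing_enforced(self):
        with pytest.raises(ValueError):
            SignificanceTier(TierLabel.very_high, 0.5)


class TestAdjustedEfficacy:
    @pytest.mark.parametrize(
        "smd,label,expected",
        [
            (0.179, TierLabel.not_significant, 0.0895),
            (0.300, TierLabel.high, 0.330),
            (-0.2, TierLabel.significant, 0.0),
        ],
    )
    def test_worked_examples(self, smd, label, expected):
        tier = SignificanceTier.from_label(label)
        assert adjusted_efficacy(smd, tier) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True)
    @given(
        smd_lo=st.floats(-2, 2),
        bump=st.floats(0, 2),
        label=st.sampled_from(list(TierLabel)),
    )
    def test_monotone_in_smd_and_never_negative(self, smd_lo, bump, label):
        tier = SignificanceTier.from_label(label)
        lo, hi = adjusted_efficacy(smd_lo, tier), adjusted_efficacy(smd_lo + bump, tier)
        assert 0.0 <= lo <= hi

    def test_cap_is_fifteen_percent(self):
        assert max(TIER_MULTIPLIERS.values()) == 1.15


class TestScoreEfficacy:
    def test_reported_smd_path(self, ct132_record):
        score = score_efficacy(ct132_record.efficacy)
        assert score.smd == 0.300
        assert score.tier.multiplier == 1.10
        assert score.adjusted == pytest.approx(0.330)
        assert score.smd_source == "reported"

    def test_group_statistics_path_normalizes_direction(self):
        evidence = EfficacyEvidence(
            group_means=(8.0, 10.0),  # treatment lowers a lower-is-better endpoint
            group_sds=(4.0, 4.0),
            group_ns=(20, 20),
            benefit_direction=BenefitDirection.lower_better,
            p_value=0.03,
        )
        score = score_efficacy(evidence)
        assert score.smd == pytest.approx(0.5 * (1 - 3 / 151))
        assert score.smd_source == "group_statistics"

    def test_mean_difference_path_uses_total_n(self):
        evidence = EfficacyEvidence(mean_diff=2.0, sd_pooled=4.0, total_n=40, p_value=0.5)
        score = score_efficacy(evidence)
        assert score.smd == pytest.approx(0.5 * (1 - 3 / 151))
        assert score.adjusted == pytest.approx(score.smd * 0.5)

    def test_reported_vs_raw_consistency_check(self):
        evidence = EfficacyEvidence(
            reported_smd=0.9,  # far from the ~0.49 the raw statistics give
            group_means=(10.0, 8.0),
            group_sds=(4.0, 4.0),
            group_ns=(20, 20),
            p_value=0.01,
        )
        with pytest.raises(EfficacyConsistencyError):
            score_efficacy(evidence)

    def test_consistent_reported_and_raw_pass(self):
        g = 0.5 * (1 - 3 / 151)
        evidence = EfficacyEvidence(
            reported_smd=round(g, 3),
            group_means=(10.0, 8.0),
            group_sds=(4.0, 4.0),
            group_ns=(20, 20),
            p_value=0.01,
        )
        assert score_efficacy(evidence).smd == round(g, 3)
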