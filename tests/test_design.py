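"""Power, sample-size and composite-stage calculations.

The statsmodels normal-approximation power solver serves as the
independent oracle for the power/sample-size round trip.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.power import NormalIndPower

from trialflow import (
    EffectContext,
    StageDesign,
    composite_stage,
    power_two_sample,
    required_n_per_arm,
    sample_size_ratio,
    standard_normal_quantile,
)

#: effect size calibrated so the 100-per-arm (N=200) reference study has 50% power
CALIBRATED_ES = 0.2772


class TestQuantile:
    @pytest.mark.parametrize(
        "p, rounding, expected",
        [
            (0.5, "none", 0.0),
            (0.975, "two_decimals", 1.96),
            (0.8, "two_decimals", 0.84),
            (0.9, "two_decimals", 1.28),
            (0.95, "two_decimals", 1.64),
            (0.995, "two_decimals", 2.58),
        ],
    )
    def test_reference_values(self, p, rounding, expected):
        assert standard_normal_quantile(p, rounding) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.7])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            standard_normal_quantile(p)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(derandomize=True)
    def test_cdf_round_trip(self, p):
        z = standard_normal_quantile(p)
        assert stats.norm.cdf(z) == pytest.approx(p, abs=1e-9)


class TestPower:
    def test_saturates_at_huge_effect(self):
        assert power_two_sample(EffectContext(10.0, 2), 0.05) == pytest.approx(1.0, abs=1e-6)

    def test_reference_study_has_half_power(self):
        # N = 200 total (100/arm) at the calibrated effect size
        p = power_two_sample(EffectContext(CALIBRATED_ES, 100), 0.05)
        assert p == pytest.approx(0.50, abs=1e-3)

    def test_eighty_percent_power_at_205_per_arm(self):
        p = power_two_sample(EffectContext(CALIBRATED_ES, 205), 0.05)
        assert p == pytest.approx(0.80, abs=2e-3)

    def test_agrees_with_statsmodels(self):
        # independent oracle; statsmodels includes the vanishing lower
        # tail of the two-sided test, hence the loose-but-tiny tolerance
        for n in (50, 100, 205, 400):
            ours = power_two_sample(EffectContext(CALIBRATED_ES, n), 0.05)
            ref = NormalIndPower().power(
                CALIBRATED_ES, nobs1=n, alpha=0.05, ratio=1.0, alternative="two-sided"
            )
            assert ours == pytest.approx(ref, abs=1e-3)

    def test_monotone_in_n_and_effect_size(self):
        es_grid = [0.1 + 0.05 * i for i in range(12)]
        n_grid = [10 * (i + 1) for i in range(12)]
        for es in es_grid:
            powers = [power_two_sample(EffectContext(es, n), 0.05) for n in n_grid]
            assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
        for n in n_grid:
            powers = [power_two_sample(EffectContext(es, n), 0.05) for es in es_grid]
            assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))


class TestRequiredN:
    def test_reference_calibration(self):
        assert required_n_per_arm(CALIBRATED_ES, 0.05, 0.5) == 100

    def test_eighty_percent_needs_205(self):
        n = required_n_per_arm(CALIBRATED_ES, 0.05, 0.8)
        assert n == 205
        assert power_two_sample(EffectContext(CALIBRATED_ES, 204), 0.05) < 0.8
        assert power_two_sample(EffectContext(CALIBRATED_ES, 205), 0.05) >= 0.8

    def test_agrees_with_statsmodels_solver(self):
        ref = NormalIndPower().solve_power(
            effect_size=CALIBRATED_ES, alpha=0.05, power=0.8, ratio=1.0,
            alternative="two-sided",
        )
        assert required_n_per_arm(CALIBRATED_ES, 0.05, 0.8) == math.ceil(ref)

    def test_doubling_effect_quarters_unrounded_n(self):
        n1 = required_n_per_arm(0.1, 0.05, 0.8)
        n2 = required_n_per_arm(0.2, 0.05, 0.8)
        assert n2 == pytest.approx(n1 / 4, abs=1)

    def test_unachievable_power_reported(self):
        with pytest.raises(ValueError, match="power"):
            required_n_per_arm(0.3, 0.05, 0.01)

    @given(
        st.floats(min_value=0.05, max_value=1.5),
        st.sampled_from([0.01, 0.05, 0.1, 0.2]),
        st.floats(min_value=0.2, max_value=0.99),
    )
    @settings(derandomize=True, max_examples=100)
    def test_inversion_minimality(self, es, alpha, power):
        n = required_n_per_arm(es, alpha, power)
        assert power_two_sample(EffectContext(es, n), alpha) >= power - 1e-12
        if n > 2:
            assert power_two_sample(EffectContext(es, n - 1), alpha) < power


class TestSampleSizeRatio:
    def test_identity(self):
        d = StageDesign(0.05, 0.8)
        assert sample_size_ratio(d, d) == pytest.approx(1.0)

    def test_high_power_doubles_the_study(self):
        # (1.96 + 0.84)^2 / 1.96^2: the 104.1% phase II cost increase
        r = sample_size_ratio(StageDesign(0.05, 0.8), StageDesign(0.05, 0.5), "two_decimals")
        assert r == pytest.approx((1.96 + 0.84) ** 2 / 1.96**2, abs=1e-12)
        assert r == pytest.approx(2.0408, abs=1e-4)

    def test_stringent_alpha_ratio(self):
        r = sample_size_ratio(StageDesign(0.01, 0.5), StageDesign(0.05, 0.5), "two_decimals")
        assert r == pytest.approx((2.58 / 1.96) ** 2, abs=1e-12)

    @given(
        st.tuples(
            st.floats(min_value=0.005, max_value=0.3),
            st.floats(min_value=0.4, max_value=0.99),
        ),
        st.tuples(
            st.floats(min_value=0.005, max_value=0.3),
            st.floats(min_value=0.4, max_value=0.99),
        ),
        st.tuples(
            st.floats(min_value=0.005, max_value=0.3),
            st.floats(min_value=0.4, max_value=0.99),
        ),
    )
    @settings(derandomize=True, max_examples=100)
    def test_chain_multiplicativity(self, pa, pb, pc):
        a, b, c = (StageDesign(al, pw) for al, pw in (pa, pb, pc))
        lhs = sample_size_ratio(a, b) * sample_size_ratio(b, c)
        assert lhs == pytest.approx(sample_size_ratio(a, c), rel=1e-9)


class TestCompositeStage:
    def test_single_trial_is_identity(self):
        a, p = composite_stage(StageDesign(0.07, 0.66, n_trials=1))
        assert (a, p) == (0.07, 0.66)

    def test_two_confirmatory_trials(self):
        a, p = composite_stage(StageDesign(0.05, 0.90, n_trials=2))
        assert a == pytest.approx(0.0025, abs=1e-12)
        assert p == pytest.approx(0.81, abs=1e-12)

    def test_lower_phase3_power_variant(self):
        a, p = composite_stage(StageDesign(0.05, 0.80, n_trials=2))
        assert (a, p) == (pytest.approx(0.0025), pytest.approx(0.64))

    @given(
        st.floats(min_value=0.001, max_value=0.5),
        st.floats(min_value=0.3, max_value=0.99),
        st.integers(min_value=1, max_value=5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_composite_never_exceeds_per_trial(self, alpha, power, k):
        a, p = composite_stage(StageDesign(alpha, power, n_trials=k))
        assert a <= alpha + 1e-15 and p <= power + 1e-15
        assert 0 < a < 1 and 0 < p < 1


class TestStageDesignValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha_per_trial=0.0, power_per_trial=0.5),
            dict(alpha_per_trial=0.05, power_per_trial=1.0),
            dict(alpha_per_trial=0.05, power_per_trial=0.5, n_trials=0),
            dict(alpha_per_trial=0.05, power_per_trial=0.5, sidedness="sideways"),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StageDesign(**kwargs)

    def test_effect_context_validation(self):
        with pytest.raises(ValueError):
            EffectContext(-0.1, 100)
        with pytest.raises(ValueError):
            EffectContext(0.3, 1)
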