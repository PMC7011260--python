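"""Effect reconstruction, power, FPRP and BFDP — values and invariants.

Frozen expected values were evaluated independently with 60-digit
mpmath arithmetic of the defining formulas.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from metacred import cred_stats
from metacred.cred_stats import (
    CredibilityConfig,
    bfdp,
    evaluate_profile,
    fprp,
    power_to_detect,
    se_from_ci,
    z_and_p,
)

Z975 = 1.9599639845400545


class TestSeFromCi:
    def test_published_style_interval(self):
        # (ln 1.33 - ln 1.06) / (2 * 1.9599640)
        assert se_from_ci(1.19, 1.06, 1.33) == pytest.approx(
            0.05788627645699716, abs=1e-12)

    def test_narrow_protective_interval(self):
        assert se_from_ci(0.90, 0.89, 0.91) == pytest.approx(
            0.005669271721318215, abs=1e-12)

    def test_symmetric_interval_inverts_exactly(self):
        k = math.exp(Z975)
        assert se_from_ci(2.0, 2.0 / k, 2.0 * k) == pytest.approx(1.0, abs=1e-9)

    def test_nondefault_level_uses_matching_quantile(self):
        z99 = stats.norm.ppf(0.995)
        se = se_from_ci(1.5, 1.2, 1.875, level=0.99)
        assert se == pytest.approx(math.log(1.875 / 1.2) / (2 * z99), abs=1e-14)

    @pytest.mark.parametrize("args", [
        (1.2, 1.3, 1.1), (1.2, -1.0, 1.4), (1.2, 1.1, 1.4, 1.2)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            se_from_ci(*args)


class TestZAndP:
    def test_moderate_effect(self):
        eff = z_and_p(1.19, 0.05788627645699716)
        assert eff.z == pytest.approx(3.005087177, abs=1e-8)
        assert eff.p_two_sided == pytest.approx(0.002655047395, rel=1e-9)

    def test_null_effect_has_p_one(self):
        eff = z_and_p(1.0, 0.3)
        assert eff.z == 0.0
        assert eff.p_two_sided == 1.0

    def test_extreme_effect_keeps_finite_log_p(self):
        eff = z_and_p(0.90, 0.005669271721318215)
        assert abs(eff.z) == pytest.approx(18.58448860, abs=1e-6)
        assert eff.log10_p == pytest.approx(-76.36747152, abs=0.01)
        assert math.isfinite(eff.log_p)

    def test_p_strictly_decreases_with_abs_z(self):
        ps = [z_and_p(math.exp(z * 0.1), 0.1).log_p for z in range(0, 60, 3)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPower:
    def test_fixed_alpha_convention(self):
        power = power_to_detect(1.2, 0.05788627645699716,
                                alpha_mode="fixed", alpha=0.05)
        assert power == pytest.approx(0.8829154062, abs=1e-9)

    def test_observed_p_convention(self):
        power = power_to_detect(1.2, 0.05788627645699716,
                                alpha_mode="observed_p",
                                observed_z=3.005087177315081)
        assert power == pytest.approx(0.5574722891, abs=1e-9)

    def test_vanishing_se_gives_full_power(self):
        assert power_to_detect(1.2, 1e-9, alpha_mode="fixed") == pytest.approx(
            1.0, abs=1e-12)

    def test_monotone_in_detection_or_and_se(self):
        se = 0.08
        p12 = power_to_detect(1.2, se, alpha_mode="fixed")
        p15 = power_to_detect(1.5, se, alpha_mode="fixed")
        assert p15 > p12
        assert power_to_detect(1.2, 0.2, alpha_mode="fixed") < p12


class TestFprp:
    def test_reduces_to_p_over_p_plus_one(self):
        # power = 1, prior = 0.5 -> p(1-pi)/(p(1-pi)+pi) = p/(p+1)
        assert fprp(0.05, 1.0, 0.5) == pytest.approx(0.05 / 1.05, rel=1e-12)

    def test_candidate_snp_example(self):
        assert fprp(0.004, 0.88293, 0.05) == pytest.approx(
            0.0792550030, abs=1e-9)

    def test_vanishing_p_with_power_gives_zero(self):
        assert fprp(0.0, 0.9, 0.05, log_p=-2000.0) == pytest.approx(
            0.0, abs=1e-300)

    def test_zero_power_with_positive_p_gives_one(self):
        assert fprp(0.01, 0.0, 0.05) == 1.0

    def test_doubly_degenerate_input_is_undefined(self):
        assert fprp(0.0, 0.0, 0.05) is None

    @given(p=st.floats(1e-12, 1.0), power=st.floats(1e-12, 1.0),
           prior=st.floats(1e-12, 1.0 - 1e-12))
    def test_bounded(self, p, power, prior):
        value = fprp(p, power, prior)
        assert 0.0 <= value <= 1.0

    @given(p=st.floats(1e-8, 0.5), power=st.floats(0.05, 1.0))
    def test_strictly_decreasing_in_prior(self, p, power):
        lo, hi = fprp(p, power, 0.001), fprp(p, power, 0.05)
        assert lo > hi

    @given(p=st.floats(1e-8, 0.5), prior=st.floats(1e-6, 0.5))
    def test_strictly_decreasing_in_power(self, p, prior):
        assert fprp(p, 0.9, prior) < fprp(p, 0.3, prior)


class TestBfdp:
    def test_algebraic_reduction_at_null_z(self):
        # z = 0, V = W, pi = 0.5  ->  BF = sqrt(2), BFDP = sqrt2/(sqrt2+1)
        w = (math.log(1.5) / Z975) ** 2
        value = bfdp(0.0, math.sqrt(w), 0.5, prior_or_bound=1.5)
        assert value.value == pytest.approx(0.5857864376269049, rel=1e-12)

    def test_candidate_snp_example(self):
        value = bfdp(math.log(1.19), 0.05788627645699716, 0.05, 1.5)
        assert value.value == pytest.approx(0.5170789890, abs=1e-9)

    def test_gwas_scale_evidence_stays_finite(self):
        value = bfdp(math.log(0.90), 0.005669271721318215, 0.001, 1.5)
        assert value.log10 == pytest.approx(-70.3808234, abs=1e-4)
        assert value.value == pytest.approx(0.0, abs=1e-60)

    @given(z=st.floats(-8, 8), se=st.floats(0.005, 0.5),
           prior=st.floats(1e-7, 0.5))
    def test_bounded(self, z, se, prior):
        value = bfdp(z * se, se, prior)
        assert 0.0 <= value.value <= 1.0
        assert value.log <= 0.0

    @given(z=st.floats(0.1, 6), se=st.floats(0.01, 0.3))
    def test_strictly_decreasing_in_prior(self, z, se):
        assert bfdp(z * se, se, 0.001).value > bfdp(z * se, se, 0.05).value

    def test_tends_to_one_as_prior_vanishes(self):
        values = [bfdp(math.log(1.2), 0.05, pi).value
                  for pi in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.999


class TestLogSpaceAgreesWithNaive:
    """Within the comfortably-representable regime the log-space routines
    must match direct evaluation of the defining formulas to 1e-10."""

    @pytest.mark.parametrize("z", [0.5, 2.0, 4.0, 6.0, 8.0])
    @pytest.mark.parametrize("prior", [0.05, 0.001, 1e-6])
    def test_fprp(self, z, prior):
        se = 0.05
        p = 2 * stats.norm.sf(z)
        power = power_to_detect(1.5, se, alpha_mode="observed_p", observed_z=z)
        naive = p * (1 - prior) / (p * (1 - prior) + power * prior)
        assert fprp(p, power, prior) == pytest.approx(naive, rel=1e-10)

    @pytest.mark.parametrize("z", [0.5, 2.0, 4.0, 6.0, 8.0])
    @pytest.mark.parametrize("prior", [0.05, 0.001, 1e-6])
    def test_bfdp(self, z, prior):
        se = 0.05
        v, w = se ** 2, (math.log(1.5) / Z975) ** 2
        bf = math.sqrt((v + w) / v) * math.exp(-z * z * w / (2 * (v + w)))
        po = (1 - prior) / prior
        naive = bf * po / (bf * po + 1)
        assert bfdp(z * se, se, prior).value == pytest.approx(naive, rel=1e-10)


class TestEvaluateProfile:
    def test_grid_shape_matches_config(self, make_record):
        config = CredibilityConfig(priors=(0.05, 0.001),
                                   detection_ors=(1.2, 1.5))
        profile = evaluate_profile(make_record(), config)
        assert len(profile.fprp) == 4
        assert len(profile.bfdp) == 2
        assert len(profile.power) == 2

    def test_protective_and_risk_orientations_match(self, make_record):
        config = CredibilityConfig()
        risk = make_record(odds_ratio=1.25, ci_lower=1.10, ci_upper=1.42,
                           p_value=None)
        prot = make_record(odds_ratio=1 / 1.25, ci_lower=1 / 1.42,
                           ci_upper=1 / 1.10, p_value=None)
        pr, pp = evaluate_profile(risk, config), evaluate_profile(prot, config)
        for key in pr.fprp:
            assert pr.fprp[key] == pytest.approx(pp.fprp[key], rel=1e-9)
        for pi in config.priors:
            assert pr.bfdp[pi].value == pytest.approx(
                pp.bfdp[pi].value, rel=1e-9)

    def test_undefined_fprp_is_never_noteworthy(self, make_record):
        config = CredibilityConfig(priors=(0.05,), detection_ors=(1.2,))
        profile = evaluate_profile(make_record(), config)
        broken = {key: None for key in profile.fprp}
        object.__setattr__(profile, "fprp", broken)
        assert not profile.noteworthy_fprp(0.05, 1.2)

    def test_printed_p_source_changes_observed_p(self, make_record):
        rec = make_record(p_value=0.004)
        from_ci = evaluate_profile(rec, CredibilityConfig(p_source="ci"))
        from_printed = evaluate_profile(
            rec, CredibilityConfig(p_source="printed"))
        assert from_printed.p_used == 0.004
        assert from_ci.p_used != from_printed.p_used
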