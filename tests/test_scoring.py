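"""Scoring: coefficient fidelity, covariate encoding rules, linear predictor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iboxkit import (
    Assessment,
    BanffProfile,
    EncodedCovariates,
    compute_score,
    encode_covariates,
    load_coefficients,
    score_assessment,
)

FULL_HRS = {
    ("time_years", ""): 1.08,
    ("egfr", ""): 0.96,
    ("log_upcr", ""): 1.5,
    ("dsa_mfi", ">=1400"): 1.84,
    ("ifta", "2"): 1.14,
    ("ifta", "3"): 1.41,
    ("gptc", "3-4"): 1.43,
    ("gptc", "5-6"): 1.84,
    ("it", ">=3"): 1.33,
    ("cg", ">=1"): 1.47,
}
ABBREVIATED_HRS = {
    ("time_years", ""): 1.12,
    ("egfr", ""): 0.95,
    ("log_upcr", ""): 1.59,
    ("dsa_mfi", ">=1400"): 1.84,
}


class TestCoefficients:
    @pytest.mark.parametrize(
        "variant,expected", [("full", FULL_HRS), ("abbreviated", ABBREVIATED_HRS)]
    )
    def test_exponentiated_weights_match_qualified_hazard_ratios(self, variant, expected):
        coeffs = load_coefficients(variant)
        assert len(coeffs.terms) == len(expected)
        for (factor, level), hr in expected.items():
            assert math.exp(dict(((f, l), b) for f, l, b in coeffs.terms)[(factor, level)]) == pytest.approx(hr, abs=5e-13)
            assert coeffs.hazard_ratio(factor, level) == pytest.approx(hr)

    def test_abbreviated_has_no_biopsy_terms(self, abbreviated_coefficients):
        factors = {f for f, _, _ in abbreviated_coefficients.terms}
        assert factors == {"time_years", "egfr", "log_upcr", "dsa_mfi"}

    def test_reference_levels_carry_weight_zero(self, full_coefficients):
        assert full_coefficients.hazard_ratio("ifta", "0-1") == 1.0
        assert full_coefficients.hazard_ratio("dsa_mfi", "<1400") == 1.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown iBOX variant"):
            load_coefficients("extended")


class TestEncoding:
    def test_upcr_floor_before_log(self, reference_banff):
        a = Assessment("s", 1.0, 50.0, 0.01, 0.0, reference_banff)
        enc = encode_covariates(a, "full")
        assert enc.values[2] == pytest.approx(math.log(0.05))

    @pytest.mark.parametrize(
        "mfi,expected", [(1399.9, 0.0), (1400.0, 1.0), (1400.1, 1.0)]
    )
    def test_dsa_cutoff_is_inclusive_at_1400(self, mfi, expected, reference_banff):
        a = Assessment("s", 1.0, 50.0, 0.3, mfi, reference_banff)
        assert encode_covariates(a, "full").values[3] == expected

    @pytest.mark.parametrize(
        "ifta,pair", [(0, (0, 0)), (1, (0, 0)), (2, (1, 0)), (3, (0, 1))]
    )
    def test_ifta_indicator_pair(self, ifta, pair):
        banff = BanffProfile(ifta=ifta, g=0, ptc=0, i=0, t=0, cg=0)
        enc = encode_covariates(Assessment("s", 1.0, 50.0, 0.3, 0.0, banff), "full")
        assert tuple(enc.values[4:6]) == pair

    @pytest.mark.parametrize(
        "g,ptc,pair", [(1, 1, (0, 0)), (2, 1, (1, 0)), (2, 2, (1, 0)), (3, 2, (0, 1)), (3, 3, (0, 1))]
    )
    def test_gptc_categorized_on_summed_scores(self, g, ptc, pair):
        banff = BanffProfile(ifta=0, g=g, ptc=ptc, i=0, t=0, cg=0)
        enc = encode_covariates(Assessment("s", 1.0, 50.0, 0.3, 0.0, banff), "full")
        assert tuple(enc.values[6:8]) == pair

    def test_it_and_cg_indicators(self):
        banff = BanffProfile(ifta=0, g=0, ptc=0, i=2, t=1, cg=1)
        enc = encode_covariates(Assessment("s", 1.0, 50.0, 0.3, 0.0, banff), "full")
        assert enc.values[8] == 1.0  # i + t = 3
        assert enc.values[9] == 1.0  # cg >= 1

    def test_full_variant_without_biopsy_refused(self):
        a = Assessment("s", 1.0, 50.0, 0.3, 0.0, banff=None)
        with pytest.raises(ValueError, match="biopsy required"):
            encode_covariates(a, "full")
        # abbreviated still fine
        assert len(encode_covariates(a, "abbreviated").values) == 4

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="egfr"):
            Assessment("s", 1.0, -5.0, 0.3, 0.0)
        with pytest.raises(ValueError, match="lesion score|score out of range"):
            BanffProfile(ifta=4, g=0, ptc=0, i=0, t=0, cg=0)

    def test_high_egfr_warns_but_is_not_capped(self, reference_banff):
        a = Assessment("s", 1.0, 130.0, 0.3, 0.0, reference_banff)
        with pytest.warns(UserWarning, match="exceeds 120"):
            enc = encode_covariates(a, "full")
        assert enc.values[1] == 130.0


class TestScore:
    def test_all_reference_zero_covariates_give_zero_score(self, full_coefficients):
        enc = EncodedCovariates(
            variant="full",
            names=tuple(full_coefficients.terms),
            values=np.zeros(10),
        )
        assert compute_score(enc, full_coefficients).value == 0.0

    def test_worked_full_example_matches_hand_summation(self, worked_assessment):
        # ln(1.08) + 50 ln(0.96) + ln(0.3) ln(1.5) + ln(1.84) + ln(1.14)
        expected = (
            math.log(1.08) + 50 * math.log(0.96) + math.log(0.3) * math.log(1.5)
            + math.log(1.84) + math.log(1.14)
        )
        score = score_assessment(worked_assessment, "full")
        assert score.value == pytest.approx(expected, abs=1e-12)
        assert score.value == pytest.approx(-1.7115, abs=5e-4)
        assert not score.imputed

    def test_worked_abbreviated_example_matches_hand_summation(self, worked_assessment):
        expected = (
            math.log(1.12) + 50 * math.log(0.95) + math.log(0.3) * math.log(1.59)
            + math.log(1.84)
        )
        score = score_assessment(worked_assessment, "abbreviated")
        assert score.value == pytest.approx(expected, abs=1e-12)
        assert score.value == pytest.approx(-2.400, abs=5e-4)

    def test_variant_mismatch_rejected(self, worked_assessment, abbreviated_coefficients):
        enc = encode_covariates(worked_assessment, "full")
        with pytest.raises(ValueError, match="variant mismatch"):
            compute_score(enc, abbreviated_coefficients)

    def test_clinically_plausible_scores_are_negative(self, reference_banff):
        for egfr in (40, 60, 80):
            for upcr in (0.05, 0.3, 1.0):
                a = Assessment("s", 1.0, float(egfr), upcr, 500.0, reference_banff)
                assert score_assessment(a, "full").value < 0


@st.composite
def assessments(draw):
    return Assessment(
        subject_id="h",
        time_from_transplant=draw(st.floats(0.1, 10)),
        egfr=draw(st.floats(0, 120)),
        upcr=draw(st.floats(0, 10)),
        dsa_mfi=draw(st.floats(0, 20000)),
        banff=BanffProfile(
            ifta=draw(st.integers(0, 3)), g=draw(st.integers(0, 3)),
            ptc=draw(st.integers(0, 3)), i=draw(st.integers(0, 3)),
            t=draw(st.integers(0, 3)), cg=draw(st.integers(0, 3)),
        ),
    )


class TestScoreProperties:
    @settings(derandomize=True, max_examples=50)
    @given(assessments(), st.floats(1, 30))
    def test_score_strictly_decreasing_in_egfr(self, a, delta):
        import dataclasses

        higher = dataclasses.replace(a, egfr=a.egfr + delta)
        for variant in ("full", "abbreviated"):
            assert score_assessment(higher, variant).value < score_assessment(a, variant).value

    @settings(derandomize=True, max_examples=50)
    @given(assessments())
    def test_dsa_flip_adds_exactly_ln_1_84(self, a):
        import dataclasses

        neg = dataclasses.replace(a, dsa_mfi=0.0)
        pos = dataclasses.replace(a, dsa_mfi=1400.0)
        for variant in ("full", "abbreviated"):
            gap = score_assessment(pos, variant).value - score_assessment(neg, variant).value
            assert gap == pytest.approx(math.log(1.84), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(assessments())
    def test_worsening_any_banff_lesion_never_decreases_full_score(self, a):
        import dataclasses

        base = score_assessment(a, "full").value
        for lesion in ("ifta", "g", "ptc", "i", "t", "cg"):
            v = getattr(a.banff, lesion)
            if v == 3:
                continue
            worse = dataclasses.replace(a, banff=dataclasses.replace(a.banff, **{lesion: v + 1}))
            assert score_assessment(worse, "full").value >= base - 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(assessments())
    def test_encode_compute_is_pure(self, a):
        for variant in ("full", "abbreviated"):
            s1 = score_assessment(a, variant).value
            s2 = score_assessment(a, variant).value
            assert s1 == s2
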