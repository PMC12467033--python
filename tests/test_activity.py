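"""Inhibition rates, viability, IC50 estimation, reversibility, stability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enzybind as eb
from enzybind.errors import BracketingError, FitError, InvariantError


class TestInhibitionRate:
    @pytest.mark.parametrize(
        "a1,a2,a3,a4,expected",
        [
            (0.5, 0.1, 0.5, 0.1, 0.0),   # sample equals blank: no inhibition
            (0.3, 0.3, 0.9, 0.1, 100.0),  # A1 == A2: full inhibition
            (0.5, 0.1, 0.9, 0.1, 50.0),
        ],
    )
    def test_known_absorbance_quadruplets(self, a1, a2, a3, a4, expected):
        rate = eb.inhibition_rate(eb.AssayAbsorbances(a1, a2, a3, a4))
        assert rate == pytest.approx(expected, abs=1e-12)

    def test_equal_blank_pair_is_an_error(self):
        with pytest.raises(InvariantError, match="A3 - A4"):
            eb.inhibition_rate(eb.AssayAbsorbances(0.5, 0.1, 0.4, 0.4))

    @given(st.floats(min_value=0.1, max_value=5.0))
    def test_rate_is_affine_in_sample_absorbance(self, scale):
        base = eb.inhibition_rate(eb.AssayAbsorbances(0.5, 0.1, 0.9, 0.1))
        scaled = eb.inhibition_rate(
            eb.AssayAbsorbances(0.1 + (0.5 - 0.1) * scale, 0.1, 0.9, 0.1)
        )
        assert 100.0 - scaled == pytest.approx((100.0 - base) * scale, rel=1e-9)


class TestCellViability:
    @pytest.mark.parametrize(
        "a_s,a_c,a_b,expected",
        [(1.1, 1.1, 0.1, 100.0), (0.1, 1.1, 0.1, 0.0), (0.6, 1.1, 0.1, 50.0)],
    )
    def test_known_triplets(self, a_s, a_c, a_b, expected):
        v = eb.cell_viability(eb.ViabilityAbsorbances(a_s, a_c, a_b))
        assert v == pytest.approx(expected, abs=1e-12)

    def test_equal_control_pair_is_an_error(self):
        with pytest.raises(InvariantError):
            eb.cell_viability(eb.ViabilityAbsorbances(0.5, 0.2, 0.2))


def _series(conc, inhib):
    return eb.DoseResponseSeries("TAPP", "alpha_amylase", tuple(conc), tuple(inhib))


class TestEstimateIC50:
    def test_exact_crossing_point_is_returned_verbatim(self):
        s = _series((1, 5, 10, 20), (10.0, 30.0, 50.0, 80.0))
        assert eb.estimate_ic50(s).ic50 == 10.0

    def test_two_point_interpolation(self):
        s = _series((1, 5, 20, 40), (5.0, 20.0, 80.0, 95.0))
        # bracketing pair (5, 20%) -> (20, 80%): midway at 12.5
        assert eb.estimate_ic50(s).ic50 == pytest.approx(12.5, rel=1e-12)

    def test_unbracketed_50_percent_raises(self):
        s = _series((1, 2, 3, 4), (60.0, 70.0, 80.0, 90.0))
        with pytest.raises(BracketingError):
            eb.estimate_ic50(s)

    def test_logistic_fit_recovers_noiseless_truth(self):
        truth = eb.GroundTruth("dose_response", {"ic50": 13.03, "hill": 1.2})
        grid = np.geomspace(1.0, 200.0, 10)
        series = eb.gen_dose_response(truth, conc_grid=grid)
        res = eb.estimate_ic50(series, method="four_parameter_logistic")
        assert res.ic50 == pytest.approx(13.03, rel=1e-6)
        assert res.fit_quality > 0.999999

    def test_logistic_fit_is_robust_to_replicate_noise(self):
        # 2 percentage points of scatter: median |error| stays below 5%
        errors = []
        for seed in range(200):
            truth = eb.GroundTruth(
                "dose_response", {"ic50": 13.03, "hill": 1.2},
                noise_sd=2.0, seed=seed,
            )
            series = eb.gen_dose_response(truth, conc_grid=np.geomspace(1, 200, 10))
            res = eb.estimate_ic50(series, method="four_parameter_logistic")
            errors.append(abs(res.ic50 - 13.03) / 13.03)
        assert np.median(errors) <= 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(InvariantError):
            eb.estimate_ic50(_series((1, 5, 10), (10.0, 40.0, 60.0)))


def _rev(conc, slope, intercept=0.0):
    e = (100.0, 200.0, 300.0, 400.0)
    return eb.ReversibilitySeries(
        conc, e, tuple(intercept + slope * x for x in e)
    )


class TestReversibility:
    def test_origin_lines_with_falling_slopes_are_reversible(self):
        verdict = eb.reversibility_verdict(
            [_rev(0.0, 2.0), _rev(5.0, 1.5), _rev(10.0, 1.0)]
        )
        assert verdict.reversible
        assert verdict.slopes == pytest.approx((2.0, 1.5, 1.0))

    def test_large_intercept_flags_not_through_origin(self):
        big = 0.5 * 400.0 * 2.0  # half the maximum velocity
        verdict = eb.reversibility_verdict(
            [_rev(0.0, 2.0), _rev(5.0, 1.5, intercept=big)]
        )
        assert not verdict.reversible
        assert "not_through_origin" in verdict.flags

    def test_non_monotone_slopes_flagged(self):
        verdict = eb.reversibility_verdict(
            [_rev(0.0, 1.0), _rev(5.0, 1.4), _rev(10.0, 0.9)]
        )
        assert "slopes_not_strictly_decreasing" in verdict.flags

    def test_point_order_within_a_line_is_irrelevant(self):
        a = eb.ReversibilitySeries(0.0, (100, 200, 300), (1.0, 2.0, 3.0))
        b = eb.ReversibilitySeries(0.0, (300, 100, 200), (3.0, 1.0, 2.0))
        va = eb.reversibility_verdict([a, _rev(5.0, 0.5)])
        vb = eb.reversibility_verdict([b, _rev(5.0, 0.5)])
        assert va.slopes == pytest.approx(vb.slopes)

    def test_degenerate_line_raises(self):
        bad = eb.ReversibilitySeries(0.0, (200, 200, 200), (1.0, 1.1, 0.9))
        with pytest.raises(FitError, match="rank-deficient"):
            eb.reversibility_verdict([bad, _rev(5.0, 0.5)])


class TestStabilityProfile:
    def test_identical_conditions_have_zero_range(self):
        a = eb.AssayAbsorbances(0.5, 0.1, 0.9, 0.1)
        profile = eb.stability_profile({"30C": a, "40C": a, "50C": a})
        assert profile.rate_range == 0.0

    def test_elevated_condition_is_reported_as_maximum(self):
        normal = eb.AssayAbsorbances(0.5, 0.1, 0.9, 0.1)  # 50%
        strong = eb.AssayAbsorbances(0.3, 0.1, 0.9, 0.1)  # 75%
        profile = eb.stability_profile({"pH4": normal, "pH7": normal, "pH9": strong})
        assert profile.max_condition == "pH9"
        assert profile.rate_range == pytest.approx(25.0)

    def test_alkaline_maximum_summary(self):
        # rates rising toward alkaline pH flag the alkaline condition
        grid = {
            f"pH{p}": eb.AssayAbsorbances(0.9 - 0.05 * p, 0.1, 0.9, 0.1)
            for p in (2, 4, 6, 8, 10)
        }
        assert eb.stability_profile(grid).max_condition == "pH10"
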