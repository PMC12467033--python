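"""Inner-filter correction, Stern-Volmer fitting, mechanism classification
and double-log binding analysis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enzybind as eb
from enzybind import datasets
from enzybind.errors import DataQualityError, InvariantError


def _titration(q, f, t=298.0, a_ex=None, a_em=None):
    return eb.QuenchTitration(t, tuple(q), tuple(f), a_ex, a_em)


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self):
        t = _titration((0, 1e-5), (100.0, 80.0),
                       a_ex=(0.0, 0.0), a_em=(0.0, 0.0))
        assert eb.inner_filter_correct(t).intensity == (100.0, 80.0)

    def test_closed_form_correction(self):
        t = _titration((0, 1e-5), (100.0, 100.0),
                       a_ex=(0.2, 0.2), a_em=(0.2, 0.2))
        corrected = eb.inner_filter_correct(t)
        assert corrected.intensity[0] == pytest.approx(100.0 * math.exp(0.2),
                                                       rel=1e-12)

    def test_correction_zeroes_absorbances_making_it_idempotent(self):
        t = _titration((0, 1e-5), (100.0, 80.0),
                       a_ex=(0.1, 0.1), a_em=(0.1, 0.1))
        once = eb.inner_filter_correct(t)
        twice = eb.inner_filter_correct(once)
        assert once.intensity == twice.intensity

    def test_missing_absorbances_pass_through(self):
        t = _titration((0, 1e-5), (100.0, 80.0))
        assert eb.inner_filter_correct(t) is t


class TestSternVolmer:
    def test_exact_linear_data_recovered(self):
        q = np.array([0, 1e-5, 2e-5, 3e-5, 4e-5])
        f0 = 600.0
        f = f0 / (1.0 + 2e4 * q)
        res = eb.stern_volmer_fit(_titration(q, f))
        assert res.ksv == pytest.approx(2e4, rel=1e-9)
        assert res.model == "linear"
        assert res.curvature_score == pytest.approx(0.0, abs=1e-9)
        assert res.kq == pytest.approx(res.ksv / 1e-8, rel=1e-12)

    def test_constant_intensity_gives_zero_ksv(self):
        res = eb.stern_volmer_fit(
            _titration((0, 1e-5, 2e-5, 3e-5), (500.0,) * 4)
        )
        assert res.ksv == 0.0

    def test_upward_curvature_selects_exponential_form(self):
        # F0/F = exp(Ksv*Q) with Ksv*Qmax = 0.8 bends visibly upward
        q = np.linspace(0, 4e-5, 6)
        ksv = 2e4
        f0 = 500.0
        f = f0 * np.exp(-ksv * q)
        res = eb.stern_volmer_fit(_titration(q, f))
        assert res.model == "exponential"
        assert res.ksv == pytest.approx(ksv, rel=1e-9)
        assert res.curvature_score > 0.05

    def test_fluorescence_enhancement_is_a_data_error(self):
        with pytest.raises(DataQualityError):
            eb.stern_volmer_fit(
                _titration((0, 1e-5, 2e-5, 3e-5), (100.0, 110.0, 120.0, 130.0))
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(InvariantError):
            eb.stern_volmer_fit(_titration((0, 1e-5, 2e-5), (100.0, 90.0, 80.0)))


def _results(ksv_by_t, model="linear", tau0=1e-8):
    return [
        eb.QuenchResult(ksv=k, kq=k / tau0, model=m, r_squared=1.0,
                        curvature_score=0.0, temperature=t)
        for (t, k), m in zip(ksv_by_t, model if isinstance(model, list)
                             else [model] * len(ksv_by_t))
    ]


class TestClassifyMechanism:
    def test_published_amylase_pattern_is_static(self):
        # Ksv falling 4.07 -> 3.07 x1e4 over 298 -> 310 K with Kq ~ 1e12
        results = _results([(298, 4.07e4), (304, 3.37e4), (310, 3.07e4)])
        assert eb.classify_mechanism(results) == "static"

    def test_falling_ksv_with_curved_plot_is_mixed_static_dominant(self):
        results = _results(
            [(298, 4.32e4), (304, 3.36e4), (310, 3.29e4)],
            model=["exponential", "linear", "linear"],
        )
        assert eb.classify_mechanism(results) == "mixed_static_dominant"

    def test_rising_ksv_or_slow_kq_is_dynamic(self):
        rising = _results([(298, 1e4), (304, 2e4), (310, 3e4)])
        assert eb.classify_mechanism(rising) == "dynamic"
        slow = _results([(298, 3e1), (304, 2e1), (310, 1e1)])  # Kq ~ 1e9
        assert eb.classify_mechanism(slow) == "dynamic"

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(InvariantError):
            eb.classify_mechanism(_results([(298, 2e4), (298, 1e4)]))

    def test_static_for_every_threshold_below_min_kq(self):
        results = _results([(298, 4.0e4), (310, 3.0e4)])
        min_kq = min(r.kq for r in results)
        for threshold in (min_kq / 10, min_kq / 2, min_kq * 0.99):
            assert eb.classify_mechanism(results, threshold) == "static"


class TestDoubleLog:
    def test_constructed_linear_case(self):
        q = np.array([0, 1e-5, 2e-5, 5e-5, 1e-4])
        f0 = 300.0
        f = f0 / (1.0 + 1e4 * q)  # (F0-F)/F = 1e4 * Q exactly
        fit = eb.double_log_fit(_titration(q, f))
        assert fit.n == pytest.approx(1.0, rel=1e-9)
        assert fit.ka == pytest.approx(1e4, rel=1e-9)

    def test_generator_inverse_recovers_published_scale_parameters(self):
        truth = eb.GroundTruth("quench", {"ka": 3.39e5, "n": 1.16})
        t = eb.gen_quench_titration(
            truth, f0=400.0, q_grid=np.linspace(0, 4e-5, 7), temperature=310.0
        )
        fit = eb.double_log_fit(t)
        assert fit.ka == pytest.approx(3.39e5, rel=1e-9)
        assert fit.n == pytest.approx(1.16, rel=1e-9)

    @given(
        log_ka=st.floats(min_value=3.0, max_value=7.0),
        n=st.floats(min_value=0.5, max_value=2.0),
    )
    def test_inverse_pair_identity_over_parameter_grid(self, log_ka, n):
        truth = eb.GroundTruth("quench", {"ka": 10.0**log_ka, "n": n})
        t = eb.gen_quench_titration(
            truth, f0=100.0, q_grid=np.linspace(0, 5e-5, 6)
        )
        fit = eb.double_log_fit(t)
        assert fit.ka == pytest.approx(10.0**log_ka, rel=1e-9)
        assert fit.n == pytest.approx(n, rel=1e-9)

    def test_unquenched_point_reported_with_index(self):
        with pytest.raises(DataQualityError, match=r"\[2\]"):
            eb.double_log_fit(
                _titration((0, 1e-5, 2e-5, 3e-5), (100.0, 100.0, 90.0, 80.0))
            )

    def test_single_site_data_yields_unit_stoichiometry(self):
        truth = eb.GroundTruth("quench", {"ka": 1e5, "n": 1.0})
        t = eb.gen_quench_titration(truth, f0=100.0,
                                    q_grid=np.linspace(0, 5e-5, 6))
        assert eb.double_log_fit(t).n == pytest.approx(1.0, abs=1e-9)


def test_recovered_ka_decreases_with_temperature_for_exothermic_binding():
    """Complexes destabilize on heating when ΔH < 0: Ka(T) recovered from
    three synthetic titrations is strictly decreasing."""
    truth = eb.GroundTruth("vant_hoff", {"dh": -9.7e4, "ds": -207.0})
    recovered = []
    for temp, ka in eb.gen_vant_hoff(truth):
        tit = eb.gen_quench_titration(
            eb.GroundTruth("quench", {"ka": ka, "n": 1.0}),
            f0=100.0, q_grid=np.linspace(0, 2e-5, 6), temperature=temp,
        )
        recovered.append(eb.double_log_fit(tit).ka)
    assert recovered[0] > recovered[1] > recovered[2]
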