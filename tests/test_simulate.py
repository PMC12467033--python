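"""Forward-model generators: closed forms, determinism and contracts."""

import numpy as np
import pytest

import enzybind as eb
from enzybind.errors import InvariantError, ParameterError


class TestGroundTruth:
    def test_missing_stage_parameters_rejected(self):
        with pytest.raises(InvariantError, match="missing"):
            eb.GroundTruth(stage="kinetics", parameters={"km": 1.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(InvariantError):
            eb.GroundTruth(stage="vant_hoff",
                           parameters={"dh": 0, "ds": 0}, noise_sd=-1)


class TestGenKinetics:
    def test_no_inhibitor_reduces_to_michaelis_menten(self, mixed_truth):
        series = eb.gen_kinetics(mixed_truth, inhibitor_grid=(0.0, 5.0))[0]
        s = np.array(series.substrate)
        expected = 0.1826 * s / (3.9047 + s)
        assert np.allclose(series.velocity, expected, rtol=1e-12)

    def test_zero_noise_is_seed_independent(self, mixed_truth):
        a = eb.gen_kinetics(mixed_truth)
        b = eb.gen_kinetics(
            eb.GroundTruth("kinetics", dict(mixed_truth.parameters), seed=999)
        )
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_seed_fixes_noisy_output_exactly(self, mixed_truth):
        noisy = eb.GroundTruth(
            "kinetics", dict(mixed_truth.parameters), noise_sd=0.002, seed=42
        )
        assert eb.gen_kinetics(noisy) == eb.gen_kinetics(noisy)

    def test_apparent_constants_trend_matches_mixed_inhibition(self, mixed_truth):
        # mixed inhibition with Ki < Kis: apparent Km rises, apparent Vmax falls
        series = eb.gen_kinetics(mixed_truth)
        fits = [eb.fit_kinetics(s) for s in series]
        km = [f.km for f in fits]
        vmax = [f.vmax for f in fits]
        assert all(a < b for a, b in zip(km, km[1:]))
        assert all(a > b for a, b in zip(vmax, vmax[1:]))

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ParameterError):
            eb.inhibited_velocity([1.0], 0.0, km=-1, vmax=0.1, ki=1.0)

    def test_mixed_without_kis_rejected(self):
        with pytest.raises(ParameterError):
            eb.inhibited_velocity([1.0], 1.0, km=1, vmax=0.1, ki=1.0,
                                  inhibition_type="mixed")


class TestGenQuench:
    def test_zero_quencher_gives_f0(self):
        truth = eb.GroundTruth("quench", {"ksv": 4.07e4})
        t = eb.gen_quench_titration(truth, f0=500.0, q_grid=(0, 1e-5, 2e-5, 3e-5))
        assert t.intensity[0] == 500.0

    def test_binding_mode_closed_form_half_intensity(self):
        # (F0-F)/F = Ka*Q^n; Ka=1e5, n=1, Q=1e-5 -> ratio 1 -> F = F0/2
        truth = eb.GroundTruth("quench", {"ka": 1e5, "n": 1.0})
        t = eb.gen_quench_titration(truth, f0=100.0, q_grid=(0, 1e-5))
        assert t.intensity[1] == pytest.approx(50.0, rel=1e-12)

    def test_mode_must_be_exactly_one_of_ksv_or_ka_n(self):
        with pytest.raises(ParameterError):
            eb.gen_quench_titration(
                eb.GroundTruth("quench", {"ksv": 1e4, "ka": 1e5, "n": 1.0}),
                f0=1.0, q_grid=(0, 1e-5),
            )
        with pytest.raises(ParameterError):
            eb.gen_quench_titration(
                eb.GroundTruth("quench", {"ka": 1e5}), f0=1.0, q_grid=(0, 1e-5)
            )

    def test_inner_filter_attenuation_is_inverted_exactly(self):
        truth = eb.GroundTruth("quench", {"ksv": 2e4})
        grid = (0, 1e-5, 2e-5, 4e-5)
        clean = eb.gen_quench_titration(truth, f0=800.0, q_grid=grid)
        attenuated = eb.gen_quench_titration(
            truth, f0=800.0, q_grid=grid, inner_filter=(0.1, 0.1)
        )
        corrected = eb.inner_filter_correct(attenuated)
        assert np.allclose(corrected.intensity, clean.intensity, rtol=1e-12)


class TestGenVantHoff:
    def test_zero_enthalpy_entropy_gives_unit_ka(self):
        pairs = eb.gen_vant_hoff(eb.GroundTruth("vant_hoff", {"dh": 0.0, "ds": 0.0}))
        assert all(ka == pytest.approx(1.0, rel=1e-14) for _, ka in pairs)

    def test_single_temperature_rejected(self):
        with pytest.raises(ParameterError):
            eb.gen_vant_hoff(
                eb.GroundTruth("vant_hoff", {"dh": -1e4, "ds": -10.0}),
                t_grid=(298.0,),
            )

    def test_published_thermodynamics_regenerate_published_ka(self):
        # ΔH = -97.17 kJ/mol, ΔS = -207.25 J/mol/K reproduce the measured
        # binding constants 15.49/8.01/3.39 x1e5 L/mol at 298/304/310 K up
        # to the scatter of the regression they came from (R² ≈ 0.98, i.e.
        # Ka residuals of several percent)
        truth = eb.GroundTruth("vant_hoff", {"dh": -97170.0, "ds": -207.25})
        pairs = eb.gen_vant_hoff(truth, t_grid=(298.0, 304.0, 310.0))
        expected = [15.49e5, 8.01e5, 3.39e5]
        for (_, ka), ref in zip(pairs, expected):
            assert ka == pytest.approx(ref, rel=0.10)


class TestGenDoseResponse:
    def test_inhibition_is_50_percent_at_ic50(self):
        truth = eb.GroundTruth("dose_response", {"ic50": 13.03, "hill": 1.2})
        series = eb.gen_dose_response(truth, conc_grid=(1.0, 13.03, 50.0))
        assert series.inhibition[1] == pytest.approx(50.0, rel=1e-12)

    def test_unit_hill_at_three_times_ic50_gives_75_percent(self):
        truth = eb.GroundTruth("dose_response", {"ic50": 10.0, "hill": 1.0})
        series = eb.gen_dose_response(truth, conc_grid=(30.0,))
        assert series.inhibition[0] == pytest.approx(75.0, rel=1e-12)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ParameterError):
            eb.gen_dose_response(
                eb.GroundTruth("dose_response", {"ic50": -1.0, "hill": 1.0}),
                conc_grid=(1.0, 2.0),
            )


class TestGenSpectra:
    def test_single_alpha_helix_gaussian_classifies_fully(self):
        truth = eb.GroundTruth(
            "ftir", {"peaks": [{"center": 1655.0, "sigma": 6.0, "area": 1.0}]}
        )
        spec = eb.gen_spectra(truth, "ftir")
        peaks = eb.deconvolve(eb.extract_amide_I(spec))
        structure = eb.assign_structure(peaks)
        assert structure.fractions["alpha_helix"] == pytest.approx(100.0, abs=0.1)

    def test_ftir_center_outside_amide_window_rejected(self):
        truth = eb.GroundTruth(
            "ftir", {"peaks": [{"center": 1500.0, "sigma": 6.0, "area": 1.0}]}
        )
        with pytest.raises(ParameterError):
            eb.gen_spectra(truth, "ftir")

    def test_synchronous_series_realizes_requested_blue_shift(self):
        truth = eb.GroundTruth(
            "synchronous",
            {
                "mode": "sync60",
                "center_nm": 330.0,
                "center_step_nm": -3.0,
                "sigma_nm": 10.0,
                "amplitude": 100.0,
                "quench_factors": (1.0, 0.8, 0.6, 0.5),
                "concentrations": (0.0, 2.0, 4.0, 6.0),
            },
        )
        series = eb.gen_spectra(truth, "synchronous")
        shift = eb.peak_shift(series)
        assert shift.direction == "blue"
        assert shift.magnitude_nm == pytest.approx(9.0, abs=0.1)

    def test_eem_contains_constructed_apexes(self):
        truth = eb.GroundTruth(
            "eem",
            {"peaks": [
                {"ex": 280.0, "em": 352.0, "amplitude": 300.0},
                {"ex": 236.0, "em": 352.0, "amplitude": 60.0},
            ]},
        )
        eem = eb.gen_spectra(truth, "eem")
        apexes = {(p.ex, p.em) for p in eb.eem_peaks(eem)}
        assert (280.0, 352.0) in apexes
        assert (236.0, 352.0) in apexes
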