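import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentaspec import (
    MeltingCurve,
    Spectrum,
    TwoStateModel,
    baseline_correct,
    classify_signature,
    compute_tds,
    derivative_curve,
    estimate_tm,
    generate_band_spectrum,
    hysteresis,
    simulate_equilibrium_melt,
    standard_protocol,
)
from pentaspec.errors import (
    ChannelError,
    ConfigurationError,
    DetectionError,
    InsufficientDataError,
    PairingError,
    ParameterError,
)


def heating_curve(values, start=30.0, step=0.25, wavelength=295.0):
    temps = start + step * np.arange(len(values))
    return MeltingCurve(temps, np.asarray(values, float), wavelength, "heating", 0.2)


def logistic_curve(center=50.0, width=2.0, start=30.0, step=0.25, n=161):
    temps = start + step * np.arange(n)
    return heating_curve(1.0 / (1.0 + np.exp(-(temps - center) / width)), start, step)


class TestBaselineCorrect:
    def test_zero_reference_leaves_curve_unchanged(self):
        c = logistic_curve()
        ref = heating_curve(np.zeros(len(c)), wavelength=335.0)
        out = baseline_correct(c, ref)
        np.testing.assert_array_equal(out.absorbance, c.absorbance)
        assert out.wavelength_nm == 295.0

    def test_self_reference_gives_zero(self):
        c = logistic_curve()
        ref = MeltingCurve(c.temperatures_C, c.absorbance, 335.0, "heating", 0.2)
        assert np.all(baseline_correct(c, ref).absorbance == 0.0)

    def test_constant_reference_shifts_pointwise(self):
        c = logistic_curve()
        ref = heating_curve(np.full(len(c), 0.01), wavelength=335.0)
        np.testing.assert_allclose(
            baseline_correct(c, ref).absorbance, c.absorbance - 0.01, rtol=0, atol=1e-15
        )

    def test_reference_on_offset_grid_is_interpolated(self):
        c = logistic_curve()
        # reference sampled on a shifted, denser grid covering the curve
        temps = np.arange(29.0, 71.5, 0.2)
        ref = MeltingCurve(temps, 0.001 * temps, 335.0, "heating", 0.2)
        out = baseline_correct(c, ref)
        np.testing.assert_allclose(
            out.absorbance, c.absorbance - 0.001 * c.temperatures_C, atol=1e-12
        )

    def test_direction_mismatch_rejected(self):
        c = logistic_curve()
        ref = MeltingCurve(
            c.temperatures_C[::-1], np.zeros(len(c)), 335.0, "cooling", 0.2
        )
        with pytest.raises(PairingError):
            baseline_correct(c, ref)


class TestComputeTds:
    def grid_spec(self, values, temperature, grid=None):
        grid = np.arange(220.0, 321.0) if grid is None else grid
        return Spectrum(grid, values, temperature, "ABS")

    def test_identical_spectra_give_zero(self):
        s = self.grid_spec(np.random.default_rng(0).normal(size=101), 5.0)
        tds = compute_tds(s, s)
        assert np.all(tds.values == 0.0)
        assert tds.is_tds()

    def test_constant_offset(self):
        low = self.grid_spec(np.linspace(0.2, 0.8, 101), 5.0)
        high = self.grid_spec(low.values + 0.1, 95.0)
        np.testing.assert_allclose(compute_tds(high, low).values, 0.1, atol=1e-15)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = self.grid_spec(rng.normal(size=101), 95.0)
        b = self.grid_spec(rng.normal(size=101), 5.0)
        np.testing.assert_array_equal(compute_tds(a, b).values, -compute_tds(b, a).values)

    def test_gaussian_bands_match_pointwise_subtraction(self):
        high = generate_band_spectrum("G4_TDS", channel="ABS", temperature_C=95.0)
        low_model = generate_band_spectrum("parallel_G4_CD", channel="ABS", temperature_C=5.0)
        tds = compute_tds(high, low_model)
        np.testing.assert_allclose(tds.values, high.values - low_model.values, atol=1e-15)

    def test_channel_mismatch_rejected(self):
        abs_spec = self.grid_spec(np.ones(101), 95.0)
        cd_spec = Spectrum(abs_spec.wavelengths_nm, np.ones(101), 5.0, "CD")
        with pytest.raises(ChannelError):
            compute_tds(abs_spec, cd_spec)

    def test_normalized_tds_has_unit_peak(self):
        high = self.grid_spec(np.linspace(0.0, 0.5, 101), 95.0)
        low = self.grid_spec(np.zeros(101), 5.0)
        assert np.max(np.abs(compute_tds(high, low, normalize=True).values)) == 1.0


class TestClassifySignature:
    @pytest.fixture
    def templates(self):
        return {
            name.removesuffix("_CD"): generate_band_spectrum(name)
            for name in ("parallel_G4_CD", "antiparallel_G4_CD", "non_G4_duplex_CD")
        }

    def test_exact_template_scores_one(self, templates):
        call = classify_signature(generate_band_spectrum("parallel_G4_CD"), templates)
        assert call.label == "parallel_G4"
        assert call.score == pytest.approx(1.0)

    def test_zero_spectrum_unclassified(self, templates):
        flat = Spectrum(np.arange(220.0, 336.0), np.zeros(116), 5.0, "CD")
        call = classify_signature(flat, templates)
        assert call.label == "unclassified"
        assert call.score == 0.0

    def test_noisy_parallel_spectrum_matches_dot_product_oracle(self, templates, rng):
        spec = generate_band_spectrum("parallel_G4_CD", noise_sd=1.0, seed=99)
        call = classify_signature(spec, templates)
        assert call.label == "parallel_G4"
        # independent oracle: plain cosine of mean-centered vectors
        u = templates["parallel_G4"].values
        v = spec.values
        u = u - u.mean()
        v = v - v.mean()
        expected = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        assert call.score == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, templates):
        spec = generate_band_spectrum("antiparallel_G4_CD", noise_sd=0.5, seed=3)
        a = classify_signature(spec, templates)
        scaled = Spectrum(spec.wavelengths_nm, 7.5 * spec.values + 2.0, 5.0, "CD")
        b = classify_signature(scaled, templates)
        assert a.label == b.label
        assert a.score == pytest.approx(b.score, abs=1e-12)

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_signature(generate_band_spectrum("parallel_G4_CD"), {})


class TestDerivativeCurve:
    def test_exact_on_linear(self):
        c = heating_curve(3.0 + 0.02 * (30.0 + 0.25 * np.arange(100)))
        np.testing.assert_allclose(derivative_curve(c), 0.02, atol=1e-10)

    def test_exact_on_quadratic_interior(self):
        temps = 30.0 + 0.25 * np.arange(161)
        c = heating_curve((temps - 50.0) ** 2)
        d = derivative_curve(c)
        np.testing.assert_allclose(d, 2.0 * (temps - 50.0), atol=1e-8)

    def test_matches_central_difference_on_vant_hoff(self):
        # local-quadratic smoothing over an 11-point window attenuates the
        # derivative peak slightly (~2% here); the extremum position, which
        # Tm estimation uses, must agree with the oracle to one grid step
        model = TwoStateModel(-50.0, -50000.0 / (60.0 + 273.15), folded_baseline=(0.0, 0.0),
                              unfolded_baseline=(1.0, 0.0))
        curve = simulate_equilibrium_melt(model, standard_protocol("heating"))
        d = derivative_curve(curve)
        t = curve.temperatures_C
        central = np.gradient(curve.absorbance, t)
        scale = np.max(np.abs(central))
        assert np.max(np.abs(d[5:-5] - central[5:-5])) < 0.02 * scale
        assert abs(t[np.argmax(np.abs(d))] - t[np.argmax(np.abs(central))]) <= 0.5

    def test_window_larger_than_series_rejected(self):
        c = heating_curve(np.zeros(9))
        with pytest.raises(ParameterError):
            derivative_curve(c, window_pts=11)


class TestEstimateTm:
    def test_flat_noisy_curve_has_no_transition(self, rng):
        c = heating_curve(0.3 + rng.normal(0.0, 1e-4, size=200))
        res = estimate_tm(c)
        assert not res.transition_detected
        assert res.tm_C is None

    def test_symmetric_logistic_centered_at_50(self):
        res = estimate_tm(logistic_curve(center=50.0))
        assert res.transition_detected
        assert res.tm_C == pytest.approx(50.0, abs=0.25)  # one grid step
        assert res.extremum_sign == "max"

    def test_vant_hoff_curve_within_half_degree(self):
        model = TwoStateModel(-50.0, -50000.0 / (60.0 + 273.15), folded_baseline=(0.0, 0.0),
                              unfolded_baseline=(1.0, 0.0))
        curve = simulate_equilibrium_melt(model, standard_protocol("heating"))
        res = estimate_tm(curve)
        assert res.transition_detected
        assert res.tm_C == pytest.approx(60.0, abs=0.5)
        # the derivative argmax agrees with a dense numeric oracle
        from pentaspec import equilibrium_fraction_folded

        dense_t = np.linspace(40.0, 80.0, 8001)
        theta = np.array([equilibrium_fraction_folded(model, t) for t in dense_t])
        oracle = dense_t[np.argmax(np.abs(np.gradient(1.0 - theta, dense_t)))]
        assert res.tm_C == pytest.approx(oracle, abs=0.5)

    def test_falling_transition_records_min_sign(self):
        c = logistic_curve()
        falling = MeltingCurve(c.temperatures_C, 1.0 - c.absorbance, 295.0, "heating", 0.2)
        assert estimate_tm(falling).extremum_sign == "min"

    def test_amplitude_from_extreme_medians(self):
        res = estimate_tm(logistic_curve())
        assert res.amplitude == pytest.approx(1.0, abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_tm(heating_curve(np.zeros(24)))

    @given(offset=st.floats(-5.0, 5.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_under_affine_signal_transforms(self, offset, scale):
        base = logistic_curve()
        res0 = estimate_tm(base)
        transformed = MeltingCurve(
            base.temperatures_C, scale * base.absorbance + offset, 295.0, "heating", 0.2
        )
        res1 = estimate_tm(transformed)
        assert res1.transition_detected == res0.transition_detected
        assert res1.tm_C == res0.tm_C
        assert res1.amplitude == pytest.approx(scale * res0.amplitude, rel=1e-9)


class TestHysteresis:
    def mk(self, tm):
        return estimate_tm(logistic_curve(center=tm))

    def test_midpoint_and_flag(self):
        h = hysteresis(self.mk(49.0), self.mk(57.0))
        assert h.midpoint_C == pytest.approx(53.0)
        assert h.hysteretic

    def test_identical_branches_not_hysteretic(self):
        h = hysteresis(self.mk(60.0), self.mk(60.0))
        assert h.midpoint_C == 60.0
        assert not h.hysteretic

    def test_missing_transition_rejected(self):
        flat = estimate_tm(heating_curve(np.full(100, 0.3)))
        with pytest.raises(DetectionError):
            hysteresis(self.mk(50.0), flat)
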