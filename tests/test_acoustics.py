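"""Beampatterns, disc reflections, spectrum superposition and inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leafecho.acoustics import (
    FrequencyBand,
    ReflectorView,
    SonarBeam,
    beam_gain,
    beamwidth_to_sigma,
    echo,
    facet_amplitude,
    facet_phase,
    impulse_response,
    in_mainlobe,
    leaf_gain,
    reflector_view,
    synthesize_spectrum,
)
from leafecho.geometry import LeafDisc

V = 343.0


class TestReflectorView:
    def test_on_boresight_facing_disc(self, beam):
        disc = LeafDisc([1.0, 0.0, 0.0], 0.02, [-1.0, 0.0, 0.0])
        v = reflector_view(beam, disc)
        assert v.r == pytest.approx(1.0)
        assert v.az == pytest.approx(0.0, abs=1e-12)
        assert v.el == pytest.approx(0.0, abs=1e-12)
        assert v.beta == pytest.approx(0.0, abs=1e-7)

    def test_normal_perpendicular_to_line_of_sight(self, beam):
        disc = LeafDisc([1.0, 0.0, 0.0], 0.02, [0.0, 1.0, 0.0])
        assert reflector_view(beam, disc).beta == pytest.approx(math.pi / 2)

    def test_two_sided_disc_folds_beta(self, beam):
        facing = LeafDisc([1.0, 0.0, 0.0], 0.02, [-1.0, 0.0, 0.0])
        away = LeafDisc([1.0, 0.0, 0.0], 0.02, [1.0, 0.0, 0.0])
        assert reflector_view(beam, facing).beta == pytest.approx(
            reflector_view(beam, away).beta
        )

    def test_disc_behind_sonar_gets_large_azimuth(self, beam):
        v = reflector_view(beam, LeafDisc([-1.0, 0.1, 0.0], 0.02, [1.0, 0.0, 0.0]))
        assert abs(v.az) > math.pi / 2
        assert not in_mainlobe(beam, v.az, v.el)

    def test_zero_range_rejected(self, beam):
        with pytest.raises(ValueError):
            reflector_view(beam, LeafDisc([0.0, 0.0, 0.0], 0.02, [1.0, 0.0, 0.0]))


class TestBeamGain:
    def test_peak_on_boresight(self, beam):
        assert beam_gain(beam, 0.0, 0.0) == pytest.approx(beam.A0)

    def test_minus_3db_at_half_beamwidth(self, beam):
        """20·log10 convention: amplitude 10^(−3/20) at θ/2 off boresight."""
        g = beam_gain(beam, beam.beamwidth_az / 2, 0.0)
        assert g == pytest.approx(beam.A0 * 10 ** (-3 / 20), rel=1e-12)
        g = beam_gain(beam, 0.0, beam.beamwidth_el / 2)
        assert g == pytest.approx(beam.A0 * 10 ** (-3 / 20), rel=1e-12)

    @given(
        st.floats(-1.5, 1.5), st.floats(-1.5, 1.5)
    )
    def test_symmetry_about_boresight(self, az, el):
        beam = SonarBeam(np.zeros(3), [1.0, 0, 0])
        assert beam_gain(beam, az, el) == pytest.approx(beam_gain(beam, -az, el))
        assert beam_gain(beam, az, el) == pytest.approx(beam_gain(beam, az, -el))

    def test_mainlobe_contour_closed(self, beam):
        assert in_mainlobe(beam, 0.0, 0.0)
        assert in_mainlobe(beam, beam.beamwidth_az / 2, 0.0)  # boundary included
        assert not in_mainlobe(beam, beam.beamwidth_az / 2 * 1.01, 0.0)

    def test_sigma_beamwidth_relation(self):
        bw = math.radians(30.0)
        sigma = beamwidth_to_sigma(bw)
        assert sigma == pytest.approx((bw / 2) / math.sqrt(0.3 * math.log(10)))


class TestLeafGain:
    def test_normal_incidence_equals_p1(self):
        for c in (0.5, 1.0, 5.0, 20.0):
            a = c * V / (2 * math.pi * 70e3)
            assert leaf_gain(0.0, a, 70e3, V) == pytest.approx(0.5003 * c**2 + 0.6867)

    def test_printed_fit_at_c_equal_one(self):
        """c = 1, β = 0.5 rad evaluates the printed polynomials directly."""
        a = V / (2 * math.pi * 70e3)  # makes c = 1 at 70 kHz
        expected = (0.5003 + 0.6867) * math.cos((0.3999 + 0.9979) * 0.5)
        assert leaf_gain(0.5, a, 70e3, V) == pytest.approx(expected, rel=1e-12)

    def test_clamped_to_zero_beyond_first_cosine_zero(self):
        a = V / (2 * math.pi * 70e3)
        beta = math.pi / (0.3999 + 0.9979) * 1.05  # past the zero of cos(P2·β)
        assert leaf_gain(beta, a, 70e3, V) == 0.0
        assert leaf_gain(beta, a, 70e3, V, clamp=False) < 0.0

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            leaf_gain(0.1, -0.01, 70e3)
        with pytest.raises(ValueError):
            leaf_gain(0.1, 0.01, 0.0)


class TestFacetAmplitudeAndPhase:
    def test_inverse_square_law(self, beam, band):
        v1 = ReflectorView(r=1.0, az=0.0, el=0.0, beta=0.0, a=0.02)
        v2 = ReflectorView(r=2.0, az=0.0, el=0.0, beta=0.0, a=0.02)
        f = 70e3
        assert facet_amplitude(v1, beam, f, band) == pytest.approx(
            4 * facet_amplitude(v2, beam, f, band)
        )

    def test_boresight_closed_form(self, beam, band):
        """On boresight at β = 0: A = A0·P1(c)·v/(2π f r²)."""
        r, a, f = 1.5, 0.02, 65e3
        view = ReflectorView(r=r, az=0.0, el=0.0, beta=0.0, a=a)
        c = 2 * math.pi * a * f / V
        expected = beam.A0 * (0.5003 * c**2 + 0.6867) * V / (2 * math.pi * f * r**2)
        assert facet_amplitude(view, beam, f, band) == pytest.approx(expected, rel=1e-12)

    def test_quarter_wavelength_phase(self):
        f = 70e3
        view = ReflectorView(r=V / (4 * f), az=0.0, el=0.0, beta=0.0, a=0.02)
        assert facet_phase(view, f, V) == pytest.approx(math.pi)

    def test_phase_linear_in_range(self):
        f = 70e3
        v1 = ReflectorView(r=0.8, az=0, el=0, beta=0, a=0.02)
        v2 = ReflectorView(r=1.6, az=0, el=0, beta=0, a=0.02)
        assert facet_phase(v2, f) == pytest.approx(2 * facet_phase(v1, f))

    def test_round_trip_delay_recovered_by_regression(self):
        """Fitting φ(f) over the band recovers the slope 2π·τ with τ = 2r/v."""
        r = 1.3
        view = ReflectorView(r=r, az=0, el=0, beta=0, a=0.02)
        f = np.linspace(60e3, 80e3, 50)
        phi = facet_phase(view, f, V)
        slope = np.polyfit(f, phi, 1)[0]
        assert slope / (2 * math.pi) == pytest.approx(2 * r / V, rel=1e-9)


class TestSpectrumSynthesis:
    def test_no_discs_gives_zero_spectrum(self, beam, band):
        spec = synthesize_spectrum(beam, [], band)
        assert spec.m == 0
        assert np.all(spec.values == 0)

    def test_out_of_band_bins_are_zero(self, beam, band, facing_disc):
        spec = synthesize_spectrum(beam, [facing_disc], band)
        out = ~band.in_band()
        assert np.all(spec.values[out] == 0)
        assert np.any(spec.values[~out] != 0)

    def test_linearity_is_exact(self, beam, band):
        rng = np.random.default_rng(0)
        discs = [
            LeafDisc(
                center=[rng.uniform(1, 3), rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)],
                radius=rng.uniform(0.01, 0.04),
                normal=rng.normal(size=3),
            )
            for _ in range(12)
        ]
        a, b = discs[:5], discs[5:]
        sa = synthesize_spectrum(beam, a, band).values
        sb = synthesize_spectrum(beam, b, band).values
        sab = synthesize_spectrum(beam, a + b, band).values
        scale = np.abs(sab).max()
        assert np.allclose(sab, sa + sb, rtol=0, atol=1e-13 * scale)

    def test_single_disc_modulus_is_amplitude(self, beam, band, facing_disc):
        spec = synthesize_spectrum(beam, [facing_disc], band)
        view = reflector_view(beam, facing_disc)
        mask = band.in_band()
        f = band.frequencies()[mask]
        A = facet_amplitude(view, beam, f, band)
        assert np.allclose(np.abs(spec.values[mask]), A, rtol=1e-12)

    def test_out_of_mainlobe_discs_excluded(self, beam, band):
        off = LeafDisc([0.0, 5.0, 0.0], 0.02, [0.0, -1.0, 0.0])  # 90 deg off boresight
        spec = synthesize_spectrum(beam, [off], band)
        assert spec.m == 0
        assert np.all(spec.values == 0)

    def test_monotone_culling_with_beamwidth(self, band):
        """Widening the beam never decreases the in-mainlobe count."""
        rng = np.random.default_rng(1)
        discs = [
            LeafDisc(
                center=[rng.uniform(2, 6), rng.uniform(-3, 3), rng.uniform(-3, 3)],
                radius=0.02,
                normal=rng.normal(size=3),
            )
            for _ in range(200)
        ]
        ms = []
        for deg in (10, 30, 50, 80):
            bw = math.radians(deg)
            b = SonarBeam(np.zeros(3), [1.0, 0, 0], beamwidth_az=bw, beamwidth_el=bw)
            ms.append(synthesize_spectrum(b, discs, band).m)
        assert ms == sorted(ms)


class TestImpulseResponse:
    def test_zero_spectrum_gives_zero_signal(self, beam, band):
        ir = impulse_response(synthesize_spectrum(beam, [], band), band)
        assert np.all(ir.samples == 0)
        assert len(ir.samples) == band.n_fft

    def test_envelope_peak_at_round_trip_delay(self, beam, band, facing_disc):
        """r = 1 m, fs = 400 kHz, v = 343 m/s: peak at sample round(2·fs/v) = 2332."""
        ir, _ = echo(beam, [facing_disc], band)
        peak = int(np.argmax(ir.envelope()))
        assert abs(peak - round(band.fs * 2 * 1.0 / band.sound_speed)) <= 1

    def test_peak_amplitude_inverse_square(self, beam, band):
        d1 = LeafDisc([1.0, 0, 0], 0.02, [-1.0, 0, 0])
        d2 = LeafDisc([2.0, 0, 0], 0.02, [-1.0, 0, 0])
        e1, _ = echo(beam, [d1], band)
        e2, _ = echo(beam, [d2], band)
        ratio = e1.envelope().max() / e2.envelope().max()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_two_discs_separated_beyond_resolution_give_two_peaks(self, beam, band):
        """Δr > v/(2·B) with B = 20 kHz: arrivals resolve into two envelope peaks."""
        from scipy.signal import find_peaks

        dr = 0.5  # well above v/(2B) ≈ 8.6 mm
        discs = [
            LeafDisc([1.0, 0, 0], 0.02, [-1.0, 0, 0]),
            LeafDisc([1.0 + dr, 0, 0], 0.02, [-1.0, 0, 0]),
        ]
        ir, _ = echo(beam, discs, band)
        env = ir.envelope()
        peaks, _ = find_peaks(env, height=0.3 * env.max())
        expected = [
            round(band.fs * 2 * 1.0 / band.sound_speed),
            round(band.fs * 2 * (1.0 + dr) / band.sound_speed),
        ]
        for e in expected:
            assert any(abs(p - e) <= 2 for p in peaks)

    def test_signal_real_within_tolerance(self, beam, band, facing_disc):
        ir, _ = echo(beam, [facing_disc], band)
        assert ir.samples.dtype == np.float64  # imaginary residue already checked < 1e-10

    def test_mirrored_scene_identical_magnitudes(self, beam, band):
        rng = np.random.default_rng(4)
        discs = [
            LeafDisc(
                center=[rng.uniform(1, 4), rng.uniform(-1, 1), rng.uniform(-1, 1)],
                radius=0.02,
                normal=rng.normal(size=3),
            )
            for _ in range(20)
        ]
        mirrored = [
            LeafDisc(
                center=d.center * np.array([1, -1, 1]),
                radius=d.radius,
                normal=d.normal * np.array([1, -1, 1]),
            )
            for d in discs
        ]
        e1, _ = echo(beam, discs, band)
        e2, _ = echo(beam, mirrored, band)
        assert np.allclose(np.abs(e1.samples), np.abs(e2.samples), atol=1e-15)

    def test_parseval_consistency(self, beam, band, facing_disc):
        """Band energy and time-domain energy agree to 1e-9 relative."""
        spec = synthesize_spectrum(beam, [facing_disc], band)
        ir = impulse_response(spec, band)
        e_band = 2.0 * np.sum(np.abs(spec.values) ** 2) / band.n_fft
        e_time = np.sum(ir.samples**2)
        assert e_time == pytest.approx(e_band, rel=1e-9)

    def test_grid_mismatch_rejected(self, beam, band):
        spec = synthesize_spectrum(beam, [], band)
        other = FrequencyBand(n_fft=8192)
        with pytest.raises(ValueError):
            impulse_response(spec, other)

    def test_raised_cosine_taper_reduces_sidelobes(self, beam, facing_disc):
        rect = FrequencyBand(taper="rectangular")
        rc = FrequencyBand(taper="raised-cosine")
        e_rect, _ = echo(beam, [facing_disc], rect)
        e_rc, _ = echo(beam, [facing_disc], rc)
        env_r, env_c = e_rect.envelope(), e_rc.envelope()
        peak = int(np.argmax(env_r))
        # energy far from the main arrival is lower with tapering
        far = np.r_[0 : peak - 200, peak + 200 : len(env_r)]
        assert (env_c[far] / env_c.max()).max() < (env_r[far] / env_r.max()).max()


class TestBandValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f_lo": 80e3, "f_hi": 60e3},
            {"fs": 100e3},
            {"n_fft": 1000},
            {"taper": "hann"},
        ],
    )
    def test_invalid_band_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FrequencyBand(**kwargs)
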