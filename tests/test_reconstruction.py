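"""Tests for the six-step A-scan reconstruction pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import octforce as of
from octforce.reconstruction import (
    N_DEPTH_BINS,
    AScanReconstructor,
    DCState,
    apodize,
    dechirp,
    peak_depth,
    reconstruct_mscan,
    spectral_window,
    subtract_dc,
    to_depth_profile,
    update_dc,
)
from octforce.signal_model import N_SPECTRAL_SAMPLES

from oracles import dft_magnitude_oracle, ema_closed_form, hann_energy_oracle


class TestDechirp:
    def test_uniform_map_is_identity(self, uniform_chirp):
        x = np.random.default_rng(0).normal(size=N_SPECTRAL_SAMPLES)
        np.testing.assert_array_equal(dechirp(x, uniform_chirp), x)

    def test_linear_data_resampled_exactly(self, chirped_map):
        """Linear interpolation reproduces data linear in wavenumber exactly,
        endpoints included."""
        k = chirped_map.wavenumbers
        samples = 3.0 * k - 7.0
        out = dechirp(samples, chirped_map)
        expected = 3.0 * chirped_map.uniform_grid - 7.0
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        assert out[0] == samples[0] and out[-1] == samples[-1]

    def test_dechirping_sharpens_the_fringe(self, chirped_map):
        """A single-reflector fringe on a chirped grid smears over many depth
        bins; resampling onto the uniform grid concentrates its energy."""
        gap = 0.9
        fringe = np.cos(2.0 * gap * chirped_map.wavenumbers)
        before = dft_magnitude_oracle(fringe * np.hanning(N_SPECTRAL_SAMPLES))
        after = dft_magnitude_oracle(
            dechirp(fringe, chirped_map) * np.hanning(N_SPECTRAL_SAMPLES)
        )
        assert after[4:].max() > before[4:].max()


class TestDCTracker:
    def test_first_call_initializes_to_spectrum(self):
        spectrum = np.random.default_rng(1).normal(size=N_SPECTRAL_SAMPLES)
        _, estimate = update_dc(DCState(), spectrum)
        np.testing.assert_array_equal(estimate, spectrum)

    def test_constant_input_is_a_fixed_point(self):
        c = np.full(N_SPECTRAL_SAMPLES, 3.25)
        state = DCState()
        for _ in range(5):
            state, estimate = update_dc(state, c)
            np.testing.assert_array_equal(estimate, c)

    @pytest.mark.parametrize("t", [1, 10, 100, 1000])
    def test_matches_loop_free_closed_form(self, t):
        rng = np.random.default_rng(2)
        x0 = rng.normal(size=N_SPECTRAL_SAMPLES)
        c = rng.normal(size=N_SPECTRAL_SAMPLES)
        state, _ = update_dc(DCState(damping=0.05), x0)
        for _ in range(t):
            state, estimate = update_dc(state, c)
        np.testing.assert_allclose(estimate, ema_closed_form(x0, c, 0.05, t), atol=1e-12)

    def test_damping_bounds_enforced(self):
        with pytest.raises(ValueError):
            DCState(damping=0.0)


class TestSubtractAndApodize:
    def test_subtracting_itself_gives_zero(self):
        x = np.random.default_rng(3).normal(size=N_SPECTRAL_SAMPLES)
        assert np.all(subtract_dc(x, x) == 0)

    def test_zero_dc_is_identity(self):
        x = np.random.default_rng(4).normal(size=N_SPECTRAL_SAMPLES)
        np.testing.assert_array_equal(subtract_dc(x, np.zeros_like(x)), x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_dc(np.zeros(N_SPECTRAL_SAMPLES), np.zeros(10))

    def test_converged_residual_is_the_pure_fringe(self, uniform_chirp):
        """With a constant source and a fringe that decorrelates scan to scan,
        the converged DC estimate approaches the source envelope, so the
        residual approaches the analytic fringe 2*S*r*cos(2*k*gap)."""
        needle = of.default_needle(noise_sd=0.0, coupling_length=None)
        rng = np.random.default_rng(5)
        state = DCState(damping=0.05)
        # burn in on decorrelated gaps, then present the probe gap
        for gap in rng.uniform(0.7, 1.0, size=2000):
            spec = of.simulate_spectrum(needle, gap, uniform_chirp, rng)
            state, dc = update_dc(state, spec.samples)
        probe_gap = 0.85
        probe = of.simulate_spectrum(needle, probe_gap, uniform_chirp, rng)
        state, dc = update_dc(state, probe.samples)
        residual = subtract_dc(probe.samples, dc)
        expected = (
            2.0
            * needle.source_spectrum
            * needle.piston_reflectivity
            * np.cos(2.0 * uniform_chirp.wavenumbers * probe_gap)
        )
        # tolerance: EMA keeps a ~sqrt(d/(2-d)) fringe memory plus the d-weighted
        # share of the current scan
        scale = np.abs(expected).max()
        assert np.max(np.abs(residual - expected)) < 0.35 * scale

    def test_hann_window_shape(self):
        w = spectral_window("hann")
        assert w[0] == 0.0 and w[-1] == pytest.approx(0.0, abs=1e-12)
        assert w[(N_SPECTRAL_SAMPLES - 1) // 2] == pytest.approx(1.0, abs=1e-5)

    def test_hann_energy_matches_direct_summation(self):
        w = spectral_window("hann")
        assert np.sum(w**2) == pytest.approx(hann_energy_oracle(N_SPECTRAL_SAMPLES), rel=1e-12)

    def test_apodize_is_elementwise_product(self):
        x = np.random.default_rng(6).normal(size=N_SPECTRAL_SAMPLES)
        np.testing.assert_allclose(apodize(x), x * spectral_window("hann"), rtol=1e-15)


class TestDepthProfile:
    def test_zero_in_zero_out(self):
        out = to_depth_profile(np.zeros(N_SPECTRAL_SAMPLES))
        assert np.all(out.magnitudes == 0)
        assert out.magnitudes.shape == (N_DEPTH_BINS,)

    def test_pure_integer_bin_cosine_peaks_exactly_there(self):
        f = 100
        i = np.arange(N_SPECTRAL_SAMPLES)
        x = np.cos(2.0 * np.pi * f * i / N_SPECTRAL_SAMPLES)
        mags = to_depth_profile(x).magnitudes
        assert int(np.argmax(mags)) == f
        others = np.delete(mags, f)
        assert others.max() < 1e-9 * mags[f]

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_dft_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=N_SPECTRAL_SAMPLES)
        mags = to_depth_profile(x).magnitudes
        expected = dft_magnitude_oracle(x)
        np.testing.assert_allclose(mags, expected, rtol=1e-9, atol=1e-9)


class TestReconstructMScan:
    def test_single_scan_reconstructs_to_zero(self, noiseless_needle, uniform_chirp):
        """The first scan initializes the DC estimate, so its residual — and
        its A-scan — is exactly zero."""
        ds = of.generate_dataset(noiseless_needle, uniform_chirp, 1, seed=0)
        recon = reconstruct_mscan(ds.mscan)
        assert recon.ascans.shape == (N_DEPTH_BINS, 1)
        assert np.all(recon.ascans == 0)

    @pytest.mark.parametrize("n_t", [1, 3, 17])
    def test_shape_conservation(self, noiseless_needle, uniform_chirp, n_t):
        ds = of.generate_dataset(noiseless_needle, uniform_chirp, n_t, seed=1)
        recon = reconstruct_mscan(ds.mscan)
        assert recon.ascans.shape == (N_DEPTH_BINS, n_t)

    def test_static_reflector_fades_into_dc_estimate(self, uniform_chirp):
        """Fixed-pattern removal absorbs a perfectly static fringe: with a
        constant gap the reconstructed peak amplitude decays geometrically."""
        needle = of.default_needle(noise_sd=0.0)
        rng = np.random.default_rng(0)
        spec = of.simulate_spectrum(needle, 0.9, uniform_chirp, rng).samples
        spectra = np.tile(spec[:, None], (1, 300))
        mscan = of.RawMScan(
            spectra=spectra, timestamps=np.arange(300.0), chirp=uniform_chirp
        )
        # seed the tracker with the fringe-free source so the fringe is
        # initially visible, then watch fixed-pattern removal absorb it
        recon = reconstruct_mscan(mscan, dc_init=needle.source_spectrum)
        early = recon.ascans[:, 0].max()
        late = recon.ascans[:, 299].max()
        assert early > 0
        assert late < 1e-4 * early

    def test_ramp_peak_index_monotone_in_force_after_burn_in(
        self, ramp_dataset, ramp_recon
    ):
        burn = 200
        forces = ramp_dataset.force_trace.forces
        up_leg = slice(burn, 1450)  # strictly increasing leg of the triangle
        peaks = np.array(
            [peak_depth(ramp_recon[:, t]) for t in range(up_leg.start, up_leg.stop)]
        )
        assert np.all(np.diff(forces[up_leg]) > 0)
        assert np.all(np.diff(peaks) < 0.2)  # non-increasing up to sub-bin wiggle
        assert peaks[0] - peaks[-1] > 5  # and the trend is real


class TestPeakDepth:
    def test_impulse_localized_exactly(self):
        a = np.zeros(N_DEPTH_BINS)
        a[100] = 1.0
        assert peak_depth(a) == pytest.approx(100.0)

    def test_all_zero_reports_no_peak(self):
        assert peak_depth(np.zeros(N_DEPTH_BINS)) is None

    def test_guard_band_excludes_residual_dc(self):
        a = np.zeros(N_DEPTH_BINS)
        a[0] = 10.0  # residual DC
        a[50] = 1.0
        assert peak_depth(a) == pytest.approx(50.0)

    def test_known_gap_recovered_within_half_a_bin(self, uniform_chirp):
        needle = of.default_needle(noise_sd=0.0, coupling_length=None)
        gap = 0.8321
        fringe = 2.0 * needle.piston_reflectivity * needle.source_spectrum * np.cos(
            2.0 * uniform_chirp.wavenumbers * gap
        )
        mags = to_depth_profile(apodize(fringe)).magnitudes
        refined = peak_depth(mags)
        assert refined == pytest.approx(float(uniform_chirp.gap_to_bin(gap)), abs=0.5)


class TestReconstructorEstimator:
    def test_transform_matches_functional_pipeline(self, ramp_dataset, ramp_recon):
        est = AScanReconstructor(chirp=ramp_dataset.mscan.chirp)
        out = est.fit_transform(ramp_dataset.mscan.spectra.T)
        np.testing.assert_allclose(out, ramp_recon.T, rtol=1e-12)

    def test_get_set_params_round_trip(self):
        est = AScanReconstructor(damping=0.1, burn_in=50)
        est.set_params(**est.get_params())
        assert est.damping == 0.1 and est.burn_in == 50
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_invalid_window_rejected_at_fit(self):
        with pytest.raises(ValueError):
            AScanReconstructor(window="boxcar").fit(np.zeros((3, N_SPECTRAL_SAMPLES)))
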