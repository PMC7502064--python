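"""Unit and property tests for the needle model and the interferogram simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import octforce as of
from octforce.signal_model import N_SPECTRAL_SAMPLES

from oracles import dominant_bin_oracle


class TestForceToGap:
    def test_unloaded_spring_sits_at_rest_gap(self, noiseless_needle):
        assert of.force_to_gap(noiseless_needle, 0.0) == noiseless_needle.rest_gap

    def test_hookes_law_arithmetic(self):
        needle = of.default_needle(spring_constant=5.0, rest_gap=1.0)
        assert of.force_to_gap(needle, 0.5) == pytest.approx(0.9)

    def test_saturates_at_mechanical_stop(self, noiseless_needle):
        n = noiseless_needle
        big = n.saturation_force * 3
        assert of.force_to_gap(n, big) == pytest.approx(n.rest_gap - n.max_gap_travel)

    def test_negative_force_rejected(self, noiseless_needle):
        with pytest.raises(ValueError):
            of.force_to_gap(noiseless_needle, -0.1)

    @settings(deadline=None, max_examples=50)
    @given(
        spring=st.floats(0.5, 20.0),
        rest=st.floats(0.5, 2.0),
        travel_frac=st.floats(0.1, 0.9),
    )
    def test_strictly_decreasing_before_saturation(self, spring, rest, travel_frac):
        needle = of.NeedleModel(
            spring_constant=spring,
            rest_gap=rest,
            max_gap_travel=rest * travel_frac,
        )
        forces = np.linspace(0.0, needle.saturation_force * 0.999, 50)
        gaps = of.force_to_gap(needle, forces)
        assert np.all(np.diff(gaps) < 0)

    def test_gap_to_force_inverts_pre_saturation(self, noiseless_needle):
        forces = np.linspace(0.0, 1.0, 11)
        gaps = of.force_to_gap(noiseless_needle, forces)
        back = of.gap_to_force(noiseless_needle, gaps)
        np.testing.assert_allclose(back, forces, atol=1e-12)


class TestSimulateSpectrum:
    def test_vanishing_reflectivity_leaves_pure_source(self, uniform_chirp):
        needle = of.default_needle(piston_reflectivity=1e-300, noise_sd=0.0)
        spec = of.simulate_spectrum(needle, 1.0, uniform_chirp, np.random.default_rng(0))
        np.testing.assert_allclose(spec.samples, needle.source_spectrum, rtol=1e-12)

    def test_raised_cosine_dominant_bin_matches_dft_oracle(self, uniform_chirp):
        """Flat source + no noise: the fringe's DFT peak must land at the bin
        predicted from the gap and the wavenumber spacing."""
        needle = of.default_needle(
            source_spectrum=np.ones(N_SPECTRAL_SAMPLES),
            noise_sd=0.0,
            coupling_length=None,
        )
        gap = 0.8
        spec = of.simulate_spectrum(needle, gap, uniform_chirp, np.random.default_rng(0))
        observed = dominant_bin_oracle(spec.samples - spec.samples.mean())
        expected = round(float(uniform_chirp.gap_to_bin(gap)))
        assert abs(observed - expected) <= 1

    def test_same_seed_bit_identical(self, uniform_chirp, noiseless_needle):
        needle = of.default_needle(noise_sd=3.0)
        a = of.simulate_spectrum(needle, 0.9, uniform_chirp, np.random.default_rng(42))
        b = of.simulate_spectrum(needle, 0.9, uniform_chirp, np.random.default_rng(42))
        assert np.array_equal(a.samples, b.samples)

    def test_non_positive_gap_rejected(self, uniform_chirp, noiseless_needle):
        with pytest.raises(ValueError):
            of.simulate_spectrum(noiseless_needle, 0.0, uniform_chirp, np.random.default_rng(0))


class TestForceProfile:
    def test_single_ramp_without_jitter_is_triangular(self):
        trace = of.generate_force_profile(
            101, 1, 0.8, np.random.default_rng(0), peak_jitter=0.0, sensor_noise_sd=0.0
        )
        assert trace.forces[0] == pytest.approx(0.0, abs=1e-12)
        assert trace.forces[-1] == pytest.approx(0.0, abs=1e-12)
        assert trace.forces.max() == pytest.approx(0.8, rel=1e-6)
        mid = np.argmax(trace.forces)
        assert np.all(np.diff(trace.forces[: mid + 1]) > 0)
        assert np.all(np.diff(trace.forces[mid:]) < 0)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), n_ramps=st.integers(1, 7))
    def test_forces_always_within_calibrated_range(self, seed, n_ramps):
        trace = of.generate_force_profile(500, n_ramps, 1.0, np.random.default_rng(seed))
        assert np.all(trace.forces >= 0.0) and np.all(trace.forces <= 1.0)

    def test_long_trace_covers_low_and_high_force_bins(self):
        trace = of.generate_force_profile(10_000, 5, 1.0, np.random.default_rng(3))
        assert np.sum(trace.forces < 0.1) > 0
        assert np.sum(trace.forces > 0.9) > 0

    def test_peak_above_calibrated_range_rejected(self):
        with pytest.raises(ValueError):
            of.generate_force_profile(100, 1, 1.2, np.random.default_rng(0))


class TestGenerateDataset:
    def test_pairs_aligned_and_sized(self, noiseless_needle, uniform_chirp):
        ds = of.generate_dataset(noiseless_needle, uniform_chirp, 1000, seed=5)
        assert ds.mscan.spectra.shape == (N_SPECTRAL_SAMPLES, 1000)
        assert ds.force_trace.forces.shape == (1000,)
        assert np.array_equal(ds.mscan.timestamps, ds.force_trace.timestamps)

    def test_same_seed_gives_identical_datasets(self, uniform_chirp):
        needle = of.default_needle(noise_sd=4.0)
        a = of.generate_dataset(needle, uniform_chirp, 300, seed=9)
        b = of.generate_dataset(needle, uniform_chirp, 300, seed=9)
        assert np.array_equal(a.mscan.spectra, b.mscan.spectra)
        assert np.array_equal(a.force_trace.forces, b.force_trace.forces)

    def test_provenance_records_seed_and_parameters(self, noiseless_needle, uniform_chirp):
        ds = of.generate_dataset(noiseless_needle, uniform_chirp, 50, seed=77)
        assert ds.provenance["seed"] == 77
        assert ds.provenance["kind"] == "simulation"
        assert ds.provenance["needle"]["spring_constant"] == pytest.approx(10 / 3)

    def test_reconstructed_peaks_track_force_monotonically(self, ramp_dataset, ramp_recon):
        """Sorting scans by force, the piston peak must move monotonically
        closer to the fiber (non-increasing depth bin)."""
        from octforce.reconstruction import peak_depth

        burn = 200
        forces = ramp_dataset.force_trace.forces[burn:]
        peaks = np.array([peak_depth(ramp_recon[:, burn + t]) for t in range(forces.size)])
        order = np.argsort(forces, kind="stable")
        sorted_peaks = peaks[order]
        # allow sub-bin interpolation wiggle, but no real reversals
        assert np.all(np.diff(sorted_peaks) < 0.2)
        assert sorted_peaks[0] > sorted_peaks[-1]


class TestValidation:
    def test_chirp_map_must_be_increasing(self):
        k = np.linspace(4400, 5200, N_SPECTRAL_SAMPLES)
        k[500] = k[499]
        with pytest.raises(ValueError):
            of.ChirpMap(wavenumbers=k)

    def test_force_trace_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            of.ForceTrace(forces=np.array([0.5, 1.2]), timestamps=np.array([0.0, 1.0]))

    def test_mscan_rejects_misaligned_timestamps(self, uniform_chirp):
        with pytest.raises(ValueError):
            of.RawMScan(
                spectra=np.zeros((N_SPECTRAL_SAMPLES, 5)),
                timestamps=np.arange(4.0),
                chirp=uniform_chirp,
            )

    def test_needle_json_round_trip(self, noiseless_needle):
        clone = of.NeedleModel.from_json(noiseless_needle.to_json())
        assert clone.spring_constant == noiseless_needle.spring_constant
        np.testing.assert_array_equal(clone.source_spectrum, noiseless_needle.source_spectrum)
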