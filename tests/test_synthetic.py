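import numpy as np
import pytest

from mesomux import (
    Phantom,
    ScopeConfig,
    default_gates,
    integrate_gates,
    make_irf_trace,
    make_phantom,
    make_photon_kernel,
    simulate_calcium_traces,
    simulate_decay_stack,
    simulate_pmt_stream,
    slice_pulse_records,
)


def measured_fwhm_samples(kernel: np.ndarray) -> float:
    """Width of the negative lobe at half its trough depth, in samples."""
    trough = int(np.argmin(kernel))
    half = kernel[trough] / 2.0
    left = trough
    while left > 0 and kernel[left] < half:
        left -= 1
    right = trough
    while right < len(kernel) - 1 and kernel[right] < half:
        right += 1
    return right - left - 1 + (half - kernel[left]) / (kernel[left + 1] - kernel[left]) \
        + (half - kernel[right]) / (kernel[right - 1] - kernel[right])


class TestPhotonKernel:
    def test_fwhm_matches_configuration(self, kernel):
        # 1.875 ns at 0.3125 ns/sample = 6 samples
        assert measured_fwhm_samples(kernel.kernel) == pytest.approx(6.0, abs=1.0)

    def test_peak_normalized_negative_lobe(self, kernel):
        assert kernel.kernel.min() == pytest.approx(-1.0)

    def test_no_ring_gives_pure_negative_lobe(self):
        k = make_photon_kernel(ring_amplitude=0.0)
        assert k.kernel.max() <= 0.0

    def test_trough_to_peak_delay_matches_configuration(self):
        k = make_photon_kernel(trough_peak_delay_ns=2.5)
        trough = int(np.argmin(k.kernel))
        peak = trough + int(np.argmax(k.kernel[trough:]))
        assert (peak - trough) * 0.3125 == pytest.approx(2.5, abs=0.3125)

    def test_unresolvable_fwhm_rejected(self):
        with pytest.raises(ValueError):
            make_photon_kernel(fwhm_ns=0.3)


class TestPhantom:
    def test_deterministic_under_seed(self):
        a = make_phantom("cells", (32, 32), 5, seed=7)
        b = make_phantom("cells", (32, 32), 5, seed=7)
        assert np.array_equal(a.brightness_maps, b.brightness_maps)
        assert np.array_equal(a.tau_map, b.tau_map)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("kind", ["beads", "cells", "vessels"])
    def test_objects_disjoint_and_counted(self, kind):
        ph = make_phantom(kind, (48, 48), 6, seed=1)
        labels = np.unique(ph.labels)
        assert set(labels) == set(range(7))  # 0 background + 6 objects

    def test_zero_objects_uniform(self):
        ph = make_phantom("beads", (16, 16), 0, seed=0, background=0.5)
        assert np.all(ph.brightness_maps == 0.5)
        assert np.all(ph.labels == 0)

    def test_tau_positive_where_bright(self):
        ph = make_phantom("vessels", (32, 32), 4, seed=3)
        bright = ph.brightness_maps.sum(axis=0) > 0
        assert np.all(ph.tau_map[bright] > 0)

    def test_invalid_phantom_rejected(self):
        with pytest.raises(ValueError):
            Phantom(
                brightness_maps=-np.ones((4, 4, 4)),
                tau_map=np.ones((4, 4)),
                labels=np.zeros((4, 4), int),
            )


@pytest.fixture(scope="module")
def stream(fast_kernel):
    config = ScopeConfig(
        lines_per_frame=4, pixels_per_line=16, scanner_phases=(0.4, 1.7),
        noise_sd=0.3,
    )
    ph = make_phantom("beads", (4, 16), 2, seed=0, brightness=3.0,
                      tau_classes=(0.5, 0.8))
    return config, simulate_pmt_stream(ph, config, seed=1, kernel=fast_kernel)


class TestStreamInvariants:

    def test_laser_clock_spacing(self, stream):
        config, s = stream
        assert np.all(np.diff(s.laser_clock) == config.samples_per_period)
        assert config.samples_per_period == 40

    def test_hsync_rate_and_phase(self, stream):
        config, s = stream
        assert np.all(np.diff(s.hsync1) == config.samples_per_sweep)
        assert np.all(np.diff(s.hsync2) == config.samples_per_sweep)
        period = config.sample_rate / config.resonant_freq
        expected = ((config.scanner_phases[1] - config.scanner_phases[0])
                    / (2 * np.pi) * period) % config.samples_per_sweep
        got = (s.hsync2[0] - s.hsync1[0]) % config.samples_per_sweep
        assert got == pytest.approx(expected, abs=1.0)

    def test_events_within_waveform(self, stream):
        _, s = stream
        n = len(s.waveform)
        for ev in (s.laser_clock, s.hsync1, s.hsync2, s.vsync):
            assert np.all((ev >= 0) & (ev < n))

    def test_geometry_mismatch_rejected(self, fast_kernel):
        config = ScopeConfig(lines_per_frame=4, pixels_per_line=16)
        ph = make_phantom("beads", (4, 8), 1, seed=0)
        with pytest.raises(ValueError):
            simulate_pmt_stream(ph, config, seed=0, kernel=fast_kernel)


class TestPhotonPlacement:
    def test_zero_brightness_gives_pure_noise(self, fast_kernel):
        config = ScopeConfig(lines_per_frame=2, pixels_per_line=8, noise_sd=1.0)
        ph = Phantom(np.zeros((4, 2, 8)), np.ones((2, 8)), np.zeros((2, 8), int))
        stream = simulate_pmt_stream(ph, config, seed=5, kernel=fast_kernel)
        assert np.mean(stream.waveform) == pytest.approx(0.0, abs=0.05)
        rec, samples, _ = slice_pulse_records(stream)
        counts = integrate_gates(rec, default_gates(), pulse_samples=samples,
                                 clip=False)
        # unclipped gate sums of pure noise are zero-mean
        assert counts.values.mean() == pytest.approx(0.0, abs=0.2)

    def test_single_path_photons_fall_in_own_gate(self, fast_kernel):
        """Brute-force gating of a one-path stream: >=99% in-channel."""
        config = ScopeConfig(lines_per_frame=4, pixels_per_line=16, noise_sd=0.0)
        bright = np.zeros((4, 4, 16))
        bright[0] = 2.0
        ph = Phantom(bright, np.full((4, 16), 0.3), np.zeros((4, 16), int))
        stream = simulate_pmt_stream(ph, config, seed=2, kernel=fast_kernel)
        gates = default_gates(offset=1)
        # brute-force oracle: per-sample accumulation over each gate
        sums = np.zeros(4)
        for start in stream.laser_clock:
            if start + 48 > len(stream.waveform):
                break
            for c, (lo, hi) in enumerate(gates.gates):
                for s in range(lo, hi + 1):
                    sums[c] += -stream.waveform[start + s]
        assert sums[0] / sums.sum() >= 0.99

    def test_total_photon_count_matches_poisson_mean(self, fast_kernel):
        config = ScopeConfig(lines_per_frame=4, pixels_per_line=16, noise_sd=0.0,
                             fill_fraction=0.5)
        bright = np.zeros((4, 4, 16))
        bright[1] = 1.5
        ph = Phantom(bright, np.full((4, 16), 0.5), np.zeros((4, 16), int))
        stream = simulate_pmt_stream(ph, config, seed=3, kernel=fast_kernel)
        # photon count from deposited waveform area
        area_per_photon = config.photon_amplitude * fast_kernel.kernel.sum()
        n_detected = stream.waveform.sum() / area_per_photon
        # expected: brightness x pulses addressing an in-fill pixel
        from mesomux.synthetic import scanner_pixel_positions

        t_exc = stream.laser_clock + config.bins_per_path_step
        line, col, inside = scanner_pixel_positions(t_exc, config, 1)
        valid = inside & (line >= 0) & (line < 4)
        expected = 1.5 * np.count_nonzero(valid)
        assert abs(n_detected - expected) < 4 * np.sqrt(expected)


class TestDecayStackSimulation:
    def test_noiseless_delta_irf_matches_analytic_decay(self):
        """Delta IRF: trace is exp(-k dt/tau) plus the periodic wrap term."""
        delta = np.zeros(40)
        delta[0] = 1.0
        tau = 2.5
        stack = simulate_decay_stack(
            np.full((2, 2), tau), delta, 100.0, None, "poisson", offset=0.0
        )
        k = np.arange(40) * 0.3125
        expected = 100.0 * (np.exp(-k / tau) + np.exp(-(k + 12.5) / tau))
        assert stack.cube[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_constant_tau_gives_identical_expectations(self, irf):
        stack = simulate_decay_stack(np.full((3, 3), 2.0), irf.u, 50.0, None,
                                     "poisson")
        assert np.all(stack.cube == stack.cube[0, 0])

    def test_poisson_variance_scales_with_averaging(self, irf):
        n_img = 8
        stack = simulate_decay_stack(
            np.full((40, 40), 2.0), irf.u, 20.0, n_img, "poisson", seed=4
        )
        lam = simulate_decay_stack(np.full((1, 1), 2.0), irf.u, 20.0, None,
                                   "poisson").cube[0, 0]
        var = stack.cube.reshape(-1, 40).var(axis=0)
        # sample variance across iid pixels ~ lambda / n_images
        assert var == pytest.approx(lam / n_img, rel=0.25)

    def test_unknown_noise_model_rejected(self, irf):
        with pytest.raises(ValueError):
            simulate_decay_stack(np.ones((2, 2)), irf.u, 10.0, 5, "bogus")

    def test_irf_reference_bin_placement(self, kernel):
        u = make_irf_trace(kernel, reference_bin=19)
        assert int(np.argmax(u)) == 19


class TestCalciumTraces:
    def test_zero_rate_leaves_baseline_plus_noise(self):
        traces, base = simulate_calcium_traces(3, 60.0, 10.0, 0.0, seed=1,
                                               noise_sd=0.02)
        assert np.abs(traces - base).max() < 0.1

    def test_transients_are_non_negative(self):
        traces, base = simulate_calcium_traces(5, 120.0, 10.0, 0.3, seed=2,
                                               noise_sd=0.0)
        assert np.all(traces.mean(axis=1) >= base.mean(axis=1) - 1e-9)

    def test_deterministic_under_seed(self):
        a = simulate_calcium_traces(2, 30.0, 20.0, 0.2, seed=9)
        b = simulate_calcium_traces(2, 30.0, 20.0, 0.2, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
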