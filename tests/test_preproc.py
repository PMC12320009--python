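"""Preprocessing tests: interpolation, filters, rejection, projections, ICA."""

import numpy as np
import pytest

import neotag as nt
from neotag.preproc import ArtifactMask, _segment_power_spectrum
from neotag.recording import Recording

from conftest import make_noise_recording


def single_channel_recording(x, fs=10.0, channels=None):
    if channels is None:
        channels = nt.make_sensor_array(1, 0.065, 1, seed=0)[:1]
    return Recording(fs, channels, np.atleast_2d(np.asarray(x, float)))


class TestInterpolation:
    def test_hand_computed_example(self):
        rec = single_channel_recording([0.0, 9.0, 0.0, 0.0], fs=1.0)
        out = nt.interpolate_artifacts(rec, ArtifactMask([(1.0, 2.0)]))
        assert np.allclose(out.data[0], [0, 0, 0, 0])

    def test_flat_channel_unchanged(self):
        rec = single_channel_recording(np.full(50, 3.0))
        out = nt.interpolate_artifacts(rec, ArtifactMask([(1.0, 2.0)]))
        assert np.allclose(out.data, rec.data)

    def test_ramp_unchanged_inside_interior_window(self):
        rec = single_channel_recording(np.arange(50, dtype=float))
        out = nt.interpolate_artifacts(rec, ArtifactMask([(1.0, 3.0)]))
        assert np.allclose(out.data, rec.data, atol=1e-12)

    def test_edge_window_holds_nearest_value(self):
        rec = single_channel_recording([5.0, 7.0, 1.0, 2.0], fs=1.0)
        out = nt.interpolate_artifacts(rec, ArtifactMask([(0.0, 2.0)]))
        assert np.allclose(out.data[0], [1, 1, 1, 2])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rec = single_channel_recording(rng.normal(size=100))
        mask = ArtifactMask([(2.0, 4.0), (6.0, 7.0)])
        once = nt.interpolate_artifacts(rec, mask)
        twice = nt.interpolate_artifacts(once, mask)
        assert np.array_equal(once.data, twice.data)


class TestFilters:
    @pytest.fixture()
    def fs(self):
        return 300.0

    def sine_rec(self, f, fs, channels=None, duration=20.0):
        t = np.arange(int(duration * fs)) / fs
        return single_channel_recording(np.sin(2 * np.pi * f * t), fs=fs)

    def test_passband_sinusoid_amplitude_preserved(self, fs):
        out = nt.bandpass(self.sine_rec(3.0, fs), 1.0, 40.0)
        mid = out.data[0, 1000:-1000]
        assert abs(mid.max() - 1.0) < 0.01

    def test_dc_attenuated_by_highpass(self, fs):
        rec = single_channel_recording(np.ones(int(20 * fs)), fs=fs)
        out = nt.bandpass(rec, 1.0, 40.0)
        assert np.abs(out.data[0, 1000:-1000]).max() < 1e-2  # > 40 dB

    def test_50hz_attenuated_by_wide_band(self, fs):
        # generous edge trim: the 0.2 Hz high-pass rings for seconds
        out = nt.bandpass(self.sine_rec(50.0, fs), 0.2, 40.0)
        assert np.abs(out.data[0, 2500:-2500]).max() < 1e-2

    def test_zero_phase_keeps_impulse_latency(self, fs):
        x = np.zeros(int(10 * fs))
        x[1500] = 1.0
        out = nt.bandpass(single_channel_recording(x, fs=fs), 1.0, 40.0)
        assert abs(int(np.argmax(np.abs(out.data[0]))) - 1500) <= 1

    def test_linearity(self, fs):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, int(5 * fs)))
        fx = nt.bandpass(single_channel_recording(x, fs=fs), 1, 40).data
        fy = nt.bandpass(single_channel_recording(y, fs=fs), 1, 40).data
        fxy = nt.bandpass(single_channel_recording(2 * x + 3 * y, fs=fs),
                          1, 40).data
        assert np.abs(fxy - 2 * fx - 3 * fy).max() < 1e-9 * np.abs(fxy).max()

    def test_notch_removes_line(self, fs):
        out = nt.notch(self.sine_rec(25.0, fs), [25.0])
        assert np.abs(out.data[0, 1000:-1000]).max() < 0.05

    def test_invalid_band_raises(self, fs):
        rec = self.sine_rec(3.0, fs)
        with pytest.raises(ValueError):
            nt.bandpass(rec, 40.0, 1.0)
        with pytest.raises(ValueError):
            nt.bandpass(rec, 1.0, 200.0)


class TestNoisePeaks:
    def test_white_noise_yields_no_peaks(self, small_array):
        rec = make_noise_recording(small_array, duration=30, seed=2)
        assert nt.detect_noise_peaks(rec) == []

    def test_injected_line_found(self, small_array):
        rec = make_noise_recording(small_array, duration=30, seed=3)
        t = rec.times
        rec.data += 5.0 * np.sin(2 * np.pi * 25.0 * t)[None, :]
        peaks = nt.detect_noise_peaks(rec)
        assert len(peaks) == 1 and abs(peaks[0] - 25.0) <= 0.5

    def test_line_outside_band_ignored(self, small_array):
        rec = make_noise_recording(small_array, duration=30, seed=4)
        t = rec.times
        rec.data += 5.0 * np.sin(2 * np.pi * 50.0 * t)[None, :]
        assert nt.detect_noise_peaks(rec, band=(13, 40)) == []


class TestRobustZ:
    def test_gaussian_noise_rarely_masked(self, small_array):
        rec = make_noise_recording(small_array, duration=60, seed=5)
        mask = nt.robust_zscore_reject(rec)
        assert mask.total_duration() / rec.duration < 1e-3

    def test_large_burst_is_masked(self, small_array):
        rec = make_noise_recording(small_array, duration=60, seed=6)
        i0, i1 = int(30 * 300), int(30.2 * 300)
        rec.data[:, i0:i1] += 50.0
        mask = nt.robust_zscore_reject(rec)
        m = mask.sample_mask(rec.n_samples, 300.0)
        assert m[i0:i1].mean() > 0.9

    def test_infinite_threshold_masks_nothing(self, small_array):
        rec = make_noise_recording(small_array, duration=10, seed=7)
        rec.data[:, 100] += 1e6
        assert nt.robust_zscore_reject(rec, threshold=np.inf).windows == []

    def test_constant_channel_contributes_nothing(self, small_array):
        rec = make_noise_recording(small_array, duration=10, seed=8)
        rec.data[0] = 2.5
        mask_const = nt.robust_zscore_reject(rec)
        rec2 = rec.copy()
        rec2.data = rec.data[1:]
        rec2.channels = rec.channels[1:]
        mask_rest = nt.robust_zscore_reject(Recording(
            300.0, rec.channels[1:], rec.data[1:]))
        assert mask_const.windows == mask_rest.windows

    def test_lowering_threshold_never_shrinks_mask(self, small_array):
        rec = make_noise_recording(small_array, duration=30, seed=9)
        rec.data[:, 4000:4100] += 8.0
        m_hi = nt.robust_zscore_reject(rec, threshold=6.0)
        m_lo = nt.robust_zscore_reject(rec, threshold=4.0)
        hi = m_hi.sample_mask(rec.n_samples, 300.0)
        lo = m_lo.sample_mask(rec.n_samples, 300.0)
        assert not np.any(hi & ~lo)


class TestExtendWindows:
    def test_simple_padding(self):
        out = nt.extend_windows(ArtifactMask([(10.0, 11.0)]), 1.5)
        assert out.windows == [(8.5, 12.5)]

    def test_padding_merges_neighbours(self):
        out = nt.extend_windows(ArtifactMask([(0.0, 1.0), (2.0, 3.0)]), 1.5)
        assert out.windows == [(0.0, 4.5)]

    def test_empty_mask_stays_empty(self):
        assert nt.extend_windows(ArtifactMask([]), 1.5).windows == []

    def test_clipping_to_duration(self):
        out = nt.extend_windows(ArtifactMask([(9.5, 10.0)]), 1.5,
                                duration=10.0)
        assert out.windows == [(8.0, 10.0)]


class TestPCProjection:
    def test_rank1_data_with_one_pc_vanishes(self, small_array):
        rng = np.random.default_rng(10)
        pattern = rng.normal(size=len(small_array))
        rec = Recording(300.0, small_array,
                        np.outer(pattern, rng.normal(size=3000)))
        out = nt.project_out_pcs(rec, None, n=1)
        assert np.abs(out.data).max() < 1e-12 * np.abs(rec.data).max()

    def test_n_zero_is_identity(self, small_array):
        rec = make_noise_recording(small_array, duration=5, seed=11)
        out = nt.project_out_pcs(rec, None, n=0)
        assert np.array_equal(out.data, rec.data)

    def test_output_orthogonal_to_removed_subspace(self, small_array):
        rec = make_noise_recording(small_array, duration=10, seed=12)
        rec.data += np.outer(np.ones(len(small_array)),
                             10 * np.sin(rec.times))
        out = nt.project_out_pcs(rec, None, n=3)
        # recompute the top PCs of the input and check residual variance
        X = rec.data - rec.data.mean(axis=1, keepdims=True)
        _, vecs = np.linalg.eigh(X @ X.T)
        U = vecs[:, -3:]
        proj = U.T @ out.data
        assert np.abs(proj).max() < 1e-10 * np.abs(rec.data).max()

    def test_projector_idempotent_for_fixed_subspace(self, small_array):
        """Applying I - U U^T twice (same U) equals applying it once."""
        rec = make_noise_recording(small_array, duration=5, seed=13)
        X = rec.data - rec.data.mean(axis=1, keepdims=True)
        _, vecs = np.linalg.eigh(X @ X.T)
        U = vecs[:, -2:]
        P = np.eye(len(small_array)) - U @ U.T
        once = P @ rec.data
        assert np.allclose(P @ once, once,
                           atol=1e-12 * np.abs(once).max())

    def test_too_many_components_raises(self, small_array):
        rec = make_noise_recording(small_array, duration=2, seed=14)
        with pytest.raises(ValueError):
            nt.project_out_pcs(rec, None, n=len(small_array))


class TestHeartbeatRemoval:
    def heartbeat_recording(self, channels, seed, amp=5.0):
        """White noise plus a strong rank-1 quasi-periodic 2.35 Hz artifact."""
        cfg = nt.SimulationConfig(
            duration=80, sampling_rate=300, seed=seed, white_noise=1.0,
            evoked_amplitude=0.0, ambient_field=0.0, pink_noise=0.0,
            drift_amplitude=0.0, burst_rate=0.0,
            infant_heart_rate=(2.35, 2.35), infant_heart_amplitude=amp,
            parent_heart_amplitude=0.0)
        rec = nt.generate_evoked_recording(cfg, channels)
        return nt.add_artifacts(rec, cfg)

    def test_strong_heartbeat_removed_below_rule_threshold(self, small_array):
        rec = self.heartbeat_recording(small_array, seed=20)
        clean, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(2.2, 2.5)], n_components=10, seed=0)
        assert len(decomp.removed_components) >= 1
        peak = decomp.removed_components[0]["peak_freq"]
        assert 2.2 <= peak <= 2.5
        # residual heart-band SNR of every channel under the rule threshold
        from neotag.freqtag import spectrum_snr
        for ch in range(clean.n_channels):
            p, f = _segment_power_spectrum(clean.data[ch], 300.0)
            snr, valid = spectrum_snr(p[None, :], f)
            sel = (f >= 2.2) & (f <= 2.5) & valid
            assert np.nanmax(snr[0, sel]) < 7.5

    def test_infinite_threshold_removes_nothing(self, small_array):
        rec = self.heartbeat_recording(small_array, seed=21)
        clean, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(2.2, 2.5)], snr_threshold=np.inf,
            n_components=10, seed=0)
        assert decomp.removed_components == []
        assert np.array_equal(clean.data, rec.data)

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_no_heartbeat_no_removal(self, small_array, seed):
        rec = make_noise_recording(small_array, duration=80, seed=seed)
        _, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(1.0, 1.5), (2.2, 2.5)],
            n_components=10, seed=seed)
        assert decomp.removed_components == []

    def test_mixing_reconstructs_fit_data(self):
        """Full-rank decomposition: mixing @ sources rebuilds the fit data."""
        chans = nt.make_sensor_array(2, 0.065, 2, seed=1)   # 6 channels
        rng = np.random.default_rng(40)
        S = rng.laplace(size=(6, 8000))                     # non-Gaussian
        A = rng.normal(size=(6, 6))
        rec = Recording(300.0, chans, A @ S)
        _, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(2.2, 2.5)], n_components=6, seed=0)
        recon = decomp.mixing @ decomp.sources + decomp.mean[:, None]
        from neotag.preproc import bandpass
        filt = bandpass(rec, 1.0, 40.0).data
        resid = np.linalg.norm(filt - recon) / np.linalg.norm(filt)
        assert resid < 1e-6


class TestHeartRateRanges:
    def test_flagged_component_maps_to_printed_range(self, small_array):
        rec = TestHeartbeatRemoval().heartbeat_recording(small_array, seed=23)
        _, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(2.2, 2.5)], n_components=10, seed=0)
        ranges = nt.estimate_heart_rate_ranges(decomp, half_width=0.15)
        assert len(ranges) >= 1
        lo, hi = ranges[0]
        assert abs(lo - 2.2) < 0.1 and abs(hi - 2.5) < 0.1

    def test_no_flagged_components_empty(self, small_array):
        rec = make_noise_recording(small_array, duration=80, seed=24)
        _, decomp = nt.remove_heartbeat_components(
            rec, None, heart_ranges=[(2.2, 2.5)], n_components=10, seed=1)
        assert nt.estimate_heart_rate_ranges(decomp) == []


class TestMaskRecovery:
    def test_injected_bursts_mostly_inside_detected_mask(self, small_array):
        """End-to-end: >= 90% of injected burst samples end up masked."""
        cfg = nt.SimulationConfig(duration=120, sampling_rate=300, seed=25,
                                  burst_rate=3.0)
        rec = nt.add_artifacts(
            nt.generate_evoked_recording(cfg, small_array), cfg)
        filt = nt.bandpass(rec, 1.0, 40.0)
        mask = nt.extend_windows(nt.robust_zscore_reject(filt), 1.5,
                                 duration=rec.duration)
        m = mask.sample_mask(rec.n_samples, 300.0)
        truth = np.zeros(rec.n_samples, bool)
        for a, b in rec.meta["injected_burst_windows"]:
            truth[int(a * 300):int(b * 300)] = True
        assert truth.any()
        assert m[truth].mean() >= 0.9
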