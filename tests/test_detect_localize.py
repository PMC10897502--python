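"""Peak detection, waveform extraction and the three localization methods."""

import numpy as np
import pandas as pd
import pytest

from driftbench.core import Recording, build_probe
from driftbench.detect_localize import (PrototypeWaveform, detect_peaks,
                                        estimate_noise_levels,
                                        extract_waveforms, localize_com,
                                        localize_grid, localize_mono,
                                        localize_peaks, make_prototype,
                                        select_peaks)
from driftbench.simulate import biphasic_waveform
from conftest import make_recording, monopole_ptp

FS = 32000.0


def inject(traces, frame, channel_amps, shape):
    m = len(shape)
    for c, a in channel_amps.items():
        traces[frame - m // 2: frame - m // 2 + m, c] += a * shape
    return traces


@pytest.fixture
def spike_shape():
    return biphasic_waveform(64, FS)


class TestNoiseLevels:
    def test_gaussian_noise_recovered(self, noise_recording):
        est = estimate_noise_levels(noise_recording, seed=0)
        np.testing.assert_allclose(est, 5.0, rtol=0.05)

    def test_constant_trace_gives_zero(self):
        rec = make_recording(np.full((40000, 2), 3.3, np.float32))
        np.testing.assert_array_equal(estimate_noise_levels(rec), 0.0)

    def test_robust_to_sparse_spikes(self, small_probe, spike_shape):
        rng = np.random.default_rng(0)
        x = 5.0 * rng.standard_normal((64000, 16), dtype=np.float32)
        for f in range(1000, 64000 - 1000, 700):   # <1% of samples
            inject(x, f, {3: 300.0}, spike_shape)
        est = estimate_noise_levels(Recording(x, FS, small_probe), seed=0)
        np.testing.assert_allclose(est, 5.0, rtol=0.10)


class TestDetectPeaks:
    def test_single_high_snr_spike_detected_exactly(self, small_probe,
                                                    spike_shape):
        rng = np.random.default_rng(2)
        x = 5.0 * rng.standard_normal((32000, 16), dtype=np.float32)
        inject(x, 9000, {5: 200.0}, spike_shape)
        rec = Recording(x, FS, small_probe)
        peaks = detect_peaks(rec, threshold=10.0, seed=0)
        assert len(peaks) == 1
        assert peaks["channel"][0] == 5
        assert abs(peaks["frame"][0] - 9000) <= 1

    def test_all_positive_trace_gives_empty_table(self):
        rec = make_recording(np.abs(np.random.default_rng(0)
                                    .standard_normal((32000, 3)))
                             .astype(np.float32))
        assert len(detect_peaks(rec, seed=0)) == 0

    def test_exclusion_keeps_strongest_of_synchronous_pair(self, spike_shape):
        # two synchronous events 22 um apart (within the 50 um radius)
        probe = build_probe(8, 1, 18.0, 22.0)
        rng = np.random.default_rng(3)
        x = 5.0 * rng.standard_normal((32000, 8), dtype=np.float32)
        inject(x, 8000, {3: 200.0}, spike_shape)
        inject(x, 8000, {4: 100.0}, spike_shape)
        peaks = detect_peaks(Recording(x, FS, probe), seed=0)
        assert len(peaks) == 1
        assert peaks["channel"][0] == 3

    def test_distant_synchronous_events_both_survive(self, spike_shape):
        probe = build_probe(16, 1, 18.0, 22.0)   # 22 um pitch column
        rng = np.random.default_rng(3)
        x = 5.0 * rng.standard_normal((32000, 16), dtype=np.float32)
        inject(x, 8000, {2: 200.0}, spike_shape)
        inject(x, 8000, {12: 100.0}, spike_shape)  # 220 um away
        peaks = detect_peaks(Recording(x, FS, probe), seed=0)
        assert sorted(peaks["channel"]) == [2, 12]

    def test_detection_translation_equivariant(self, small_probe, spike_shape):
        rng = np.random.default_rng(4)
        base = 5.0 * rng.standard_normal((64000, 16), dtype=np.float32)
        for f, c in ((9000, 2), (20000, 7), (41000, 11)):
            inject(base, f, {c: 150.0}, spike_shape)
        shift = 500
        shifted = np.roll(base, shift, axis=0)
        p0 = detect_peaks(Recording(base, FS, small_probe), seed=0)
        p1 = detect_peaks(Recording(shifted, FS, small_probe), seed=0)
        f0 = p0["frame"].to_numpy()
        f1 = p1["frame"].to_numpy()
        keep = (f0 + shift < 64000 - 100) & (f0 > 100)
        np.testing.assert_array_equal(f0[keep] + shift,
                                      f1[np.isin(f1, f0[keep] + shift)])
        assert keep.sum() >= 3

    def test_select_peaks_subsamples_deterministically(self):
        peaks = pd.DataFrame({"frame": np.arange(1000),
                              "channel": np.zeros(1000, int),
                              "amplitude": -np.ones(1000)})
        a = select_peaks(peaks, 100, seed=1)
        b = select_peaks(peaks, 100, seed=1)
        assert len(a) == 100
        pd.testing.assert_frame_equal(a, b)
        assert a["frame"].is_monotonic_increasing


class TestExtractWaveforms:
    def test_edge_peak_dropped_and_counted(self, noise_recording):
        peaks = pd.DataFrame({"frame": [0, 16000], "channel": [1, 1],
                              "amplitude": [-60.0, -60.0]})
        wfs = extract_waveforms(noise_recording, peaks)
        assert wfs.n_dropped_edges == 1
        assert wfs.n_peaks == 1

    def test_window_is_64_samples_at_32khz(self, noise_recording):
        peaks = pd.DataFrame({"frame": [16000], "channel": [1],
                              "amplitude": [-60.0]})
        wfs = extract_waveforms(noise_recording, peaks)
        assert wfs.n_samples == 64

    def test_noiseless_template_recovered_exactly(self, small_probe,
                                                  spike_shape):
        x = np.zeros((32000, 16), np.float32)
        inject(x, 9000, {5: 120.0, 6: 60.0}, spike_shape)
        rec = Recording(x, FS, small_probe)
        peaks = pd.DataFrame({"frame": [9000], "channel": [5],
                              "amplitude": [x[9000, 5]]})
        wfs = extract_waveforms(rec, peaks)
        rows, neigh, data = wfs.groups[5]
        j5 = int(np.flatnonzero(neigh == 5)[0])
        np.testing.assert_allclose(data[0, j5],
                                   (120.0 * spike_shape).astype(np.float32),
                                   atol=1e-4)


def _waveform_set_from_ptp(probe, ptp_by_channel, det_channel, shape,
                           frame=9000, n_samples=32000):
    """Build a noiseless recording realizing given per-channel ptp values."""
    x = np.zeros((n_samples, probe.n_channels), np.float32)
    shape_ptp = shape.max() - shape.min()
    amps = {c: p / shape_ptp for c, p in ptp_by_channel.items()}
    inject(x, frame, amps, shape)
    rec = Recording(x, FS, probe)
    peaks = pd.DataFrame({"frame": [frame], "channel": [det_channel],
                          "amplitude": [float(x[frame, det_channel])]})
    return extract_waveforms(rec, peaks, radius_um=1000.0)


class TestLocalizeCom:
    def test_equal_ptp_gives_midpoint(self, spike_shape):
        probe = build_probe(2, 1, 18.0, 22.0)
        wfs = _waveform_set_from_ptp(probe, {0: 50.0, 1: 50.0}, 0, spike_shape)
        loc = localize_com(wfs)
        assert loc.y[0] == pytest.approx(11.0, abs=1e-3)

    def test_weighted_mean_hand_case(self, spike_shape):
        # ptp (3, 1) at y = (0, 22) -> y = (3*0 + 1*22)/4 = 5.5
        probe = build_probe(2, 1, 18.0, 22.0)
        wfs = _waveform_set_from_ptp(probe, {0: 30.0, 1: 10.0}, 0, spike_shape)
        loc = localize_com(wfs)
        assert loc.y[0] == pytest.approx(5.5, abs=1e-3)

    def test_single_channel_returns_channel_position(self, spike_shape):
        probe = build_probe(1, 1, 18.0, 22.0)
        wfs = _waveform_set_from_ptp(probe, {0: 50.0}, 0, spike_shape)
        loc = localize_com(wfs)
        assert (loc.x[0], loc.y[0]) == (0.0, 0.0)

    def test_location_inside_convex_hull(self, small_probe, spike_shape):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ptp = {c: float(rng.uniform(5, 100))
                   for c in range(small_probe.n_channels)}
            wfs = _waveform_set_from_ptp(small_probe, ptp, 5, spike_shape)
            loc = localize_com(wfs)
            assert small_probe.y.min() <= loc.y[0] <= small_probe.y.max()
            assert small_probe.x.min() <= loc.x[0] <= small_probe.x.max()


class TestPrototype:
    def test_identical_spikes_give_normalized_template(self, small_probe,
                                                       spike_shape):
        x = np.zeros((64000, 16), np.float32)
        frames = [8000, 16000, 24000]
        for f in frames:
            inject(x, f, {5: 150.0}, spike_shape)
        rec = Recording(x, FS, small_probe)
        peaks = pd.DataFrame({"frame": frames, "channel": [5] * 3,
                              "amplitude": [x[f, 5] for f in frames]})
        wfs = extract_waveforms(rec, peaks)
        proto = make_prototype(wfs, n=3, seed=0)
        expected = spike_shape / -spike_shape.min()
        np.testing.assert_allclose(proto.h, expected, atol=1e-5)

    def test_single_waveform_prototype(self, small_probe, spike_shape):
        x = np.zeros((32000, 16), np.float32)
        inject(x, 9000, {3: 90.0}, spike_shape)
        rec = Recording(x, FS, small_probe)
        peaks = pd.DataFrame({"frame": [9000], "channel": [3],
                              "amplitude": [x[9000, 3]]})
        with pytest.warns(UserWarning):
            proto = make_prototype(extract_waveforms(rec, peaks), n=1000,
                                   seed=0)
        np.testing.assert_allclose(proto.h, spike_shape / -spike_shape.min(),
                                   atol=1e-5)

    def test_zero_peaks_raises(self, noise_recording):
        peaks = pd.DataFrame({"frame": [], "channel": [], "amplitude": []})
        wfs = extract_waveforms(noise_recording, peaks)
        with pytest.raises(ValueError):
            make_prototype(wfs, seed=0)


class TestLocalizeGrid:
    def _grid_setup(self, probe, src, spike_shape, sigma=20.0):
        # waveform = prototype decayed as a Gaussian from a known position
        d2 = ((probe.positions - np.asarray(src)) ** 2).sum(axis=1)
        amps = 80.0 * np.exp(-d2 / (2 * sigma ** 2))
        det = int(np.argmax(amps))
        shape_ptp = spike_shape.max() - spike_shape.min()
        ptp = {c: amps[c] * shape_ptp for c in range(probe.n_channels)}
        wfs = _waveform_set_from_ptp(probe, ptp, det, spike_shape)
        proto = PrototypeWaveform(spike_shape / -spike_shape.min())
        return wfs, proto

    def test_recovers_catalog_node_position(self, spike_shape):
        probe = build_probe(32, 2, 18.0, 22.0)
        src = (10.0, 150.0)         # on the 5 um node grid, between columns
        wfs, proto = self._grid_setup(probe, src, spike_shape)
        loc = localize_grid(wfs, proto)
        # depth (the drift axis) recovers to within half a grid pitch; x is
        # only weakly identified on a probe whose x span is 27 um
        assert abs(loc.y[0] - src[1]) <= 2.5
        assert abs(loc.x[0] - src[0]) <= 5.0

    def test_symmetric_waveform_centers_on_node(self, spike_shape):
        probe = build_probe(32, 1, 18.0, 22.0)
        src = (0.0, 77.0)           # midway between rows 3 and 4
        wfs, proto = self._grid_setup(probe, src, spike_shape)
        loc = localize_grid(wfs, proto)
        assert loc.y[0] == pytest.approx(77.0, abs=1.0)

    def test_finer_grid_at_least_as_accurate(self, spike_shape):
        probe = build_probe(32, 2, 18.0, 22.0)
        src = (13.0, 141.0)
        wfs, proto = self._grid_setup(probe, src, spike_shape)
        err = {}
        for pitch in (5.0, 2.5):
            loc = localize_grid(wfs, proto, grid_pitch_um=pitch)
            err[pitch] = np.hypot(loc.x[0] - src[0], loc.y[0] - src[1])
        assert err[2.5] <= err[5.0] + 1e-9


class TestLocalizeMono:
    def test_noiseless_forward_model_recovered(self, spike_shape):
        probe = build_probe(20, 2, 18.0, 22.0)
        x, y, z, k = 10.0, 100.0, 25.0, 2500.0
        ptp = monopole_ptp(probe.positions, x, y, z, k)
        wfs = _waveform_set_from_ptp(probe, dict(enumerate(ptp)),
                                     int(np.argmax(ptp)), spike_shape)
        loc = localize_mono(wfs)
        assert abs(loc.x[0] - x) < 1.0
        assert abs(loc.y[0] - y) < 1.0
        assert abs(loc.z[0] - z) < 2.0

    def test_amplitude_scaling_homogeneity(self, spike_shape):
        probe = build_probe(20, 2, 18.0, 22.0)
        ptp = monopole_ptp(probe.positions, 10.0, 100.0, 25.0, 2500.0)
        loc1 = localize_mono(_waveform_set_from_ptp(
            probe, dict(enumerate(ptp)), int(np.argmax(ptp)), spike_shape))
        loc2 = localize_mono(_waveform_set_from_ptp(
            probe, dict(enumerate(2 * ptp)), int(np.argmax(ptp)), spike_shape))
        assert loc2.x[0] == pytest.approx(loc1.x[0], abs=0.1)
        assert loc2.y[0] == pytest.approx(loc1.y[0], abs=0.1)
        assert loc2.z[0] == pytest.approx(loc1.z[0], abs=0.2)
        assert loc2.k[0] == pytest.approx(2 * loc1.k[0], rel=0.01)

    def test_median_error_under_amplitude_noise(self):
        from driftbench.detect_localize import _fit_monopole_batch

        probe = build_probe(20, 2, 18.0, 22.0)
        rng = np.random.default_rng(0)
        n = 200
        ys = rng.uniform(60.0, 160.0, n)
        xs = rng.uniform(0.0, 27.0, n)
        ptp = np.stack([monopole_ptp(probe.positions, xs[i], ys[i], 25.0,
                                     2500.0) for i in range(n)])
        ptp *= 1.0 + 0.05 * rng.standard_normal(ptp.shape)
        x0 = (ptp * probe.x).sum(1) / ptp.sum(1)
        y0 = (ptp * probe.y).sum(1) / ptp.sum(1)
        x, y, z, k, _ = _fit_monopole_batch(ptp, probe.x, probe.y, x0, y0)
        assert np.median(np.abs(y - ys)) < 3.0

    def test_mono_beats_com_on_monopole_sources(self, spike_shape):
        probe = build_probe(20, 2, 18.0, 22.0)
        rng = np.random.default_rng(1)
        errs_mono, errs_com = [], []
        for _ in range(100):
            y = rng.uniform(60.0, 160.0)
            ptp = monopole_ptp(probe.positions, 10.0, y, 25.0, 2500.0)
            ptp = ptp * (1.0 + 0.05 * rng.standard_normal(len(ptp)))
            wfs = _waveform_set_from_ptp(probe, dict(enumerate(ptp)),
                                         int(np.argmax(ptp)), spike_shape)
            errs_mono.append(abs(localize_mono(wfs).y[0] - y))
            errs_com.append(abs(localize_com(wfs).y[0] - y))
        assert np.median(errs_mono) <= np.median(errs_com)

    def test_too_few_channels_falls_back_to_com(self, spike_shape):
        probe = build_probe(2, 1, 18.0, 22.0)
        wfs = _waveform_set_from_ptp(probe, {0: 50.0, 1: 25.0}, 0, spike_shape)
        loc = localize_mono(wfs)
        assert np.isnan(loc.z[0])
        assert loc.flags[0]


def test_localize_peaks_wrapper_aligns_outputs(noise_recording):
    peaks = detect_peaks(noise_recording, threshold=3.0, seed=0)
    loc = localize_peaks(noise_recording, peaks, method="com")
    assert len(loc) == len(loc.peaks)
    assert loc.method == "com"
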