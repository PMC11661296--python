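import numpy as np
import pytest

import mtq
from mtq import nuclear_binding as nb
from conftest import best_iou, three_nuclei


class TestPreprocessing:
    def test_rolling_ball_constant_to_zero(self):
        out = nb.rolling_ball_subtract(np.full((1, 128, 128), 13.0))
        assert np.abs(out).max() < 1e-9

    def test_rolling_ball_removes_shading_gradient(self):
        """A linear shading ramp is strongly attenuated for a large ball."""
        ramp = np.tile(np.linspace(0.0, 10.0, 256), (256, 1))[None]
        out = nb.rolling_ball_subtract(ramp, radius_px=50)
        reduction = 10.0 / max(float(out.max() - out.min()), 1e-12)
        assert reduction >= 2.0  # bounded by ball geometry, not noise

    def test_rolling_ball_preserves_small_object(self):
        img = np.zeros((1, 128, 128))
        img[0, 60:68, 60:68] = 50.0
        out = nb.rolling_ball_subtract(img, radius_px=50)
        assert out[0, 63, 63] > 40.0

    def test_phantom_contrast_preserved(self, nucleus_scene):
        """Rim/interior contrast survives preprocessing within 10%."""
        stack, gt = nucleus_scene
        pre = nb.preprocess_nuclei(stack, 0)
        lab = gt.labels[0] == 1
        mid = np.argmax(lab.sum(axis=(1, 2)))
        vals = pre[0][mid][lab[mid]]
        hi, lo = np.percentile(vals, [95, 40])
        # truth contrast is 2.0 (rim 300 / interior 150)
        assert hi / max(lo, 1e-9) > 1.5

    def test_percentile_normalize_range(self):
        rng = np.random.default_rng(0)
        out = nb.percentile_normalize(rng.uniform(10, 20, (4, 32, 32)))
        assert out.min() >= 0 and out.max() <= 1


class TestSegmentation:
    def test_three_nuclei_high_iou(self, nucleus_scene):
        stack, gt = nucleus_scene
        pre = nb.preprocess_nuclei(stack, 0)
        labels = nb.segment_nuclei(pre[0])
        assert labels.max() == 3
        for lab in (1, 2, 3):
            assert best_iou(gt.labels[0] == lab, labels) >= 0.9

    def test_blank_frame_zero_labels(self):
        labels = nb.segment_nuclei(np.zeros((5, 64, 64)))
        assert labels.max() == 0

    def test_touching_nuclei_split_by_markers(self):
        """Two adjacent ellipsoids with distinct peaks become two labels."""
        acq = mtq.AcquisitionModel(psf_sigma_px=0.6, gaussian_noise_sd=2.0,
                                   background_level=2.0, seed=3)
        ph = [
            mtq.NucleusPhantom(center_um=(5, 9, 9), semiaxes_um=(4, 5, 5)),
            mtq.NucleusPhantom(center_um=(5, 9, 19.5), semiaxes_um=(4, 5, 5)),
        ]
        stack, gt = mtq.make_nucleus_timelapse([ph[0], ph[1]], 1, acq,
                                               shape_yx=(120, 200), n_z=7)
        pre = nb.preprocess_nuclei(stack, 0)
        labels = nb.segment_nuclei(pre[0])
        assert labels.max() == 2

    def test_label_count_stable_across_seeds(self):
        """Non-touching phantoms yield one label per nucleus for many seeds."""
        for seed in range(10):
            acq = mtq.AcquisitionModel(psf_sigma_px=0.6, gaussian_noise_sd=3.0,
                                       background_level=2.0, seed=seed)
            stack, _ = mtq.make_nucleus_timelapse(
                three_nuclei(), 1, acq, shape_yx=(200, 200), n_z=7
            )
            pre = nb.preprocess_nuclei(stack, 0)
            assert nb.segment_nuclei(pre[0]).max() == 3


class TestTracking:
    def test_stationary_single_track(self, nucleus_scene):
        stack, _ = nucleus_scene
        pre = nb.preprocess_nuclei(stack, 0)
        maps = [nb.segment_nuclei(pre[t]) for t in range(stack.n_frames)]
        tracks = nb.track_nuclei(maps, stack.calibration)
        assert len(tracks) == 3
        assert all(len(t) == stack.n_frames for t in tracks)

    def test_drifting_nucleus_single_track(self):
        acq = mtq.AcquisitionModel(psf_sigma_px=0.6, gaussian_noise_sd=3.0,
                                   background_level=2.0, seed=6)
        ph = mtq.NucleusPhantom(center_um=(5, 10, 8), semiaxes_um=(4, 5, 5),
                                drift_um_per_frame=(0, 0, 2.0))
        stack, _ = mtq.make_nucleus_timelapse([ph], 6, acq, shape_yx=(130, 220), n_z=7)
        pre = nb.preprocess_nuclei(stack, 0)
        maps = [nb.segment_nuclei(pre[t]) for t in range(6)]
        tracks = nb.track_nuclei(maps, stack.calibration)
        assert len(tracks) == 1 and len(tracks[0]) == 6

    def test_displacement_bound_splits_jump(self, calibration):
        """A 60 µm jump exceeds the 50 µm bound and starts a new track."""
        maps = []
        for t in range(6):
            lab = np.zeros((1, 64, 500), dtype=np.int32)
            x = 50 if t < 3 else 50 + int(60 / calibration.dx)  # 60 µm jump at t=3
            lab[0, 28:36, x - 4 : x + 4] = 1
            maps.append(lab)
        tracks = nb.track_nuclei(maps, calibration, max_displacement_um=50.0)
        assert len(tracks) == 2

    def test_short_tracks_dropped(self, calibration):
        maps = [np.zeros((1, 32, 32), dtype=np.int32) for _ in range(5)]
        maps[2][0, 10:20, 10:20] = 1  # appears in one frame only
        assert nb.track_nuclei(maps, calibration, min_track_length=3) == []


class TestBindingMeasurement:
    def test_known_ratio_recovered(self):
        acq = mtq.AcquisitionModel(psf_sigma_px=0.6, gaussian_noise_sd=0.0,
                                   background_level=0.0, seed=0)
        ph = mtq.NucleusPhantom(center_um=(5, 8, 8), semiaxes_um=(4, 5.5, 5.5),
                                rim_intensity=300.0, interior_intensity=150.0)
        stack, _ = mtq.make_nucleus_timelapse([ph], 3, acq, shape_yx=(120, 120), n_z=7)
        pre = nb.preprocess_nuclei(stack, 0)
        maps = [nb.segment_nuclei(pre[t]) for t in range(3)]
        tracks = nb.track_nuclei(maps, stack.calibration)
        ts = nb.measure_nm_binding(tracks[0], maps, stack, 0)
        assert np.allclose(ts.ratio, 2.0, rtol=0.02)

    def test_ratio_norm_definition(self):
        ts = nb.BindingTimeSeries.from_medians(0, [0, 1, 2], [2, 3, 4], [1, 1, 1])
        assert np.allclose(ts.ratio_norm, [1.0, 1.5, 2.0])
        assert ts.ratio_norm[0] == 1.0

    def test_uniform_nucleus_ratio_one(self):
        acq = mtq.AcquisitionModel(seed=0)
        ph = mtq.NucleusPhantom(center_um=(5, 8, 8), semiaxes_um=(4, 5, 5),
                                rim_intensity=150.0, interior_intensity=150.0)
        stack, _ = mtq.make_nucleus_timelapse([ph], 3, acq, shape_yx=(110, 110), n_z=7)
        pre = nb.preprocess_nuclei(stack, 0)
        maps = [nb.segment_nuclei(pre[t]) for t in range(3)]
        tracks = nb.track_nuclei(maps, stack.calibration)
        ts = nb.measure_nm_binding(tracks[0], maps, stack, 0)
        assert np.allclose(ts.ratio, 1.0, rtol=0.01)

    def test_nucleoplasm_caveat_ratiometric_control(self):
        """Falling nucleoplasm intensity inflates ratio(t) but leaves the
        lamin-normalised ratiometric readout constant."""
        acq = mtq.AcquisitionModel(psf_sigma_px=0.6, gaussian_noise_sd=0.0,
                                   background_level=0.0, seed=0)
        ph = mtq.NucleusPhantom(
            center_um=(5, 8, 8), semiaxes_um=(4, 5.5, 5.5),
            rim_intensity=300.0,
            interior_intensity=np.linspace(150, 75, 5),  # nucleoplasm dims
        )
        stack, _ = mtq.make_nucleus_timelapse([ph], 5, acq, shape_yx=(120, 120),
                                              n_z=7, lamin_channel=True)
        pre = nb.preprocess_nuclei(stack, 0)
        maps = [nb.segment_nuclei(pre[t]) for t in range(5)]
        tracks = nb.track_nuclei(maps, stack.calibration)
        ts = nb.measure_nm_binding(tracks[0], maps, stack, 0, lamin_channel=1)
        assert ts.ratio[-1] > 1.5 * ts.ratio[0]  # apparent binding rise
        ratiometric_change = ts.ratiometric[-1] / ts.ratiometric[0]
        assert abs(ratiometric_change - 1.0) < 0.05  # control stays flat


class TestLineProfile:
    def test_constant_image(self):
        prof = nb.line_profile(np.full((32, 32), 9.0), (16, 5), (16, 25))
        assert len(prof) == 21  # 20 px line, endpoints inclusive
        assert (prof["intensity"] == 9.0).all()

    def test_rim_peaks_flank_interior(self):
        acq = mtq.AcquisitionModel(psf_sigma_px=0.6, seed=0)
        ph = mtq.NucleusPhantom(center_um=(5, 9.6, 9.6), semiaxes_um=(4, 6, 6),
                                rim_intensity=300.0, interior_intensity=150.0)
        stack, _ = mtq.make_nucleus_timelapse([ph], 1, acq, shape_yx=(120, 120), n_z=7)
        mid = stack.frame(0, 0)[3]
        prof = nb.line_profile(mid, (60, 10), (60, 110), stack.calibration)
        v = prof["intensity"].to_numpy()
        centre = v[len(v) // 2]
        assert v.max() > 1.5 * centre  # rim peak above interior plateau
        left_peak = np.argmax(v[: len(v) // 2])
        right_peak = len(v) // 2 + np.argmax(v[len(v) // 2 :])
        assert left_peak < len(v) // 2 < right_peak

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            nb.line_profile(np.zeros((8, 8)), (4, 4), (4, 4))

    def test_distance_calibrated(self, calibration):
        prof = nb.line_profile(np.zeros((32, 32)), (0, 0), (0, 10), calibration)
        assert prof["distance_um"].iloc[-1] == pytest.approx(10 * calibration.dx)
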