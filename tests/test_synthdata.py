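import numpy as np
import pytest
from scipy import ndimage as ndi

import mtq
from mtq import synthdata


class TestAcquisitionModel:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            mtq.AcquisitionModel(psf_sigma_px=-1)
        with pytest.raises(ValueError):
            mtq.AcquisitionModel(shading_amplitude=1.0)

    def test_determinism(self):
        acq = mtq.AcquisitionModel(psf_sigma_px=1, gaussian_noise_sd=5,
                                   poisson_scale=2.0, seed=42)
        a, _ = mtq.make_guv_scene(3.2, 100, 5, acq)
        b, _ = mtq.make_guv_scene(3.2, 100, 5, acq)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a, _ = mtq.make_guv_scene(3.2, 100, 5, mtq.AcquisitionModel(gaussian_noise_sd=5, seed=1))
        b, _ = mtq.make_guv_scene(3.2, 100, 5, mtq.AcquisitionModel(gaussian_noise_sd=5, seed=2))
        assert not np.array_equal(a.data, b.data)


class TestGUVScene:
    def test_shell_construction(self, clean_acq):
        stack, gt = mtq.make_guv_scene(3.2, 100.0, 5.0, clean_acq)
        shell = np.abs(gt.extras["clean"] - 100.0) < 1e-9
        assert shell.any()
        assert np.all(stack.data[0, 0][shell] == 100.0)

    def test_psf_matches_direct_convolution(self):
        """The generator's blurred image equals a directly convolved clean shell."""
        acq = mtq.AcquisitionModel(psf_sigma_px=2.0, seed=0)
        stack, gt = mtq.make_guv_scene(3.2, 100.0, 5.0, acq)
        cal = stack.calibration
        sigma = (2.0 * cal.dx / cal.dz, 2.0, 2.0)
        oracle = ndi.gaussian_filter(gt.extras["clean"].astype(float), sigma)
        assert np.allclose(stack.data[0, 0], np.clip(oracle, 0, None))
        assert stack.data[0, 0].max() < 100.0  # peak strictly attenuated

    def test_too_small_radius_rejected(self, clean_acq):
        with pytest.raises(ValueError, match="resolvable"):
            mtq.make_guv_scene(0.3, 100, 5, clean_acq)

    def test_rim_radius_truth(self, clean_acq):
        stack, gt = mtq.make_guv_scene(3.2, 100, 5, clean_acq)
        r = gt.extras["rim_radius_um_per_slice"]
        mid = len(r) // 2
        assert r[mid] == pytest.approx(3.2)
        assert r[0] == 0.0  # above/below the sphere


class TestNucleusTimelapse:
    def test_ratio_ramp_ground_truth(self, clean_acq):
        ph = mtq.NucleusPhantom(
            center_um=(5, 8, 8), semiaxes_um=(4, 5, 5),
            rim_intensity=np.linspace(100, 300, 10), interior_intensity=100.0,
        )
        _, gt = mtq.make_nucleus_timelapse([ph], 10, clean_acq, shape_yx=(96, 96))
        assert np.allclose(gt.ratio_series[1], np.linspace(1, 3, 10))

    def test_three_nuclei_three_labels(self, nucleus_scene):
        _, gt = nucleus_scene
        for t in range(gt.labels.shape[0]):
            assert len(np.unique(gt.labels[t])) == 4  # 0 + 3 nuclei

    def test_overlap_rejected(self, clean_acq):
        ph = [
            mtq.NucleusPhantom(center_um=(5, 8, 8), semiaxes_um=(4, 5, 5)),
            mtq.NucleusPhantom(center_um=(5, 8, 12), semiaxes_um=(4, 5, 5)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            mtq.make_nucleus_timelapse(ph, 2, clean_acq, shape_yx=(120, 120))

    def test_drift_stays_under_tracking_bound(self, clean_acq):
        ph = mtq.NucleusPhantom(
            center_um=(5, 10, 10), semiaxes_um=(4, 5, 5),
            drift_um_per_frame=(0, 0, 2.0),
        )
        _, gt = mtq.make_nucleus_timelapse([ph], 10, clean_acq, shape_yx=(120, 240))
        c0 = ndi.center_of_mass(gt.labels[0] > 0)
        c9 = ndi.center_of_mass(gt.labels[9] > 0)
        disp = (c9[2] - c0[2]) * 0.16
        assert disp == pytest.approx(18.0, abs=1.0)  # 9 frames x 2 µm < 50 µm

    def test_lamin_channel_constant(self, clean_acq):
        ph = mtq.NucleusPhantom(
            center_um=(5, 8, 8), semiaxes_um=(4, 5, 5),
            rim_intensity=np.linspace(100, 300, 5),
        )
        stack, _ = mtq.make_nucleus_timelapse(
            [ph], 5, clean_acq, shape_yx=(96, 96), lamin_channel=True
        )
        lamin_max = [stack.frame(t, 1).max() for t in range(5)]
        assert np.allclose(lamin_max, lamin_max[0])


class TestERScene:
    def test_single_disc_truth(self, clean_acq):
        ph = mtq.ERPhantom(mode="vesiculated", n_vesicles=1,
                           vesicle_radius_px=(20.0, 0.0))
        _, gt = mtq.make_er_scene(ph, clean_acq, shape_yx=(128, 128))
        assert len(gt.objects) == 1
        row = gt.objects.iloc[0]
        assert row.analytic
        assert row.circularity == pytest.approx(1.0)

    def test_vesiculated_above_tubular_any_seed(self):
        for seed in range(5):
            acq = mtq.AcquisitionModel(seed=seed)
            _, gv = mtq.make_er_scene(mtq.ERPhantom(mode="vesiculated", n_vesicles=30), acq)
            _, gtb = mtq.make_er_scene(mtq.ERPhantom(mode="tubular", n_nodes=10), acq)
            assert gv.objects.circularity.median() > gtb.objects.circularity.median()
            assert gv.objects.area_um2.median() < gtb.objects.area_um2.median()

    def test_tubular_connected(self, clean_acq):
        _, gt = mtq.make_er_scene(mtq.ERPhantom(mode="tubular", n_nodes=15), clean_acq)
        assert len(gt.objects) == 1  # spanning tree -> one component

    def test_zero_objects_error(self, clean_acq):
        with pytest.raises(ValueError, match="zero objects"):
            mtq.make_er_scene(
                mtq.ERPhantom(mode="vesiculated", n_vesicles=0), clean_acq
            )

    def test_mixed_reproducible(self):
        acq = mtq.AcquisitionModel(seed=9)
        _, a = mtq.make_er_scene(mtq.ERPhantom(mode="mixed", mixed_fraction=0.5), acq)
        _, b = mtq.make_er_scene(mtq.ERPhantom(mode="mixed", mixed_fraction=0.5), acq)
        assert len(a.objects) == len(b.objects)


class TestBindingCurve:
    def test_half_saturation_identity(self):
        t = mtq.simulate_binding_curve(2.0, 100.0, 2.0, [100.0])
        assert t.bound.iloc[0] == pytest.approx(1.0)

    def test_zero_concentration(self):
        t = mtq.simulate_binding_curve(1.0, 100.0, 2.0, [0.0])
        assert t.bound.iloc[0] == 0.0

    def test_direct_evaluation(self):
        t = mtq.simulate_binding_curve(1.0, 100.0, 2.0, [500.0])
        assert t.bound.iloc[0] == pytest.approx(500**2 / (500**2 + 100**2), rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mtq.simulate_binding_curve(1, 100, 2, [-1.0])

    def test_noise_reproducible(self):
        a = mtq.simulate_binding_curve(1, 100, 2, [10, 50], noise_sd=0.1, seed=3)
        b = mtq.simulate_binding_curve(1, 100, 2, [10, 50], noise_sd=0.1, seed=3)
        assert np.array_equal(a.bound, b.bound)


class TestRateTimeseries:
    def test_piecewise_values(self):
        ts = mtq.simulate_rate_timeseries(1.0, 0.1, 5, 15, 20)
        assert ts.ratio[4] == pytest.approx(1.0)
        assert ts.ratio[15] == pytest.approx(2.0)
        assert ts.ratio[19] == pytest.approx(2.0)  # plateau

    def test_zero_slope_constant(self):
        ts = mtq.simulate_rate_timeseries(1.5, 0.0, 2, 8, 10)
        assert np.allclose(ts.ratio, 1.5)

    def test_invalid_breakpoints(self):
        with pytest.raises(ValueError):
            mtq.simulate_rate_timeseries(1, 0.1, 15, 5, 20)

    def test_reproducible(self):
        a = mtq.simulate_rate_timeseries(1, 0.1, 5, 15, 20, noise_sd=0.05, seed=4)
        b = mtq.simulate_rate_timeseries(1, 0.1, 5, 15, 20, noise_sd=0.05, seed=4)
        assert np.array_equal(a.ratio, b.ratio)


class TestGroundTruthAlignment:
    def test_labels_align_with_rim_voxels(self, clean_acq):
        """Rim voxels of the noiseless render sit inside the truth labels."""
        stack, gt = mtq.make_guv_scene(3.2, 100.0, 5.0, clean_acq)
        rim = stack.data[0, 0] == 100.0
        # rim is centred on the sphere surface: the inner half lies in the label
        inner = rim & (gt.labels[0] > 0)
        assert inner.sum() >= 0.4 * rim.sum()
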