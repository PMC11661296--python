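import numpy as np
import pytest

import mtq


@pytest.fixture(scope="session")
def calibration():
    return mtq.PixelCalibration()


@pytest.fixture(scope="session")
def noisy_acq():
    """Realistic acquisition: diffraction-scale PSF, ~2% noise, low background."""
    return mtq.AcquisitionModel(
        psf_sigma_px=0.6, gaussian_noise_sd=3.0, background_level=2.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_acq():
    return mtq.AcquisitionModel(seed=0)


def three_nuclei(rim=300.0, interior=150.0):
    """Three well-separated nucleus phantoms in a 200x200 px field."""
    return [
        mtq.NucleusPhantom(center_um=(5.0, 8.0, 8.0), semiaxes_um=(4.0, 5.5, 5.5),
                           rim_intensity=rim, interior_intensity=interior),
        mtq.NucleusPhantom(center_um=(5.0, 8.0, 24.0), semiaxes_um=(4.0, 5.0, 5.0),
                           rim_intensity=rim, interior_intensity=interior),
        mtq.NucleusPhantom(center_um=(5.0, 24.0, 16.0), semiaxes_um=(4.0, 5.0, 5.0),
                           rim_intensity=rim, interior_intensity=interior),
    ]


@pytest.fixture(scope="session")
def nucleus_scene(noisy_acq):
    stack, gt = mtq.make_nucleus_timelapse(
        three_nuclei(), 4, noisy_acq, shape_yx=(200, 200), n_z=7
    )
    return stack, gt


def best_iou(true_mask: np.ndarray, labels: np.ndarray) -> float:
    """IoU of the best-matching label against a ground-truth mask."""
    best = 0.0
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        inter = (true_mask & m).sum()
        union = (true_mask | m).sum()
        if union:
            best = max(best, inter / union)
    return best
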