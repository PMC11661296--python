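"""GUV equilibrium membrane-binding quantification.

Semi-automatic pipeline for measuring protein adsorption to giant
unilamellar vesicle (GUV) membranes.  A user-supplied line from the GUV
centre to its edge seeds the analysis: the stack is cropped around the GUV,
normalised and blurred, each z-slice is segmented with a marker-controlled
watershed, the slice of largest segmented area is taken as the equatorial
"middle section", and the rim-binding signal is the median raw intensity
along a 3-pixel-wide contour of the GUV on that slice.  Rim values are
normalised by the fluorescence of a 1 µM protein solution from the same
purification batch so that measurements are comparable across batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import watershed

from .io_core import ImageStack, RunConfig
from .nuclear_binding import _membrane_contour, percentile_normalize

logger = logging.getLogger("mtq")


@dataclass(frozen=True)
class GUVSelection:
    """User line from GUV centre to edge, in (y, x) pixel coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    frame: int = 0
    channel: int = 0

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))


@dataclass
class RimMeasurement:
    """Rim-binding readout for one GUV."""

    middle_slice: int
    rim_median: float
    contour_pixel_count: int
    normalized_rim: float | None = None

    def __post_init__(self) -> None:
        if self.contour_pixel_count <= 0:
            raise ValueError("contour pixel count must be > 0")


def crop_guv(stack: ImageStack, sel: GUVSelection) -> tuple[ImageStack, tuple[int, int]]:
    """Square crop around the selection's start point, all z-slices retained.

    The half-width is ceil(1.5 x line length); the crop is clipped to image
    bounds.  Returns the cropped stack and the (row, col) offset of the crop
    within the original image.
    """
    if sel.length_px < 3:
        raise ValueError("selection line must be at least 3 px long")
    ny, nx = stack.data.shape[-2:]
    for y, x in (sel.start, sel.end):
        if not (0 <= y < ny and 0 <= x < nx):
            raise ValueError(f"selection point ({y}, {x}) outside image")
    hw = int(np.ceil(1.5 * sel.length_px))
    y0 = int(round(sel.start[0]))
    x0 = int(round(sel.start[1]))
    r0, r1 = max(y0 - hw, 0), min(y0 + hw, ny)
    c0, c1 = max(x0 - hw, 0), min(x0 + hw, nx)
    if (r1 - r0) < 8 or (c1 - c0) < 8:
        raise ValueError(f"crop {r1 - r0}x{c1 - c0} smaller than 8x8 px")
    cropped = ImageStack(
        data=stack.data[..., r0:r1, c0:c1].copy(),
        calibration=stack.calibration,
        channel_roles=dict(stack.channel_roles),
    )
    return cropped, (r0, c0)


def preprocess_guv(crop: ImageStack, config: RunConfig | None = None) -> np.ndarray:
    """Percentile-normalise and 3D Gaussian blur (sigma 3 px, z-scaled).

    Returns the (Z, Y, X) volume of the selection frame/channel used for
    segmentation.  Measurement medians are taken on raw intensities.
    """
    config = config or RunConfig()
    cal = crop.calibration
    vol = percentile_normalize(
        crop.frame(0, 0).astype(float), config.norm_percentiles
    )
    sigma = (
        config.guv_blur_sigma_px * cal.dx / cal.dz,
        config.guv_blur_sigma_px,
        config.guv_blur_sigma_px,
    )
    return ndi.gaussian_filter(vol, sigma)


def segment_guv(
    volume: np.ndarray, seed_yx: tuple[int, int] | None = None
) -> tuple[np.ndarray, int]:
    """Per-slice marker-controlled watershed; returns labels and middle slice.

    The GUV interior basin is seeded at ``seed_yx`` (default: the crop
    centre, where the user line starts) and the background at the four crop
    corners; flooding the intensity surface places the basin boundary on the
    bright rim.  The middle section is the slice with the largest segmented
    area (ties to the lowest index).
    """
    nz, ny, nx = volume.shape
    if seed_yx is None:
        seed_yx = (ny // 2, nx // 2)
    labels = np.zeros(volume.shape, dtype=np.int32)
    areas = np.zeros(nz, dtype=int)
    vmax, vmin = float(volume.max()), float(volume.min())
    for z in range(nz):
        markers = np.zeros((ny, nx), dtype=np.int32)
        markers[int(seed_yx[0]), int(seed_yx[1])] = 1
        for cy, cx in ((0, 0), (0, nx - 1), (ny - 1, 0), (ny - 1, nx - 1)):
            markers[cy, cx] = 2
        ws = watershed(volume[z], markers=markers, watershed_line=True)
        mask = ws == 1
        # the watershed line runs along the rim crest; count it as part of
        # the GUV so the segmented disc extends to the membrane centre
        line = ws == 0
        mask |= line & ndi.binary_dilation(mask, structure=disk(1))
        # a real GUV interior is enclosed by its rim: reject basins that reach
        # the crop border or whose boundary carries no membrane signal
        if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
            mask[:] = False
        elif mask.any():
            boundary = ndi.binary_dilation(mask, structure=disk(1)) & ~mask
            if np.median(volume[z][boundary]) < vmin + 0.25 * (vmax - vmin):
                mask[:] = False
        labels[z][mask] = 1
        areas[z] = mask.sum()
    if areas.max() == 0:
        raise ValueError("GUV not found: no slice produced a segmented area")
    middle = int(np.argmax(areas))  # argmax ties -> lowest index
    return labels, middle


def measure_rim(
    labels: np.ndarray,
    middle_slice: int,
    raw_volume: np.ndarray,
    contour_width_px: int = 3,
) -> RimMeasurement:
    """Median raw intensity along the contour of the GUV middle section.

    The watershed basin boundary sits on the crest of the rim signal, so the
    ``contour_width_px``-wide band is centred on the segmentation boundary
    (erosion-difference applied to the slightly dilated mask) to keep it on
    the membrane.  If erosion empties the mask the full mask is used, with a
    warning.
    """
    mask = labels[middle_slice] > 0
    if not mask.any():
        raise ValueError("middle slice has an empty label")
    grow = contour_width_px // 2
    grown = ndi.binary_dilation(mask, structure=disk(1), iterations=grow) if grow else mask
    contour = _membrane_contour(grown, contour_width_px)
    rim_median = float(np.median(raw_volume[middle_slice][contour]))
    return RimMeasurement(
        middle_slice=middle_slice,
        rim_median=rim_median,
        contour_pixel_count=int(contour.sum()),
    )


def normalize_rim(m: RimMeasurement, reference_signal: float) -> RimMeasurement:
    """Normalise rim binding by the 1 µM same-batch solution fluorescence."""
    if reference_signal <= 0:
        raise ValueError("reference signal must be > 0")
    return RimMeasurement(
        middle_slice=m.middle_slice,
        rim_median=m.rim_median,
        contour_pixel_count=m.contour_pixel_count,
        normalized_rim=m.rim_median / reference_signal,
    )


def analyze_guv(
    stack: ImageStack,
    sel: GUVSelection,
    reference_signal: float | None = None,
    config: RunConfig | None = None,
) -> RimMeasurement:
    """Full GUV chain: crop, preprocess, segment, measure, normalise."""
    config = config or RunConfig()
    crop, (r0, c0) = crop_guv(stack, sel)
    seed = (int(round(sel.start[0])) - r0, int(round(sel.start[1])) - c0)
    sub = ImageStack(
        data=crop.data[sel.frame : sel.frame + 1, sel.channel : sel.channel + 1],
        calibration=crop.calibration,
        channel_roles={0: crop.channel_roles.get(sel.channel, "probe")},
    )
    vol = preprocess_guv(sub, config)
    labels, middle = segment_guv(vol, seed_yx=seed)
    raw = crop.frame(sel.frame, sel.channel).astype(float)
    source = raw if config.median_on_raw else vol
    m = measure_rim(labels, middle, source, config.contour_width_px)
    if reference_signal is not None:
        m = normalize_rim(m, reference_signal)
    return m
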