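"""Synthetic microscopy phantoms and model-based datasets with ground truth.

Every experimental input the analysis pipelines consume can be emulated
here with known ground truth:

* spherical GUV shells with rim fluorescence,
* ellipsoidal nuclei with a bright membrane rim and dimmer nucleoplasmic
  interior whose rim/interior ratio follows a prescribed time course
  (optionally drifting, optionally with a constant-amplitude lamin channel),
* ER scenes rendered as either a connected tubular network (low circularity,
  large components) or dispersed quasi-circular vesicles (high circularity,
  small components), or a mixture,
* Hill-model equilibrium binding curves and piecewise-linear binding-rate
  time series with additive noise.

Scenes are rendered on the anisotropic voxel grid (physical-space geometry
sampled at dx, dy, dz) and passed through a simple acquisition model:
Gaussian PSF blur, multiplicative low-frequency shading, Poisson shot noise
and additive Gaussian read noise.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.measure import regionprops
from skimage.morphology import disk as disk_footprint

from .io_core import ImageStack, PixelCalibration
from .nuclear_binding import BindingTimeSeries

# ---------------------------------------------------------------------------
# acquisition model


@dataclass(frozen=True)
class AcquisitionModel:
    """Confocal acquisition emulation: PSF, shading, shot and read noise."""

    psf_sigma_px: float = 0.0
    gaussian_noise_sd: float = 0.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    background_level: float = 0.0
    shading_amplitude: float = 0.0  # in [0, 1): multiplicative linear gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px < 0 or self.gaussian_noise_sd < 0 or self.poisson_scale < 0:
            raise ValueError("acquisition parameters must be non-negative")
        if not 0 <= self.shading_amplitude < 1:
            raise ValueError("shading_amplitude must be in [0, 1)")


def apply_acquisition(
    clean: np.ndarray,
    acq: AcquisitionModel,
    calibration: PixelCalibration,
    rng: np.random.Generator,
) -> np.ndarray:
    """Degrade a clean (Z, Y, X) volume through the acquisition model."""
    img = clean.astype(float) + acq.background_level
    if acq.psf_sigma_px > 0:
        sigma = (
            acq.psf_sigma_px * calibration.dx / calibration.dz,
            acq.psf_sigma_px,
            acq.psf_sigma_px,
        )
        img = ndi.gaussian_filter(img, sigma)
    if acq.shading_amplitude > 0:
        nx = img.shape[-1]
        ramp = 1.0 + acq.shading_amplitude * (np.linspace(-1, 1, nx))[None, None, :]
        img = img * ramp
    if acq.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * acq.poisson_scale) / acq.poisson_scale
    if acq.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, acq.gaussian_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Labels and analytic measurements aligned with a generated ImageStack."""

    labels: np.ndarray  # (T, Z, Y, X) int
    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    ratio_series: dict[int, np.ndarray] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phantom descriptions


def _as_series(value, n_frames: int) -> np.ndarray:
    """Broadcast a scalar / sequence / callable-of-frame to an n_frames array."""
    if callable(value):
        return np.array([float(value(t)) for t in range(n_frames)])
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n_frames, arr[0])
    if arr.size != n_frames:
        raise ValueError(f"series of length {arr.size} != n_frames {n_frames}")
    return arr


@dataclass
class NucleusPhantom:
    """Ellipsoidal nucleus with membrane rim and nucleoplasmic interior.

    Intensities may be scalars, per-frame sequences, or callables of the
    frame index; rim/interior is the ground-truth binding signal.
    """

    center_um: tuple[float, float, float]  # (z, y, x)
    semiaxes_um: tuple[float, float, float]  # (az, ay, ax)
    rim_intensity: float | Sequence[float] | Callable[[int], float] = 300.0
    interior_intensity: float | Sequence[float] | Callable[[int], float] = 150.0
    rim_thickness_px: int = 4
    drift_um_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def center_at(self, t: int) -> np.ndarray:
        return np.asarray(self.center_um) + t * np.asarray(self.drift_um_per_frame)


@dataclass
class ERPhantom:
    """ER scene description: tubular network, dispersed vesicles, or mixed."""

    mode: str = "tubular"  # tubular | vesiculated | mixed
    mixed_fraction: float = 0.5  # fraction of vesiculated signal in mixed mode
    n_nodes: int = 10  # network nodes (tubular)
    tubule_width_px: int = 4
    n_vesicles: int = 40
    vesicle_radius_px: tuple[float, float] = (4.0, 1.0)  # mean, sd
    amplitude: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("tubular", "vesiculated", "mixed"):
            raise ValueError(f"unknown ER phantom mode {self.mode!r}")


# ---------------------------------------------------------------------------
# geometric rendering helpers


def _ellipsoid_distance(
    shape_zyx: tuple[int, int, int],
    center_um: np.ndarray,
    semiaxes_um: np.ndarray,
    cal: PixelCalibration,
) -> np.ndarray:
    """Normalised ellipsoid distance (<= 1 inside) on the voxel grid."""
    z, y, x = np.indices(shape_zyx, dtype=float)
    z = z * cal.dz
    y = y * cal.dy
    x = x * cal.dx
    return np.sqrt(
        ((z - center_um[0]) / semiaxes_um[0]) ** 2
        + ((y - center_um[1]) / semiaxes_um[1]) ** 2
        + ((x - center_um[2]) / semiaxes_um[2]) ** 2
    )


def _render_nucleus(
    shape_zyx, phantom: NucleusPhantom, t: int, cal: PixelCalibration
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (interior mask, rim mask, full mask) for one frame."""
    center = phantom.center_at(t)
    semi = np.asarray(phantom.semiaxes_um, float)
    d = _ellipsoid_distance(shape_zyx, center, semi, cal)
    full = d <= 1.0
    # rim band of ~rim_thickness_px in-plane pixels, expressed in normalised units
    w = phantom.rim_thickness_px * cal.dx / float(np.min(semi[1:]))
    interior = d <= 1.0 - w
    rim = full & ~interior
    return interior, rim, full


# ---------------------------------------------------------------------------
# scene generators


def make_guv_scene(
    radius_um: float,
    rim_amp: float = 100.0,
    interior_amp: float = 5.0,
    acq: AcquisitionModel | None = None,
    calibration: PixelCalibration | None = None,
    shape_yx: tuple[int, int] | None = None,
    rim_thickness_px: int = 3,
) -> tuple[ImageStack, GroundTruth]:
    """Single spherical GUV shell over background, with analytic rim truth.

    The ground truth stores the analytic rim circle radius per z-slice
    (``extras["rim_radius_um_per_slice"]``) and a label volume of the ball.
    """
    acq = acq or AcquisitionModel()
    cal = calibration or PixelCalibration()
    r_px = radius_um / cal.dx
    if r_px < 3:
        raise ValueError(f"GUV radius {radius_um} µm is below the resolvable size")
    if shape_yx is None:
        half = int(np.ceil(r_px * 1.8)) + 8
        shape_yx = (2 * half, 2 * half)
    # odd slice count puts the sphere equator exactly on the central slice
    nz = 2 * int(np.ceil(radius_um / cal.dz)) + 3
    shape = (nz, *shape_yx)
    center = np.array(
        [(nz - 1) / 2 * cal.dz, (shape_yx[0] - 1) / 2 * cal.dy,
         (shape_yx[1] - 1) / 2 * cal.dx]
    )
    d = _ellipsoid_distance(shape, center, np.full(3, radius_um), cal)
    w = rim_thickness_px * cal.dx / radius_um
    ball = d <= 1.0
    # shell centred on the sphere surface: the analytic rim circle of each
    # z-slice runs through the middle of the rendered membrane
    shell = np.abs(d - 1.0) <= w / 2
    clean = rim_amp * shell + interior_amp * (ball & ~shell)
    rng = np.random.default_rng(acq.seed)
    img = apply_acquisition(clean, acq, cal, rng)
    stack = ImageStack(
        data=img[np.newaxis, np.newaxis], calibration=cal, channel_roles={0: "probe"}
    )
    z_um = np.arange(nz) * cal.dz
    rim_r = np.sqrt(np.clip(radius_um**2 - (z_um - center[0]) ** 2, 0.0, None))
    gt = GroundTruth(
        labels=ball.astype(np.int32)[np.newaxis],
        extras={
            "rim_radius_um_per_slice": rim_r,
            "center_um": center,
            "radius_um": radius_um,
            "rim_amp": rim_amp,
            "clean": clean,
        },
    )
    return stack, gt


def make_nucleus_timelapse(
    phantoms: Sequence[NucleusPhantom],
    n_frames: int,
    acq: AcquisitionModel | None = None,
    calibration: PixelCalibration | None = None,
    shape_yx: tuple[int, int] = (160, 160),
    n_z: int = 7,
    lamin_channel: bool = False,
    lamin_amp: float = 200.0,
) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse of non-overlapping nuclei with prescribed ratio courses.

    Channel 0 is the probe (rim + interior render); when ``lamin_channel``
    is set, channel 1 carries a constant-amplitude rim, emulating a stable
    nuclear-lamina marker.  Ground-truth per-nucleus ratio series equal
    rim_intensity(t) / interior_intensity(t).
    """
    acq = acq or AcquisitionModel()
    cal = calibration or PixelCalibration()
    shape = (n_z, *shape_yx)
    n_ch = 2 if lamin_channel else 1
    data = np.zeros((n_frames, n_ch, *shape))
    labels = np.zeros((n_frames, *shape), dtype=np.int32)
    rims = [_as_series(p.rim_intensity, n_frames) for p in phantoms]
    interiors = [_as_series(p.interior_intensity, n_frames) for p in phantoms]
    rng = np.random.default_rng(acq.seed)
    for t in range(n_frames):
        masks = [_render_nucleus(shape, p, t, cal) for p in phantoms]
        for i in range(len(phantoms)):
            for j in range(i + 1, len(phantoms)):
                if (masks[i][2] & masks[j][2]).any():
                    raise ValueError(
                        f"phantoms {i} and {j} overlap at frame {t}"
                    )
        probe = np.zeros(shape)
        lamin = np.zeros(shape)
        for i, (interior, rim, full) in enumerate(masks):
            probe[rim] = rims[i][t]
            probe[interior] = interiors[i][t]
            lamin[rim] = lamin_amp
            labels[t][full] = i + 1
        data[t, 0] = apply_acquisition(probe, acq, cal, rng)
        if lamin_channel:
            data[t, 1] = apply_acquisition(lamin, acq, cal, rng)
    roles = {0: "probe"}
    if lamin_channel:
        roles[1] = "lamin"
    stack = ImageStack(data=data, calibration=cal, channel_roles=roles)
    gt = GroundTruth(
        labels=labels,
        ratio_series={i + 1: rims[i] / interiors[i] for i in range(len(phantoms))},
        extras={"n_nuclei": len(phantoms)},
    )
    return stack, gt


def _place_vesicles(
    rng: np.random.Generator,
    shape_yx: tuple[int, int],
    n: int,
    radius_mean: float,
    radius_sd: float,
    occupied: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Rejection-sample non-overlapping discs; returns mask and (y, x, r)."""
    mask = np.zeros(shape_yx, bool)
    if occupied is not None:
        forbidden = occupied.copy()
    else:
        forbidden = np.zeros(shape_yx, bool)
    placed = []
    attempts = 0
    while len(placed) < n and attempts < n * 60:
        attempts += 1
        r = max(2.0, rng.normal(radius_mean, radius_sd))
        margin = int(np.ceil(r)) + 2
        y = rng.uniform(margin, shape_yx[0] - margin)
        x = rng.uniform(margin, shape_yx[1] - margin)
        rr, cc = draw_disk((y, x), r, shape=shape_yx)
        # keep one-pixel clearance so vesicles stay disjoint objects
        rr2, cc2 = draw_disk((y, x), r + 2, shape=shape_yx)
        if forbidden[rr2, cc2].any():
            continue
        mask[rr, cc] = True
        forbidden[rr2, cc2] = True
        placed.append((y, x, r))
    return mask, placed


def _draw_network(
    rng: np.random.Generator,
    shape_yx: tuple[int, int],
    n_nodes: int,
    width_px: int,
) -> np.ndarray:
    """Connected tubular network: minimum spanning tree over random nodes."""
    margin = 3 * width_px
    pts = np.column_stack(
        [
            rng.uniform(margin, shape_yx[0] - margin, n_nodes),
            rng.uniform(margin, shape_yx[1] - margin, n_nodes),
        ]
    )
    mask = np.zeros(shape_yx, bool)
    # Prim's algorithm keeps the network a single connected component
    in_tree = [0]
    out_tree = list(range(1, n_nodes))
    while out_tree:
        d = ((pts[in_tree][:, None, :] - pts[out_tree][None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        a, b = pts[in_tree[i]], pts[out_tree[j]]
        rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
        mask[rr, cc] = True
        in_tree.append(out_tree.pop(j))
    return ndi.binary_dilation(mask, structure=disk_footprint(max(width_px // 2, 1)))


def make_er_scene(
    phantom: ERPhantom,
    acq: AcquisitionModel | None = None,
    calibration: PixelCalibration | None = None,
    shape_yx: tuple[int, int] = (256, 256),
) -> tuple[ImageStack, GroundTruth]:
    """Single-plane ER scene with per-object ground-truth morphology.

    Ground truth is defined on the single 2D analysis plane.  For parametric
    shapes (vesicle discs) the stored area/perimeter are analytic; for
    network components they are measured on the pre-noise label mask with
    the same Crofton boundary estimator used downstream.
    """
    acq = acq or AcquisitionModel()
    cal = calibration or PixelCalibration()
    rng = np.random.default_rng(acq.seed)
    ves_mask = np.zeros(shape_yx, bool)
    tub_mask = np.zeros(shape_yx, bool)
    vesicles: list[tuple[float, float, float]] = []
    if phantom.mode in ("tubular", "mixed"):
        frac = 0.0 if phantom.mode == "tubular" else phantom.mixed_fraction
        n_nodes = max(2, int(round(phantom.n_nodes * (1 - frac))) + 1)
        tub_mask = _draw_network(rng, shape_yx, n_nodes, phantom.tubule_width_px)
    if phantom.mode in ("vesiculated", "mixed"):
        frac = 1.0 if phantom.mode == "vesiculated" else phantom.mixed_fraction
        n_ves = int(round(phantom.n_vesicles * frac))
        ves_mask, vesicles = _place_vesicles(
            rng, shape_yx, n_ves, *phantom.vesicle_radius_px, occupied=tub_mask
        )
    mask = tub_mask | ves_mask
    labels2d, n_obj = ndi.label(mask)
    if n_obj == 0:
        raise ValueError("ER phantom produced zero objects; increase density")
    rows = []
    analytic_by_label: dict[int, tuple[float, float]] = {}
    for y, x, r in vesicles:
        lab = labels2d[int(round(y)), int(round(x))]
        if lab > 0:
            analytic_by_label[lab] = (np.pi * r**2, 2 * np.pi * r)
    for p in regionprops(labels2d):
        if p.label in analytic_by_label:
            a_px, per_px = analytic_by_label[p.label]
            analytic = True
        else:
            a_px, per_px = float(p.area), float(p.perimeter_crofton)
            analytic = False
        area_um2 = a_px * cal.dx * cal.dy
        perim_um = per_px * cal.dx
        circ = 4 * np.pi * a_px / per_px**2 if per_px > 0 else np.nan
        rows.append(
            {
                "frame": 0,
                "label": p.label,
                "area_um2": area_um2,
                "perimeter_um": perim_um,
                "circularity": min(circ, 1.0),
                "analytic": analytic,
            }
        )
    clean = phantom.amplitude * mask.astype(float)
    img = apply_acquisition(clean[np.newaxis], acq, cal, rng)
    stack = ImageStack(
        data=img[np.newaxis, np.newaxis],
        calibration=cal,
        channel_roles={0: "er_luminal" if phantom.mode != "tubular" else "er_membrane"},
    )
    gt = GroundTruth(
        labels=labels2d.astype(np.int32)[np.newaxis, np.newaxis],
        objects=pd.DataFrame(rows),
        extras={"mode": phantom.mode, "clean": clean},
    )
    return stack, gt


def make_er_timelapse(
    phantom: ERPhantom,
    n_frames: int,
    acq: AcquisitionModel | None = None,
    calibration: PixelCalibration | None = None,
    shape_yx: tuple[int, int] = (256, 256),
) -> tuple[list[ImageStack], list[GroundTruth]]:
    """Frame sequence morphing from tubular to fully vesiculated ER.

    Frame f is a mixed scene with vesiculated fraction f/(n_frames-1); the
    first frame is purely tubular, the last purely vesiculated — the
    geometry of stress-induced ER fragmentation.
    """
    acq = acq or AcquisitionModel()
    stacks, gts = [], []
    for f in range(n_frames):
        frac = f / max(n_frames - 1, 1)
        mode = "tubular" if frac == 0 else ("vesiculated" if frac == 1 else "mixed")
        ph = ERPhantom(
            mode=mode,
            mixed_fraction=frac,
            n_nodes=phantom.n_nodes,
            tubule_width_px=phantom.tubule_width_px,
            n_vesicles=phantom.n_vesicles,
            vesicle_radius_px=phantom.vesicle_radius_px,
            amplitude=phantom.amplitude,
        )
        frame_acq = AcquisitionModel(
            psf_sigma_px=acq.psf_sigma_px,
            gaussian_noise_sd=acq.gaussian_noise_sd,
            poisson_scale=acq.poisson_scale,
            background_level=acq.background_level,
            shading_amplitude=acq.shading_amplitude,
            seed=acq.seed + f,
        )
        s, g = make_er_scene(ph, frame_acq, calibration, shape_yx)
        stacks.append(s)
        gts.append(g)
    return stacks, gts


# ---------------------------------------------------------------------------
# model-based datasets


def hill_curve(c, bmax: float, kd: float, h: float):
    """Langmuir adsorption isotherm with Hill expansion.

    B(c) = Bmax * c^h / (c^h + Kd'^h); B(0) = 0.
    """
    from scipy.special import expit

    c = np.asarray(c, dtype=float)
    # c^h/(c^h + kd^h) = logistic(h·(ln c − ln kd)); overflow-safe for any h
    with np.errstate(divide="ignore"):
        out = np.where(c > 0, bmax * expit(h * (np.log(np.where(c > 0, c, 1.0)) - np.log(kd))), 0.0)
    return out


def simulate_binding_curve(
    bmax: float,
    kd: float,
    h: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Equilibrium binding measurements from the Hill–Langmuir model.

    Returns a table of (concentration_nM, bound) with additive Gaussian
    noise of standard deviation ``noise_sd``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if bmax <= 0 or kd <= 0 or h <= 0:
        raise ValueError("bmax, kd and h must be positive")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    bound = hill_curve(conc, bmax, kd, h)
    if noise_sd > 0:
        bound = bound + np.random.default_rng(seed).normal(0, noise_sd, conc.shape)
    return pd.DataFrame({"concentration_nM": conc, "bound": bound})


def simulate_rate_timeseries(
    baseline: float,
    slope: float,
    t_linear_start: int,
    t_plateau: int,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_min: float = 1.0,
) -> BindingTimeSeries:
    """Flat baseline, linear rise, plateau — the canonical binding-rate shape.

    ``slope`` is in ratio units per frame; the ground-truth slope (per
    minute) is stored on the returned series (``true_slope``).
    """
    if not (0 <= t_linear_start < t_plateau <= n_frames):
        raise ValueError(
            f"invalid breakpoints: need 0 <= {t_linear_start} < {t_plateau} <= {n_frames}"
        )
    t = np.arange(n_frames, dtype=float)
    ratio = baseline + slope * np.clip(t - t_linear_start, 0, t_plateau - t_linear_start)
    if noise_sd > 0:
        ratio = ratio + np.random.default_rng(seed).normal(0, noise_sd, n_frames)
    return BindingTimeSeries.from_medians(
        track_id=0,
        times_min=t * dt_min,
        membrane_median=ratio,
        background_median=np.ones(n_frames),
        true_slope=slope / dt_min,
    )
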