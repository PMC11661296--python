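"""Shared I/O: calibrated image stacks, result tables, run configuration.

All pipelines operate on a single in-memory container, :class:`ImageStack`,
which stores intensities in a fixed ``T, C, Z, Y, X`` axis order together with
the physical voxel calibration and a mapping from channel index to biological
role (probe, ER marker, lamin, ...).  Stacks are read from and written to
TIFF / OME-TIFF via :mod:`tifffile`; tabular results are plain pandas
DataFrames serialised to CSV.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger("mtq")

AXES = "TCZYX"

CHANNEL_ROLES = ("probe", "er_luminal", "er_membrane", "lamin", "other")


@dataclass(frozen=True)
class PixelCalibration:
    """Physical voxel/frame calibration.

    dx, dy are µm per pixel in-plane, dz µm per z-step, dt minutes per frame.
    Defaults correspond to a 100x objective on an EMCCD with ~1.5 µm z-steps
    and one frame per minute.
    """

    dx: float = 0.16
    dy: float = 0.16
    dz: float = 1.5
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PixelCalibration.{name} must be > 0")

    @property
    def anisotropy(self) -> float:
        """z-step over in-plane pixel size (dz/dx)."""
        return self.dz / self.dx


@dataclass
class ImageStack:
    """5D fluorescence stack with calibration and channel roles.

    ``data`` is always ordered T, C, Z, Y, X; singleton axes are allowed
    (a single 2D image is stored as shape ``(1, 1, 1, Y, X)``).
    """

    data: np.ndarray
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    channel_roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5D (T,C,Z,Y,X), got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("ImageStack intensities must be non-negative")
        n_c = self.data.shape[1]
        for c, role in self.channel_roles.items():
            if not (0 <= int(c) < n_c):
                raise ValueError(f"channel_roles key {c} outside 0..{n_c - 1}")
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, role: str) -> int:
        """Index of the first channel annotated with ``role``."""
        for c, r in sorted(self.channel_roles.items()):
            if r == role:
                return c
        raise KeyError(f"no channel with role {role!r}")

    def frame(self, t: int, c: int) -> np.ndarray:
        """Z,Y,X volume of one timepoint/channel."""
        return self.data[t, c]


def normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/pad an array with labelled axes to canonical T,C,Z,Y,X.

    ``axes`` is a string such as "ZYX" or "TYX" naming ``data``'s axes in
    order. Missing axes are inserted with length 1. Idempotent for "TCZYX".
    """
    axes = axes.upper()
    if data.ndim != len(axes):
        raise ValueError(f"axes {axes!r} does not match ndim {data.ndim}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axis in {axes!r}")
    unknown = set(axes) - set(AXES)
    if unknown:
        raise ValueError(f"unknown axes {sorted(unknown)}; expected subset of {AXES}")
    # insert missing singleton axes, then transpose into canonical order
    for ax in AXES:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(data, order)


def _parse_ome(xml_text: str) -> tuple[dict, list[str]]:
    """Pull physical sizes and channel names out of OME-XML."""
    cal: dict = {}
    names: list[str] = []
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return cal, names
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag.split("}")[0] + "}"
    pixels = root.find(f".//{ns}Pixels")
    if pixels is not None:
        for attr, key in (
            ("PhysicalSizeX", "dx"),
            ("PhysicalSizeY", "dy"),
            ("PhysicalSizeZ", "dz"),
            ("TimeIncrement", "dt"),
        ):
            v = pixels.get(attr)
            if v is not None:
                cal[key] = float(v)
        for ch in pixels.findall(f"{ns}Channel"):
            names.append(ch.get("Name") or "other")
    return cal, names


def read_stack(
    path: str | Path,
    axes_hint: str | None = None,
    calibration: PixelCalibration | None = None,
    channel_roles: Mapping[int, str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into a canonical ImageStack.

    Axis order is taken from OME/ImageJ metadata when present, else from
    ``axes_hint``.  OME calibration metadata, when present, overrides the
    ``calibration`` argument.  Raises a ValueError when the axis order cannot
    be determined (no silent guessing).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "")
        ome_cal: dict = {}
        ome_names: list[str] = []
        if tif.ome_metadata:
            ome_cal, ome_names = _parse_ome(tif.ome_metadata)
    known = set(AXES)
    if not axes or not set(axes) <= known or len(axes) != data.ndim:
        if axes_hint is None:
            raise ValueError(
                f"axes underdetermined for {path.name} (metadata axes={axes!r}); "
                "pass axes_hint"
            )
        axes = axes_hint
    data = normalize_axes(data, axes)
    cal = calibration or PixelCalibration()
    if ome_cal:
        cal = PixelCalibration(
            dx=ome_cal.get("dx", cal.dx),
            dy=ome_cal.get("dy", cal.dy),
            dz=ome_cal.get("dz", cal.dz),
            dt=ome_cal.get("dt", cal.dt),
        )
    roles = dict(channel_roles or {})
    if not roles and ome_names:
        roles = {
            i: (n if n in CHANNEL_ROLES else "other") for i, n in enumerate(ome_names)
        }
    return ImageStack(data=data, calibration=cal, channel_roles=roles)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as OME-TIFF, preserving calibration and roles."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cal = stack.calibration
    names = [
        stack.channel_roles.get(c, "other") for c in range(stack.n_channels)
    ]
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": AXES,
            "PhysicalSizeX": cal.dx,
            "PhysicalSizeY": cal.dy,
            "PhysicalSizeZ": cal.dz,
            "TimeIncrement": cal.dt,
            "Channel": {"Name": names},
        },
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV (header row, >=6 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if table.columns.duplicated().any():
        raise ValueError("result table column names must be unique")
    table.to_csv(path, index=False, float_format="%.9g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


class OsmolarityPreset(BaseModel):
    """One row of the hypoosmotic dilution scheme (volumes in µL)."""

    model_config = ConfigDict(extra="forbid")

    v_start_ul: float
    v_diluent_ul: float
    start_osm: float = 341.0
    diluent_osm: float = 3.78  # water + 1.26 mM CaCl2, ideal full dissociation


class RunConfig(BaseModel):
    """Validated configuration for every pipeline stage.

    Unknown keys are rejected so that typos surface as errors rather than
    silently falling back to defaults.
    """

    model_config = ConfigDict(extra="forbid")

    # preprocessing
    guv_blur_sigma_px: float = 3.0
    nuclei_blur_sigma_px: float = 1.0
    rolling_ball_radius_px: int = 50
    norm_percentiles: tuple[float, float] = (0.1, 99.9)
    # contours / segmentation
    contour_width_px: int = 3
    min_nucleus_volume_vox: int = 200
    min_er_volume_vox: int = 10
    er_ridge_sigmas_px: tuple[float, ...] = (1.0, 2.0)
    # tracking
    max_displacement_um: float = 50.0
    min_track_length: int = 3
    # measurement
    median_on_raw: bool = True
    background_ring_radius_frac: float = 0.5
    # calibration defaults
    dx_um: float = 0.16
    dy_um: float = 0.16
    dz_um: float = 1.5
    dt_min: float = 1.0
    # experiment presets
    guv_buffer_delta_mosm: float = Field(
        default=240.0, description="osmotic differential of the GUV binding buffers"
    )
    hypoosmotic_presets: dict[str, OsmolarityPreset] = Field(
        default_factory=lambda: {
            "mild": OsmolarityPreset(v_start_ul=80, v_diluent_ul=320),
            "maximal": OsmolarityPreset(v_start_ul=40, v_diluent_ul=360),
        }
    )

    def calibration(self) -> PixelCalibration:
        return PixelCalibration(
            dx=self.dx_um, dy=self.dy_um, dz=self.dz_um, dt=self.dt_min
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty / missing file yields the full default configuration; unknown
    keys raise a validation error naming the key.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
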