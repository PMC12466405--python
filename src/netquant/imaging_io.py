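"""Calibrated image I/O and region-of-interest sampling.

The assay works on single-channel fluorescence rasters of a DNA stain
(Sytox Orange in the source protocol).  Physical calibration (µm per pixel
edge) is mandatory user input: scanner metadata, when present, is only
cross-checked, never trusted over the explicit value.

Coordinate conventions
----------------------
Pixel indices are 0-based and row-major.  Physical coordinates place pixel
``(r, c)`` with its top-left corner at ``(c * s, r * s)`` where ``s`` is the
pixel size; the x axis runs rightward (columns), y downward (rows).
Rectangles are half-open in pixel space so that areas add up exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, PlacementError

logger = logging.getLogger(__name__)

#: Total sampled area for the single-region strategy (5 mm² in µm²).
SINGLE_AREA_DEFAULT_UM2 = 5_000_000.0
#: Per-quadrant area for the random-quadrant strategy (4 mm² in µm²).
QUADRANT_AREA_DEFAULT_UM2 = 4_000_000.0
#: Number of random quadrants sampled per preparation.
QUADRANT_COUNT_DEFAULT = 5
#: Rejection-sampling budget for non-overlapping quadrant placement.
PLACEMENT_ATTEMPTS_DEFAULT = 10_000


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel size of the acquisition, in microns per pixel edge."""

    pixel_size_um: float
    objective_label: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")


@dataclass
class Image2D:
    """A calibrated single-channel intensity raster.

    ``pixels`` is a 2D unsigned-integer grid; every intensity lies in
    ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        info_max = 2 ** self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > info_max:
            raise ValueError(f"intensities must lie in [0, {info_max}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_um(self) -> float:
        return self.pixels.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.pixel_size_um

    @property
    def intensity_max(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region of interest in physical units.

    ``strategy`` records how the rectangle was produced (``single_area`` or
    ``random_quadrants``); ``index`` is its ordinal within the sample.
    """

    x0_um: float
    y0_um: float
    width_um: float
    height_um: float
    strategy: str = "single_area"
    index: int = 0

    def __post_init__(self) -> None:
        if self.width_um * self.height_um <= 0:
            raise ValueError("ROI must have positive area")
        if self.x0_um < 0 or self.y0_um < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def to_pixel_slices(self, pixel_size_um: float) -> tuple[slice, slice]:
        """Half-open (row, column) slices covering the rectangle."""
        c0 = int(round(self.x0_um / pixel_size_um))
        r0 = int(round(self.y0_um / pixel_size_um))
        c1 = int(round((self.x0_um + self.width_um) / pixel_size_um))
        r1 = int(round((self.y0_um + self.height_um) / pixel_size_um))
        return slice(r0, r1), slice(c0, c1)


def area_um2(area_px: int | float, calibration: PixelCalibration | float) -> float:
    """Convert a pixel count to physical area (µm²).

    Linear in the pixel count: ``area_px * pixel_size_um**2``.
    """
    if area_px < 0:
        raise ValueError(f"area_px must be non-negative, got {area_px}")
    s = calibration.pixel_size_um if isinstance(calibration, PixelCalibration) else float(calibration)
    return float(area_px) * s * s


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"unsupported dtype {arr.dtype}: expected uint8 or uint16")


_OME_SIZE_RE = re.compile(r'PhysicalSizeX="([0-9.eE+-]+)"')


def load_image(path: str | Path, calibration: PixelCalibration, channel_label: str = "") -> Image2D:
    """Read a single-channel 8/16-bit TIFF/OME-TIFF as a calibrated image.

    The first plane of a multi-page file is taken.  If OME metadata records a
    pixel size that conflicts with ``calibration`` the explicit calibration
    wins and a warning is logged.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.pages[0].asarray()
            ome = tf.ome_metadata
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            raise FormatError(f"{path} looks RGB(A); a single channel is required")
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D plane, got shape {arr.shape}")
    if ome:
        m = _OME_SIZE_RE.search(ome)
        if m:
            meta_size = float(m.group(1))
            if not np.isclose(meta_size, calibration.pixel_size_um, rtol=1e-3):
                logger.warning(
                    "OME pixel size %.6g um conflicts with configured %.6g um; using configured value",
                    meta_size,
                    calibration.pixel_size_um,
                )
    return Image2D(
        pixels=arr,
        bit_depth=_bit_depth_of(arr),
        pixel_size_um=calibration.pixel_size_um,
        channel_label=channel_label,
    )


def save_image(image: Image2D, path: str | Path) -> None:
    """Write the raster back to TIFF, preserving dtype and pixel values."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(Path(path), image.pixels.astype(dtype))


def sample_rois(
    image: Image2D,
    strategy: str,
    *,
    seed: int = 0,
    total_area_um2: float = SINGLE_AREA_DEFAULT_UM2,
    n_rois: int = QUADRANT_COUNT_DEFAULT,
    roi_area_um2: float = QUADRANT_AREA_DEFAULT_UM2,
    origin_um: tuple[float, float] | None = None,
    max_attempts: int = PLACEMENT_ATTEMPTS_DEFAULT,
) -> list[ROISpec]:
    """Generate measurement ROIs under one of the two sampling strategies.

    ``single_area`` produces one square of ``total_area_um2`` (default 5 mm²),
    centred unless ``origin_um`` pins its top-left corner — placement is
    exposed so the user can steer clear of preparation artefacts such as air
    bubbles, which the assay avoids by eye.  ``random_quadrants`` draws
    ``n_rois`` (default 5) squares of ``roi_area_um2`` each (default 4 mm²),
    uniformly at random without mutual overlap, reproducibly for a fixed seed.
    """
    s = image.pixel_size_um
    W, H = image.width_um, image.height_um

    if strategy == "single_area":
        side = float(np.sqrt(total_area_um2))
        if side > W + 1e-9 or side > H + 1e-9:
            raise ConfigurationError(
                f"single_area ROI of {total_area_um2} um^2 (side {side:.1f} um) "
                f"does not fit in a {W:.1f} x {H:.1f} um image"
            )
        side_px = int(round(side / s))
        if origin_um is None:
            c0 = (image.shape[1] - side_px) // 2
            r0 = (image.shape[0] - side_px) // 2
        else:
            c0 = int(round(origin_um[0] / s))
            r0 = int(round(origin_um[1] / s))
            if c0 < 0 or r0 < 0 or c0 + side_px > image.shape[1] or r0 + side_px > image.shape[0]:
                raise ConfigurationError("requested single_area origin places the ROI outside the image")
        return [
            ROISpec(
                x0_um=c0 * s,
                y0_um=r0 * s,
                width_um=side_px * s,
                height_um=side_px * s,
                strategy="single_area",
                index=0,
            )
        ]

    if strategy == "random_quadrants":
        side = float(np.sqrt(roi_area_um2))
        side_px = int(round(side / s))
        if side_px > image.shape[1] or side_px > image.shape[0]:
            raise ConfigurationError(
                f"quadrant of {roi_area_um2} um^2 (side {side:.1f} um) exceeds the image extent"
            )
        if n_rois * roi_area_um2 > W * H + 1e-9:
            raise ConfigurationError(
                f"total requested ROI area {n_rois * roi_area_um2} um^2 exceeds the image area"
            )
        rng = np.random.default_rng(seed)
        placed: list[tuple[int, int]] = []  # (r0, c0) in px
        attempts = 0
        while len(placed) < n_rois:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"could not place {n_rois} disjoint quadrants in {max_attempts} attempts"
                )
            attempts += 1
            c0 = int(rng.integers(0, image.shape[1] - side_px + 1))
            r0 = int(rng.integers(0, image.shape[0] - side_px + 1))
            if all(
                abs(c0 - pc) >= side_px or abs(r0 - pr) >= side_px for pr, pc in placed
            ):
                placed.append((r0, c0))
        return [
            ROISpec(
                x0_um=c0 * s,
                y0_um=r0 * s,
                width_um=side_px * s,
                height_um=side_px * s,
                strategy="random_quadrants",
                index=i,
            )
            for i, (r0, c0) in enumerate(placed)
        ]

    raise ValueError(f"unknown ROI strategy {strategy!r}")


_ROI_COLUMNS = ["index", "strategy", "x0_um", "y0_um", "width_um", "height_um"]


def rois_to_csv(rois: list[ROISpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "index": r.index,
                "strategy": r.strategy,
                "x0_um": r.x0_um,
                "y0_um": r.y0_um,
                "width_um": r.width_um,
                "height_um": r.height_um,
            }
            for r in rois
        ],
        columns=_ROI_COLUMNS,
    ).to_csv(path, index=False)


def rois_from_csv(path: str | Path) -> list[ROISpec]:
    df = pd.read_csv(path)
    return [
        ROISpec(
            x0_um=row["x0_um"],
            y0_um=row["y0_um"],
            width_um=row["width_um"],
            height_um=row["height_um"],
            strategy=row["strategy"],
            index=int(row["index"]),
        )
        for _, row in df.iterrows()
    ]
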