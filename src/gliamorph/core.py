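"""Calibrated image containers, region-of-interest handling and raster I/O.

All images use (row, col) indexing, 0-based, row 0 at the top.  Spatial
calibration (µm per pixel edge) is mandatory metadata on every container;
reported lengths and areas downstream are in µm and µm².

ROI polygons live in pixel coordinates as ``[[row, col], ...]`` vertex lists.
Rasterization uses pixel-center containment: pixel ``(r, c)`` belongs to a
polygon iff its center ``(r + 0.5, c + 0.5)`` lies strictly inside.  For
integer-vertex axis-aligned polygons this reproduces the half-open convention
(a square spanning rows/cols 0..10 covers exactly the 10×10 pixel block).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import shapely

from .errors import InputError, ValidationError

__all__ = [
    "StainedSection",
    "GrayImage",
    "BinaryMask",
    "LabelMap",
    "RoiSet",
    "read_section",
    "read_roiset",
    "write_mask_png",
    "rasterize_polygon",
]


@dataclass
class StainedSection:
    """An 8-bit RGB brightfield image of a stained section.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        RGB intensities, 0–255 per channel.
    calibration : float
        Pixel edge length in µm/pixel; must be > 0.
    label : str
        Free-text section identifier.
    stain_pair : (str, str)
        Names of the expected chromogen and counterstain, e.g.
        ``("dab", "hematoxylin")``.
    """

    pixels: np.ndarray
    calibration: float
    label: str = ""
    stain_pair: tuple[str, str] = ("dab", "hematoxylin")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"StainedSection expects an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValidationError("StainedSection grid is empty")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("RGB intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        _check_calibration(self.calibration)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def mean_gray(self) -> "GrayImage":
        """Unweighted mean of the three channels, as a float gray image."""
        return GrayImage(self.pixels.mean(axis=2), self.calibration)


@dataclass
class GrayImage:
    """A single-channel image of real-valued intensities with calibration.

    Intensities must be finite unless ``allow_nan`` is set, in which case
    NaN marks flagged/invalid pixels (used by the MTR map).
    """

    pixels: np.ndarray
    calibration: float
    allow_nan: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("GrayImage expects a non-empty 2-D array")
        finite = np.isfinite(self.pixels)
        if self.allow_nan:
            if np.any(~finite & ~np.isnan(self.pixels)):
                raise ValidationError("GrayImage intensities must be finite or NaN")
        elif not np.all(finite):
            raise ValidationError("GrayImage intensities must be finite")
        _check_calibration(self.calibration)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0, 1} mask sharing the grid and calibration of its source image."""

    pixels: np.ndarray
    calibration: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("BinaryMask values must be strictly in {0, 1}")
        self.pixels = arr.astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("BinaryMask expects a non-empty 2-D array")
        _check_calibration(self.calibration)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.calibration**2


@dataclass
class LabelMap:
    """Connected objects as a non-negative integer label image.

    0 is background; objects are labeled 1..object_count consecutively and
    are 8-connected.
    """

    pixels: np.ndarray
    object_count: int = field(default=-1)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("LabelMap expects a 2-D array")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("LabelMap values must be non-negative")
        self.pixels = self.pixels.astype(np.int32)
        n = int(self.pixels.max(initial=0))
        if self.object_count == -1:
            self.object_count = n
        labels = np.unique(self.pixels)
        labels = labels[labels > 0]
        if len(labels) != self.object_count or (
            len(labels) and (labels[0] != 1 or labels[-1] != self.object_count)
        ):
            raise ValidationError(
                "LabelMap labels must be consecutive 1..object_count"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_mask(self, calibration: float = 1.0) -> BinaryMask:
        return BinaryMask(self.pixels > 0, calibration)


def _check_calibration(calibration: float) -> None:
    if not (np.isfinite(calibration) and calibration > 0):
        raise ValidationError(f"calibration must be a positive µm/pixel value, got {calibration!r}")


# ---------------------------------------------------------------------------
# ROI handling
# ---------------------------------------------------------------------------

class RoiSet:
    """Named regions of interest, stored as polygons and/or masks.

    Regions are held in insertion order; names must be unique.
    """

    def __init__(self) -> None:
        self._regions: dict[str, np.ndarray | None] = {}
        self._polygons: dict[str, np.ndarray | None] = {}

    @property
    def names(self) -> list[str]:
        return list(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def add_polygon(self, name: str, polygon: Sequence[Sequence[float]]) -> None:
        if name in self._regions:
            raise ValidationError(f"duplicate ROI name: {name!r}")
        poly = np.asarray(polygon, dtype=np.float64)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValidationError(
                f"ROI {name!r}: polygon must be an (N>=3, 2) list of [row, col] vertices"
            )
        self._regions[name] = None
        self._polygons[name] = poly

    def add_mask(self, name: str, mask: np.ndarray) -> None:
        if name in self._regions:
            raise ValidationError(f"duplicate ROI name: {name!r}")
        m = np.asarray(mask).astype(bool)
        if not m.any():
            raise ValidationError(f"ROI {name!r}: mask is empty")
        self._regions[name] = m
        self._polygons[name] = None

    def mask(self, name: str, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize region ``name`` onto a grid of ``shape``."""
        if name not in self._regions:
            raise ValidationError(f"unknown ROI name: {name!r}")
        stored = self._regions[name]
        if stored is not None:
            if stored.shape != tuple(shape):
                raise ValidationError(
                    f"ROI {name!r}: stored mask shape {stored.shape} != image shape {tuple(shape)}"
                )
            return stored.copy()
        mask = rasterize_polygon(self._polygons[name], shape)
        if not mask.any():
            raise ValidationError(f"ROI {name!r}: polygon covers no pixel inside the image")
        return mask

    def masks(self, shape: tuple[int, int]) -> dict[str, np.ndarray]:
        return {name: self.mask(name, shape) for name in self._regions}


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a [row, col] polygon by pixel-center containment.

    A pixel (r, c) is covered iff (r + 0.5, c + 0.5) lies strictly inside
    the polygon, which is orientation-independent and half-open on integer
    axis-aligned boundaries.
    """
    poly = np.asarray(polygon, dtype=np.float64)
    h, w = shape
    geom = shapely.Polygon(poly[:, ::-1])  # shapely wants (x, y) = (col, row)
    if not geom.is_valid:
        geom = geom.buffer(0)
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())), h)
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())), w)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = shapely.contains_xy(geom, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def read_roiset(path: str | Path, image_shape: tuple[int, int]) -> RoiSet:
    """Read a ROI-JSON file ``{"regions": [{"name": ..., "polygon": [[r, c], ...]}]}``.

    Every polygon must rasterize to at least one pixel of ``image_shape``;
    duplicate names are rejected.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except OSError as exc:
        raise InputError(f"cannot read ROI file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise InputError(f"ROI file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "regions" not in payload:
        raise ValidationError(f"ROI file {path} lacks a top-level 'regions' list")
    rois = RoiSet()
    for entry in payload["regions"]:
        if "name" not in entry or "polygon" not in entry:
            raise ValidationError(f"ROI file {path}: each region needs 'name' and 'polygon'")
        rois.add_polygon(str(entry["name"]), entry["polygon"])
    # validate every polygon against the image bounds up front
    for name in rois.names:
        rois.mask(name, image_shape)
    return rois


def write_roiset(rois: RoiSet, path: str | Path) -> None:
    regions = []
    for name in rois.names:
        poly = rois._polygons[name]
        if poly is None:
            raise ValidationError(f"ROI {name!r} is mask-backed and cannot be saved as polygon JSON")
        regions.append({"name": name, "polygon": poly.tolist()})
    Path(path).write_text(json.dumps({"regions": regions}), encoding="utf-8")


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def read_section(
    path: str | Path,
    calibration: float,
    stain_pair: tuple[str, str] = ("dab", "hematoxylin"),
    label: str | None = None,
) -> StainedSection:
    """Read an 8-bit RGB TIFF/PNG as a calibrated stained section.

    Intensities pass through losslessly; ``calibration`` (µm/pixel) is
    required because scan files rarely carry trustworthy pixel-size metadata.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read image {path}: file not found") from exc
    except Exception as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if fully opaque
        if np.all(arr[:, :, 3] == 255):
            arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise InputError(
            f"{path} is not an 8-bit RGB raster (got shape {arr.shape}, dtype {arr.dtype})"
        )
    return StainedSection(arr, calibration, label=label or path.stem, stain_pair=stain_pair)


def read_gray(path: str | Path, calibration: float) -> GrayImage:
    """Read a grayscale raster (8- or 16-bit) as a float gray image."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read image {path}: file not found") from exc
    except Exception as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise InputError(f"{path} is not a single-channel grayscale raster (shape {arr.shape})")
    return GrayImage(arr.astype(np.float64), calibration)


def write_mask_png(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))


def write_section_png(section: StainedSection, path: str | Path) -> None:
    iio.imwrite(Path(path), section.pixels)


def write_gray_u16(gray: GrayImage, path: str | Path) -> None:
    """Write a gray image as 16-bit TIFF/PNG, clipping to [0, 65535]."""
    arr = np.clip(np.round(gray.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)
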