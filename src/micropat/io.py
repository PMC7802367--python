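"""Image containers and file I/O.

Images are plain numpy arrays wrapped with the two pieces of calibration
metadata every downstream metric needs: the pixel size (µm/px) and, for
movies, the frame interval (s). TIFF reading/writing is delegated to
:mod:`tifffile`; masks travel either as 16-bit label TIFFs or as JSON
polygon lists (rasterized with scikit-image).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon as _draw_polygon

#: default pixel size, µm per pixel (100x objective on a back-illuminated sCMOS)
DEFAULT_PIXEL_SIZE_UM = 0.11


@dataclass
class ImageFrame:
    """A single calibrated 2D fluorescence image."""

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ImageFrame expects a 2D array, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class TimeLapse:
    """A calibrated time-lapse movie stored as a (t, y, x) array."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"TimeLapse expects a (t, y, x) array, got shape {self.data.shape}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> ImageFrame:
        return ImageFrame(self.data[t], self.pixel_size_um, self.channel)


def as_array(image) -> np.ndarray:
    """Accept an ImageFrame or a bare 2D array and return the array."""
    if isinstance(image, ImageFrame):
        return image.data
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
               channel: str = "") -> ImageFrame:
    return ImageFrame(tifffile.imread(str(path)), pixel_size_um, channel)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (t, y, x) array (a single page gains a t axis)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def read_movie(path: str | Path, frame_interval_s: float,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM, channel: str = "") -> TimeLapse:
    return TimeLapse(read_stack(path), frame_interval_s, pixel_size_um, channel)


def write_image(path: str | Path, image: ImageFrame | np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(as_array(image)))


def write_stack(path: str | Path, stack: np.ndarray | TimeLapse) -> None:
    data = stack.data if isinstance(stack, TimeLapse) else np.asarray(stack)
    tifffile.imwrite(str(path), data)


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# Polygon ROIs and run configuration
# ---------------------------------------------------------------------------

def polygons_to_mask(polygons: list, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a list of polygons (each a list of (row, col) vertices) to a
    boolean mask. Vertices are pixel-centered, 0-based, row-major."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        rr, cc = _draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        mask[rr, cc] = True
    return mask


def read_roi_json(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read a JSON file holding either one polygon or a list of polygons."""
    with open(path) as fh:
        data = json.load(fh)
    if data and isinstance(data[0][0], (int, float)):
        data = [data]
    return polygons_to_mask(data, shape)


@dataclass
class RunConfig:
    """Run configuration: which channel was acquired for which micropattern,
    in micropatterning order, plus the pixel calibration."""

    assignment: dict[str, int] = field(default_factory=dict)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float | None = None
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw.pop(k) for k in ("assignment", "pixel_size_um", "frame_interval_s")
             if k in raw}
    cfg = RunConfig(**known, extra=raw)
    if cfg.assignment:
        cfg.assignment = {str(k): int(v) for k, v in cfg.assignment.items()}
    return cfg
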