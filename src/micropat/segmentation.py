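"""Micropattern detection from an anchor-fluorescence channel.

Produces the label masks consumed by the ROI metrics, plus the pattern-size
filter (equivalent diameter 20–40 µm by default) applied before
cell-adhesion analysis. Manual ROIs remain first-class inputs that bypass
this module entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as _label, regionprops

from .io import DEFAULT_PIXEL_SIZE_UM, ImageFrame, as_array

#: diameter gate used for the cell-adhesion analysis, µm
DEFAULT_DIAMETER_RANGE_UM = (20.0, 40.0)


@dataclass
class LabelMask:
    """Integer label image (0 = background) with pixel calibration.

    Per-label area (µm²) and equivalent diameter (2·sqrt(area/π), µm) are
    derived on demand from the label image.
    """

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    def mask_for(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def areas_um2(self) -> dict[int, float]:
        px_area = self.pixel_size_um ** 2
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): float(c) * px_area for i, c in zip(ids, counts)}

    def equivalent_diameters_um(self) -> dict[int, float]:
        return {i: 2.0 * np.sqrt(a / np.pi) for i, a in self.areas_um2().items()}

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def total_area_um2(self) -> float:
        return float(np.count_nonzero(self.labels)) * self.pixel_size_um ** 2


def segment_patterns(anchor: ImageFrame | np.ndarray,
                     min_area_um2: float = 10.0,
                     method: str = "otsu",
                     threshold: float | None = None,
                     pixel_size_um: float | None = None,
                     smooth_sigma_px: float = 1.0,
                     connectivity: int = 2) -> LabelMask:
    """Threshold the anchor channel, fill holes, drop small components, label.

    ``method`` is ``"otsu"`` (default; Otsu threshold on a Gaussian-smoothed
    copy) or ``"fixed_threshold"`` (absolute intensity ``threshold``, for
    reproducible tests). ``connectivity`` 1 = 4-connected, 2 = 8-connected.
    An image where nothing survives yields an empty mask with a warning,
    not an error.
    """
    data = np.asarray(as_array(anchor), dtype=float)
    if pixel_size_um is None:
        pixel_size_um = anchor.pixel_size_um if isinstance(anchor, ImageFrame) \
            else DEFAULT_PIXEL_SIZE_UM
    smoothed = gaussian(data, sigma=smooth_sigma_px, preserve_range=True) \
        if smooth_sigma_px > 0 else data
    if method == "otsu":
        if smoothed.max() <= smoothed.min():
            warnings.warn("anchor image has no dynamic range; empty mask returned")
            return LabelMask(np.zeros(data.shape, dtype=np.int32), pixel_size_um)
        thr = threshold_otsu(smoothed)
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold method requires a threshold value")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    binary = ndi.binary_fill_holes(smoothed > thr)
    labels = _label(binary, connectivity=connectivity)
    min_px = int(np.ceil(min_area_um2 / pixel_size_um ** 2))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= max(min_px, 1)]
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    if out.max() == 0:
        warnings.warn("no micropattern survived segmentation; empty mask returned")
    return LabelMask(out, pixel_size_um)


def filter_by_diameter(mask: LabelMask,
                       min_d_um: float = DEFAULT_DIAMETER_RANGE_UM[0],
                       max_d_um: float = DEFAULT_DIAMETER_RANGE_UM[1]) -> LabelMask:
    """Keep labels whose equivalent diameter lies in [min_d_um, max_d_um]
    (inclusive bounds). Surviving labels keep their ids and pixel sets."""
    if min_d_um > max_d_um:
        raise ValueError("min_d_um must not exceed max_d_um")
    diam = mask.equivalent_diameters_um()
    keep = {i for i, d in diam.items() if min_d_um <= d <= max_d_um}
    out = np.where(np.isin(mask.labels, sorted(keep)), mask.labels, 0).astype(np.int32)
    return LabelMask(out, mask.pixel_size_um)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
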