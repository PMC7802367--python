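"""Cell-on-micropattern adhesion metrics.

Compares coatings (e.g. Con A vs fibrinogen–Con A) by how densely cells
decorate the micropatterns and how specific that adhesion is. A cell is
"on" a pattern iff its centroid lies in a labeled pixel (configurable to
any-overlap); the pattern mask should already be diameter-filtered
(20–40 µm) before counting.

* normalized patterned cell density — the sample's on-pattern density
  (cells/µm²) divided by the mean on-pattern density of the reference
  condition (Con A), so the reference averages to 1 by construction;
* normalized nonspecific adhesion — 100·d_off/(d_on + d_off) with d the
  count/area densities, a percentage in [0, 100]: 50% when adhesion is
  indifferent to the pattern, 0% when perfectly specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import Unmeasurable
from .segmentation import LabelMask


@dataclass(frozen=True)
class CellCounts:
    """Cells and areas on/off the micropatterns for one field of view."""

    n_on: int
    area_on_um2: float
    n_off: int
    area_off_um2: float
    condition: str = ""
    is_reference: bool = False

    def __post_init__(self):
        if self.n_on < 0 or self.n_off < 0:
            raise ValueError("counts must be >= 0")
        if self.area_on_um2 < 0 or self.area_off_um2 < 0:
            raise ValueError("areas must be >= 0")
        if (self.area_on_um2 == 0 and self.n_on > 0) or \
                (self.area_off_um2 == 0 and self.n_off > 0):
            raise ValueError("cells counted in a region of zero area")

    @property
    def density_on(self) -> float:
        return self.n_on / self.area_on_um2 if self.area_on_um2 > 0 else 0.0

    @property
    def density_off(self) -> float:
        return self.n_off / self.area_off_um2 if self.area_off_um2 > 0 else 0.0


def assign_cells(centroids, mask: LabelMask, condition: str = "",
                 is_reference: bool = False, rule: str = "centroid",
                 cell_radius_um: float | None = None) -> CellCounts:
    """Count cells on/off the patterns of one field.

    ``centroids`` is an (n, 2) array of (row, col) pixel points. The default
    ``"centroid"`` rule counts a cell as on-pattern iff its centroid lies in
    a labeled pixel; ``"any_overlap"`` counts it if any labeled pixel lies
    within ``cell_radius_um`` of the centroid.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    labels = mask.labels
    h, w = labels.shape
    if len(pts) and ((pts[:, 0] < 0).any() or (pts[:, 1] < 0).any()
                     or (pts[:, 0] >= h).any() or (pts[:, 1] >= w).any()):
        raise ValueError("centroids must lie within the field bounds")
    if rule == "centroid":
        on = np.array([labels[int(round(r)), int(round(c))] > 0 for r, c in pts],
                      dtype=bool) if len(pts) else np.zeros(0, dtype=bool)
    elif rule == "any_overlap":
        if cell_radius_um is None:
            raise ValueError("any_overlap rule requires cell_radius_um")
        r_px = cell_radius_um / mask.pixel_size_um
        fg = np.argwhere(labels > 0)
        on = np.array([
            bool(len(fg)) and (np.min(np.hypot(fg[:, 0] - r, fg[:, 1] - c)) <= r_px)
            for r, c in pts], dtype=bool) if len(pts) else np.zeros(0, dtype=bool)
    else:
        raise ValueError(f"unknown assignment rule {rule!r}")
    px_area = mask.pixel_size_um ** 2
    area_on = float(np.count_nonzero(labels)) * px_area
    area_off = float(labels.size - np.count_nonzero(labels)) * px_area
    return CellCounts(int(on.sum()), area_on, int(len(pts) - on.sum()), area_off,
                      condition=condition, is_reference=is_reference)


def reference_mean_density(reference_fields: list[CellCounts]) -> float:
    """Mean on-pattern density of the reference condition's fields."""
    if not reference_fields:
        raise ValueError("at least one reference field is required")
    return float(np.mean([f.density_on for f in reference_fields]))


def normalized_density(sample: CellCounts, reference_mean: float) -> float:
    """On-pattern density of the sample divided by the reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean density must be positive")
    return sample.density_on / reference_mean


def nonspecific_adhesion(sample: CellCounts) -> float | Unmeasurable:
    """100 · d_off / (d_on + d_off), a percentage in [0, 100]."""
    d_on = sample.density_on
    d_off = sample.density_off
    if d_on + d_off == 0:
        return Unmeasurable("no cells in the field")
    return 100.0 * d_off / (d_on + d_off)
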