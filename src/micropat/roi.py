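"""Per-micropattern intensity statistics.

The atoms of every metric in this package are background-subtracted ROI
means. A micropattern is scored by three numbers:

* **selectivity** — (on-pattern mean − camera background) divided by the
  same quantity for an adjacent, equally sized off-pattern ROI. A perfectly
  clean pattern on a perfectly passivated surface has high selectivity; a
  pattern indistinguishable from its surroundings scores 1.
* **homogeneity** — background-corrected on-pattern mean divided by the
  background-corrected on-pattern *variance* (units ADU⁻¹). More uniform
  deposition gives a higher value. The variance (not SD) denominator is the
  field convention this package follows; an SD-based variant is available
  as :func:`homogeneity_sd` and is never substituted silently.
* **amount patterned** — on-pattern mean minus off-pattern mean, a proxy
  for deposited protein that is only comparable within one fluorophore.

Sequential multiplexed patterns are additionally scored by a normalized
cross-adsorption matrix: for each imaging channel, the background-corrected
signal on every pattern divided by the signal on the channel's *intended*
pattern (the one its protein was deposited on), so the diagonal is 1 by
construction and off-diagonal entries are cross-contamination fractions.

Denominators at or below the camera floor are reported as a typed
:class:`Unmeasurable` result — never clipped, never infinite — so that
downstream aggregation has to exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageFrame, as_array


@dataclass(frozen=True)
class Unmeasurable:
    """Typed marker for a metric whose denominator sits at or below the
    camera floor. Evaluates falsy so ``if result:`` skips it."""

    reason: str

    def __bool__(self) -> bool:
        return False


def is_measurable(value) -> bool:
    return not isinstance(value, Unmeasurable)


@dataclass(frozen=True)
class RoiStats:
    """Mean, unbiased (n−1) sample variance and pixel count of one ROI.

    ``degenerate`` flags a single-pixel ROI, whose variance is defined
    as 0 by convention.
    """

    mean: float
    variance: float
    n_pixels: int
    degenerate: bool = False

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValueError("RoiStats requires at least one pixel")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass(frozen=True)
class CameraBackground:
    """Scalar dark-signal mean and variance of the camera."""

    mean: float
    variance: float

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass
class PatternSet:
    """Ordered sequential micropatterns plus the channel → intended-pattern map.

    ``patterns`` maps pattern_id → boolean mask; ``assignment`` maps each
    imaging channel to the pattern its protein was deposited on, reflecting
    the micropatterning order. Masks must be pairwise disjoint.
    """

    patterns: dict[int, np.ndarray]
    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.patterns = {int(k): np.asarray(v, dtype=bool) for k, v in self.patterns.items()}
        total = None
        for pid, mask in self.patterns.items():
            if not mask.any():
                raise ValueError(f"pattern {pid} has an empty mask")
            if total is None:
                total = mask.astype(np.int8).copy()
            else:
                if mask.shape != total.shape:
                    raise ValueError("pattern masks must share one shape")
                total += mask
        if total is not None and (total > 1).any():
            raise ValueError("pattern masks must be disjoint")
        for ch, pid in self.assignment.items():
            if pid not in self.patterns:
                raise ValueError(f"channel {ch!r} assigned to missing pattern {pid}")

    @property
    def union_mask(self) -> np.ndarray:
        out = np.zeros(next(iter(self.patterns.values())).shape, dtype=bool)
        for mask in self.patterns.values():
            out |= mask
        return out


@dataclass(frozen=True)
class PatternMetrics:
    pattern_id: int
    channel: str
    selectivity: float | Unmeasurable
    homogeneity: float | Unmeasurable
    amount: float
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_roi(image: ImageFrame | np.ndarray, mask: np.ndarray) -> RoiStats:
    """Arithmetic mean, unbiased sample variance and pixel count over ``mask``."""
    data = as_array(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {data.shape}")
    values = data[mask]
    if values.size == 0:
        raise ValueError("empty mask")
    if values.size == 1:
        return RoiStats(float(values[0]), 0.0, 1, degenerate=True)
    return RoiStats(float(values.mean()), float(values.var(ddof=1)), int(values.size))


def estimate_camera_background(dark_stack: np.ndarray) -> CameraBackground:
    """Pool a dark-frame stack into a scalar camera background.

    Per-pixel temporal mean and unbiased variance are computed across the
    stack and then averaged over pixels, yielding the single (mean, variance)
    pair used by every metric.
    """
    stack = np.asarray(dark_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("dark stack must be (t, y, x)")
    mean = float(stack.mean(axis=0).mean())
    if stack.shape[0] < 2:
        raise ValueError("at least two dark frames are needed to estimate variance")
    var = float(stack.var(axis=0, ddof=1).mean())
    return CameraBackground(mean, var)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def selectivity(pattern: RoiStats, not_pattern: RoiStats,
                camera: CameraBackground) -> float | Unmeasurable:
    """(pattern.mean − camera.mean) / (not_pattern.mean − camera.mean)."""
    denom = not_pattern.mean - camera.mean
    if denom <= 0:
        return Unmeasurable("off-pattern mean at or below the camera floor")
    return (pattern.mean - camera.mean) / denom


def homogeneity(pattern: RoiStats, camera: CameraBackground) -> float | Unmeasurable:
    """(pattern.mean − camera.mean) / (pattern.variance − camera.variance).

    Units ADU⁻¹: the background-corrected mean divided by the
    background-corrected *variance*.
    """
    denom = pattern.variance - camera.variance
    if denom <= 0:
        return Unmeasurable("pattern variance at or below the camera floor")
    return (pattern.mean - camera.mean) / denom


def homogeneity_sd(pattern: RoiStats, camera: CameraBackground) -> float | Unmeasurable:
    """Variant normalizing by the background-corrected SD instead of the
    variance (unitless, akin to an inverse CV). Exposed under its own name;
    never substituted for :func:`homogeneity`."""
    denom = pattern.variance - camera.variance
    if denom <= 0:
        return Unmeasurable("pattern variance at or below the camera floor")
    return (pattern.mean - camera.mean) / float(np.sqrt(denom))


def amount_patterned(pattern: RoiStats, not_pattern: RoiStats) -> float:
    """pattern.mean − not_pattern.mean. Comparable only within one fluorophore;
    may legitimately be negative (pattern dimmer than its surroundings)."""
    return pattern.mean - not_pattern.mean


# ---------------------------------------------------------------------------
# multi-pattern quantities
# ---------------------------------------------------------------------------

def _image_dict(images: dict) -> dict[str, np.ndarray]:
    return {str(ch): as_array(im) for ch, im in images.items()}


def cross_adsorption_matrix(images: dict[str, ImageFrame | np.ndarray],
                            patterns: PatternSet,
                            camera: CameraBackground) -> pd.DataFrame:
    """Normalized cross-adsorption: entry[c, i] is the background-corrected
    mean of channel ``c`` on pattern ``i`` divided by the same on the
    channel's intended pattern. Diagonal entries are exactly 1; a channel
    whose intended-pattern signal sits at the background is returned as NaN
    for all entries (unmeasurable).
    """
    arrays = _image_dict(images)
    for ch in patterns.assignment:
        if ch not in arrays:
            raise ValueError(f"no image supplied for channel {ch!r}")
    pattern_ids = sorted(patterns.patterns)
    rows = {}
    for ch, intended in patterns.assignment.items():
        means = {pid: measure_roi(arrays[ch], patterns.patterns[pid]).mean
                 for pid in pattern_ids}
        denom = means[intended] - camera.mean
        if denom <= 0:
            rows[ch] = {pid: np.nan for pid in pattern_ids}
            continue
        rows[ch] = {pid: 1.0 if pid == intended else (means[pid] - camera.mean) / denom
                    for pid in pattern_ids}
    return pd.DataFrame.from_dict(rows, orient="index")[pattern_ids]


def _is_translation_of(roi: np.ndarray, reference: np.ndarray) -> bool:
    """True when ``roi`` is an exact pixelwise translation of ``reference``."""
    a = np.argwhere(roi)
    b = np.argwhere(reference)
    if len(a) != len(b):
        return False
    return bool(np.array_equal(a - a.min(axis=0), b - b.min(axis=0)))


def nonspecific_binding(image: ImageFrame | np.ndarray,
                        intended_mask: np.ndarray,
                        camera: CameraBackground,
                        offfield_image: ImageFrame | np.ndarray | None = None,
                        offfield_roi: np.ndarray | None = None) -> float | Unmeasurable:
    """Fraction of protein bound to the unexposed passivated surface,
    relative to the intended micropattern.

    The off-pattern measurement must be congruent with the intended-pattern
    ROI so that illumination inhomogeneity cancels. Two modes:

    * ``offfield_image`` — a second acquisition of an unpatterned sample
      region; the *same* ``intended_mask`` is applied to it, keeping the ROI
      at the identical position in the field of view.
    * ``offfield_roi`` — an ROI within ``image`` itself; it must be an exact
      translation of ``intended_mask`` (same shape, same pixel count) or it
      is rejected.
    """
    data = as_array(image)
    on = measure_roi(data, intended_mask)
    if offfield_image is not None:
        off = measure_roi(as_array(offfield_image), intended_mask)
    elif offfield_roi is not None:
        offfield_roi = np.asarray(offfield_roi, dtype=bool)
        if not _is_translation_of(offfield_roi, np.asarray(intended_mask, dtype=bool)):
            raise ValueError("off-field ROI must be congruent (a translation) "
                             "of the intended-pattern ROI")
        off = measure_roi(data, offfield_roi)
    else:
        raise ValueError("provide offfield_image or offfield_roi")
    denom = on.mean - camera.mean
    if denom <= 0:
        return Unmeasurable("intended-pattern signal at or below the camera floor")
    return (off.mean - camera.mean) / denom


# ---------------------------------------------------------------------------
# off-pattern ROI auto-placement
# ---------------------------------------------------------------------------

def auto_offpattern_roi(pattern_mask: np.ndarray,
                        exclusion_mask: np.ndarray,
                        margin_px: int = 3,
                        max_radius: int | None = None) -> np.ndarray:
    """Translate ``pattern_mask`` to the nearest position whose footprint
    avoids all patterns (``exclusion_mask`` dilated by ``margin_px``) and
    stays in bounds.

    Deterministic: among all collision-free translations, the shortest wins,
    ties broken by angle from east, counterclockwise. Collision testing uses
    a cross-correlation of the exclusion map with the ROI footprint, so the
    whole field is scanned at once.
    """
    from scipy.ndimage import binary_dilation
    from scipy.signal import fftconvolve

    pattern_mask = np.asarray(pattern_mask, dtype=bool)
    exclusion = np.asarray(exclusion_mask, dtype=bool)
    if margin_px > 0:
        exclusion = binary_dilation(exclusion, iterations=margin_px)
    coords = np.argwhere(pattern_mask)
    if coords.size == 0:
        raise ValueError("empty pattern mask")
    h, w = pattern_mask.shape
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    window = pattern_mask[rmin:rmax + 1, cmin:cmax + 1].astype(float)
    hm, wm = window.shape

    # overlap count for every top-left placement of the footprint
    corr = fftconvolve(exclusion.astype(float), window[::-1, ::-1], mode="full")
    corr = corr[hm - 1:hm - 1 + h - hm + 1, wm - 1:wm - 1 + w - wm + 1]
    free = corr < 0.5
    ii, jj = np.nonzero(free)
    dr = ii - rmin
    dc = jj - cmin
    keep = (dr != 0) | (dc != 0)
    dr, dc = dr[keep], dc[keep]
    if len(dr) == 0:
        raise ValueError("no off-pattern position found in the field")
    r2 = dr.astype(np.int64) ** 2 + dc.astype(np.int64) ** 2
    if max_radius is not None:
        within = r2 <= max_radius ** 2
        if not within.any():
            raise ValueError("no off-pattern position found within the search radius")
        dr, dc, r2 = dr[within], dc[within], r2[within]
    # CCW angle from east; row indices grow downward, hence the sign flip
    ang = np.arctan2(-dr, dc) % (2 * np.pi)
    best = np.lexsort((ang, r2))[0]
    out = np.zeros_like(pattern_mask)
    out[coords[:, 0] + dr[best], coords[:, 1] + dc[best]] = True
    return out


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def quantify_patterns(image: ImageFrame | np.ndarray,
                      patterns: PatternSet,
                      camera: CameraBackground,
                      channel: str = "",
                      offpattern_rois: dict[int, np.ndarray] | None = None) -> pd.DataFrame:
    """Selectivity, homogeneity and amount for every pattern in one channel.

    Off-pattern ROIs default to auto-placement (the pattern mask translated
    to the nearest clear position). Returns a tidy table with one row per
    pattern; unmeasurable metrics appear as NaN with a reason in ``flags``.
    """
    data = as_array(image)
    exclusion = patterns.union_mask
    records = []
    for pid in sorted(patterns.patterns):
        mask = patterns.patterns[pid]
        if offpattern_rois and pid in offpattern_rois:
            off_mask = np.asarray(offpattern_rois[pid], dtype=bool)
        else:
            off_mask = auto_offpattern_roi(mask, exclusion)
        on = measure_roi(data, mask)
        off = measure_roi(data, off_mask)
        sel = selectivity(on, off, camera)
        hom = homogeneity(on, camera)
        amt = amount_patterned(on, off)
        flags = []
        if on.degenerate:
            flags.append("single-pixel ROI")
        for name, value in (("selectivity", sel), ("homogeneity", hom)):
            if not is_measurable(value):
                flags.append(f"{name}: {value.reason}")
        if amt < 0:
            flags.append("amount negative (pattern dimmer than surround)")
        records.append({
            "pattern_id": pid,
            "channel": channel,
            "selectivity": sel if is_measurable(sel) else np.nan,
            "homogeneity": hom if is_measurable(hom) else np.nan,
            "amount": amt,
            "flags": "; ".join(flags),
        })
    return pd.DataFrame.from_records(records)
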