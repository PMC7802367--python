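"""Receptor-relocalization enrichment indices for dual micropatterns.

A dual micropattern has a small ligand-bearing center (e.g. GFP, EGF or
DLL4 bound to a fibrinogen anchor) surrounded by an adhesive ring
(fibronectin). A cell spreading over it relocalizes its receptor to the
center; the degree of relocalization is quantified as a background- or
bleed-through-corrected ratio of the receptor signal on the inner ROI
versus the surrounding ring:

* :func:`enrichment_simple` — corrects both ROIs by the off-pattern
  background (synthetic receptors such as GBP-TM-mScarlet).
* :func:`enrichment_bleedthrough_corrected` — corrects each ROI by its
  *cell-free* counterpart on a neighboring pattern, removing ligand
  fluorescence bleeding into the receptor channel (EGFR, clathrin).
* :func:`enrichment_temporal` — corrects each ROI by its own pre-landing
  (t = 0) value (GFP-Notch1 fold enrichment at 20 min).
* :func:`signal_increase` — the raw (not fold) increase of the inner ROI
  over the outer one relative to t = 0; less volatile at low signal and
  invariant to any global additive drift.

Cell-free ROI pairing is explicit user input (neighboring patterns are
paired by hand); there is no automatic cell detection here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TimeLapse
from .roi import RoiStats, Unmeasurable, measure_roi


def _ratio(num: float, denom: float, reason: str) -> float | Unmeasurable:
    if denom <= 0:
        return Unmeasurable(reason)
    return num / denom


def enrichment_simple(inner: RoiStats, outer: RoiStats,
                      nonpattern_bg: RoiStats) -> float | Unmeasurable:
    """(inner − background) / (outer − background), background taken from an
    unpatterned region of the coverslip."""
    return _ratio(inner.mean - nonpattern_bg.mean,
                  outer.mean - nonpattern_bg.mean,
                  "outer signal at or below the off-pattern background")


def enrichment_bleedthrough_corrected(inner: RoiStats, inner_cellfree: RoiStats,
                                      outer: RoiStats, outer_cellfree: RoiStats,
                                      ) -> float | Unmeasurable:
    """(inner − cell-free inner) / (outer − cell-free outer); the cell-free
    ROIs sit on neighboring patterns without an adhered cell and capture
    ligand bleed-through into the receptor channel."""
    return _ratio(inner.mean - inner_cellfree.mean,
                  outer.mean - outer_cellfree.mean,
                  "outer signal at or below its cell-free counterpart")


def enrichment_temporal(inner_t: RoiStats, inner_t0: RoiStats,
                        outer_t: RoiStats, outer_t0: RoiStats,
                        ) -> float | Unmeasurable:
    """(inner(t) − inner(t0)) / (outer(t) − outer(t0)), with t0 preceding the
    cell landing; the t0 frame plays the bleed-through-correction role."""
    return _ratio(inner_t.mean - inner_t0.mean,
                  outer_t.mean - outer_t0.mean,
                  "outer signal did not rise above its pre-landing value")


def signal_increase(inner_t: RoiStats, inner_t0: RoiStats,
                    outer_t: RoiStats, outer_t0: RoiStats) -> float:
    """(inner(t) − inner(t0)) − (outer(t) − outer(t0)), in ADU. Any additive
    drift common to all four terms cancels exactly."""
    return (inner_t.mean - inner_t0.mean) - (outer_t.mean - outer_t0.mean)


def enrichment_timecourse(movie: TimeLapse, inner_mask: np.ndarray,
                          outer_mask: np.ndarray, t0: int = 0,
                          window: int = 1) -> pd.DataFrame:
    """Per-frame raw signal increase of the inner over the outer ROI,
    relative to frame ``t0`` (the last frame before the cell lands).

    ``window`` > 1 averages that many frames centered on each time point.
    Returns a tidy table with time in minutes.
    """
    inner_mask = np.asarray(inner_mask, dtype=bool)
    outer_mask = np.asarray(outer_mask, dtype=bool)
    if np.logical_and(inner_mask, outer_mask).any():
        raise ValueError("inner and outer ROIs must be disjoint")
    if not 0 <= t0 < movie.n_frames:
        raise ValueError(f"t0={t0} out of range for a {movie.n_frames}-frame movie")
    if window < 1:
        raise ValueError("window must be >= 1")

    def _stats(t: int, mask: np.ndarray) -> RoiStats:
        lo = max(t - window // 2, 0)
        hi = min(lo + window, movie.n_frames)
        frame = movie.data[lo:hi].mean(axis=0)
        return measure_roi(frame, mask)

    inner0 = _stats(t0, inner_mask)
    outer0 = _stats(t0, outer_mask)
    rows = []
    for t in range(movie.n_frames):
        rows.append({
            "frame": t,
            "time_min": (t - t0) * movie.frame_interval_s / 60.0,
            "signal_increase": signal_increase(_stats(t, inner_mask), inner0,
                                               _stats(t, outer_mask), outer0),
        })
    return pd.DataFrame(rows)
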