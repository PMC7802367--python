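"""Synthetic fluorescence-imaging generator with known ground truth.

Every quantification stage in this package is validated against images
produced here, because the statistics the metrics assume are fully
controlled:

* camera: constant offset plus Gaussian read noise (the dark-frame mean and
  variance the metrics subtract), with Poisson shot noise on the signal;
* micropatterns: regions of specified mean photon rate whose within-pattern
  spatial variation is a low-pass-filtered Gaussian field scaled to a
  requested coefficient of variation, so homogeneity is controllable
  independently of the mean;
* sub-percent off-pattern adsorption, and per-channel cross-adsorption at
  specified fractions for sequential multiplexed patterns;
* gliding filaments rendered as Gaussian-profile line segments advancing
  along scripted paths with run/pause schedules;
* cell-like disks adhering to patterns and passivated surface at specified
  densities.

All expected metric values are computed in closed form from the generating
parameters *before* noise is added and returned in a :class:`GroundTruth`
record, so parameter-recovery tests compare measured against generated.
All randomness flows from one seeded :class:`numpy.random.Generator`;
a fixed seed reproduces every output bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk

from .io import DEFAULT_PIXEL_SIZE_UM, ImageFrame, TimeLapse, write_label_mask


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Minimal sCMOS-like camera: constant offset, Gaussian read noise,
    linear gain. Defaults are conventional for a back-illuminated sCMOS
    (offset 100 ADU, read noise 2 ADU, gain 1 ADU/photon)."""

    offset_mean: float = 100.0
    read_noise_sd: float = 2.0
    gain: float = 1.0

    def __post_init__(self):
        if self.offset_mean < 0:
            raise ValueError("offset_mean must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    def acquire(self, signal_photons: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Expose: Poisson shot noise on signal·gain plus Gaussian read noise
        around the offset. Returns float64 ADU."""
        signal = np.clip(np.asarray(signal_photons, dtype=float), 0.0, None)
        shot = rng.poisson(signal * self.gain).astype(float)
        read = rng.normal(self.offset_mean, self.read_noise_sd, size=signal.shape)
        return shot + read


def simulate_dark_stack(camera: CameraModel, shape: tuple[int, int],
                        n_frames: int, seed=0) -> np.ndarray:
    """Dark frames: read noise around the offset, no signal."""
    rng = as_rng(seed)
    return rng.normal(camera.offset_mean, camera.read_noise_sd,
                      size=(n_frames, *shape))


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSpec:
    """One micropattern: geometry plus the photon statistics of the protein
    deposited on it.

    ``on_mean`` is the mean photon rate per pixel on the pattern; ``on_cv``
    the coefficient of variation of the spatially varying deposition;
    ``off_fraction`` the fraction of ``on_mean`` adsorbed nonspecifically on
    the passivated surface outside any pattern.
    """

    shape: str  # disk | stripe | annulus | rectangle
    center: tuple[float, float]  # (row, col) px
    size_um: float  # diameter (disk/annulus outer), width (stripe), side (rectangle)
    on_mean: float
    on_cv: float = 0.1
    off_fraction: float = 0.005
    inner_size_um: float | None = None  # annulus inner diameter
    height_um: float | None = None  # rectangle height; defaults to size_um

    def __post_init__(self):
        if self.shape not in ("disk", "stripe", "annulus", "rectangle"):
            raise ValueError(f"unknown pattern shape {self.shape!r}")
        if self.size_um <= 0:
            raise ValueError("size_um must be positive")
        if self.on_mean <= 0:
            raise ValueError("on_mean must be positive")
        if self.on_cv < 0:
            raise ValueError("on_cv must be >= 0")
        if not 0.0 <= self.off_fraction <= 1.0:
            raise ValueError("off_fraction must lie in [0, 1]")
        if self.shape == "annulus":
            if self.inner_size_um is None or not 0 < self.inner_size_um < self.size_um:
                raise ValueError("annulus requires 0 < inner_size_um < size_um")

    def render_mask(self, field_size: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        h, w = field_size
        rr, cc = np.mgrid[0:h, 0:w]
        r0, c0 = self.center
        if self.shape == "disk":
            rad = self.size_um / 2.0 / pixel_size_um
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
        if self.shape == "annulus":
            rad = self.size_um / 2.0 / pixel_size_um
            rin = self.inner_size_um / 2.0 / pixel_size_um
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            return (d2 <= rad ** 2) & (d2 > rin ** 2)
        if self.shape == "stripe":
            half = self.size_um / 2.0 / pixel_size_um
            return np.abs(rr - r0) <= half
        # rectangle
        half_w = self.size_um / 2.0 / pixel_size_um
        half_h = (self.height_um or self.size_um) / 2.0 / pixel_size_um
        return (np.abs(rr - r0) <= half_h) & (np.abs(cc - c0) <= half_w)


@dataclass
class GroundTruth:
    """Everything the generator knows that a blinded analyst would not.

    ``per_pattern`` maps pattern_id to the closed-form expected selectivity
    (unitless), homogeneity (ADU⁻¹) and amount (ADU) implied by the
    generating parameters before noise. ``crosstalk`` echoes the generating
    matrix; ``filaments`` and ``cells`` carry per-object motility/adhesion
    records.
    """

    pattern_labels: np.ndarray | None = None
    per_pattern: dict = dc_field(default_factory=dict)
    crosstalk: pd.DataFrame | None = None
    filaments: list = dc_field(default_factory=list)
    cells: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {"per_pattern": self.per_pattern, "meta": self.meta,
               "filaments": self.filaments, "cells": self.cells}
        if self.crosstalk is not None:
            out["crosstalk"] = {str(ch): {str(p): float(v) for p, v in row.items()}
                                for ch, row in self.crosstalk.iterrows()}
        return out

    def save(self, prefix: str | Path) -> None:
        """Write a JSON sidecar (and the label mask as 16-bit TIFF if present)."""
        prefix = Path(prefix)

        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, (np.bool_,)):
                return bool(obj)
            return obj

        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(_clean(self.to_json_dict()), fh, indent=2)
        if self.pattern_labels is not None:
            write_label_mask(prefix.parent / (prefix.name + "_labels.tif"),
                             self.pattern_labels)


def _spatial_variation(mask: np.ndarray, cv: float, rng: np.random.Generator,
                       sigma_px: float = 3.0) -> np.ndarray:
    """Multiplicative within-pattern variation field: 1 + cv·z with z a
    low-pass-filtered Gaussian field normalized to zero mean and unit SD over
    the pattern pixels, so the realized spatial CV matches the request."""
    factor = np.ones(mask.shape)
    n = int(mask.sum())
    if cv <= 0 or n < 2:
        return factor
    raw = ndi.gaussian_filter(rng.standard_normal(mask.shape), sigma_px)
    vals = raw[mask]
    z = (vals - vals.mean()) / vals.std()
    factor[mask] = np.clip(1.0 + cv * z, 0.0, None)
    return factor


def _expected_pattern_metrics(spec: PatternSpec, off_signal: float,
                              camera: CameraModel) -> dict:
    g = camera.gain
    sel = spec.on_mean / off_signal if off_signal > 0 else None
    mean_adu = g * spec.on_mean
    # on-pattern variance beyond the camera: shot term + spatial term
    var_adu = g * spec.on_mean + (g * spec.on_cv * spec.on_mean) ** 2
    return {
        "selectivity": sel,
        "homogeneity": mean_adu / var_adu,
        "amount": g * (spec.on_mean - off_signal),
        "on_mean_photons": spec.on_mean,
        "on_cv": spec.on_cv,
        "off_signal_photons": off_signal,
    }


def _pattern_labels(specs: list[PatternSpec], field_size: tuple[int, int],
                    pixel_size_um: float) -> np.ndarray:
    """Rasterize all specs into a label image; reject overlaps and patterns
    touching the field border (an off-pattern margin is required)."""
    labels = np.zeros(field_size, dtype=np.int32)
    for i, spec in enumerate(specs, start=1):
        mask = spec.render_mask(field_size, pixel_size_um)
        if not mask.any():
            raise ValueError(f"pattern {i} falls outside the field")
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError(f"pattern {i} touches the field border; "
                             "enlarge the field to keep an off-pattern margin")
        if (labels[mask] != 0).any():
            raise ValueError(f"pattern {i} overlaps another pattern")
        labels[mask] = i
    return labels


def simulate_pattern_image(specs: list[PatternSpec], camera: CameraModel,
                           field_size: tuple[int, int] = (128, 128),
                           seed=0,
                           pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                           channel: str = "sim") -> tuple[ImageFrame, GroundTruth]:
    """Single-channel micropattern image.

    Signal (photons/px) is ``on_mean·(1 + variation)`` inside each pattern
    and the summed nonspecific adsorption ``Σ on_mean·off_fraction`` outside
    all patterns; pixel values are ``Poisson(signal·gain) +
    Normal(offset, read_noise)``.
    """
    rng = as_rng(seed)
    labels = _pattern_labels(specs, field_size, pixel_size_um)
    off_signal = float(sum(s.on_mean * s.off_fraction for s in specs))
    signal = np.full(field_size, off_signal)
    truth = GroundTruth(pattern_labels=labels,
                        meta={"pixel_size_um": pixel_size_um,
                              "field_size": list(field_size),
                              "off_signal_photons": off_signal,
                              "camera": {"offset_mean": camera.offset_mean,
                                         "read_noise_sd": camera.read_noise_sd,
                                         "gain": camera.gain}})
    for i, spec in enumerate(specs, start=1):
        mask = labels == i
        factor = _spatial_variation(mask, spec.on_cv, rng)
        signal[mask] = spec.on_mean * factor[mask]
        truth.per_pattern[i] = _expected_pattern_metrics(spec, off_signal, camera)
    image = ImageFrame(camera.acquire(signal, rng), pixel_size_um, channel)
    return image, truth


def simulate_offfield_image(off_signal_photons: float, camera: CameraModel,
                            field_size: tuple[int, int] = (128, 128),
                            seed=0,
                            pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                            channel: str = "sim") -> ImageFrame:
    """An unpatterned sample region carrying only nonspecific adsorption —
    the second acquisition used by the nonspecific-binding measurement."""
    rng = as_rng(seed)
    signal = np.full(field_size, float(off_signal_photons))
    return ImageFrame(camera.acquire(signal, rng), pixel_size_um, channel)


def simulate_multiplex_series(pattern_specs: list[PatternSpec],
                              assignment: dict[str, int],
                              crosstalk: pd.DataFrame | np.ndarray,
                              camera: CameraModel,
                              field_size: tuple[int, int] = (128, 192),
                              seed=0,
                              pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                              ) -> tuple[dict[str, ImageFrame], GroundTruth]:
    """Sequential multiplexed patterns imaged in one channel per protein.

    ``crosstalk[c, i]`` is the fraction of channel ``c``'s intended
    on-pattern photon rate deposited on pattern ``i``; intended entries must
    be exactly 1. Off-pattern signal in channel ``c`` is the intended
    spec's ``off_fraction`` of its ``on_mean``.
    """
    rng = as_rng(seed)
    channels = list(assignment)
    pattern_ids = list(range(1, len(pattern_specs) + 1))
    for ch, pid in assignment.items():
        if pid not in pattern_ids:
            raise ValueError(f"channel {ch!r} assigned to missing pattern {pid}")
    if not isinstance(crosstalk, pd.DataFrame):
        crosstalk = pd.DataFrame(np.asarray(crosstalk, dtype=float),
                                 index=channels, columns=pattern_ids)
    ct = crosstalk.astype(float)
    if ((ct.values < 0) | (ct.values > 1)).any():
        raise ValueError("crosstalk entries must lie in [0, 1]")
    for ch in channels:
        if not np.isclose(ct.loc[ch, assignment[ch]], 1.0):
            raise ValueError(f"crosstalk[{ch!r}, intended] must equal 1")

    labels = _pattern_labels(pattern_specs, field_size, pixel_size_um)
    truth = GroundTruth(pattern_labels=labels, crosstalk=ct.copy(),
                        meta={"pixel_size_um": pixel_size_um,
                              "assignment": dict(assignment)})
    images: dict[str, ImageFrame] = {}
    for ch in channels:
        spec = pattern_specs[assignment[ch] - 1]
        signal = np.full(field_size, spec.on_mean * spec.off_fraction)
        for pid in pattern_ids:
            mask = labels == pid
            frac = float(ct.loc[ch, pid])
            if frac == 0.0:
                signal[mask] = 0.0
                continue
            factor = _spatial_variation(mask, spec.on_cv, rng)
            signal[mask] = spec.on_mean * frac * factor[mask]
        images[ch] = ImageFrame(camera.acquire(signal, rng), pixel_size_um, ch)
        truth.per_pattern[assignment[ch]] = _expected_pattern_metrics(
            spec, spec.on_mean * spec.off_fraction, camera)
    return images, truth


# ---------------------------------------------------------------------------
# gliding filaments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentScript:
    """Scripted motion of one microtubule-like filament.

    ``path`` is a polyline in pixel coordinates along which the filament
    glides; ``duty_ratio`` the fraction of frame intervals spent moving
    (pauses are emitted as blocks of at least ``min_pause_block`` frames so
    that a run-length pause detector can see them); ``on_pattern`` False
    scripts a filament stuck outside the motor pattern that never moves.
    """

    path: tuple  # polyline ((r, c), ...) px
    speed_um_s: float
    duty_ratio: float
    frame_interval_s: float
    on_pattern: bool = True
    length_um: float = 3.0
    peak_photons: float = 300.0
    min_pause_block: int = 3

    def __post_init__(self):
        if not 0.0 <= self.duty_ratio <= 1.0:
            raise ValueError("duty_ratio must lie in [0, 1]")
        if self.speed_um_s < 0:
            raise ValueError("speed must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if len(self.path) < 2:
            raise ValueError("path needs at least two vertices")


def _path_interp(path: np.ndarray):
    """Arc-length parametrization of a polyline (px). Returns (total_len,
    fn) where fn(s) maps arc length (px, scalar or array) to (r, c)."""
    path = np.asarray(path, dtype=float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    if total <= 0:
        raise ValueError("degenerate (zero-length) path")

    def fn(s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, total)
        return np.stack([np.interp(s, cum, path[:, 0]),
                         np.interp(s, cum, path[:, 1])], axis=-1)

    return total, fn


def _pause_schedule(n_steps: int, duty: float, rng: np.random.Generator,
                    min_block: int = 3) -> np.ndarray:
    """Boolean moving/paused schedule over ``n_steps`` frame intervals whose
    paused count is round((1−duty)·n_steps), arranged in blocks of at least
    ``min_block`` frames at random, non-adjacent positions."""
    if duty >= 1.0:
        return np.ones(n_steps, dtype=bool)
    if duty <= 0.0:
        return np.zeros(n_steps, dtype=bool)
    n_paused = int(round((1.0 - duty) * n_steps))
    if n_paused == 0:
        return np.ones(n_steps, dtype=bool)
    n_paused = max(n_paused, min_block)
    n_paused = min(n_paused, n_steps)
    # split the paused budget into blocks of size >= min_block
    blocks = []
    remaining = n_paused
    while remaining > 0:
        if remaining < 2 * min_block:
            blocks.append(remaining)
            break
        size = min_block + int(rng.integers(0, min_block + 1))
        size = min(size, remaining - min_block)
        blocks.append(size)
        remaining -= size
    n_moving = n_steps - n_paused
    k = len(blocks)
    if n_moving + 1 < k:  # cannot separate that many blocks; merge
        blocks = [n_paused]
        k = 1
    gaps = rng.choice(n_moving + 1, size=k, replace=False)
    rng.shuffle(blocks)
    schedule = []
    order = np.argsort(gaps)
    gaps_sorted = np.sort(gaps)
    prev = 0
    for gi, g in enumerate(gaps_sorted):
        schedule.extend([True] * (g - prev))
        schedule.extend([False] * blocks[order[gi]])
        prev = g
    schedule.extend([True] * (n_moving - prev))
    return np.asarray(schedule, dtype=bool)


def _render_filament(signal: np.ndarray, pts_px: np.ndarray, ds_px: float,
                     peak: float, sigma_px: float) -> None:
    """Add a Gaussian-profile line (sampled at ``pts_px``) to ``signal``.
    Sub-pixel positions are handled by analytic profile evaluation; the
    centerline of a long filament reaches ``peak`` photons."""
    h, w = signal.shape
    pad = int(np.ceil(4 * sigma_px)) + 1
    rmin = max(int(np.floor(pts_px[:, 0].min())) - pad, 0)
    rmax = min(int(np.ceil(pts_px[:, 0].max())) + pad, h - 1)
    cmin = max(int(np.floor(pts_px[:, 1].min())) - pad, 0)
    cmax = min(int(np.ceil(pts_px[:, 1].max())) + pad, w - 1)
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    acc = np.zeros(rr.shape)
    inv2s2 = 1.0 / (2.0 * sigma_px ** 2)
    for r0, c0 in pts_px:
        acc += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) * inv2s2)
    # ds/(sqrt(2π)σ) normalizes the sampled line integral of the 2D kernel
    acc *= peak * ds_px / (np.sqrt(2.0 * np.pi) * sigma_px)
    signal[rmin:rmax + 1, cmin:cmax + 1] += acc


def simulate_gliding_movie(scripts: list[FilamentScript],
                           pattern_mask: np.ndarray,
                           camera: CameraModel,
                           n_frames: int = 200,
                           seed=0,
                           pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                           sigma_px: float = 1.0,
                           field_size: tuple[int, int] | None = None,
                           ) -> tuple[TimeLapse, GroundTruth]:
    """Gliding-assay movie: each filament advances along its path at its
    scripted speed during moving intervals and holds position during pauses;
    off-pattern filaments never move. The realized per-frame schedule and
    head positions are recorded in the ground truth."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    pattern_mask = np.asarray(pattern_mask, dtype=bool)
    if field_size is None:
        field_size = pattern_mask.shape
    rng = as_rng(seed)
    intervals = {s.frame_interval_s for s in scripts}
    if len(intervals) > 1:
        raise ValueError("all scripts in one movie must share frame_interval_s")
    frame_interval = intervals.pop() if intervals else 1.0

    ds_px = 0.3
    records = []
    per_filament_pos = []
    for script in scripts:
        total_px, interp = _path_interp(np.asarray(script.path, dtype=float))
        total_um = total_px * pixel_size_um
        length_um = min(script.length_um, total_um)
        if length_um / pixel_size_um >= max(field_size):
            raise ValueError("filament length must be smaller than the field")
        moving = (_pause_schedule(n_frames - 1, script.duty_ratio, rng,
                                  script.min_pause_block)
                  if script.on_pattern and script.speed_um_s > 0
                  else np.zeros(n_frames - 1, dtype=bool))
        step = script.speed_um_s * frame_interval
        head = np.empty(n_frames)
        head[0] = length_um
        for t in range(1, n_frames):
            head[t] = head[t - 1] + (step if moving[t - 1] else 0.0)
        truncated = bool(head[-1] > total_um)
        head = np.clip(head, length_um, total_um)
        per_filament_pos.append((script, interp, head, length_um))
        records.append({
            "speed_um_s": script.speed_um_s,
            "duty_requested": script.duty_ratio,
            "duty_realized": float(moving.mean()) if len(moving) else 0.0,
            "moving": moving.astype(int).tolist(),
            "head_um": head.tolist(),
            "on_pattern": script.on_pattern,
            "net_displacement_um": float(head[-1] - head[0]),
            "truncated": truncated,
        })
        if truncated:
            warnings.warn("filament reached the end of its path; motion truncated")

    frames = np.empty((n_frames, *field_size))
    for t in range(n_frames):
        signal = np.zeros(field_size)
        for script, interp, head, length_um in per_filament_pos:
            s_head = head[t] / pixel_size_um
            s_tail = max(s_head - length_um / pixel_size_um, 0.0)
            n_pts = max(int(np.ceil((s_head - s_tail) / ds_px)), 2)
            pts = interp(np.linspace(s_tail, s_head, n_pts))
            eff_ds = (s_head - s_tail) / (n_pts - 1)
            _render_filament(signal, pts, eff_ds, script.peak_photons, sigma_px)
        frames[t] = camera.acquire(signal, rng)

    movie = TimeLapse(frames, frame_interval, pixel_size_um, "gliding")
    truth = GroundTruth(pattern_labels=pattern_mask.astype(np.int32),
                        filaments=records,
                        meta={"pixel_size_um": pixel_size_um,
                              "frame_interval_s": frame_interval,
                              "sigma_px": sigma_px, "n_frames": n_frames})
    return movie, truth


# ---------------------------------------------------------------------------
# cell adhesion
# ---------------------------------------------------------------------------

def simulate_adhesion_field(pattern_labels: np.ndarray,
                            density_on: float, density_off: float,
                            seed=0,
                            pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                            cell_radius_um: float = 5.0,
                            peak_photons: float = 200.0,
                            camera: CameraModel | None = None,
                            ) -> tuple[ImageFrame, pd.DataFrame, GroundTruth]:
    """Cell-like disks placed on patterns and passivated surface at the
    requested densities (cells/µm²); counts are Poisson(density × area) and
    centroids are uniform within each region, rejected to non-overlap.

    Returns the rendered image, a centroid table (row, col, on_pattern) and
    a ground truth carrying counts, areas and the expected adhesion metrics.
    """
    if density_on < 0 or density_off < 0:
        raise ValueError("densities must be >= 0")
    labels = np.asarray(pattern_labels)
    rng = as_rng(seed)
    camera = camera or CameraModel()
    on_mask = labels > 0
    px_area = pixel_size_um ** 2
    area_on = float(on_mask.sum()) * px_area
    area_off = float((~on_mask).sum()) * px_area
    packing = max(density_on, density_off) * np.pi * cell_radius_um ** 2
    if packing > 0.6:
        raise ValueError("requested density exceeds the non-overlap packing limit")

    r_px = cell_radius_um / pixel_size_um
    placed: list[tuple[float, float, bool]] = []

    def _place(region_mask: np.ndarray, n: int, on: bool) -> int:
        coords = np.argwhere(region_mask)
        done = 0
        for _ in range(n):
            ok = False
            for _attempt in range(500):
                r, c = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, 2)
                r = float(np.clip(r, 0, labels.shape[0] - 1))
                c = float(np.clip(c, 0, labels.shape[1] - 1))
                if all((r - pr) ** 2 + (c - pc) ** 2 >= (2 * r_px) ** 2
                       for pr, pc, _ in placed):
                    placed.append((float(r), float(c), on))
                    ok = True
                    break
            if ok:
                done += 1
            else:
                warnings.warn("could not place all cells without overlap")
        return done

    n_on = _place(on_mask, int(rng.poisson(density_on * area_on)), True) \
        if area_on > 0 else 0
    n_off = _place(~on_mask, int(rng.poisson(density_off * area_off)), False) \
        if area_off > 0 else 0

    signal = np.zeros(labels.shape)
    for r, c, _ in placed:
        rr, cc = _draw_disk((r, c), r_px, shape=labels.shape)
        signal[rr, cc] += peak_photons
    image = ImageFrame(camera.acquire(signal, rng), pixel_size_um, "cells")

    centroids = pd.DataFrame(placed, columns=["row", "col", "on_pattern"])
    d_on = n_on / area_on if area_on > 0 else 0.0
    d_off = n_off / area_off if area_off > 0 else 0.0
    expected_nonspecific = (100.0 * density_off / (density_on + density_off)
                            if density_on + density_off > 0 else None)
    truth = GroundTruth(
        pattern_labels=labels.astype(np.int32),
        cells={"n_on": n_on, "n_off": n_off,
               "area_on_um2": area_on, "area_off_um2": area_off,
               "density_on_requested": density_on,
               "density_off_requested": density_off,
               "density_on_realized": d_on, "density_off_realized": d_off,
               "expected_nonspecific_adhesion_pct": expected_nonspecific,
               "expected_n_on": density_on * area_on,
               "expected_n_off": density_off * area_off},
        meta={"pixel_size_um": pixel_size_um, "cell_radius_um": cell_radius_um})
    return image, centroids, truth
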