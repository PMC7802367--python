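"""Gliding-assay motility analysis.

Surface-bound kinesin motors propel fluorescent microtubules; activity of
the micropatterned motor is read out from time-lapse movies in four steps:

1. project the movie in time (max by default) to reveal each filament's
   swept path;
2. build a kymograph — a distance-along-path × time intensity image — by
   sampling the movie along a user-drawn (or scripted) polyline;
3. trace the filament through the kymograph (per-frame intensity-weighted
   centroid), segment the trace into runs and pauses, and report the mean
   speed while moving plus the fraction of time spent moving processively
   (the duty fraction);
4. classify traces as motile/immobile by net displacement and aggregate
   motile fractions for on-pattern versus off-pattern filaments.

The pause criterion (threshold at 20% of the trace's median moving speed,
minimum pause length 2 frames) and the motility criterion (net displacement
≥ 1 µm) are explicit, configurable parameters recorded in the outputs.
Group statistics are reported as mean ± SEM with n.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io import ImageFrame, TimeLapse

#: default pause threshold as a fraction of the median moving speed
PAUSE_THRESHOLD_FRAC = 0.2
#: minimum consecutive sub-threshold frames to call a pause
MIN_PAUSE_FRAMES = 2
#: minimum net displacement (µm) for a trace to count as motile
MIN_NET_DISPLACEMENT_UM = 1.0
#: absolute speed floor, px/frame — below this nothing is "moving"
ABS_SPEED_FLOOR_PX_PER_FRAME = 0.5


class TraceRejected(ValueError):
    """Raised when a kymograph is too dim/noisy to localize the filament."""


def time_project(movie: TimeLapse, method: str = "max") -> ImageFrame:
    """Per-pixel max (default) or mean over time."""
    if movie.n_frames < 1:
        raise ValueError("empty movie")
    if method == "max":
        data = movie.data.max(axis=0)
    elif method == "mean":
        data = movie.data.mean(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return ImageFrame(data, movie.pixel_size_um, movie.channel)


@dataclass
class Kymograph:
    """distance-along-path × time intensity array with its calibration."""

    data: np.ndarray  # (n_positions, n_frames)
    path: np.ndarray  # polyline, px
    pixel_size_um: float
    frame_interval_s: float

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def _sample_positions(path: np.ndarray, spacing_px: float = 1.0):
    """Resample a polyline at uniform arc-length spacing; returns the sample
    points and unit normals."""
    path = np.asarray(path, dtype=float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    if total <= 0:
        raise ValueError("degenerate (zero-length) path")
    n = int(np.floor(total / spacing_px)) + 1
    s = np.arange(n) * spacing_px
    pts = np.stack([np.interp(s, cum, path[:, 0]),
                    np.interp(s, cum, path[:, 1])], axis=1)
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    return pts, normals


def build_kymograph(movie: TimeLapse, path, width: int = 1) -> Kymograph:
    """Sample the movie along ``path`` (1 px arc-length steps, bilinear
    interpolation), averaging over ``width`` perpendicular pixels, and stack
    per-frame profiles into a distance × time image. ``width`` must be odd."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    pts, normals = _sample_positions(np.asarray(path, dtype=float))
    half = width // 2
    offsets = np.arange(-half, half + 1)
    # (n_offsets, n_positions, 2)
    coords = pts[None, :, :] + offsets[None, :, None].reshape(-1, 1, 1) * normals[None, :, :]
    profiles = np.empty((movie.n_frames, len(pts)))
    for t in range(movie.n_frames):
        sampled = map_coordinates(movie.data[t].astype(float),
                                  [coords[..., 0].ravel(), coords[..., 1].ravel()],
                                  order=1, mode="nearest").reshape(len(offsets), len(pts))
        profiles[t] = sampled.mean(axis=0)
    return Kymograph(profiles.T, np.asarray(path, dtype=float),
                     movie.pixel_size_um, movie.frame_interval_s)


@dataclass
class MotilityTrace:
    """One filament's position-vs-time along its path, segmented into runs
    and pauses. ``speeds_um_s`` has one entry per frame interval; ``moving``
    marks intervals above the pause threshold; mean speed is computed over
    moving intervals only and is None for a fully paused trace."""

    positions_um: np.ndarray
    speeds_um_s: np.ndarray
    moving: np.ndarray
    mean_speed_um_s: float | None
    duty: float
    net_displacement_um: float
    frame_interval_s: float
    on_pattern: bool | None = None
    flags: tuple[str, ...] = ()
    params: dict = dc_field(default_factory=dict)

    @property
    def paused_fraction(self) -> float:
        return 1.0 - self.duty

    def segments(self) -> list[tuple[int, int, str]]:
        """Maximal (start, stop, state) intervals tiling the trace; ``stop``
        is exclusive, indices refer to frame intervals."""
        out = []
        if len(self.moving) == 0:
            return out
        start = 0
        for i in range(1, len(self.moving) + 1):
            if i == len(self.moving) or self.moving[i] != self.moving[start]:
                out.append((start, i, "run" if self.moving[start] else "pause"))
                start = i
        return out


def _suppress_short_pauses(moving: np.ndarray, min_pause_frames: int) -> np.ndarray:
    """Pauses shorter than ``min_pause_frames`` are relabeled as moving."""
    moving = moving.copy()
    i = 0
    n = len(moving)
    while i < n:
        if not moving[i]:
            j = i
            while j < n and not moving[j]:
                j += 1
            if j - i < min_pause_frames:
                moving[i:j] = True
            i = j
        else:
            i += 1
    return moving


def trace_filament(kymo: Kymograph,
                   pause_threshold_frac: float = PAUSE_THRESHOLD_FRAC,
                   min_pause_frames: int = MIN_PAUSE_FRAMES,
                   abs_speed_floor_px_per_frame: float = ABS_SPEED_FLOOR_PX_PER_FRAME,
                   snr_floor: float = 5.0,
                   window_px: int = 25,
                   on_pattern: bool | None = None) -> MotilityTrace:
    """Localize the filament per frame and segment its motion.

    Per frame, the background (column median) is subtracted and the position
    is the intensity-weighted centroid within a tracking window of
    ``window_px`` pixels around the previous position (the global maximum at
    the first frame); the window keeps far-away noise bins from leveraging
    the centroid and must exceed the filament half-length. A frame whose
    windowed peak falls below ``snr_floor``× the column's robust noise
    rejects the whole trace (low SNR). Speeds are per-interval displacements;
    an interval is paused when its |speed| falls below
    max(``pause_threshold_frac``·median moving speed, the absolute floor)
    within a run of at least ``min_pause_frames``.
    """
    data = np.asarray(kymo.data, dtype=float)
    n_pos, n_frames = data.shape
    if n_frames < 2:
        raise ValueError("kymograph needs at least two frames")
    positions_px = np.empty(n_frames)
    center = None
    for t in range(n_frames):
        col = data[:, t]
        resid = col - np.median(col)
        noise = 1.4826 * np.median(np.abs(resid)) + 1e-12
        if center is None:
            center = int(np.argmax(resid))
        lo = max(center - window_px, 0)
        hi = min(center + window_px + 1, n_pos)
        sig = np.clip(resid[lo:hi], 0.0, None)
        peak = sig.max(initial=0.0)
        if peak < snr_floor * noise:
            raise TraceRejected(
                f"frame {t}: filament peak below the localization floor "
                f"(peak {peak:.1f} < {snr_floor}x noise {noise:.1f})")
        total = sig.sum()
        positions_px[t] = float((sig * np.arange(lo, hi)).sum() / total)
        center = int(round(positions_px[t]))

    positions_um = positions_px * kymo.pixel_size_um
    dt = kymo.frame_interval_s
    speeds = np.diff(positions_um) / dt
    abs_speed = np.abs(speeds)
    floor = abs_speed_floor_px_per_frame * kymo.pixel_size_um / dt

    thr = max(pause_threshold_frac * float(np.median(abs_speed)), floor)
    moving = abs_speed >= thr
    if moving.any():  # second pass: threshold from the median *moving* speed
        thr = max(pause_threshold_frac * float(np.median(abs_speed[moving])), floor)
        moving = abs_speed >= thr
    moving = _suppress_short_pauses(moving, min_pause_frames)

    flags = []
    if moving.any():
        mean_speed = float(abs_speed[moving].mean())
    else:
        mean_speed = None
        flags.append("no moving frames; speed undefined")
    return MotilityTrace(
        positions_um=positions_um,
        speeds_um_s=speeds,
        moving=moving,
        mean_speed_um_s=mean_speed,
        duty=float(moving.mean()),
        net_displacement_um=float(abs(positions_um[-1] - positions_um[0])),
        frame_interval_s=dt,
        on_pattern=on_pattern,
        flags=tuple(flags),
        params={"pause_threshold_um_s": thr,
                "pause_threshold_frac": pause_threshold_frac,
                "min_pause_frames": min_pause_frames})


def path_on_pattern(path, pattern_mask: np.ndarray) -> bool:
    """Tag a path on/off pattern by the majority of its rasterized pixels."""
    pts, _ = _sample_positions(np.asarray(path, dtype=float))
    mask = np.asarray(pattern_mask) > 0
    h, w = mask.shape
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    return bool(mask[rr, cc].mean() > 0.5)


def classify_motile(traces: list[MotilityTrace],
                    min_net_displacement_um: float = MIN_NET_DISPLACEMENT_UM,
                    manual_overrides: dict[int, bool] | None = None) -> pd.DataFrame:
    """Motile fraction for on-pattern and off-pattern trace groups.

    A trace is motile iff its net displacement is at least
    ``min_net_displacement_um``; ``manual_overrides`` (trace index → bool)
    takes precedence, standing in for by-eye segmentation. Empty groups
    report a NaN fraction (undefined), never 0.
    """
    manual_overrides = manual_overrides or {}
    rows = {"on_pattern": {"n": 0, "n_motile": 0},
            "off_pattern": {"n": 0, "n_motile": 0}}
    for i, trace in enumerate(traces):
        if trace.on_pattern is None:
            raise ValueError(f"trace {i} has no on/off-pattern tag")
        motile = manual_overrides.get(
            i, trace.net_displacement_um >= min_net_displacement_um)
        group = "on_pattern" if trace.on_pattern else "off_pattern"
        rows[group]["n"] += 1
        rows[group]["n_motile"] += int(motile)
    records = []
    for group, r in rows.items():
        frac = r["n_motile"] / r["n"] if r["n"] else np.nan
        records.append({"group": group, "n": r["n"], "n_motile": r["n_motile"],
                        "motile_fraction": frac})
    return pd.DataFrame.from_records(records)


def summarize_traces(traces: list[MotilityTrace]) -> pd.DataFrame:
    """Mean ± SEM (with n) of speed-while-moving and duty fraction."""
    speeds = [t.mean_speed_um_s for t in traces if t.mean_speed_um_s is not None]
    duties = [t.duty for t in traces]

    def _row(name, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return {"metric": name, "n": n,
                "mean": float(values.mean()) if n else np.nan,
                "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan}

    return pd.DataFrame([_row("speed_um_s", speeds), _row("duty_fraction", duties)])
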