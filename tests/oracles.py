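"""Naive reference implementations used as independent oracles.

Everything here is written as explicit Python loops over pixels or plain
arithmetic on scalars, deliberately sharing no code with the package, so
that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def roi_stats_loop(image, mask):
    """Pixel-loop mean / unbiased variance / count over a boolean mask."""
    values = []
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                values.append(float(image[r, c]))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1) if n > 1 else 0.0
    return mean, var, n


def selectivity_formula(p_mean, np_mean, cam_mean):
    return (p_mean - cam_mean) / (np_mean - cam_mean)


def homogeneity_formula(p_mean, p_var, cam_mean, cam_var):
    return (p_mean - cam_mean) / (p_var - cam_var)


def amount_formula(p_mean, np_mean):
    return p_mean - np_mean


def crosstalk_entry_formula(wrong_mean, intended_mean, bg_mean):
    return (wrong_mean - bg_mean) / (intended_mean - bg_mean)


def nonspecific_formula(off_mean, intended_mean, bg_mean):
    return (off_mean - bg_mean) / (intended_mean - bg_mean)


def enrichment_simple_formula(inner, outer, bg):
    return (inner - bg) / (outer - bg)


def enrichment_corrected_formula(inner, inner_cf, outer, outer_cf):
    return (inner - inner_cf) / (outer - outer_cf)


def enrichment_temporal_formula(inner_t, inner_t0, outer_t, outer_t0):
    return (inner_t - inner_t0) / (outer_t - outer_t0)


def signal_increase_formula(inner_t, inner_t0, outer_t, outer_t0):
    return (inner_t - inner_t0) - (outer_t - outer_t0)


def density_formula(n_on, area_on, reference_mean):
    return (n_on / area_on) / reference_mean


def nonspecific_adhesion_formula(n_on, area_on, n_off, area_off):
    d_on = n_on / area_on
    d_off = n_off / area_off
    return 100.0 * d_off / (d_on + d_off)


def time_project_loop(movie, method):
    """Per-pixel loop over a (t, y, x) stack."""
    t, h, w = movie.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            pix = [movie[i, r, c] for i in range(t)]
            out[r, c] = max(pix) if method == "max" else sum(pix) / t
    return out


def bilinear(image, r, c):
    """Bilinear interpolation with edge clamping (matches map_coordinates
    order=1, mode='nearest')."""
    h, w = image.shape
    r = min(max(r, 0.0), h - 1)
    c = min(max(c, 0.0), w - 1)
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * image[r0, c0] + (1 - fr) * fc * image[r0, c1]
            + fr * (1 - fc) * image[r1, c0] + fr * fc * image[r1, c1])


def kymograph_loop(movie, pts, normals, width):
    """Naive per-frame sampling along precomputed path points/normals."""
    half = width // 2
    t = movie.shape[0]
    out = np.empty((len(pts), t))
    for i, ((pr, pc), (nr, nc)) in enumerate(zip(pts, normals)):
        for f in range(t):
            vals = []
            for k in range(-half, half + 1):
                vals.append(bilinear(movie[f], pr + k * nr, pc + k * nc))
            out[i, f] = sum(vals) / len(vals)
    return out
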