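"""Rasterization and noise-free image formation.

The skeleton of each filament is rasterized with a supercover rule: a pixel
is set iff the continuous polyline intersects that pixel's closed unit
square (boundary and corner touches count).  The union skeleton is convolved
with an isotropic Gaussian PSF and mapped to intensities

    I_ideal = A · (M * psf) + B

with signed contrast A and background B.  Convolution is zero-padded at the
borders; the background is added afterwards, so image borders darken
slightly unless vignetting in the degradation stage compensates — a
documented contract, absorbed by the domain tuner in practice.

Ground-truth instance masks are the rasterized skeletons dilated by a disk
of radius 1 so that they carry physical width, keeping the skeleton-IoU
numerator non-degenerate under one-pixel lateral shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk

from .geometry import Polyline, Scene, filament_to_polyline
from .parameters import ThetaParams

__all__ = [
    "Psf",
    "IdealImage",
    "rasterize_polyline",
    "make_gaussian_psf",
    "render_ideal",
    "render_seeds",
    "compose_rgb",
    "dilate_mask",
    "truncate_polyline",
]

GT_DILATION_RADIUS = 1  # disk radius for ground-truth instance masks


@dataclass
class Psf:
    """Odd-sized square non-negative kernel, entries summing to 1."""

    kernel: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] % 2 == 0:
            raise ValueError("PSF kernel must be square with odd side")
        if np.any(k < 0):
            raise ValueError("PSF kernel must be non-negative")
        if abs(k.sum() - 1.0) > 1e-9:
            raise ValueError("PSF kernel must sum to 1")
        self.kernel = k


@dataclass
class IdealImage:
    """Noise-free rendered frame plus optional separate seed support."""

    base: np.ndarray                    # (h, w) float
    seed_support: np.ndarray | None = None  # (h, w) bool


def _segment_cells(p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (row, col) cells whose closed unit square a segment intersects.

    Pixel (r, c) covers [c−0.5, c+0.5] × [r−0.5, r+0.5].  Inclusive slab
    test, so boundary and corner touches are counted (supercover).
    """
    x0, y0 = p0
    x1, y1 = p1
    eps = 1e-12
    cmin = int(np.ceil(min(x0, x1) - 0.5 - eps))
    cmax = int(np.floor(max(x0, x1) + 0.5 + eps))
    rmin = int(np.ceil(min(y0, y1) - 0.5 - eps))
    rmax = int(np.floor(max(y0, y1) + 0.5 + eps))
    cols = np.arange(cmin, cmax + 1)
    rows = np.arange(rmin, rmax + 1)
    if len(cols) == 0 or len(rows) == 0:
        return np.empty(0, int), np.empty(0, int)
    cc, rr = np.meshgrid(cols, rows)
    cc = cc.ravel().astype(float)
    rr = rr.ravel().astype(float)

    dx = x1 - x0
    dy = y1 - y0
    tlo = np.zeros_like(cc)
    thi = np.ones_like(cc)
    ok = np.ones(cc.shape, dtype=bool)

    for d, o, lo_edge, hi_edge in ((dx, x0, cc - 0.5, cc + 0.5),
                                   (dy, y0, rr - 0.5, rr + 0.5)):
        if abs(d) < eps:
            ok &= (o >= lo_edge - eps) & (o <= hi_edge + eps)
        else:
            t1 = (lo_edge - o) / d
            t2 = (hi_edge - o) / d
            tlo = np.maximum(tlo, np.minimum(t1, t2))
            thi = np.minimum(thi, np.maximum(t1, t2))
    ok &= tlo <= thi + eps
    return rr[ok].astype(int), cc[ok].astype(int)


def rasterize_polyline(polyline: Polyline, h: int, w: int) -> np.ndarray:
    """Supercover-rasterize a polyline into an (h, w) boolean mask.

    Segments outside the canvas are clipped; a polyline entirely outside
    yields an empty mask.  A single-vertex polyline sets the one pixel
    containing the point.
    """
    mask = np.zeros((h, w), dtype=bool)
    v = polyline.vertices
    if len(v) == 1:
        c = int(np.floor(v[0, 0] + 0.5))
        r = int(np.floor(v[0, 1] + 0.5))
        if 0 <= r < h and 0 <= c < w:
            mask[r, c] = True
        return mask
    for k in range(len(v) - 1):
        rows, cols = _segment_cells(v[k], v[k + 1])
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        mask[rows[keep], cols[keep]] = True
    return mask


def make_gaussian_psf(sigma: float, truncate_radius: float = 4.0) -> Psf:
    """Discretized isotropic Gaussian, truncated at ``truncate_radius``·σ."""
    if sigma <= 0:
        raise ValueError("psf sigma must be > 0")
    half = max(1, int(np.ceil(truncate_radius * sigma)))
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return Psf(k / k.sum())


def render_ideal(masks: list[np.ndarray], psf: Psf, contrast: float,
                 background: float) -> IdealImage:
    """Image formation: A·(union(masks) * psf) + B, zero-padded borders."""
    if not masks:
        raise ValueError("render_ideal needs at least one mask (may be empty)")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("all masks must share one shape")
    union = np.zeros(shape, dtype=float)
    for m in masks:
        union[m] = 1.0
    blurred = ndimage.convolve(union, psf.kernel, mode="constant", cval=0.0)
    return IdealImage(base=contrast * blurred + background)


def truncate_polyline(polyline: Polyline, max_arc: float) -> Polyline:
    """Sub-polyline covering the first ``max_arc`` of arc length."""
    v = polyline.vertices
    if max_arc <= 0 or len(v) < 2:
        return Polyline(v[:1])
    out = [v[0]]
    remaining = max_arc
    for k in range(len(v) - 1):
        seg = v[k + 1] - v[k]
        ell = float(np.linalg.norm(seg))
        if ell <= remaining or ell == 0.0:
            out.append(v[k + 1])
            remaining -= ell
            if remaining <= 0:
                break
        else:
            out.append(v[k] + seg * (remaining / ell))
            break
    return Polyline(np.asarray(out))


def render_seeds(scene: Scene, theta: ThetaParams, h: int, w: int) -> np.ndarray:
    """Shared mask of the first ``seed_len`` of arc length of each filament."""
    seed_mask = np.zeros((h, w), dtype=bool)
    if theta.seed_len <= 0:
        return seed_mask
    for spec in scene.filaments:
        poly = truncate_polyline(filament_to_polyline(spec), theta.seed_len)
        if len(poly.vertices) >= 2:
            seed_mask |= rasterize_polyline(poly, h, w)
    return seed_mask


def compose_rgb(ideal: IdealImage, seed_support: np.ndarray, psf: Psf,
                seed_gain: float) -> np.ndarray:
    """Replicate the base on 3 channels; add blurred seed signal to red only."""
    base = ideal.base
    if seed_support.shape != base.shape:
        raise ValueError("seed support shape must match the image")
    rgb = np.repeat(base[:, :, None], 3, axis=2).astype(float)
    if seed_support.any() and seed_gain != 0.0:
        seed_signal = ndimage.convolve(seed_support.astype(float), psf.kernel,
                                       mode="constant", cval=0.0)
        rgb[:, :, 0] += seed_gain * seed_signal
    return np.clip(rgb, 0.0, 1.0)


def dilate_mask(mask: np.ndarray, radius: int = GT_DILATION_RADIUS) -> np.ndarray:
    """Disk dilation used to give ground-truth masks physical width."""
    if radius <= 0:
        return mask.copy()
    return dilation(mask, disk(radius)).astype(bool)
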