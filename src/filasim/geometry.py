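"""Filament geometry: correlated random walks in the plane.

Each filament is a polyline of n segments.  Segment k has length ℓ_k (drawn
from a truncated-positive Gaussian) and absolute direction ϕ_k.  Directions
evolve as a correlated random walk

    ϕ_k = ϕ_{k−1} + B_k · η_k,      η_k ~ Gamma(shape, scale),

where B_k ∈ {−1, +1} chooses the bending side.  The sign process flips with
probability ``flip_prob`` per step, and the total number of flips is capped
at ``max_flips`` (Σ|B_k − B_{k−1}| ≤ 2·max_flips); once the budget is spent
the sign freezes.  Persistence (apparent stiffness) is governed by the
product shape·scale per unit of arc length.

Coordinate convention, shared by all modules: continuous (x, y) with the
origin at the center of the top-left pixel, x rightward, y downward.
Filaments may leave the canvas; clipping happens at rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ThetaParams

__all__ = [
    "FilamentSpec",
    "Polyline",
    "Scene",
    "sample_filament",
    "filament_to_polyline",
    "sample_scene",
    "truncated_positive_normal",
]

_MAX_REDRAWS = 1000


def truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw rejected-and-redrawn until > 0 (cap 1000 redraws)."""
    if sd == 0.0:
        if mean <= 0:
            raise ValueError("degenerate length law with non-positive mean")
        return mean
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValueError(
        f"could not draw a positive value from N({mean}, {sd}^2) in {_MAX_REDRAWS} tries"
    )


@dataclass
class FilamentSpec:
    """One filament's sampled random-walk realization.

    ``bend_angles[k]`` is the absolute direction ϕ_k of segment k;
    ``bend_angles[0]`` equals ``seed_orientation`` (no bend on the first
    segment).  ``signs[k]`` is B_k, with ``signs[0]`` the initial side.
    """

    seg_lengths: np.ndarray     # (n,) > 0, pixels
    bend_angles: np.ndarray     # (n,) radians, absolute directions
    signs: np.ndarray           # (n,) in {-1, +1}
    seed_origin: tuple[float, float]
    seed_orientation: float
    total_length: float

    @property
    def n_segments(self) -> int:
        return len(self.seg_lengths)

    def n_sign_flips(self) -> int:
        """Number of k with B_k != B_{k-1} (= Σ|B_k−B_{k−1}| / 2)."""
        return int(np.sum(self.signs[1:] != self.signs[:-1]))


@dataclass
class Polyline:
    """Ordered chain of continuous (x, y) vertices."""

    vertices: np.ndarray  # (m, 2) float, columns (x, y)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 1:
            raise ValueError("polyline needs an (m, 2) array with m >= 1")

    def arc_length(self) -> float:
        if len(self.vertices) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))


@dataclass
class Scene:
    """Per-image collection of filaments plus the canvas they live on."""

    filaments: list[FilamentSpec]
    canvas: tuple[int, int]  # (h, w)

    def __post_init__(self):
        h, w = self.canvas
        for f in self.filaments:
            x, y = f.seed_origin
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"seed origin {f.seed_origin} outside canvas {self.canvas}")


def sample_filament(theta: ThetaParams, rng: np.random.Generator) -> FilamentSpec:
    """Sample one correlated-random-walk filament under θ.

    The total length L is drawn first; segments are drawn until their
    cumulative length reaches L, and the last segment is truncated so the
    arc length equals L exactly (n is emergent, L is exact).
    """
    L = truncated_positive_normal(rng, theta.fil_len_mean, theta.fil_len_sd)
    origin = None  # assigned by sample_scene; standalone use gets (0, 0)

    seg_lengths: list[float] = []
    cum = 0.0
    while cum < L - 1e-12:
        ell = truncated_positive_normal(rng, theta.seg_len_mean, theta.seg_len_sd)
        if cum + ell >= L:
            ell = L - cum  # truncate the last segment to hit L exactly
        seg_lengths.append(ell)
        cum += ell
    seg = np.asarray(seg_lengths, dtype=float)
    n = len(seg)

    phi0 = float(rng.uniform(0.0, 2.0 * np.pi))
    signs = np.empty(n, dtype=int)
    signs[0] = 1 if rng.random() < 0.5 else -1
    flips_left = int(theta.max_flips)
    for k in range(1, n):
        if flips_left > 0 and rng.random() < theta.flip_prob:
            signs[k] = -signs[k - 1]
            flips_left -= 1
        else:
            signs[k] = signs[k - 1]

    if theta.bend_scale > 0 and theta.bend_shape > 0:
        eta = rng.gamma(theta.bend_shape, theta.bend_scale, size=n)
    else:
        eta = np.zeros(n)
    eta[0] = 0.0  # first segment points along the seed orientation
    phi = phi0 + np.cumsum(signs * eta)

    return FilamentSpec(
        seg_lengths=seg,
        bend_angles=phi,
        signs=signs,
        seed_origin=origin if origin is not None else (0.0, 0.0),
        seed_orientation=phi0,
        total_length=L,
    )


def filament_to_polyline(spec: FilamentSpec) -> Polyline:
    """Integrate the walk: vertex_{k+1} = vertex_k + ℓ_k·(cos ϕ_k, sin ϕ_k)."""
    steps = spec.seg_lengths[:, None] * np.stack(
        [np.cos(spec.bend_angles), np.sin(spec.bend_angles)], axis=1
    )
    verts = np.empty((spec.n_segments + 1, 2))
    verts[0] = spec.seed_origin
    verts[1:] = spec.seed_origin + np.cumsum(steps, axis=0)
    return Polyline(verts)


def sample_scene(theta: ThetaParams, rng: np.random.Generator) -> Scene:
    """Sample a scene: count ~ round(truncated-at-0 Gaussian), origins uniform."""
    h, w = theta.image_h, theta.image_w
    if theta.count_sd == 0.0:
        count = int(round(max(theta.count_mean, 0.0)))
    else:
        # truncated-at-0 Gaussian: negatives rejected and redrawn, then rounded
        for _ in range(_MAX_REDRAWS):
            draw = rng.normal(theta.count_mean, theta.count_sd)
            if draw >= 0.0:
                break
        else:
            draw = 0.0
        count = int(round(draw))
    filaments = []
    for _ in range(count):
        spec = sample_filament(theta, rng)
        spec.seed_origin = (float(rng.uniform(0, w)), float(rng.uniform(0, h)))
        filaments.append(spec)
    return Scene(filaments=filaments, canvas=(h, w))
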