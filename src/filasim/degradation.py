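"""Stochastic degradation operator: noise, artifacts and distractors.

The operator applies, in a fixed documented order:

  1. low-frequency multiplicative background field
  2. distractor spots (blurred disks; never added to ground-truth masks)
  3. Gaussian blur
  4. vignetting (radial cosine falloff, 1 at center, 1−strength at corners)
  5. multiplicative speckle
  6. Poisson shot noise at ``photon_scale`` (0 = off)
  7. additive Gaussian noise
  8. per-channel multiplicative gain jitter (RGB inputs only)
  9. clip to [0, 1]

Signal-dependent noise therefore acts on the already-structured image, and
a zero-amplitude configuration is a bit-exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .parameters import ThetaParams

__all__ = ["DegradationConfig", "degrade", "make_background_field", "add_distractor_spots"]


@dataclass
class DegradationConfig:
    """Noise/artifact subset of θ; all amplitudes are >= 0."""

    noise_gauss_sd: float = 0.0
    photon_scale: float = 0.0   # 0 is the documented sentinel for "Poisson off"
    speckle_sd: float = 0.0
    vignette_strength: float = 0.0
    blur_sigma: float = 0.0
    bgfield_amp: float = 0.0
    bgfield_scale: float = 1.0
    n_spots_mean: float = 0.0
    spot_radius_range: tuple[float, float] = (2.0, 6.0)
    spot_gain_range: tuple[float, float] = (-0.1, 0.1)
    spot_blur_sigma: float = 0.0
    channel_jitter_sd: float = 0.0

    def __post_init__(self):
        for f in ("noise_gauss_sd", "photon_scale", "speckle_sd", "vignette_strength",
                  "blur_sigma", "bgfield_amp", "n_spots_mean", "spot_blur_sigma",
                  "channel_jitter_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.bgfield_scale <= 0:
            raise ValueError("bgfield_scale must be > 0")

    @classmethod
    def from_theta(cls, theta: ThetaParams) -> "DegradationConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{n: getattr(theta, n) for n in names})


def make_background_field(h: int, w: int, amp: float, scale: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Multiplicative field 1 + amp·G with G smoothed, zero-mean, max|G| = 1."""
    if amp == 0.0:
        return np.ones((h, w))
    noise = rng.standard_normal((h, w))
    g = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    g = g - g.mean()
    peak = np.max(np.abs(g))
    if peak > 0:
        g = g / peak
    return 1.0 + amp * g


def _vignette_field(h: int, w: int, strength: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_corner = np.hypot(cy, cx)
    if r_corner == 0:
        return np.ones((h, w))
    # cosine falloff: 1 at center, (1 - strength) at the farthest corner
    return (1.0 - strength) + strength * np.cos(0.5 * np.pi * r / r_corner)


def add_distractor_spots(image: np.ndarray, config: DegradationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Stamp Poisson(n_spots_mean) blurred disks; ground truth is untouched."""
    if config.n_spots_mean == 0.0:
        return image
    out = image.copy()
    h, w = image.shape[:2]
    n = int(rng.poisson(config.n_spots_mean))
    for _ in range(n):
        radius = rng.uniform(*config.spot_radius_range)
        gain = rng.uniform(*config.spot_gain_range)
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        stamp = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2).astype(float)
        if config.spot_blur_sigma > 0:
            stamp = ndimage.gaussian_filter(stamp, config.spot_blur_sigma)
        if image.ndim == 3:
            out += gain * stamp[:, :, None]
        else:
            out += gain * stamp
    return out


def degrade(image: np.ndarray, config: DegradationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the degradation stages in their fixed order (seed-deterministic).

    A configuration with every amplitude at zero (and photon_scale 0)
    returns the input bit-exactly.
    """
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    identity = (
        config.bgfield_amp == 0.0 and config.n_spots_mean == 0.0
        and config.blur_sigma == 0.0 and config.vignette_strength == 0.0
        and config.speckle_sd == 0.0 and config.photon_scale == 0.0
        and config.noise_gauss_sd == 0.0 and config.channel_jitter_sd == 0.0
    )
    if identity:
        return image.copy()

    out = image.astype(float, copy=True)
    h, w = out.shape[:2]
    is_rgb = out.ndim == 3

    if config.bgfield_amp > 0:
        field = make_background_field(h, w, config.bgfield_amp, config.bgfield_scale, rng)
        out = out * (field[:, :, None] if is_rgb else field)

    out = add_distractor_spots(out, config, rng)

    if config.blur_sigma > 0:
        sigma = (config.blur_sigma, config.blur_sigma, 0) if is_rgb else config.blur_sigma
        out = ndimage.gaussian_filter(out, sigma=sigma)

    if config.vignette_strength > 0:
        field = _vignette_field(h, w, config.vignette_strength)
        out = out * (field[:, :, None] if is_rgb else field)

    if config.speckle_sd > 0:
        out = out * (1.0 + config.speckle_sd * rng.standard_normal(out.shape))

    if config.photon_scale > 0:
        out = rng.poisson(np.clip(out, 0.0, None) * config.photon_scale) / config.photon_scale

    if config.noise_gauss_sd > 0:
        out = out + config.noise_gauss_sd * rng.standard_normal(out.shape)

    if is_rgb and config.channel_jitter_sd > 0:
        out = out * (1.0 + config.channel_jitter_sd * rng.standard_normal(3))[None, None, :]

    return np.clip(out, 0.0, 1.0)
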