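"""Generation parameter vector θ: definition, validation, serialization, sampling.

θ is deliberately a flat named-field record so the domain tuner can treat it
as a vector; which fields are tunable is declared by a :class:`SearchSpace`,
not by the type itself.  The canvas size is part of θ but excluded from
tuning by default (the reference datasets use 512×512 crops).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ThetaParams",
    "SearchSpace",
    "default_theta",
    "validate_theta",
    "sample_theta",
    "save_theta",
    "load_theta",
    "save_space",
    "load_space",
]

# Fields that must be >= 0 (standard deviations, scales, amplitudes).
_NONNEG_FIELDS = (
    "count_mean", "count_sd", "seg_len_sd", "fil_len_sd",
    "bend_shape", "bend_scale", "seed_len", "noise_gauss_sd",
    "photon_scale", "speckle_sd", "vignette_strength", "blur_sigma",
    "bgfield_amp", "bgfield_scale", "n_spots_mean", "channel_jitter_sd",
    "spot_blur_sigma", "max_flips",
)
# Fields that must be strictly positive.
_POS_FIELDS = ("seg_len_mean", "fil_len_mean", "psf_sigma", "image_h", "image_w")
# Fields bounded to [0, 1].
_UNIT_FIELDS = ("flip_prob", "background")


@dataclass
class ThetaParams:
    """Full generation parameter vector θ (geometry + imaging + degradation).

    Units: lengths in pixels, angles in radians, intensities on [0, 1].
    ``contrast`` is signed: negative values render dark filaments on a
    brighter background, as in interference reflection microscopy.
    """

    # filament population
    count_mean: float = 11.28
    count_sd: float = 5.1
    # segment length law (pixels)
    seg_len_mean: float = 3.0
    seg_len_sd: float = 1.0
    # bend-increment Gamma law (radians)
    bend_shape: float = 2.0
    bend_scale: float = 0.03
    # bending-direction process
    flip_prob: float = 0.1
    max_flips: int = 5
    # total filament length law (pixels)
    fil_len_mean: float = 130.0
    fil_len_sd: float = 65.0
    # optics
    psf_sigma: float = 1.2
    contrast: float = -0.35
    background: float = 0.55
    # nucleation seeds (red channel)
    seed_len: float = 15.0
    seed_gain: float = 0.3
    # degradation amplitudes
    noise_gauss_sd: float = 0.02
    photon_scale: float = 200.0
    speckle_sd: float = 0.05
    vignette_strength: float = 0.15
    blur_sigma: float = 0.5
    bgfield_amp: float = 0.08
    bgfield_scale: float = 40.0
    n_spots_mean: float = 3.0
    spot_radius_range: tuple[float, float] = (2.0, 6.0)
    spot_gain_range: tuple[float, float] = (-0.15, 0.15)
    spot_blur_sigma: float = 1.0
    channel_jitter_sd: float = 0.01
    # canvas
    image_h: int = 512
    image_w: int = 512

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spot_radius_range"] = list(d["spot_radius_range"])
        d["spot_gain_range"] = list(d["spot_gain_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThetaParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown theta fields: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("spot_radius_range", "spot_gain_range"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        for key in ("max_flips", "image_h", "image_w"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ThetaParams":
        return dataclasses.replace(self, **kwargs)

    @staticmethod
    def field_names() -> list[str]:
        return [f.name for f in dataclasses.fields(ThetaParams)]


def default_theta() -> ThetaParams:
    """Default θ: visible dark filaments on a mid-gray 512×512 background."""
    return ThetaParams()


def validate_theta(theta: ThetaParams) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations: list[str] = []
    for name in _NONNEG_FIELDS:
        if getattr(theta, name) < 0:
            violations.append(f"{name} must be >= 0, got {getattr(theta, name)}")
    for name in _POS_FIELDS:
        if getattr(theta, name) <= 0:
            violations.append(f"{name} must be > 0, got {getattr(theta, name)}")
    for name in _UNIT_FIELDS:
        v = getattr(theta, name)
        if not (0.0 <= v <= 1.0):
            violations.append(f"{name} must lie in [0, 1], got {v}")
    for name in ("spot_radius_range", "spot_gain_range"):
        lo, hi = getattr(theta, name)
        if lo > hi:
            violations.append(f"{name} must satisfy low <= high, got ({lo}, {hi})")
    if theta.spot_radius_range[0] < 0:
        violations.append("spot_radius_range lower bound must be >= 0")
    return violations


@dataclass
class SearchSpace:
    """Per-parameter (low, high, scale) bounds for the tunable subset of θ.

    ``scale`` is ``"linear"`` or ``"log"``; log-scaled fields are sampled
    uniformly in log-space, which suits noise amplitudes spanning orders of
    magnitude.  ``check_theta_fields=False`` allows the same class to carry
    arbitrary named hyperparameters (segmenter adaptation harness).
    """

    bounds: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    check_theta_fields: bool = True

    def __post_init__(self):
        theta_fields = set(ThetaParams.field_names())
        for name, spec in self.bounds.items():
            if len(spec) == 2:
                spec = (spec[0], spec[1], "linear")
                self.bounds[name] = spec
            low, high, scale = spec
            # degenerate low == high is allowed and samples the boundary point
            if not (low <= high):
                raise ValueError(f"search space field {name!r}: low must be <= high")
            if scale not in ("linear", "log"):
                raise ValueError(f"search space field {name!r}: scale must be linear or log")
            if scale == "log" and low <= 0:
                raise ValueError(f"search space field {name!r}: log scale needs low > 0")
            if self.check_theta_fields and name not in theta_fields:
                raise ValueError(f"search space field {name!r} is not a theta field")

    def __iter__(self) -> Iterator[str]:
        return iter(self.bounds)

    def __len__(self) -> int:
        return len(self.bounds)

    def sample_values(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw one value per field, uniform on its (possibly log) scale."""
        out = {}
        for name, (low, high, scale) in self.bounds.items():
            if scale == "log":
                out[name] = float(np.exp(rng.uniform(np.log(low), np.log(high))))
            else:
                out[name] = float(rng.uniform(low, high))
        return out


def sample_theta(space: SearchSpace, rng: np.random.Generator,
                 base: ThetaParams | None = None) -> ThetaParams:
    """Draw a θ with tunable fields sampled from ``space``, rest from ``base``.

    Degenerate bounds are not representable (SearchSpace enforces low < high);
    integer θ fields are rounded after sampling.
    """
    base = base if base is not None else default_theta()
    values = space.sample_values(rng)
    int_fields = {"max_flips", "image_h", "image_w"}
    kwargs = {k: (int(round(v)) if k in int_fields else v) for k, v in values.items()}
    return base.replace(**kwargs)


# ----------------------------------------------------------------------------
# YAML round trips (flat key-value for θ; low/high/scale mapping for spaces)

def save_theta(theta: ThetaParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(theta.to_dict(), fh, sort_keys=True)


def load_theta(path) -> ThetaParams:
    with open(path) as fh:
        return ThetaParams.from_dict(yaml.safe_load(fh))


def save_space(space: SearchSpace, path) -> None:
    doc = {name: {"low": lo, "high": hi, "scale": sc}
           for name, (lo, hi, sc) in space.bounds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_space(path, check_theta_fields: bool = True) -> SearchSpace:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    bounds = {name: (float(v["low"]), float(v["high"]), v.get("scale", "linear"))
              for name, v in doc.items()}
    return SearchSpace(bounds=bounds, check_theta_fields=check_theta_fields)
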