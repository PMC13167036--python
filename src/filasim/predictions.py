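"""Prediction dialects and the unified pre/postprocessing pipeline.

Segmenters emit one of three dialects: per-instance boolean mask stacks,
integer-labeled maps, or ordered anchor-point chains (the native output of
filament tracers).  Everything is normalized to mask stacks for scoring.

Anchor chains are converted two ways, both kept on purpose: an
interpolating parametric cubic spline (smoothing s = 0) for the metrics
path, and straight-line joining for the curvature-preprocessing path.
Chains with fewer than 4 distinct points fall back to piecewise-linear
interpolation, where both conversions coincide.

The unified postprocessing filters predicted instances by skeleton length
and pixel area against bounds computed automatically from the ground
truth (expanded by a relative margin, default 10%); anchor-dialect
predictions are filtered by chain length only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .dataset_io import InstanceMaskStack, labeled_map_to_stack
from .rendering import rasterize_polyline
from .geometry import Polyline
from .seg_metrics import skeletonize

__all__ = [
    "AnchorChain",
    "PredictionSet",
    "GtThresholds",
    "anchors_to_mask_spline",
    "anchors_to_mask_lines",
    "anchor_length",
    "normalize_predictions",
    "compute_gt_thresholds",
    "unified_postprocess",
    "preprocess_image",
    "read_anchor_csv",
    "read_anchor_json",
]

SPLINE_SAMPLES_PER_PIXEL = 4  # dense sampling rate along the fitted spline


@dataclass
class AnchorChain:
    """Ordered list of >= 2 continuous (x, y) anchor points."""

    points: np.ndarray  # (k, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("anchor chain needs an (k, 2) array with k >= 2")
        if not np.all(np.isfinite(pts)):
            raise ValueError("anchor coordinates must be finite")
        self.points = pts

    def deduplicated(self) -> np.ndarray:
        """Collapse consecutive duplicate anchors; error if all collapse."""
        pts = self.points
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        out = pts[keep]
        if len(out) < 2:
            raise ValueError("anchor chain collapses to a single point")
        return out


@dataclass
class PredictionSet:
    """Exactly one payload, tagged with its dialect and canvas shape."""

    dialect: str                 # "stack" | "labels" | "anchors"
    shape: tuple[int, int]
    stack: InstanceMaskStack | None = None
    labels: np.ndarray | None = None
    chains: list[AnchorChain] | None = None

    def __post_init__(self):
        payloads = {"stack": self.stack is not None,
                    "labels": self.labels is not None,
                    "anchors": self.chains is not None}
        if self.dialect not in payloads:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not payloads[self.dialect] or sum(payloads.values()) != 1:
            raise ValueError(f"dialect {self.dialect!r} inconsistent with payload")

    def n_instances(self) -> int:
        if self.dialect == "stack":
            return len(self.stack)
        if self.dialect == "labels":
            return int(np.sum(np.unique(self.labels) > 0))
        return len(self.chains)


@dataclass
class GtThresholds:
    """Dataset-specific plausibility bounds derived from the ground truth."""

    min_length: float
    max_length: float
    min_area: float
    max_area: float

    def __post_init__(self):
        if self.min_length > self.max_length or self.min_area > self.max_area:
            raise ValueError("thresholds must satisfy min <= max")
        if min(self.min_length, self.min_area) < 0:
            raise ValueError("thresholds must be >= 0")


def anchor_length(chain: AnchorChain) -> float:
    """Sum of consecutive Euclidean distances along the chain."""
    return float(np.sum(np.linalg.norm(np.diff(chain.points, axis=0), axis=1)))


def _dense_spline_polyline(pts: np.ndarray) -> np.ndarray:
    """Interpolating cubic spline through the anchors, densely sampled."""
    chord = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    n_samp = max(2, int(np.ceil(SPLINE_SAMPLES_PER_PIXEL * chord)))
    if len(pts) < 4:
        # cubic interpolation undefined; piecewise-linear degeneracy
        return pts
    tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0, k=3)
    u = np.linspace(0.0, 1.0, n_samp)
    x, y = splev(u, tck)
    return np.stack([x, y], axis=1)


def anchors_to_mask_spline(chain: AnchorChain, h: int, w: int) -> np.ndarray:
    """Spline-interpolate the chain (s = 0) and supercover-rasterize it."""
    pts = chain.deduplicated()
    return rasterize_polyline(Polyline(_dense_spline_polyline(pts)), h, w)


def anchors_to_mask_lines(chain: AnchorChain, h: int, w: int) -> np.ndarray:
    """Join consecutive anchors by straight lines and rasterize the union."""
    pts = chain.deduplicated()
    return rasterize_polyline(Polyline(pts), h, w)


def normalize_predictions(preds: PredictionSet) -> InstanceMaskStack:
    """Convert any dialect to an instance mask stack (metrics path).

    Anchor chains go through the spline conversion; the instance count and
    order are always preserved.
    """
    h, w = preds.shape
    if preds.dialect == "stack":
        return preds.stack
    if preds.dialect == "labels":
        return labeled_map_to_stack(preds.labels)
    return InstanceMaskStack(
        [anchors_to_mask_spline(c, h, w) for c in preds.chains], (h, w))


def compute_gt_thresholds(gt: InstanceMaskStack, margin: float = 0.1) -> GtThresholds:
    """Min/max of GT skeleton lengths and areas, expanded by ``margin``."""
    if len(gt) == 0:
        raise ValueError("cannot derive thresholds from empty ground truth")
    lengths = np.array([int(skeletonize(m).sum()) for m in gt], dtype=float)
    areas = np.array([int(m.sum()) for m in gt], dtype=float)
    return GtThresholds(
        min_length=float(lengths.min() * (1 - margin)),
        max_length=float(lengths.max() * (1 + margin)),
        min_area=float(areas.min() * (1 - margin)),
        max_area=float(areas.max() * (1 + margin)),
    )


def unified_postprocess(preds: PredictionSet, thresholds: GtThresholds) -> PredictionSet:
    """Filter implausible instances; survivor order is preserved.

    Mask dialects keep an instance iff its skeleton length AND pixel area
    fall within bounds; anchor dialects use the chain length only (area is
    meaningless there).  Labeled-map inputs come back as a mask stack.
    """
    h, w = preds.shape
    if preds.dialect == "anchors":
        kept = [c for c in preds.chains
                if thresholds.min_length <= anchor_length(c) <= thresholds.max_length]
        return PredictionSet(dialect="anchors", shape=preds.shape, chains=kept)
    stack = preds.stack if preds.dialect == "stack" else labeled_map_to_stack(preds.labels)
    kept_masks = []
    for m in stack:
        length = int(skeletonize(m).sum())
        area = int(m.sum())
        if (thresholds.min_length <= length <= thresholds.max_length
                and thresholds.min_area <= area <= thresholds.max_area):
            kept_masks.append(m)
    return PredictionSet(dialect="stack", shape=(h, w),
                         stack=InstanceMaskStack(kept_masks, (h, w)))


# ----------------------------------------------------------------------------
# shared preprocessing

def preprocess_image(image: np.ndarray, config: list[dict] | None) -> np.ndarray:
    """Apply a configurable preprocessing chain (identity for empty config).

    Steps: ``minmax``, ``stretch`` (percentile contrast stretch, params
    ``plow``/``phigh``), ``invert``, ``denoise`` (Gaussian, param ``sigma``),
    ``to_rgb`` (grayscale replication).
    """
    if not config:
        return image
    out = image.astype(float, copy=True)
    for step in config:
        name = step.get("name")
        if name == "minmax":
            lo, hi = out.min(), out.max()
            out = (out - lo) / (hi - lo) if hi > lo else out - lo
        elif name == "stretch":
            plow = step.get("plow", 1.0)
            phigh = step.get("phigh", 99.0)
            lo, hi = np.percentile(out, [plow, phigh])
            out = np.clip((out - lo) / (hi - lo), 0, 1) if hi > lo else out - lo
        elif name == "invert":
            out = 1.0 - out
        elif name == "denoise":
            sigma = step.get("sigma", 1.0)
            if out.ndim == 3:
                out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0))
            else:
                out = ndimage.gaussian_filter(out, sigma=sigma)
        elif name == "to_rgb":
            if out.ndim == 2:
                out = np.repeat(out[:, :, None], 3, axis=2)
        else:
            raise ValueError(f"unknown preprocessing step {name!r}")
    return out


# ----------------------------------------------------------------------------
# anchor-chain file formats

def read_anchor_csv(path) -> list[AnchorChain]:
    """CSV columns: instance_id, point_index, x, y (chains ordered by id)."""
    rows: dict[int, list[tuple[int, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            iid = int(rec["instance_id"])
            rows.setdefault(iid, []).append(
                (int(rec["point_index"]), float(rec["x"]), float(rec["y"])))
    chains = []
    for iid in sorted(rows):
        pts = sorted(rows[iid])
        chains.append(AnchorChain(np.array([(x, y) for _, x, y in pts])))
    return chains


def read_anchor_json(path) -> list[AnchorChain]:
    """JSON: list of instances, each a list of [x, y] points."""
    with open(path) as fh:
        doc = json.load(fh)
    return [AnchorChain(np.asarray(pts, dtype=float)) for pts in doc]
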