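"""Sample generation, dataset assembly and on-disk formats.

A sample couples one rendered frame with an ordered stack of per-instance
boolean masks.  Masks are stored as multi-page TIFFs (one page per
instance, 0/255) so that overlapping filaments are preserved exactly; the
reader accepts any nonzero pixel as foreground.  A JSON ImageDescription
header records the instance count, which disambiguates the empty stack
(tifffile cannot write a zero-page file, so an empty stack is stored as a
single all-zero sentinel page with ``n_instances: 0``).

Dataset assembly mirrors the benchmark combinatorics: per domain group, a
list of retained parameter sets, and a fixed number of draws per set; each
record's seed derives deterministically from the master seed so the whole
dataset is reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .degradation import DegradationConfig, degrade
from .geometry import Scene, filament_to_polyline, sample_scene
from .parameters import ThetaParams
from .rendering import (compose_rgb, dilate_mask, make_gaussian_psf,
                        rasterize_polyline, render_ideal, render_seeds)

__all__ = [
    "InstanceMaskStack",
    "SampleRecord",
    "DatasetManifest",
    "generate_sample",
    "write_mask_stack",
    "read_mask_stack",
    "labeled_map_to_stack",
    "assemble_dataset",
    "read_image",
    "write_image",
    "derive_sample_seed",
    "load_manifest",
]

MIN_SKELETON_PIXELS = 2  # filaments with fewer in-canvas skeleton px are dropped


@dataclass
class InstanceMaskStack:
    """Ordered, overlap-preserving collection of same-shape boolean masks."""

    masks: list[np.ndarray]
    shape: tuple[int, int]

    def __post_init__(self):
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for i, m in enumerate(self.masks):
            if m.shape != tuple(self.shape):
                raise ValueError(f"mask {i} has shape {m.shape}, expected {self.shape}")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i) -> np.ndarray:
        return self.masks[i]

    def as_array(self) -> np.ndarray:
        if not self.masks:
            return np.zeros((0, *self.shape), dtype=bool)
        return np.stack(self.masks)


@dataclass
class SampleRecord:
    image_path: str
    mask_path: str
    domain_id: int
    theta_id: int
    draw_index: int
    seed: int
    theta: dict


@dataclass
class DatasetManifest:
    master_seed: int
    version: str
    records: list[SampleRecord] = field(default_factory=list)


def generate_sample(theta: ThetaParams, seed: int,
                    scene: Scene | None = None
                    ) -> tuple[np.ndarray, InstanceMaskStack, Scene]:
    """Run geometry → rendering → degradation with one seeded stream.

    Returns the degraded RGB image (h, w, 3) in [0, 1], the ground-truth
    instance stack (skeletons dilated by 1 px, one slice per filament whose
    in-canvas skeleton has at least 2 pixels), and the sampled scene.
    """
    rng = np.random.default_rng(seed)
    h, w = theta.image_h, theta.image_w
    if scene is None:
        scene = sample_scene(theta, rng)

    skeleton_masks: list[np.ndarray] = []
    kept = []
    for spec in scene.filaments:
        m = rasterize_polyline(filament_to_polyline(spec), h, w)
        if m.sum() >= MIN_SKELETON_PIXELS:
            skeleton_masks.append(m)
            kept.append(spec)
    visible = Scene(filaments=kept, canvas=(h, w))

    psf = make_gaussian_psf(theta.psf_sigma)
    ideal = render_ideal(skeleton_masks or [np.zeros((h, w), bool)], psf,
                         theta.contrast, theta.background)
    seed_mask = render_seeds(visible, theta, h, w)
    rgb = compose_rgb(ideal, seed_mask, psf, theta.seed_gain)
    image = degrade(rgb, DegradationConfig.from_theta(theta), rng)

    gt = InstanceMaskStack([dilate_mask(m) for m in skeleton_masks], (h, w))
    return image, gt, visible


# ----------------------------------------------------------------------------
# mask stacks

def write_mask_stack(stack: InstanceMaskStack, path) -> None:
    header = json.dumps({"n_instances": len(stack), "shape": list(stack.shape)})
    if len(stack) == 0:
        data = np.zeros((1, *stack.shape), dtype=np.uint8)  # sentinel page
    else:
        data = stack.as_array().astype(np.uint8) * 255
    tifffile.imwrite(path, data, photometric="minisblack", description=header)


def read_mask_stack(path) -> InstanceMaskStack:
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            desc = tif.pages[0].description
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"not a readable TIFF mask stack: {path}: {exc}") from exc
    if not pages:
        raise ValueError(f"mask stack {path} has no pages")
    shape = pages[0].shape
    for i, p in enumerate(pages):
        if p.ndim != 2 or p.shape != shape:
            raise ValueError(f"mask stack {path}: page {i} has shape {p.shape}, "
                             f"expected {shape}")
    n = None
    if desc:
        try:
            n = int(json.loads(desc).get("n_instances"))
        except (ValueError, TypeError, json.JSONDecodeError):
            n = None
    if n == 0:
        return InstanceMaskStack([], shape)
    masks = [p != 0 for p in pages]  # any nonzero value counts as foreground
    return InstanceMaskStack(masks, shape)


def labeled_map_to_stack(labeled: np.ndarray) -> InstanceMaskStack:
    """One slice per distinct nonzero label, ascending label order."""
    labeled = np.asarray(labeled)
    if np.any(labeled < 0):
        raise ValueError("labeled map must be non-negative")
    labels = np.unique(labeled)
    labels = labels[labels > 0]
    return InstanceMaskStack([labeled == lab for lab in labels], labeled.shape)


# ----------------------------------------------------------------------------
# images

def write_image(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Quantize a float [0, 1] image to 8 or 16 bits and write TIFF/PNG."""
    if bit_depth == 8:
        arr = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path) -> np.ndarray:
    """Read a 1- or 3-channel 8/16-bit image as floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float)
    raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")


# ----------------------------------------------------------------------------
# dataset assembly

def derive_sample_seed(master_seed: int, domain_id: int, theta_id: int,
                       draw: int) -> int:
    """Deterministic per-sample seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(domain_id),
                                 int(theta_id), int(draw)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def assemble_dataset(groups: list[tuple[int, list[ThetaParams]]],
                     draws_per_set: int, master_seed: int, out_dir) -> DatasetManifest:
    """Draw ``draws_per_set`` samples per (group, parameter set) and write all.

    With 66 groups × 10 sets × 10 draws this yields the benchmark's 6600
    records.  Images are 8-bit RGB TIFFs; masks are multi-page TIFF stacks;
    the manifest is JSON-lines with a header record.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    from . import __version__
    manifest = DatasetManifest(master_seed=master_seed, version=__version__)
    for domain_id, thetas in groups:
        for theta_id, theta in enumerate(thetas):
            for draw in range(draws_per_set):
                seed = derive_sample_seed(master_seed, domain_id, theta_id, draw)
                image, gt, _ = generate_sample(theta, seed)
                stem = f"d{domain_id:03d}_t{theta_id:02d}_s{draw:02d}"
                img_path = out_dir / "images" / f"{stem}.tif"
                mask_path = out_dir / "masks" / f"{stem}_masks.tif"
                write_image(image, img_path)
                write_mask_stack(gt, mask_path)
                manifest.records.append(SampleRecord(
                    image_path=str(img_path.relative_to(out_dir)),
                    mask_path=str(mask_path.relative_to(out_dir)),
                    domain_id=domain_id, theta_id=theta_id, draw_index=draw,
                    seed=seed, theta=theta.to_dict()))

    with open(out_dir / "manifest.jsonl", "w") as fh:
        fh.write(json.dumps({"kind": "header", "master_seed": master_seed,
                             "version": manifest.version,
                             "n_records": len(manifest.records)}) + "\n")
        for rec in manifest.records:
            fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")
    return manifest


def load_manifest(path) -> DatasetManifest:
    records = []
    master_seed = 0
    version = ""
    with open(path) as fh:
        for line in fh:
            doc = json.loads(line)
            if doc.get("kind") == "header":
                master_seed = doc["master_seed"]
                version = doc.get("version", "")
            else:
                records.append(SampleRecord(**doc))
    return DatasetManifest(master_seed=master_seed, version=version, records=records)
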