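"""Assemble a small labeled dataset on disk (images, mask stacks, manifest).

The benchmark-scale layout is groups x parameter sets x draws; here we
build 2 x 2 x 3 = 12 samples at reduced canvas size.  Every sample's seed
derives from the master seed, so the dataset regenerates byte-for-byte.
"""

import tempfile
from pathlib import Path

from filasim import default_theta
from filasim.dataset_io import assemble_dataset, load_manifest

theta = default_theta().replace(image_h=128, image_w=128, count_mean=4,
                                count_sd=1, fil_len_mean=50, fil_len_sd=15)
out = Path(tempfile.mkdtemp()) / "demo_dataset"
groups = [(g, [theta, theta]) for g in range(2)]
manifest = assemble_dataset(groups, draws_per_set=3, master_seed=7, out_dir=out)

print(f"wrote {len(manifest.records)} samples under {out}")
reloaded = load_manifest(out / "manifest.jsonl")
print(f"manifest round trip: {len(reloaded.records)} records, "
      f"master seed {reloaded.master_seed}")
rec = reloaded.records[0]
print(f"first record: {rec.image_path} / {rec.mask_path} (seed {rec.seed})")
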