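"""Generate one synthetic IRM-like frame with per-filament ground truth.

The generator draws a scene of correlated-random-walk filaments, renders
them through a Gaussian PSF as dark lines on a gray background (with red
nucleation seeds), degrades the frame with realistic noise/artifacts, and
returns one boolean mask per filament (overlaps preserved).
"""

from filasim import default_theta, generate_sample

theta = default_theta()
image, gt, scene = generate_sample(theta, seed=1)

print(f"image shape: {image.shape} (RGB float in [0, 1])")
print(f"filaments drawn: {len(scene.filaments)}, ground-truth slices: {len(gt)}")
print(f"intensity range: [{image.min():.3f}, {image.max():.3f}]")
print(f"first filament: L = {scene.filaments[0].total_length:.1f} px, "
      f"{scene.filaments[0].n_segments} segments")
# Each ground-truth slice is the filament's rasterized centerline dilated
# to physical width; slice pixel counts are the instance areas.
print("slice areas (px):", [int(m.sum()) for m in gt][:5], "...")
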