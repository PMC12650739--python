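"""Generate a small synthetic bright-field organoid dataset.

Each frame contains one dark, irregularly-shaped organoid with a dark
rim on a bright, slightly uneven background, plus sensor noise; the
ground-truth mask is the exact interior of the generated boundary curve.
"""

from pathlib import Path

from organoidseg import SynthParams, generate_dataset, split_dataset

out = Path("scratch/example_dataset")
params = SynthParams()  # defaults: bg 0.82, organoid 0.45, noise sd 0.03

ds = generate_dataset(n=30, side=128, params=params, seed=42, out_dir=out)
split = split_dataset(ds, seed=42)

print(f"wrote {len(ds)} image/mask pairs to {out}")
print(f"train/val/test = {len(split.train_ids)}/{len(split.val_ids)}/"
      f"{len(split.test_ids)}  (70/10/20 split)")
image, mask = ds.load_pair(split.train_ids[0])
print(f"first training frame: {image.shape[0]}x{image.shape[1]} px, "
      f"organoid covers {mask.mean():.1%} of the frame")
# the foreground fraction reflects the sampled radius (15-35% of the side)
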