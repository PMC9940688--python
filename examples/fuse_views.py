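"""Attention-selection fusion of three complementary importance maps.

Generates one synthetic insect whose three view maps each highlight a
different band of the body, fuses them with the selection rule
w0*min + w1*(max - min), and compares the textural information (spatial
frequency SF, average gradient AG) of the fused map against a plain
per-pixel average.  Higher SF/AG means more of the views' detail survived
fusion.
"""

import numpy as np

from camfuse import (
    FusionConfig,
    SyntheticSpec,
    average_gradient,
    fuse_maps,
    generate_dataset,
    iou,
    spatial_frequency,
    threshold_mask,
)
from camfuse.synthetic import VIEWS

ds = generate_dataset(SyntheticSpec(n_classes=3, per_class=2, seed=0))
maps = [ds.view_maps[v][0] for v in VIEWS]
mask = ds.masks[0]

for v, m in zip(VIEWS, maps):
    cov = (threshold_mask(m, 0.5) & mask).sum() / mask.sum()
    print(f"view {v:>4}: covers {cov:.0%} of the insect")

cfg = FusionConfig(w0=1.0, w1=0.5)
fused = fuse_maps(maps, cfg, mode="map")
print(f"fused    : IoU with insect mask {iou(threshold_mask(fused, 0.5), mask):.3f}")

avg = np.mean([m.values for m in maps], axis=0)
avg = (avg - avg.min()) / (avg.max() - avg.min())
print(f"SF  fused {spatial_frequency(fused.values, 1.0):.4f}  "
      f"vs averaged {spatial_frequency(avg, 1.0):.4f}")
print(f"AG  fused {average_gradient(fused.values, 255.0):.3f}  "
      f"vs averaged {average_gradient(avg, 255.0):.3f}")
print("The selection rule recovers the whole insect from partial views and")
print("keeps more texture than naive averaging (higher SF and AG).")
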