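"""The seven-method augmentation protocol and dataset balancing.

Samples augmentation plans (each method included with its fixed
probability, parameters uniform in their intervals), applies one plan to an
image, and balances a small unbalanced manifest up to a target count.
"""

import collections

import numpy as np

from camfuse import SyntheticSpec, apply_plan, balance_dataset, generate_dataset, sample_plan

plan = sample_plan(rng_seed=7)
print("sampled plan (seed 7):")
for method, params in plan:
    shown = {k: round(v, 3) if isinstance(v, float) else v for k, v in params.items()}
    print(f"  {method}: {shown}")

ds = generate_dataset(SyntheticSpec(n_classes=2, per_class=2, seed=0))
out = apply_plan(ds.images[0], plan)
print(f"augmented image: shape {out.shape}, range [{out.min():.2f}, {out.max():.2f}]")

counts = collections.Counter(m for s in range(10_000) for m, _ in sample_plan(rng_seed=s))
print("inclusion frequency over 10,000 plans (target probabilities in parens):")
for method, p in [("HF", 0.5), ("BC", 0.4), ("Shift", 0.4), ("Scale", 0.3),
                  ("Rotate", 0.4), ("GB", 0.5), ("Sharpen", 0.3)]:
    print(f"  {method:>7}: {counts[method] / 10_000:.3f} ({p})")

manifest = [{"path": f"a/{i}.png", "label": "a", "origin": "original", "plan": ""}
            for i in range(3)]
manifest += [{"path": f"b/{i}.png", "label": "b", "origin": "original", "plan": ""}
             for i in range(10)]
balanced = balance_dataset(manifest, target_per_class=10, rng_seed=0)
added = sum(1 for r in balanced if r["origin"] == "augmented")
print(f"balancing: {len(manifest)} entries -> {len(balanced)} "
      f"({added} augmented copies added to the minority class)")
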