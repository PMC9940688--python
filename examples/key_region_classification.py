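"""Full pipeline: complementary views -> fusion -> key regions -> SVM.

Runs the end-to-end recognition chain on the synthetic fixture set (3
classes x 100 images).  Class identity is carried by a marking whose
position no single view fully observes, so the fused key region should beat
every single-view key region.  Accuracies are percentages on the held-out
20% split.
"""

from camfuse import PipelineConfig, SplitSpec, SvmConfig, SyntheticSpec, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticSpec(n_classes=3, per_class=100, image_side=64, seed=0),
    split=SplitSpec(seed=0),
    svm=SvmConfig(seed=0),
)
result = run_pipeline(cfg)
for view in ("cnn", "vit", "swin", "fused"):
    rep = result.reports[view]
    print(f"{view:>5}: acc {rep.accuracy:5.1f}  F1 {rep.f1:5.1f}  "
          f"rec {rep.recall:5.1f}  pre {rep.precision:5.1f}")
print(f"(n = {result.n_samples} images, config {result.config_hash})")
print("The fused view sees all three marking positions; each single view")
print("confuses the two classes whose markings fall outside its band.")
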