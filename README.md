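# camfuse

Multi-view Grad-CAM fusion and key-region classification for fine-grained
image recognition, built around the insect-pest setting: species differ in
subtle local detail, single feature extractors attend to only part of that
detail, and the discriminative evidence is scattered across the body.

## The method

Three backbone *views* — a CNN-style residual network and two
transformer-style networks (ViT-like and Swin-like) — each produce a
per-pixel importance map for an image via Grad-CAM: with target-layer
activations `A^k` and a class score `y_c`,

    alpha_k = (1 / uv) * sum_{i,j} dy_c / dA^k_{ij}         (neuron importance)
    CAM     = ReLU( sum_k alpha_k * A^k ),                   upsampled, min-max to [0, 1]

Transformers have no convolutional target layer, so a **patch
transformation** reshapes the final token tensor into a spatial map first:
ViT drops the class token and arranges its `N` patch tokens row-major into
a `sqrt(N) x sqrt(N)` grid; the Swin-style network's `(H/32)(W/32)` tokens
with `8C` channels become an `(H/32) x (W/32)` map.

Because the views attend to complementary regions, the three maps are fused
by an **attention-selection** rule applied per feature channel `k` and
pixel, with balance weights `w0 >= w1 >= 0`:

    fused^k = Eigen{ w0 * min_i alpha_i^k  +  w1 * ( max_i alpha_i^k - min_i alpha_i^k ) }

i.e. the consensus (fuzzy intersection) is weighted up, the
union-minus-intersection remainder is kept at reduced weight, and `Eigen{}`
denotes an optional rank-1 reconstruction of the channel stack that
suppresses channel-incoherent noise.  The rule runs either directly on the
raw maps (map-level, `K = 1`) or inside an IFCNN-style
extract-select-reconstruct convolutional network (CONV1 7x7 and CONV2 3x3
shared across inputs, CONV3 3x3 tuning, CONV4 1x1 to a 3-channel output).

The fused map is thresholded at `tau` (default 0.5); pixels below it are
masked to black.  The surviving **key region** is resized, flattened and
classified with an SVM.  Fusion quality is scored by spatial frequency (SF)
and average gradient (AG); a seven-method augmentation protocol
(flip, brightness/contrast, shift, scale, rotation, blur, sharpen — each
with fixed probability and parameter ranges) balances unbalanced classes.

No external dataset or pretrained weights are required: a synthetic fixture
generator builds textured elliptical "insects" whose class marking no
single view fully observes, which makes the benefit of fusion a designed,
measurable property.

## Worked example

```
$ python examples/key_region_classification.py
  cnn: acc  45.0  F1  46.0  rec  45.0  pre  48.7
  vit: acc  61.7  F1  60.2  rec  61.7  pre  59.7
 swin: acc  46.7  F1  47.2  rec  46.7  pre  48.6
fused: acc  73.3  F1  72.6  rec  73.3  pre  73.2
(n = 300 images, config c044832b35958873)
```

Each row is the held-out accuracy/F1/recall/precision (in percent) of an
SVM trained on key regions extracted from that view's importance maps, on
3 synthetic classes x 100 images.  Single views cap out well below the
fused view because each one misses two of the three class-marking
positions; fusing the complementary maps recovers the whole insect and
lifts accuracy by ~12-28 points.

Other examples: `gradcam_basics.py` (backbone contracts and the patch
transformation), `fuse_views.py` (selection rule + SF/AG vs plain
averaging), `augmentation_protocol.py` (plan sampling and balancing),
`robustness_to_rotation.py` (stability of fused maps under augmentation).
A thin CLI mirrors the library: `camfuse synth | cam | fuse | extract |
augment | metrics | ablate | run | robustness`.

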