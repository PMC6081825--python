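# nucseg

Nuclear instance segmentation for H&E histology tiles with fused
encoder-decoder networks, implemented end to end on CPU:

- **`nucseg.synth`** — seeded synthetic H&E scenes: overlapping rotated
  elliptical nuclei (hyperchromatic and vesicular phenotypes) rendered
  through a two-stain Beer–Lambert model, with instance ground truth and
  exact touching-pair annotations. The only data source used by the
  tests.
- **`nucseg.stains`** — optical-density color deconvolution with the
  standard published H&E stain vectors; the hematoxylin channel
  (min-max rescaled) is the default single-channel network input.
- **`nucseg.networks` / `nucseg.nn`** — a self-contained numpy
  implementation (forward + hand-written backward, verified against
  finite differences) of two encoder-decoder families: symmetric
  networks with 3–10 encoder/decoder blocks (max-unpooling driven by
  encoder pooling indices, feature plan 32/64/128), and an asymmetric
  bottleneck network mixing normal, dilated, and factorized 5×1/1×5
  convolutions with a deliberately shallower decoder. Also a multitask
  variant (shared trunk, region + boundary heads).
- **`nucseg.training`** — Adam (lr 5e-4, L2 2e-4, batch 4), per-pixel
  cross entropy, boundary targets computed from label masks, two-stage
  fusion training (region and boundary nets trained independently, then
  a third net trained on their stacked probability outputs), and
  multitask training.
- **`nucseg.postprocess`** — threshold + marker-controlled watershed on
  the distance transform (h-maxima markers) to split touching nuclei.
- **`nucseg.evaluation`** — object-level precision/recall/F1 with
  strict IoU > 0.5 one-to-one matching, pixel standard error, and the
  touching-pair separation assay.
- **`nucseg.cli`** — `nucseg synth | train | predict | evaluate`.

No GPU or deep-learning framework is required; everything runs on
numpy/scipy/scikit-image.

## CLI walkthrough

```bash
# 1. write a config
python - <<'EOF'
from nucseg.config import PipelineConfig
PipelineConfig().to_yaml("config.yaml")
EOF

# 2. generate synthetic scenes (PNG image + 16-bit PNG mask + JSON sidecar)
nucseg synth --config config.yaml --n-scenes 16 --seed 0

# 3. train region, boundary and fusion networks (3 checkpoints + loss CSVs)
nucseg train --config config.yaml --scenes out/scenes

# 4. segment a tile (32-bit probability TIFF + 16-bit label PNG)
nucseg predict --config config.yaml --region out/region.npz \
    --boundary out/boundary.npz --fusion out/fusion.npz \
    --image out/scenes/scene_0000_image.png

# 5. object-level metrics between two directories of label masks
nucseg evaluate --pred out --gt out/scenes --out metrics.csv
```

Non-divisible tile sizes are reflect-padded internally and cropped back.
All commands are deterministic given identical inputs and seeds.

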