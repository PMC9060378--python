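# singanseg

Single-image GAN synthesis of medical images **jointly with their
segmentation masks**, plus a style-transfer refinement step and the
Fréchet-distance evaluation machinery (FID / per-image SIFID) and
mask-distribution statistics used to assess the synthetic data.

The pipeline has two steps:

1. **Train** a pyramid of per-scale generator/critic pairs (WGAN-GP +
   reconstruction loss) on *one* four-channel sample — an RGB image
   stacked with its binary mask — then draw any number of random
   image+mask samples from the trained checkpoint. Injecting fresh noise
   from the coarsest scale (`start_scale 0`) maximizes diversity.
2. **Refine** each generated RGB image by neural style transfer against
   the real image (content = generated, style = real; default
   content:style ratio 1:1000, 1000 L-BFGS steps). The mask channel is
   never touched by refinement.

Because no deep-learning framework (and no pretrained weights) is
available in the target environment, the networks run on a small
reverse-mode autodiff engine built on numpy (`singanseg/_autodiff.py`),
including the double backprop needed by the gradient penalty. Pretrained
VGG/Inception feature backends are stubbed with informative errors;
seeded random-weight CNN backends (`deterministic-test`) provide the same
interfaces fully offline and are what the test suite uses.

## CLI

```sh
singanseg fixtures --n 10 --size 64 --seed 1 --out data/          # toy lesion dataset
singanseg train --image data/images/toy_0000.png --mask data/masks/toy_0000.png \
    --out run/ --epochs-per-scale 2000 --seed 0
singanseg generate --ckpt run/checkpoint --n 10 --start-scale 0 --seed 0 --out run/gen
singanseg diversity --masks run/gen --out-mean mean.png --out-sd sd.png
singanseg style-transfer --content run/gen/gen_0.png --style data/images/toy_0000.png \
    --ratio 1000 --steps 1000 --out refined.png
singanseg eval fid --real data/images --fake run/gen
singanseg eval sifid --real data/images --fake run/gen
singanseg eval mask-stats --masks data/masks --bin-width 5 --out hist.csv
singanseg pipeline --image IMG --mask MASK --out run/ [--config cfg.yaml] [--skip-style-transfer]
```

`pipeline` runs train → generate → diversity maps → style transfer and
writes a `manifest.json` (full merged config + seeds + versions), per-scale
loss CSVs, and all sample/refined images. Config precedence is
defaults < YAML file < flags; unknown keys are rejected.

Defaults mirror the published setup: 2,000 epochs per scale, pyramid
scale factor 0.75 with min/max sizes 25/250 (a capped 250-pixel image
spans scales 0–9), 10 samples per image, style ratio 1:1000 with 1,000
steps. Smoke-scale configs (64 px, 3 scales, 150 epochs, 8 base
channels) train in ~2 minutes on one CPU.

## Layout

- `singanseg/io_types.py` — four-channel samples, normalization, pyramids, PNG I/O
- `singanseg/model_core.py` — per-scale GAN, losses, training loop, checkpoints
- `singanseg/sampling.py` — sample generation, mask binarization, diversity maps
- `singanseg/style_transfer.py` — Gram/content/style losses, L-BFGS refinement
- `singanseg/metrics.py` — Fréchet distance, FID, SIFID, mask statistics
- `singanseg/fixtures.py` — procedural lesion-like toy data
- `singanseg/cli.py` — `singanseg` command-line entry point
- `singanseg/_autodiff.py`, `singanseg/_nn.py` — numpy autodiff engine and layers
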