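# vesselseg

Automatic segmentation of blood vessels in retinal fundus photographs with a
**butterfly fully-convolutional network (BFCN)** — an encoder–decoder built
around multiscale dilated convolutions, channel recalibration, and gated skip
connections — plus the surrounding pipeline: contrast-enhancement
preprocessing, patch-based training and sliding-window inference, Laplacian
sharpening of the predicted probability map, and a pixel-classification
evaluation suite. A synthetic vascular-phantom generator makes every stage
testable end-to-end without downloading DRIVE/STARE/CHASE.

The package is aimed at researchers in retinal image analysis who want a
transparent, dependency-light reference implementation: the network and its
gradients are written directly in NumPy, so every block can be inspected,
unit-tested against loop oracles, and run anywhere.

## The method

**Preprocessing.** Vessels show the best contrast against the retinal
background in the green channel. The input image is reduced to a single
enhanced grayscale plane by stacking (1) the green channel, (2) its CLAHE
equalization, and (3) its gamma transform, then converting the stack to
grayscale and rescaling to [0, 1].

**Network.** Let a dilated convolution have kernel size k and expansion
rate r; its effective kernel side is

    K = k + (k − 1)(r − 1)

so a 3×3 kernel at rate 2 sees a 5×5 window with only 9 weights. Each
encoder level applies a *multiscale information extraction* (MSIE) block:
four parallel dilated 3×3 convolutions with distinct rates (default
{1, 2, 4, 8}), a 1×1 branch for the current scale, concatenation, a 1×1
fusion, and a squeeze-and-excite recalibration

    R = G(X),  R″ = σ(F(R)),  U = X ⊙ R″

where G is global average pooling and F a two-layer 1×1 bottleneck. Skip
connections pass through a *transfer layer*: a channel gate
α = σ(W₁·maxpool(X) + W₂·meanpool(X)) followed by a spatial gate
β = σ(w₃·chanmax(αX) + w₄·chanmean(αX)); the gated map is projected by a
fifth 1×1 convolution. Downscaled copies of the input (an image pyramid)
are fused into every encoder level. The decoder upsamples ×2 per level by
transposed convolution, concatenates the gated skip, refines with two 3×3
convolutions, and ends in a 1×1 convolution + sigmoid giving per-pixel
vessel probability.

**Training / inference.** Pixelwise binary cross-entropy, Adam
(lr 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) with plateau learning-rate decay;
random 128×128 patches for training, a 128×128 sliding window with stride 5
and overlap averaging at test time (window/stride configurable).

**Postprocessing.** The probability map is sharpened with the abs/10
transform of the extended Laplacian template (centre 0.8, neighbours 0.1),
which strengthens the continuity of broken small vessels, then thresholded
(e.g. 0.6 on DRIVE-like data, 0.5 on phantoms). Sensitivity, specificity,
accuracy, precision, F-measure and ROC-AUC are computed inside the
field-of-view mask.

## Worked example

A desk-scale run on synthetic phantoms (depth-3 network, 8 base channels,
200 patches of 64×64, 20 epochs, a few minutes on one CPU):

```python
import vesselseg as vs

pairs = []
for seed in range(4):
    ph = vs.generate_phantom(vs.PhantomSpec(seed=seed))
    enhanced = vs.preprocess(ph.image)
    pairs += vs.sample_training_patches(enhanced.pixels, ph.truth,
                                        50, size=64, seed=seed, fov=ph.fov)

result = vs.train(vs.ModelConfig(depth=3, base_channels=8, seed=0),
                  vs.TrainConfig(epochs=20, batch=16, seed=0), pairs)

ph = vs.generate_phantom(vs.PhantomSpec(seed=100))          # held out
prob = vs.predict_image(result.model, vs.preprocess(ph.image),
                        window=64, stride=32)
mask = vs.binarize(vs.sharpen(prob, "abs_template"), threshold=0.5)
report = vs.metrics(vs.confusion(mask.values, ph.truth, ph.fov))
auc, _ = vs.roc_auc(prob, ph.truth, ph.fov)
```

This prints (see `tests/conftest.py` for the identical configuration):

```
loss: epoch 0 = 2348.4, epoch 19 = 485.4
sensitivity = 0.839
specificity = 0.978
accuracy    = 0.962
F-measure   = 0.837
AUC         = 0.984
```

The training loss falls by a factor ~5 over 20 epochs and the tiny model
recovers the phantom vasculature with F ≈ 0.84 inside the FOV; sharpening
bridges rendered vessel breaks (see `tests/test_acceptance.py`).

The same pipeline is available from the shell:

```bash
vesselseg synth --n 20 --out data/
vesselseg train --config train.yaml --data data/ --out model.ckpt
vesselseg predict --model model.ckpt --in data/images/01.png --out prob.png
vesselseg postprocess --in prob.png --out seg.png --threshold 0.5
vesselseg evaluate --pred preds/ --truth data/labels --fov data/masks
```

## Layout

- `src/vesselseg/nn.py` — NumPy reverse-mode autodiff (conv2d with
  dilation, transposed conv, pooling, gates, Adam)
- `src/vesselseg/preprocessing.py` — green channel, CLAHE, gamma, stacking
- `src/vesselseg/model.py` — MSIE blocks, transfer layers, decoder, BFCN
- `src/vesselseg/patching.py` — patch sampling, sliding window, reassembly
- `src/vesselseg/training.py` — loss, Adam + plateau decay, training loop
- `src/vesselseg/postprocessing.py` — gradient/Laplacian sharpening, thresholds
- `src/vesselseg/evaluation.py` — confusion metrics, ROC/AUC
- `src/vesselseg/synthetic.py` — vascular phantom generator
- `docs/methods.md` — modelling assumptions, defaults, and limitations
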