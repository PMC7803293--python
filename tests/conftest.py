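"""Shared fixtures.

The session-scoped ``trained_pipeline`` fixture runs the one CPU-scale
training of the suite (a depth-3, 8-channel model on 200 phantom patches)
and is shared between the end-to-end recovery test and the
difficulty-monotonicity test so the cost is paid once.
"""

import numpy as np
import pytest

import vesselseg as vs

PHANTOM_TRAIN_SEEDS = (0, 1, 2, 3)
HELDOUT_SEED = 100


@pytest.fixture(scope="session")
def default_phantom():
    return vs.generate_phantom(vs.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def trained_pipeline():
    """Train a small BFCN on synthetic patches; return model and history."""
    pairs = []
    for s in PHANTOM_TRAIN_SEEDS:
        ph = vs.generate_phantom(vs.PhantomSpec(seed=s))
        enh = vs.preprocess(ph.image)
        pairs += vs.sample_training_patches(
            enh.pixels, ph.truth, 50, size=64, seed=s, fov=ph.fov)
    model_cfg = vs.ModelConfig(depth=3, base_channels=8, seed=0)
    train_cfg = vs.TrainConfig(epochs=20, batch=16, seed=0,
                               patches_per_set=len(pairs), patch_size=64)
    result = vs.train(model_cfg, train_cfg, pairs)
    return result


def heldout_f_measure(model, spec=None, threshold=0.5):
    """F-measure of ``model`` on a held-out phantom, inside the FOV."""
    spec = spec or vs.PhantomSpec(seed=HELDOUT_SEED)
    ph = vs.generate_phantom(spec)
    enh = vs.preprocess(ph.image)
    prob = vs.predict_image(model, enh, window=64, stride=32)
    mask = vs.binarize(prob, threshold)
    rep = vs.metrics(vs.confusion(mask.values, ph.truth, ph.fov))
    return rep.f_measure
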