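"""Shared fixtures: synthetic images and one desk-scale trained classifier.

The smoke-trained network is expensive (a few dozen seconds), so it is
trained once per session and shared by the training, Grad-CAM and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import garlicnet as gn

#: Desk-scale training conditions used across the suite: 60 images per class
#: at 64 px, reduced-width backbone (8-16-32-64 channels), 5 epochs of SGD
#: with the standard batch size 8 and base learning rate 0.01.
SMOKE = {
    "n_per_class": 60,
    "image_size": 64,
    "data_seed": 7,
    "train_seed": 0,
    "stage_channels": (8, 16, 32, 64),
    "epochs": 5,
}


@pytest.fixture(scope="session")
def fixture_data():
    """(dataset, ground truths) of 180 synthetic garlic images, 60/class."""
    return gn.generate_dataset(SMOKE["n_per_class"],
                               image_size=SMOKE["image_size"],
                               seed=SMOKE["data_seed"])


@pytest.fixture(scope="session")
def smoke_run(fixture_data):
    """Train the reduced-width full classifier once on the synthetic set.

    Returns a dict with the trained network, split plan, training history
    and the underlying dataset/ground truths.
    """
    ds, truths = fixture_data
    seed = SMOKE["train_seed"]
    plan = gn.make_split(ds, seed=seed)
    net = gn.build_model("dh_garlicnet", num_classes=3, seed=seed,
                         stage_channels=SMOKE["stage_channels"])
    train_aug = gn.augment_dataset(ds.subset(plan.train_idx), factor=3,
                                   seed=seed)
    cfg = gn.TrainConfig(input_size=SMOKE["image_size"], batch_size=8,
                         lr=0.01, epochs=SMOKE["epochs"], seed=seed)
    net, history = gn.train(net, train_aug, ds.subset(plan.val_idx), cfg)
    return {
        "net": net,
        "plan": plan,
        "history": history,
        "dataset": ds,
        "truths": truths,
        "config": cfg,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
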