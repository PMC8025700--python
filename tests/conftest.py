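"""Shared fixtures: small random clouds and the desk-scale trained model.

The expensive fixture (`light_training`) trains the half-width network on
40 synthetic plants for 30 epochs, three seeds, at 512 points per cloud —
the package's reference desk-scale experiment — and is session-scoped so
the segmentation-recovery, counting-pipeline and resolution-robustness
tests all share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from patternnet.network import NetworkConfig
from patternnet.pointcloud_io import LabeledCloud, resample_to_count
from patternnet.synthetic_plants import generate_dataset
from patternnet.train_infer import TrainConfig, fit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    coords = rng.normal(size=(64, 3))
    labels = rng.integers(1, 3, 64)
    return LabeledCloud(coords, labels, "random64")


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Small architecture for fast functional tests."""
    return NetworkConfig(L=2, K=4, lp_widths=(8, 8), global_mlp_widths=(16,),
                         decoder_widths=(12,), num_classes=2, drop_rate=0.5)


@pytest.fixture(scope="session")
def light_training():
    """Light config trained on 40 synthetic plants, 3 seeds, M=512."""
    plants, _ = generate_dataset(50, {"n_ears": (0, 8), "n_points": 1200}, seed=123)
    clouds = [resample_to_count(c, 512, 7 + i) for i, (c, _) in enumerate(plants)]
    train_set, val_set = clouds[:40], clouds[40:]
    net_cfg = NetworkConfig.light(L=4, K=8)
    runs = []
    for seed in (11, 12, 13):
        params, history = fit(train_set, val_set, net_cfg,
                              TrainConfig(epochs=30, seed=seed))
        runs.append({"seed": seed, "params": params, "history": history})
    return {"net_cfg": net_cfg, "runs": runs,
            "train_set": train_set, "val_set": val_set}
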