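"""Shared fixtures: all data is generated programmatically at test time.

The heavyweight session fixtures (trained toy models) reflect the
desk-scale study conditions: 32x32x32 volumes, LNCC window 5,
learning rate 1e-3, 150 steps per scale, master seed 0.
"""

import dataclasses

import numpy as np
import pytest

import proreg as pr
from proreg.losses import LossWeights
from proreg.progressive import IterationSchedule, TrainConfig, train

DESK_WEIGHTS = dict(lambda_smooth=1.0, lncc_window=5)
DESK_LR = 1e-3


def desk_train_config(steps: int, n_train: int, n_test: int,
                      seed: int = 0) -> TrainConfig:
    return TrainConfig(learning_rate=DESK_LR, steps=steps, seed=seed,
                       weights=LossWeights(**DESK_WEIGHTS),
                       schedule=IterationSchedule(n_train, n_test))


def zeroed_backbone(config=None) -> pr.UNetBackbone:
    """A backbone whose every parameter is zero: predicts the zero flow."""
    net = pr.UNetBackbone(config or pr.BackboneConfig(), seed=0)
    for p in net.params.values():
        p.value[...] = 0.0
    return net


SMALL_BACKBONE = pr.BackboneConfig(levels=3, enc_channels=(16, 32, 32),
                                   dec_channels=(32, 32, 16, 16))


def perturbed_backbone(seed: int = 0, head_std: float = 0.05,
                       config=None) -> pr.UNetBackbone:
    """An untrained backbone with a non-degenerate head, so predicted
    flows are small but nonzero — useful for plumbing tests."""
    net = pr.UNetBackbone(config or pr.BackboneConfig(), seed=seed)
    rng = np.random.default_rng(seed + 1)
    w = net.params["head.w"]
    w.value = rng.normal(0.0, head_std, size=w.value.shape).astype(np.float32)
    return net


@pytest.fixture(scope="session")
def large_preset():
    """32^3 phantom spec + deformation calibrated to the large-deformation
    regime.  Calibration targets the interior of the band (Dice around
    0.5) so that pairs sampled with fresh field seeds still fall below
    the 0.6 large-deformation threshold on average."""
    pspec = pr.PhantomSpec(shape=(32, 32, 32), seed=0)
    dspec = pr.calibrate_severity(pspec, (0.0, 0.5), which="smallest",
                                  seed=100, n_fields=4)
    return pspec, dspec


@pytest.fixture(scope="session")
def toy_dataset(large_preset):
    """8 training + 4 held-out 32^3 pairs at the large-deformation preset."""
    pspec, dspec = large_preset
    train_pairs = [pr.make_pair(dataclasses.replace(pspec, seed=i),
                                dataclasses.replace(dspec, seed=200 + i))
                   for i in range(8)]
    test_pairs = [pr.make_pair(dataclasses.replace(pspec, seed=50 + i),
                               dataclasses.replace(dspec, seed=300 + i))
                  for i in range(4)]
    return train_pairs, test_pairs


@pytest.fixture(scope="session")
def trained_two_scale(toy_dataset):
    """Two-scale cascade trained on the toy dataset (150 + 150 steps)."""
    train_pairs, _ = toy_dataset
    cfg_low = desk_train_config(steps=150, n_train=3, n_test=3)
    cfg_orig = desk_train_config(steps=150, n_train=3, n_test=2)
    low, orig, hist_low, hist_orig = pr.train_hierarchical(
        train_pairs, cfg_low, cfg_orig)
    return dict(low=low, orig=orig, cfg_low=cfg_low, cfg_orig=cfg_orig,
                hist_low=hist_low, hist_orig=hist_orig)


@pytest.fixture(scope="session")
def sharp_toy():
    """Single-scale toy model trained on 16^3 sharp-edged phantoms, plus a
    held-out sharp pair — the information-loss comparison fixture."""
    pspec = pr.PhantomSpec(shape=(16, 16, 16), smoothing_sigma=0.0, seed=0)
    dspec = pr.DeformationSpec(amplitude=2.5, seed=7)
    pairs = [pr.make_pair(dataclasses.replace(pspec, seed=i),
                          dataclasses.replace(dspec, seed=40 + i))
             for i in range(4)]
    net = pr.UNetBackbone(pr.BackboneConfig(), seed=0)
    train(pairs, net, desk_train_config(steps=60, n_train=3, n_test=3))
    held_out = pr.make_pair(dataclasses.replace(pspec, seed=9),
                            dataclasses.replace(dspec, seed=77))
    return net, held_out
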