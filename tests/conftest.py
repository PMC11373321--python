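"""Shared fixtures: tiny SWC files, random-tree factories, and one small
self-distillation study reused by the evaluation tests."""

from __future__ import annotations

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

import morphembed as me
from morphembed.augment import AugmentationConfig
from morphembed.pretrain import PretrainConfig, pretrain

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def class_specs() -> dict[str, me.NeuronClassSpec]:
    return me.example_class_specs()


@pytest.fixture(scope="session")
def small_tree_factory(class_specs):
    """Random small trees (20-60 nodes) cycling over the class presets."""
    presets = list(class_specs.values())

    def make(seed: int) -> me.NeuronTree:
        spec = presets[seed % len(presets)].with_node_range(20, 60)
        return me.generate_neuron(spec, seed)

    return make


@pytest.fixture(scope="session")
def y_tree(data_dir) -> me.NeuronTree:
    return me.read_swc(data_dir / "y_neuron.swc")


@pytest.fixture(scope="session")
def study(class_specs):
    """A complete small pre-training study on two distinct synthetic classes.

    200 neurons (100 per class), axon-pruned, encoded by a 2-layer
    64-dimensional graph transformer pre-trained for 300 steps.  Shared
    across evaluation tests because the run is the expensive part.
    """
    specs = [class_specs["tufted"], class_specs["sparse"]]
    trees, labels = me.generate_dataset(specs, n_per_class=100, seed=11)
    pruned = [me.prune_axon(me.center_tree(t)) for t in trees]
    enc_cfg = me.EncoderConfig(n_layers=2, d_model=64, n_heads=4, d_k=16,
                               n_eigvecs=8, mlp_hidden=128, seed=0)
    cfg = PretrainConfig(steps=300, batch_size=8, seed=5)
    state, log = pretrain(pruned, cfg, enc_cfg, AugmentationConfig(seed=7))
    return SimpleNamespace(trees=trees, pruned=pruned, labels=labels,
                           enc_cfg=enc_cfg, pretrain_cfg=cfg, state=state,
                           log=log, ckpt=state.encoder_checkpoint("teacher"))
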