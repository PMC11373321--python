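"""Seeded synthetic neuron generator.

Neurons are grown by recursive stochastic elongation/bifurcation: stems
leave the soma in random directions and tips either elongate (direction
jittered by a Gaussian) or bifurcate with a class-specific probability,
up to a branch-order cap.  The generator hits its target node count
exactly, is fully deterministic under a seed, and the class presets below
produce neurons with well-separated morphometric signatures, so every
downstream module is testable without downloading reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .swc import AXON, BASAL_DENDRITE, NeuronTree, SOMA, SwcNode


@dataclass(frozen=True)
class NeuronClassSpec:
    """Growth statistics for one synthetic morphological class."""

    name: str
    n_stems: tuple[int, int] = (3, 6)          # inclusive range
    branch_prob: float = 0.2                   # per elongation step
    segment_length: tuple[float, float] = (10.0, 2.0)  # mean, sd in µm
    tortuosity: float = 0.15                   # direction jitter sd (radians)
    max_depth: int = 6                         # branch-order cap
    axon_fraction: float = 0.3                 # probability a stem is axon-typed
    root_radius: float = 6.0                   # µm
    radius_decay: float = 0.92                 # per-step multiplicative taper
    node_range: tuple[int, int] = (150, 250)   # inclusive target node count

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if not 0.0 <= self.axon_fraction <= 1.0:
            raise ValueError("axon_fraction must be in [0, 1]")
        if self.segment_length[0] <= 0:
            raise ValueError("segment_length mean must be positive")
        if self.node_range[0] < 2 or self.node_range[1] < self.node_range[0]:
            raise ValueError("node_range must be an increasing range >= 2")

    def with_node_range(self, lo: int, hi: int) -> "NeuronClassSpec":
        return replace(self, node_range=(lo, hi))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _jitter(direction: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    # small-angle parameterization: add isotropic noise of magnitude ~ sd
    return _unit(direction + rng.normal(0.0, sd, size=3))


def generate_neuron(spec: NeuronClassSpec, seed: int) -> NeuronTree:
    """Grow one neuron under ``spec``; same seed, same tree."""
    rng = np.random.default_rng(seed)
    target = int(rng.integers(spec.node_range[0], spec.node_range[1] + 1))
    n_stems = int(rng.integers(spec.n_stems[0], spec.n_stems[1] + 1))
    n_stems = max(1, min(n_stems, target - 1))
    mean_len, sd_len = spec.segment_length

    nodes = [SwcNode(1, SOMA, 0.0, 0.0, 0.0, spec.root_radius, -1)]
    # active tips: (node array-position, direction, branch order, type, radius)
    tips: list[tuple[int, np.ndarray, int, int, float]] = []

    def grow(parent_pos: int, direction: np.ndarray, order: int,
             type_code: int, radius: float) -> int:
        parent = nodes[parent_pos]
        length = max(0.5, rng.normal(mean_len, sd_len))
        x, y, z = (np.array([parent.x, parent.y, parent.z])
                   + direction * length)
        idx = len(nodes) + 1
        nodes.append(SwcNode(idx, type_code, float(x), float(y), float(z),
                             max(0.05, radius), parent.index))
        return len(nodes) - 1

    for _ in range(n_stems):
        direction = _unit(rng.normal(size=3))
        type_code = AXON if rng.random() < spec.axon_fraction else BASAL_DENDRITE
        radius = spec.root_radius * spec.radius_decay
        pos = grow(0, direction, 0, type_code, radius)
        tips.append((pos, direction, 0, type_code, radius))
        if len(nodes) == target:
            break

    while len(nodes) < target:
        t = int(rng.integers(len(tips)))
        pos, direction, order, type_code, radius = tips.pop(t)
        can_branch = order < spec.max_depth and len(nodes) + 2 <= target
        if can_branch and rng.random() < spec.branch_prob:
            for _ in range(2):
                d = _jitter(direction, spec.tortuosity + 0.4, rng)
                r = radius * spec.radius_decay
                p = grow(pos, d, order + 1, type_code, r)
                tips.append((p, d, order + 1, type_code, r))
        else:
            d = _jitter(direction, spec.tortuosity, rng)
            r = radius * spec.radius_decay
            p = grow(pos, d, order, type_code, r)
            tips.append((p, d, order, type_code, r))

    return NeuronTree(nodes, name=f"{spec.name}-{seed}")


def generate_dataset(specs: list[NeuronClassSpec], n_per_class: int,
                     seed: int) -> tuple[list[NeuronTree], list[str]]:
    """``n_per_class`` neurons per spec with aligned class labels."""
    ss = np.random.SeedSequence(seed)
    trees: list[NeuronTree] = []
    labels: list[str] = []
    for spec, spec_ss in zip(specs, ss.spawn(len(specs))):
        for i, child in enumerate(spec_ss.spawn(n_per_class)):
            t = generate_neuron(spec, int(child.generate_state(1)[0] % 2**31))
            t.name = f"{spec.name}_{i:04d}"
            trees.append(t)
            labels.append(spec.name)
    return trees, labels


def example_class_specs() -> dict[str, NeuronClassSpec]:
    """Three morphologically distinct presets used throughout the test bench.

    ``tufted`` is a densely branching short-segment cell, ``sparse`` a
    sparsely branching interneuron-like cell, ``projecting`` a long-range
    cell with few, long, straight neurites.
    """
    return {
        "tufted": NeuronClassSpec(
            name="tufted", n_stems=(4, 7), branch_prob=0.40,
            segment_length=(6.0, 1.5), tortuosity=0.20, max_depth=8,
            axon_fraction=0.3, root_radius=7.0),
        "sparse": NeuronClassSpec(
            name="sparse", n_stems=(2, 4), branch_prob=0.06,
            segment_length=(18.0, 4.0), tortuosity=0.12, max_depth=5,
            axon_fraction=0.3, root_radius=5.0),
        "projecting": NeuronClassSpec(
            name="projecting", n_stems=(1, 2), branch_prob=0.18,
            segment_length=(35.0, 8.0), tortuosity=0.05, max_depth=6,
            axon_fraction=0.5, root_radius=4.0),
    }
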