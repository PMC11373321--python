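"""Connectivity-preserving morphology augmentations.

Shape augmentations (coordinate noise, random 3-D rotation) leave the node
and edge sets untouched; topology augmentations (terminal-branch deletion,
subgraph sampling) shrink the tree but always return one connected,
acyclic tree with the root intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .preprocess import is_centered, relink_to_ancestors
from .swc import NeuronTree


@dataclass
class AugmentationConfig:
    """Magnitudes of the four augmentations, plus the seed all draws derive from."""

    shift_sigma: float = 1.0          # µm, per-axis Gaussian sd
    rotate: bool = True
    branch_delete_prob: float = 0.2   # per terminal branch
    subgraph_fraction: float = 0.8    # fraction of nodes retained
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_sigma < 0:
            raise ValueError("shift_sigma must be >= 0")
        if not 0.0 <= self.branch_delete_prob <= 1.0:
            raise ValueError("branch_delete_prob must be in [0, 1]")
        if not 0.0 < self.subgraph_fraction <= 1.0:
            raise ValueError("subgraph_fraction must be in (0, 1]")


def shift(tree: NeuronTree, sigma: float, seed: int) -> NeuronTree:
    """Perturb every coordinate by independent N(0, sigma^2) noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return tree
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(tree), 3))
    return tree.with_nodes(
        [n.moved_to(n.x + d[0], n.y + d[1], n.z + d[2])
         for n, d in zip(tree.nodes, noise)])


def random_rotation(seed: int) -> np.ndarray:
    """A rotation about an axis uniform on the unit sphere, angle U[0, 2pi)."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def rotate(tree: NeuronTree, seed: int) -> NeuronTree:
    """Apply one random rigid rotation about the origin (the root)."""
    if not is_centered(tree):
        raise ValueError("rotate requires a centered tree (root at origin)")
    R = random_rotation(seed)
    coords = np.array([[n.x, n.y, n.z] for n in tree.nodes])
    rotated = coords @ R.T
    return tree.with_nodes(
        [n.moved_to(*xyz) for n, xyz in zip(tree.nodes, rotated)])


def terminal_branches(tree: NeuronTree) -> list[list[int]]:
    """Maximal leaf-ending segments below a branch point (or the root).

    One branch per leaf: the leaf plus its chain of single-child ancestors,
    stopping (exclusive) at the first node with >= 2 children or at the root.
    Branches of distinct leaves are disjoint.
    """
    branches = []
    for leaf in sorted(tree.leaf_indices()):
        branch = [leaf]
        for anc in tree.ancestors(leaf):
            if anc == tree.root_index or len(tree.children(anc)) >= 2:
                break
            branch.append(anc)
        branches.append(branch)
    return branches


def delete_branches(tree: NeuronTree, prob: float, seed: int) -> NeuronTree:
    """Independently delete each terminal branch with probability ``prob``."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    if prob == 0 or len(tree) == 1:
        return tree
    rng = np.random.default_rng(seed)
    drop: set[int] = set()
    for branch in terminal_branches(tree):
        if rng.random() < prob:
            drop.update(branch)
    if not drop:
        return tree
    keep = {n.index for n in tree.nodes} - drop
    return relink_to_ancestors(tree, keep)


def sample_subgraph(tree: NeuronTree, fraction: float, seed: int) -> NeuronTree:
    """Keep ceil(fraction * n) nodes (always the root), re-linked to ancestors."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * len(tree))
    if n_keep >= len(tree):
        return tree
    rng = np.random.default_rng(seed)
    others = sorted(n.index for n in tree.nodes if n.index != tree.root_index)
    chosen = rng.choice(len(others), size=n_keep - 1, replace=False)
    keep = {tree.root_index} | {others[i] for i in chosen}
    return relink_to_ancestors(tree, keep)


def augment(tree: NeuronTree, config: AugmentationConfig) -> NeuronTree:
    """Topology then shape: delete branches, sample subgraph, rotate, shift.

    All randomness is derived from ``config.seed`` via a split sequence, so
    the same configuration always produces the same tree.
    """
    s_del, s_sub, s_rot, s_shift = (
        int(ss.generate_state(1)[0]) for ss in
        np.random.SeedSequence(config.seed).spawn(4))
    out = delete_branches(tree, config.branch_delete_prob, s_del)
    out = sample_subgraph(out, config.subgraph_fraction, s_sub)
    if config.rotate:
        out = rotate(out, s_rot)
    out = shift(out, config.shift_sigma, s_shift)
    return out
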