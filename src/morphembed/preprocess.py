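"""Preprocessing: centering, axon pruning, node downsampling, featurization.

The model consumes a :class:`FeatureGraph` — a node-feature table plus a
symmetric binary adjacency matrix — built from a centered neuron tree.
Per-node features are the centered coordinates (µm), the radius (µm) and a
five-way one-hot type encoding {soma, axon, basal, apical, other}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .swc import AXON, APICAL_DENDRITE, BASAL_DENDRITE, NeuronTree, SOMA, SwcNode

FEATURE_DIM = 9  # x, y, z, radius, one-hot(5)

_TYPE_SLOT = {SOMA: 0, AXON: 1, BASAL_DENDRITE: 2, APICAL_DENDRITE: 3}


@dataclass
class FeatureGraph:
    """Model-ready neuron: features, adjacency and original SWC indices.

    Row 0 is the tree root and its centered coordinates are (0, 0, 0).
    """

    n: int
    features: np.ndarray        # (n, FEATURE_DIM)
    adjacency: np.ndarray       # (n, n) symmetric 0/1, zero diagonal
    node_ids: np.ndarray        # (n,) original SWC indices

    def validate(self) -> None:
        assert self.features.shape == (self.n, FEATURE_DIM)
        assert self.adjacency.shape == (self.n, self.n)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")


def center_tree(tree: NeuronTree) -> NeuronTree:
    """Shift all coordinates so the root (usually the soma) sits at the origin."""
    r = tree.root
    if r.x == 0.0 and r.y == 0.0 and r.z == 0.0:
        return tree
    return tree.with_nodes(
        [n.moved_to(n.x - r.x, n.y - r.y, n.z - r.z) for n in tree.nodes])


def is_centered(tree: NeuronTree, tol: float = 1e-9) -> bool:
    r = tree.root
    return abs(r.x) <= tol and abs(r.y) <= tol and abs(r.z) <= tol


def relink_to_ancestors(tree: NeuronTree, keep: set[int]) -> NeuronTree:
    """Restrict ``tree`` to ``keep`` (must contain the root), re-linking each
    survivor to its nearest surviving ancestor.

    Contracting removed chain nodes this way preserves the tree topology of
    the survivors, so the result is always one connected tree.
    """
    if tree.root_index not in keep:
        raise ValueError("the root must be kept")
    new_nodes: list[SwcNode] = []
    for n in tree.nodes:
        if n.index not in keep:
            continue
        if n.parent == -1:
            new_nodes.append(n)
            continue
        parent = next((a for a in tree.ancestors(n.index) if a in keep),
                      None)
        if parent is None:
            raise ValueError(f"node {n.index}: no surviving ancestor")
        new_nodes.append(SwcNode(n.index, n.type_code, n.x, n.y, n.z,
                                 n.radius, parent))
    return tree.with_nodes(new_nodes)


def prune_axon(tree: NeuronTree) -> NeuronTree:
    """Remove non-branching axon nodes; keep axon branch points.

    An axon node (type 2) with undirected degree <= 2 lies on a sampling
    chain or is a terminal tip and carries little topology, so it is
    removed; axon branch points (degree >= 3) and all non-axon nodes are
    kept.  Degrees are those of the input tree (one pass).  The root is
    never removed; if everything else is removable the root-only tree is
    returned with a warning.
    """
    root = tree.root_index
    keep = {n.index for n in tree.nodes
            if n.index == root
            or n.type_code != AXON
            or tree.degree(n.index) >= 3}
    if keep == {root} and len(tree) > 1:
        warnings.warn("prune_axon removed every non-root node; "
                      "returning the soma-only tree", stacklevel=2)
    return relink_to_ancestors(tree, keep)


def downsample_nodes(tree: NeuronTree, n_target: int, seed: int) -> NeuronTree:
    """Reduce a tree to exactly ``n_target`` nodes, preserving connectivity.

    The root and all branch points are kept preferentially (non-branching
    nodes carry little topology); the remaining quota is filled by seeded
    uniform sampling.  Removed chain nodes are contracted by re-linking
    survivors to their nearest surviving ancestor.
    """
    if n_target < 2:
        raise ValueError(f"n_target must be >= 2, got {n_target}")
    if len(tree) <= n_target:
        return tree
    rng = np.random.default_rng(seed)
    root = tree.root_index
    branch = sorted(i for i in tree.branch_point_indices() if i != root)
    if 1 + len(branch) > n_target:
        chosen = rng.choice(len(branch), size=n_target - 1, replace=False)
        keep = {root} | {branch[i] for i in chosen}
    else:
        keep = {root} | set(branch)
        others = sorted(n.index for n in tree.nodes if n.index not in keep)
        quota = n_target - len(keep)
        chosen = rng.choice(len(others), size=quota, replace=False)
        keep |= {others[i] for i in chosen}
    return relink_to_ancestors(tree, keep)


def featurize(tree: NeuronTree) -> FeatureGraph:
    """Assemble the model-ready feature graph from a centered tree."""
    if not is_centered(tree):
        raise ValueError(
            "featurize requires a centered tree (root at origin); "
            "call center_tree first")
    order = tree.bfs_order()
    row_of = {idx: r for r, idx in enumerate(order)}
    n = len(order)
    feats = np.zeros((n, FEATURE_DIM))
    adj = np.zeros((n, n))
    for idx in order:
        node = tree.node(idx)
        r = row_of[idx]
        feats[r, 0:3] = (node.x, node.y, node.z)
        feats[r, 3] = node.radius
        feats[r, 4 + _TYPE_SLOT.get(node.type_code, 4)] = 1.0
        if node.parent != -1:
            p = row_of[node.parent]
            adj[r, p] = adj[p, r] = 1.0
    return FeatureGraph(n=n, features=feats, adjacency=adj,
                        node_ids=np.array(order, dtype=np.int64))
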