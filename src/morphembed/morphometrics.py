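"""Hand-crafted morphometric descriptors of a centered neuron tree.

The panel covers the classical single-neuron measurements: total cable
length, bounding extents, stem/branch/tip counts, branch order, maximal
Euclidean and along-tree path distances from the soma, a spherical soma
surface, and the mean diameter.  Extents are assigned depth/height/width
= z/y/x of the centered coordinates (the axis convention is configurable
only by permuting inputs; it is documented, not inferred).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .preprocess import is_centered
from .swc import NeuronTree

#: Column order of the exported table.
FIELDS = [
    "total_length", "depth", "height", "width", "n_stems",
    "n_branch_points", "n_tips", "max_branch_order",
    "max_euclidean_distance", "max_path_distance",
    "soma_surface", "average_diameter",
]


@dataclass
class MorphometricRecord:
    neuron_id: str
    total_length: float
    depth: float
    height: float
    width: float
    n_stems: int
    n_branch_points: int
    n_tips: int
    max_branch_order: int
    max_euclidean_distance: float
    max_path_distance: float
    soma_surface: float
    average_diameter: float


def compute_morphometrics(tree: NeuronTree) -> MorphometricRecord:
    """All descriptors in one root-first traversal of a centered tree."""
    if not is_centered(tree):
        raise ValueError("compute_morphometrics requires a centered tree")
    coords = {n.index: np.array([n.x, n.y, n.z]) for n in tree.nodes}
    root = tree.root_index

    total_length = 0.0
    path_dist = {root: 0.0}
    # branch order counts branch points strictly below the root on the
    # root-to-node path (the soma is not a bifurcation)
    order = {root: 0}
    for idx in tree.bfs_order():
        node = tree.node(idx)
        if node.parent != -1:
            seg = float(np.linalg.norm(coords[idx] - coords[node.parent]))
            total_length += seg
            path_dist[idx] = path_dist[node.parent] + seg
            parent_is_bp = (node.parent != root
                            and len(tree.children(node.parent)) >= 2)
            order[idx] = order[node.parent] + (1 if parent_is_bp else 0)

    xyz = np.array([coords[n.index] for n in tree.nodes])
    extent = xyz.max(axis=0) - xyz.min(axis=0) if len(tree) > 1 else np.zeros(3)
    radii = np.array([n.radius for n in tree.nodes])

    return MorphometricRecord(
        neuron_id=tree.name or str(root),
        total_length=total_length,
        depth=float(extent[2]),
        height=float(extent[1]),
        width=float(extent[0]),
        n_stems=len(tree.children(root)),
        # the soma is not a bifurcation: a multi-stem root is not counted
        n_branch_points=len([i for i in tree.branch_point_indices()
                             if i != root]),
        n_tips=len(tree.leaf_indices()),
        max_branch_order=max(order.values()) if order else 0,
        max_euclidean_distance=float(np.linalg.norm(xyz, axis=1).max()),
        max_path_distance=max(path_dist.values()),
        soma_surface=4.0 * math.pi * tree.root.radius ** 2,
        average_diameter=float(np.mean(2.0 * radii)),
    )


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in records]
    return pd.DataFrame(rows).set_index("neuron_id")[FIELDS]


def log_transform(records: list[MorphometricRecord],
                  fields: list[str] | None = None) -> pd.DataFrame:
    """log(1 + value) per selected field; zero maps to zero, counts allowed."""
    frame = records_to_frame(records)
    fields = list(fields) if fields is not None else FIELDS
    out = frame.copy()
    for f in fields:
        if (frame[f] < 0).any():
            raise ValueError(f"field {f} has negative values")
        out[f] = np.log1p(frame[f].astype(float))
    return out
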