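"""SWC reconstruction I/O and the rooted-tree container.

The SWC format stores one node per line with seven whitespace-separated
fields: index, type code, x, y, z, radius, parent index.  Type codes follow
the usual convention (1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite);
codes outside 1-4 are preserved verbatim.  A neuron is a rooted tree: one
node has parent -1 and every other node points at an existing node.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4


class SwcFormatError(ValueError):
    """Raised when a file does not parse as valid SWC."""


class TreeValidationError(ValueError):
    """Raised when a collection of nodes does not form a valid neuron tree."""


@dataclass(frozen=True)
class SwcNode:
    """One reconstruction point: typed 3-D position with radius and parent link."""

    index: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    def moved_to(self, x: float, y: float, z: float) -> "SwcNode":
        return replace(self, x=x, y=y, z=z)

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class NeuronTree:
    """A neuron reconstruction as a rooted tree of :class:`SwcNode`.

    Invariants (checked at construction unless ``validate=False``):
    exactly one root (parent -1), unique indices, every parent resolves,
    the undirected graph is connected and acyclic, radii are non-negative.
    """

    def __init__(self, nodes: Sequence[SwcNode], name: str | None = None,
                 validate: bool = True) -> None:
        self.nodes: tuple[SwcNode, ...] = tuple(nodes)
        self.name = name
        self._index_map = {n.index: n for n in self.nodes}
        self._children: dict[int, list[int]] = {n.index: [] for n in self.nodes}
        roots = []
        for n in self.nodes:
            if n.parent == -1:
                roots.append(n.index)
            elif n.parent in self._children:
                self._children[n.parent].append(n.index)
        self.root_index: int | None = roots[0] if len(roots) == 1 else None
        self._roots = roots
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, index: int) -> SwcNode:
        return self._index_map[index]

    @property
    def root(self) -> SwcNode:
        if self.root_index is None:
            raise TreeValidationError("tree has no unique root")
        return self._index_map[self.root_index]

    def children(self, index: int) -> list[int]:
        return list(self._children[index])

    def degree(self, index: int) -> int:
        """Undirected degree: number of children plus one for the parent edge."""
        n = self._index_map[index]
        return len(self._children[index]) + (0 if n.parent == -1 else 1)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected parent-child edges as (parent, child) index pairs."""
        return [(n.parent, n.index) for n in self.nodes if n.parent != -1]

    def leaf_indices(self) -> list[int]:
        """Non-root nodes with no children."""
        return [n.index for n in self.nodes
                if not self._children[n.index] and n.parent != -1]

    def branch_point_indices(self) -> list[int]:
        """Nodes with two or more children (the root may qualify)."""
        return [i for i, ch in self._children.items() if len(ch) >= 2]

    def bfs_order(self) -> list[int]:
        """Node indices root-first, parents before children."""
        order = []
        queue = deque([self.root_index])
        while queue:
            i = queue.popleft()
            order.append(i)
            queue.extend(self._children[i])
        return order

    def ancestors(self, index: int) -> Iterator[int]:
        """Walk parent links from ``index`` (exclusive) up to the root."""
        p = self._index_map[index].parent
        while p != -1:
            yield p
            p = self._index_map[p].parent

    def with_nodes(self, nodes: Sequence[SwcNode]) -> "NeuronTree":
        return NeuronTree(nodes, name=self.name)

    # -- validation & equality --------------------------------------------

    def validate(self) -> None:
        if not self.nodes:
            raise TreeValidationError("tree has no nodes")
        if len(self._index_map) != len(self.nodes):
            raise TreeValidationError("duplicate node indices")
        if len(self._roots) != 1:
            raise TreeValidationError(
                f"expected exactly one root (parent -1), found {len(self._roots)}")
        for n in self.nodes:
            if n.radius < 0:
                raise TreeValidationError(f"node {n.index}: negative radius")
            if n.parent != -1 and n.parent not in self._index_map:
                raise TreeValidationError(
                    f"node {n.index}: parent {n.parent} does not exist")
        reached = set(self.bfs_order())
        if len(reached) != len(self.nodes):
            raise TreeValidationError(
                "graph is not a single connected tree rooted at the parent=-1 node")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuronTree):
            return NotImplemented
        a = sorted(self.nodes, key=lambda n: n.index)
        b = sorted(other.nodes, key=lambda n: n.index)
        return a == b

    def __repr__(self) -> str:
        return (f"NeuronTree(name={self.name!r}, n_nodes={len(self.nodes)}, "
                f"root={self.root_index})")


# -- parsing ---------------------------------------------------------------

def _parse_line(line: str, lineno: int) -> SwcNode:
    fields = line.split()
    if len(fields) != 7:
        raise SwcFormatError(
            f"line {lineno}: expected 7 fields, got {len(fields)}")
    try:
        idx, tc = int(fields[0]), int(fields[1])
        x, y, z, r = (float(f) for f in fields[2:6])
        parent = int(fields[6])
    except ValueError as exc:
        raise SwcFormatError(f"line {lineno}: {exc}") from None
    if r < 0:
        raise SwcFormatError(f"line {lineno}: negative radius {r}")
    return SwcNode(idx, tc, x, y, z, r, parent)


def read_swc(path: str | Path, strict: bool = False) -> NeuronTree:
    """Parse an SWC file into a :class:`NeuronTree`.

    The parse is two-pass (collect nodes, then resolve parents) so
    child-before-parent line order is legal.  Comment lines (leading ``#``)
    and blank lines are skipped; file node order is preserved.  In strict
    mode any multi-root or disconnected file is an error; otherwise the
    largest component rooted at a parent=-1 node is kept with a warning.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    lineno_of: dict[int, int] = {}
    with path.open("r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            node = _parse_line(line, lineno)
            if node.index in lineno_of:
                raise SwcFormatError(
                    f"line {lineno}: duplicate index {node.index} "
                    f"(first seen on line {lineno_of[node.index]})")
            lineno_of[node.index] = lineno
            nodes.append(node)
    if not nodes:
        raise SwcFormatError(f"{path}: no data lines")

    index_set = {n.index for n in nodes}
    for n in nodes:
        if n.parent != -1 and n.parent not in index_set:
            raise SwcFormatError(
                f"line {lineno_of[n.index]}: node {n.index} references "
                f"missing parent {n.parent}")

    roots = [n.index for n in nodes if n.parent == -1]
    if not roots:
        raise SwcFormatError(f"{path}: no root node (parent -1)")

    children: dict[int, list[int]] = {n.index: [] for n in nodes}
    for n in nodes:
        if n.parent != -1:
            children[n.parent].append(n.index)

    def component(root: int) -> set[int]:
        seen, queue = {root}, deque([root])
        while queue:
            for c in children[queue.popleft()]:
                if c not in seen:
                    seen.add(c)
                    queue.append(c)
        return seen

    components = {r: component(r) for r in roots}
    covered = set().union(*components.values())
    if len(roots) > 1 or len(covered) != len(nodes):
        if strict:
            raise SwcFormatError(
                f"{path}: {len(roots)} roots, {len(nodes) - len(covered)} "
                f"unreachable nodes (strict mode)")
        best = max(roots, key=lambda r: (len(components[r]), -r))
        keep = components[best]
        warnings.warn(
            f"{path}: keeping largest component ({len(keep)}/{len(nodes)} "
            f"nodes, root {best}); file contains multiple fragments",
            stacklevel=2)
        nodes = [n for n in nodes if n.index in keep]
    return NeuronTree(nodes, name=path.stem)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write a tree as 7-column SWC, root first, parents before children."""
    tree.validate()
    path = Path(path)
    lines = ["# SWC reconstruction written by morphembed",
             "# index type x y z radius parent"]
    for i in tree.bfs_order():
        n = tree.node(i)
        lines.append(f"{n.index} {n.type_code} {n.x!r} {n.y!r} {n.z!r} "
                     f"{n.radius!r} {n.parent}")
    path.write_text("\n".join(lines) + "\n")
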