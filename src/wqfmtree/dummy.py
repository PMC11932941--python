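"""Dummy taxa and the leaf-weight normalization.

Each divide step replaces the opposite side of a bipartition by a single
"dummy taxon".  A dummy is modeled as a rooted tree: the children of its
root are the items it represents (real taxa, or dummies created at earlier
divide steps, which appear as nested subtrees).  The real taxa appearing as
leaves anywhere beneath the root form the set ``XR``.

A dummy must contribute to bipartition scores like a single taxon, so the
real taxa under it share one unit of weight: the weight of an edge (u, v)
with parent u is the number of children of u, and the weight of a leaf a is
the reciprocal of the product of edge weights on the root-to-a path.  Taxa
not under any dummy of the current subproblem have weight 1.  Weights are
kept as exact rationals (products of small child counts), so per-dummy sums
equal 1 exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

_dummy_counter = itertools.count(1)

#: Items of a subproblem are real taxon labels (str) or DummyStructure objects.
Item = object


class DummyOverlapError(ValueError):
    """Raised when items handed to one dummy cover overlapping real taxa."""


class DummyStructure:
    """Rooted recursive structure standing in for one side of a bipartition."""

    __slots__ = ("id", "children", "xr", "name")

    def __init__(self, children: tuple, xr: frozenset[str], name: str):
        self.id = next(_dummy_counter)
        self.children = children
        self.xr = xr
        self.name = name

    def __repr__(self):
        return self.name

    def render(self, indent: int = 0) -> str:
        """Indented multi-line rendering, for logging/debugging."""
        pad = "  " * indent
        lines = [f"{pad}{self.name} XR={{{','.join(sorted(self.xr))}}}"]
        for c in self.children:
            if isinstance(c, DummyStructure):
                lines.append(c.render(indent + 1))
            else:
                lines.append(f"{pad}  {c}")
        return "\n".join(lines)


def coverage(item) -> frozenset[str]:
    """Real taxa covered by an item (itself if real, XR if a dummy)."""
    if isinstance(item, DummyStructure):
        return item.xr
    return frozenset((item,))


def make_dummy(items) -> DummyStructure:
    """Create a dummy whose root children are exactly ``items``.

    ``items`` may mix real taxon labels and previously created dummies; their
    real-taxon coverage sets must be pairwise disjoint.  A single-item dummy
    is permitted (arises when a bipartition isolates one item).
    """
    items = tuple(sorted(items, key=_item_key))
    if not items:
        raise ValueError("cannot create a dummy over an empty item set")
    xr: set[str] = set()
    for it in items:
        cov = coverage(it)
        if xr & cov:
            raise DummyOverlapError(
                f"overlapping real-taxon coverage among dummy items: {sorted(xr & cov)}"
            )
        xr |= cov
    d = DummyStructure(items, frozenset(xr), name="")
    d.name = f"X{d.id}"
    return d


def _item_key(item):
    if isinstance(item, DummyStructure):
        return (1, item.id, "")
    return (0, 0, str(item))


def sort_items(items):
    """Deterministic stable ordering of subproblem items (real first, by label)."""
    return sorted(items, key=_item_key)


@dataclass
class WeightAssignment:
    """Per-subproblem taxon weights and item membership.

    ``weight`` maps every real taxon covered by the subproblem to its exact
    Fraction weight; ``item_of`` maps it to the covering item of the current
    subproblem (the taxon itself, or the top-level dummy it sits under).
    """

    weight: dict[str, Fraction]
    item_of: dict[str, object]
    float_weight: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.float_weight = {a: float(w) for a, w in self.weight.items()}

    def dummy_id_of(self, taxon: str) -> int:
        """Id of the covering dummy, or -1 for a free real taxon."""
        it = self.item_of[taxon]
        return it.id if isinstance(it, DummyStructure) else -1


def leaf_weights(items) -> WeightAssignment:
    """Compute the weight of every real taxon covered by a set of items.

    Free real taxa get weight 1; a taxon under a dummy gets the reciprocal
    of the product of child counts along the root-to-leaf path of that
    dummy's structure.  For every dummy the weights of XR sum to exactly 1.
    """
    weight: dict[str, Fraction] = {}
    item_of: dict[str, object] = {}

    def descend(node, share: Fraction, top_item):
        if isinstance(node, DummyStructure):
            m = len(node.children)
            # A single-child node contributes edge weight 1 via m=1.
            for c in node.children:
                descend(c, share / m, top_item)
        else:
            weight[node] = share
            item_of[node] = top_item

    for it in sort_items(items):
        if isinstance(it, DummyStructure):
            descend(it, Fraction(1), it)
        else:
            weight[it] = Fraction(1)
            item_of[it] = it
    return WeightAssignment(weight, item_of)


def check_normalization(items, assignment: WeightAssignment, tol: float = 1e-12):
    """Assert that each dummy's covered weights sum to 1 (within ``tol``)."""
    for it in items:
        if isinstance(it, DummyStructure):
            total = sum(assignment.weight[a] for a in it.xr)
            if abs(float(total) - 1.0) > tol:
                raise AssertionError(
                    f"dummy {it.name}: weights sum to {float(total)}, expected 1"
                )
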