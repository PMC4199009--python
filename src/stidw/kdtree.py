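"""Median-split k-d tree with a bounded-priority-queue multi-neighbor search.

The tree stores one point at every node (internal nodes included) and cycles
the splitting dimension with depth: dimension ``depth % k``.  The k-nearest
neighbor search keeps candidates in a fixed-capacity priority queue and prunes
a subtree on the far side of a splitting plane only when the queue is full and
the plane lies beyond the candidate hypersphere along the splitting axis
(``|q_i - a_i| <= r`` descends, with ``r`` the worst retained distance).

Distance ties are broken by each point's position in the build input, giving
the search a canonical answer — the k smallest (distance, input order) pairs —
that does not depend on tree shape.  This matters for cross-validation, where
same-site records on symmetric day offsets are exactly equidistant and the
hold-out neighborhoods must agree between a full tree and a rebuilt one.

This structure is the package's own nearest-neighbor engine; SciPy's trees are
deliberately not used here so that the search semantics (lower-median splits,
ties-go-left, strict hypersphere test, stable tie rejection in the queue) are
fully under our control and testable.
"""

from __future__ import annotations

import math
from bisect import insort
from typing import Any, Iterator, Sequence

from .errors import DimensionMismatchError, NoDataError

__all__ = ["KdNode", "KdTree", "NeighborQueue", "build_tree", "bpq_insert", "knn_search"]


class KdNode:
    """One point of the tree, discriminating along ``split_dim``.

    ``seq`` is the point's index in the build input; it breaks distance ties
    during searches.
    """

    __slots__ = ("point", "payload", "split_dim", "seq", "left", "right")

    def __init__(self, point, payload, split_dim, seq=0):
        self.point = point
        self.payload = payload
        self.split_dim = split_dim
        self.seq = seq
        self.left: KdNode | None = None
        self.right: KdNode | None = None


class NeighborQueue:
    """Fixed-capacity priority queue keeping the smallest-distance candidates.

    Entries are held in ascending priority order. When the queue is full,
    inserting a candidate strictly closer than the current worst ejects the
    worst entry; a candidate at priority >= the worst is rejected (ties keep
    the incumbent, making searches deterministic).

    An explicit ``order`` key may accompany an insert, in which case full-queue
    comparisons use the pair (priority, order) — how the tree search imposes
    its canonical input-order tie-break.  Without one, the insertion counter
    serves as the order key, which reproduces the plain reject-on-tie rule.
    """

    __slots__ = ("capacity", "_entries", "_counter")

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        self.capacity = capacity
        self._entries: list[tuple[float, int, Any]] = []
        self._counter = 0

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[Any, float]]:
        return ((payload, priority) for priority, _, payload in self._entries)

    @property
    def is_full(self) -> bool:
        return len(self._entries) >= self.capacity

    @property
    def radius(self) -> float:
        """Worst retained priority when full, else +inf (nothing prunable)."""
        if not self.is_full:
            return math.inf
        return self._entries[-1][0]

    def insert(self, payload, priority: float, order: int | None = None) -> bool:
        """Offer a candidate; returns True if it was retained."""
        if priority < 0:
            raise ValueError(f"priority must be >= 0, got {priority}")
        if order is None:
            order = self._counter
            self._counter += 1
        if self.is_full:
            worst = self._entries[-1]
            if (priority, order) >= (worst[0], worst[1]):
                return False
            self._entries.pop()
        insort(self._entries, (priority, order, payload))
        return True

    def items(self) -> list[tuple[Any, float]]:
        """Retained (payload, priority) pairs, ascending by priority."""
        return [(payload, priority) for priority, _, payload in self._entries]


def bpq_insert(queue: NeighborQueue, payload, priority: float) -> NeighborQueue:
    """Insert into a bounded priority queue (mutates and returns ``queue``)."""
    queue.insert(payload, priority)
    return queue


class KdTree:
    """Immutable k-d tree built once over a point set."""

    __slots__ = ("root", "k_dims", "size")

    def __init__(self, root: KdNode | None, k_dims: int, size: int):
        self.root = root
        self.k_dims = k_dims
        self.size = size

    @classmethod
    def build(cls, points: Sequence[Sequence[float]], payloads=None,
              k_dims: int | None = None) -> "KdTree":
        return build_tree(points, payloads, k_dims)

    def query(self, point: Sequence[float], k: int, *, prune: bool = True,
              stats: dict | None = None) -> list[tuple[Any, float]]:
        return knn_search(self, point, k, prune=prune, stats=stats)


def build_tree(points: Sequence[Sequence[float]], payloads=None,
               k_dims: int | None = None) -> KdTree:
    """Build a k-d tree by recursive lower-median splits.

    At each level the lower median along the cycling axis becomes the node;
    points whose coordinate equals the node's go to the left subtree, strictly
    greater ones to the right, so construction is deterministic under
    duplicate keys.

    Parameters
    ----------
    points : sequence of k-dim coordinate sequences
    payloads : optional parallel sequence attached to each point; defaults to
        the point's index in ``points``.
    k_dims : dimensionality; inferred from the first point when omitted.
    """
    pts = [tuple(p) for p in points]
    if pts:
        inferred = len(pts[0])
        if k_dims is None:
            k_dims = inferred
        for p in pts:
            if len(p) != k_dims:
                raise DimensionMismatchError(
                    f"expected {k_dims}-dimensional points, got {len(p)}: {p}"
                )
    elif k_dims is None:
        k_dims = 1
    if payloads is None:
        payloads = list(range(len(pts)))
    elif len(payloads) != len(pts):
        raise ValueError("payloads must parallel points")

    def _build(indices: list[int], depth: int) -> KdNode | None:
        if not indices:
            return None
        axis = depth % k_dims
        indices.sort(key=lambda i: pts[i][axis])
        median_value = pts[indices[(len(indices) - 1) // 2]][axis]
        # node = last element equal to the lower median, so every remaining
        # equal key lands in the left subtree (<= goes left)
        pos = (len(indices) - 1) // 2
        while pos + 1 < len(indices) and pts[indices[pos + 1]][axis] == median_value:
            pos += 1
        node_index = indices[pos]
        node = KdNode(pts[node_index], payloads[node_index], axis, seq=node_index)
        node.left = _build(indices[:pos], depth + 1)
        node.right = _build(indices[pos + 1:], depth + 1)
        return node

    root = _build(list(range(len(pts))), 0)
    return KdTree(root, k_dims, len(pts))


def knn_search(tree: KdTree, query: Sequence[float], k: int, *,
               prune: bool = True, stats: dict | None = None
               ) -> list[tuple[Any, float]]:
    """Return the ``min(k, tree.size)`` nearest stored points to ``query``.

    Results are (payload, distance) pairs ascending by Euclidean distance,
    ties broken by build input order — the unique k smallest under that total
    order, whatever the tree's shape.  The traversal descends toward the
    query's own cell first, then unwinds, crossing a splitting plane only
    while the candidate queue is not yet full or the plane touches the
    current candidate hypersphere.

    ``prune=False`` disables the hypersphere test (every node is visited) and
    exists for soundness checks; ``stats['visited']`` counts visited nodes.
    """
    if tree.root is None:
        raise NoDataError("knn_search on an empty tree")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    q = tuple(query)
    if len(q) != tree.k_dims:
        raise DimensionMismatchError(
            f"query has {len(q)} dimensions, tree has {tree.k_dims}"
        )
    queue = NeighborQueue(k)
    visited = 0

    def _search(node: KdNode | None) -> None:
        nonlocal visited
        if node is None:
            return
        visited += 1
        axis = node.split_dim
        diff = q[axis] - node.point[axis]
        if diff <= 0:
            near, far = node.left, node.right
        else:
            near, far = node.right, node.left
        _search(near)
        queue.insert(node.payload, math.dist(q, node.point), order=node.seq)
        if not prune or not queue.is_full or abs(diff) <= queue.radius:
            _search(far)

    _search(tree.root)
    if stats is not None:
        stats["visited"] = visited
    return queue.items()
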