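"""Representative sequence sampling inside a LECA clade.

The clade tree is first rooted by the least-squares criterion: the root is the
point on any edge minimizing the sum of squared deviations of root-to-leaf
path lengths from their mean (the molecular-clock least-squares fit). Leaves
are then pruned iteratively down to k representatives, removing at each round
the leaf furthest from the root in edge count, breaking ties by path length,
then by reverse label order. This preferentially discards long, fast-evolving
branches while keeping the sequence diversity of the clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .trees import GeneTree, TreeError

logger = logging.getLogger(__name__)


class RNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length  # length of the edge to the parent
        self.children: list[RNode] = []
        self.parent: RNode | None = None

    def add(self, child: "RNode") -> "RNode":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RootedCladeTree:
    """A rooted view of a clade tree, produced by least-squares rooting.

    ``root_edge`` identifies the original unrooted edge carrying the root (as
    the leaf set on one side) and ``root_offset`` the distance of the root
    from the other side's endpoint.
    """

    root: RNode
    root_edge: frozenset = frozenset()
    root_offset: float = 0.0

    def leaves(self) -> list[RNode]:
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v.is_leaf():
                out.append(v)
            stack.extend(v.children)
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(v.label for v in self.leaves())

    def depths(self) -> dict[str, tuple[int, float]]:
        """Per leaf label: (node-wise depth, path-length depth) from the root."""
        out: dict[str, tuple[int, float]] = {}
        stack = [(self.root, 0, 0.0)]
        while stack:
            v, d, length = stack.pop()
            if v.is_leaf():
                out[v.label] = (d, length)
            for w in v.children:
                stack.append((w, d + 1, length + w.length))
        return out

    def remove_leaf(self, label: str) -> None:
        """Remove one leaf; unary non-root nodes are suppressed with their
        branch lengths summed. A unary root is kept (it marks the root point)."""
        target = None
        for v in self.leaves():
            if v.label == label:
                target = v
                break
        if target is None:
            raise TreeError(f"no leaf labeled {label!r}")
        parent = target.parent
        if parent is None:
            raise TreeError("cannot remove the only node")
        parent.children.remove(target)
        while not parent.children and parent.parent is not None:
            # an internal node left childless is itself removed
            grand = parent.parent
            grand.children.remove(parent)
            parent = grand
        while (parent is not None and parent.parent is not None
               and len(parent.children) == 1):
            (child,) = parent.children
            grand = parent.parent
            child.length += parent.length
            child.parent = grand
            grand.children[grand.children.index(parent)] = child
            parent = grand

    def copy(self) -> "RootedCladeTree":
        def clone(v: RNode) -> RNode:
            c = RNode(v.label, v.length)
            for w in v.children:
                c.add(clone(w))
            return c
        return RootedCladeTree(clone(self.root), self.root_edge,
                               self.root_offset)


# -------------------------------------------------------------- LS rooting

def _merge(*stats):
    n = sum(s[0] for s in stats)
    total = sum(s[1] for s in stats)
    sq = sum(s[2] for s in stats)
    return (n, total, sq)


def _shift(stats, length: float):
    n, s, q = stats
    return (n, s + n * length, q + 2.0 * length * s + n * length * length)


def _edge_sse(down, up, b: float):
    """Minimal sum of squared depth deviations for a root on this edge.

    ``up``/``down`` are (count, sum, sum-of-squares) of leaf distances to the
    two edge endpoints; x is the root's distance from the ``up`` endpoint.
    Returns (sse, x)."""
    nu, su, qu = up
    nv, sv, qv = down
    n = nu + nv
    q0 = qu + qv + 2.0 * b * sv + nv * b * b
    q1 = 2.0 * su - 2.0 * sv - 2.0 * nv * b
    s0 = su + sv + nv * b
    s1 = nu - nv
    alpha = n - s1 * s1 / n
    beta = q1 - 2.0 * s0 * s1 / n

    def f(x: float) -> float:
        q = q0 + q1 * x + n * x * x
        s = s0 + s1 * x
        return q - s * s / n

    if alpha <= 0.0:  # nu == 0 or nv == 0 cannot happen on a real edge
        x = b / 2.0
    else:
        x = min(max(-beta / (2.0 * alpha), 0.0), b)
    return f(x), x


def least_squares_root(tree: GeneTree) -> RootedCladeTree:
    """Root an unrooted tree at the point minimizing the variance of
    root-to-leaf path lengths; the offset within each edge is solved in closed
    form and the global optimum found by scanning all edges."""
    if tree.n_leaves < 2:
        raise TreeError("need at least 2 leaves to root")
    all_zero = all(tree.edge_length(u, v) == 0.0 for u, v in tree.edges())
    if all_zero:
        logger.warning("all branch lengths are zero; rooting at an arbitrary "
                       "edge midpoint")

    # down[v]: distance stats (count, sum, sumsq) measured at v of the leaves
    # in v's canonical subtree; A[v]: stats measured at parent(v) of the
    # leaves outside v's subtree.
    down: dict[int, tuple] = {}
    for v in tree.postorder():
        parts = [(1, 0.0, 0.0)] if tree.is_leaf(v) else []
        parts += [_shift(down[w], tree.edge_length(v, w))
                  for w in tree.children_of(v)]
        down[v] = _merge(*parts)
    A: dict[int, tuple] = {}
    order = list(reversed(tree.postorder()))  # parents before children
    for p in order:
        kids = tree.children_of(p)
        gp = tree.parent_of(p)
        base = [(1, 0.0, 0.0)] if tree.is_leaf(p) else []
        if gp is not None:
            base.append(_shift(A[p], tree.edge_length(gp, p)))
        for v in kids:
            sibs = [_shift(down[s], tree.edge_length(p, s))
                    for s in kids if s is not v]
            A[v] = _merge(*(base + sibs))

    best = None  # (sse, edge_index, p, v, x)
    for idx, v in enumerate(tree.postorder()):
        p = tree.parent_of(v)
        if p is None:
            continue
        b = tree.edge_length(p, v)
        sse, x = _edge_sse(down[v], A[v], b)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, idx, p, v, x)
    _, _, p, v, x = best
    if all_zero:
        x = 0.0

    # build the rooted tree with the root inserted on edge (p, v), at
    # distance x from p
    b = tree.edge_length(p, v)

    def build(prev: int, node: int, length: float) -> RNode:
        r = RNode(tree.label_of(node), length)
        for w in tree.neighbors(node):
            if w != prev:
                r.add(build(node, w, tree.edge_length(node, w)))
        return r

    root = RNode()
    root.add(build(v, p, x))
    root.add(build(p, v, b - x))
    side = tree.subtree_leaves(p, v)
    return RootedCladeTree(root=root, root_edge=frozenset(side), root_offset=x)


# ------------------------------------------------------------------ pruning

def prune_to_k(rooted: RootedCladeTree, k: int) -> frozenset:
    """Iteratively prune the deepest leaves until k remain.

    Each round removes the leaf with the greatest node-wise depth, breaking
    ties by the greatest path-length depth, then by reverse lexicographic
    label order. Node-wise depths are recomputed after every removal because
    suppressing unary nodes changes them. Returns the retained leaf labels;
    the k-1 selection is always a subset of the k selection.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    work = rooted.copy()
    labels = work.leaf_labels()
    if len(labels) <= k:
        return labels
    while len(labels) > k:
        depths = work.depths()
        # maximize (nodewise, pathwise, label): reverse label order last
        victim = max(depths, key=lambda lab: (depths[lab][0],
                                              depths[lab][1], lab))
        work.remove_leaf(victim)
        labels = labels - {victim}
    return labels


def sample_representatives(clade_tree: GeneTree, k: int = 10) -> frozenset:
    """Least-squares-root a clade tree and prune it to k representatives."""
    if clade_tree.n_leaves <= k:
        return clade_tree.leaves
    return prune_to_k(least_squares_root(clade_tree), k)
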