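"""Unrooted gene trees and their combinatorics.

A :class:`GeneTree` is an unrooted, possibly multifurcating tree over uniquely
labeled leaves, with non-negative branch lengths and optional integer supports
(0-100) on internal edges. Newick I/O is delegated to dendropy; everything
that touches unrooted-tree structure — bipartitions, clans (the unrooted
analogue of clades), tripartitions, and sister groups — is implemented here on
a plain adjacency structure.

Terminology: a *clan* is a leaf set that forms one side of some bipartition of
the tree (single leaves and the full leaf set are trivial clans). The *sister
group* of a clan is the smaller of the two subtrees adjacent to the clan's
stem edge; the *tripartition at the base* of a clan is the partition of leaves
into {clan, sister, remainder} induced by the node where the clan's stem
attaches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy


class TreeError(ValueError):
    pass


class DuplicateLeafError(TreeError):
    pass


class NewickParseError(TreeError):
    pass


class NotAClanError(TreeError):
    pass


class DegenerateBaseError(TreeError):
    """The node at the base of a clan's stem is multifurcating or a leaf."""


@dataclass(frozen=True)
class Bipartition:
    """An unordered split of the leaf set into two non-empty sides."""

    sides: frozenset  # frozenset of two frozensets of labels

    @staticmethod
    def of(side_a: Iterable[str], side_b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be non-empty")
        if a & b:
            raise TreeError("bipartition sides must be disjoint")
        return Bipartition(frozenset((a, b)))

    @property
    def side_a(self) -> frozenset:
        return min(self.sides, key=lambda s: (len(s), tuple(sorted(s))))

    @property
    def side_b(self) -> frozenset:
        return max(self.sides, key=lambda s: (len(s), tuple(sorted(s))))


@dataclass(frozen=True)
class Tripartition:
    """The three leaf sets around one internal node of a binary unrooted tree."""

    parts: frozenset  # frozenset of three frozensets of labels

    @staticmethod
    def of(*parts: Iterable[str]) -> "Tripartition":
        sets = tuple(frozenset(p) for p in parts)
        if len(sets) != 3 or any(not s for s in sets):
            raise TreeError("a tripartition has exactly three non-empty parts")
        if len(frozenset(sets)) != 3:
            raise TreeError("tripartition parts must be distinct")
        union = sets[0] | sets[1] | sets[2]
        if len(union) != sum(len(s) for s in sets):
            raise TreeError("tripartition parts must be pairwise disjoint")
        return Tripartition(frozenset(sets))

    def bipartitions(self) -> tuple[Bipartition, ...]:
        parts = tuple(self.parts)
        out = []
        for i in range(3):
            side = parts[i]
            other = parts[(i + 1) % 3] | parts[(i + 2) % 3]
            out.append(Bipartition.of(side, other))
        return tuple(out)


@dataclass(frozen=True)
class SisterResult:
    """Sister group of a clan; ``resolved`` is False at a multifurcating base."""

    leaves: frozenset
    resolved: bool


class GeneTree:
    """Immutable unrooted tree with labeled leaves.

    Internally nodes are integers; a canonical traversal is rooted at the leaf
    with the lexicographically smallest label, which makes every derived
    quantity (and hence every downstream tie-break) deterministic.
    """

    __slots__ = ("_adj", "_lengths", "_supports", "_leaf_label", "_node_of",
                 "_leaves", "_root", "_parent", "_postorder", "_subsize")

    def __init__(self, leaf_labels: dict[int, str],
                 edges: Iterable[tuple[int, int, float, int | None]]):
        adj: dict[int, dict[int, int]] = {}
        lengths: dict[frozenset, float] = {}
        supports: dict[frozenset, int | None] = {}
        for u, v, length, support in edges:
            if u == v:
                raise TreeError("self-loop edge")
            key = frozenset((u, v))
            if key in lengths:
                raise TreeError("duplicate edge")
            if length < 0:
                raise TreeError("negative branch length")
            lengths[key] = float(length)
            supports[key] = support
            adj.setdefault(u, {})[v] = 1
            adj.setdefault(v, {})[u] = 1
        labels = list(leaf_labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})[0]
            raise DuplicateLeafError(f"duplicate leaf label {dup!r}")
        for node, deg in ((n, len(nb)) for n, nb in adj.items()):
            if node in leaf_labels and deg != 1:
                raise TreeError(f"leaf node {leaf_labels[node]!r} has degree {deg}")
        if len(leaf_labels) < 2:
            raise TreeError("a gene tree needs at least 2 leaves")
        self._adj = adj
        self._lengths = lengths
        self._supports = supports
        self._leaf_label = dict(leaf_labels)
        self._node_of = {lab: n for n, lab in leaf_labels.items()}
        self._leaves = frozenset(labels)
        self._collapse_degree_two()
        self._check_connected()
        self._root = self._node_of[min(self._leaves)]
        self._parent, self._postorder = self._orient(self._root)
        self._subsize = self._subtree_sizes()

    # ------------------------------------------------------------------ build

    def _collapse_degree_two(self) -> None:
        # Unrooted semantics: a degree-2 node is an artifact of a rooted
        # Newick string; merge its two incident edges (lengths summed).
        for node in [n for n, nb in self._adj.items()
                     if len(nb) == 2 and n not in self._leaf_label]:
            a, b = self._adj[node]
            ka, kb = frozenset((node, a)), frozenset((node, b))
            length = self._lengths.pop(ka) + self._lengths.pop(kb)
            sup_a, sup_b = self._supports.pop(ka), self._supports.pop(kb)
            support = sup_a if sup_a is not None else sup_b
            del self._adj[node]
            del self._adj[a][node]
            del self._adj[b][node]
            key = frozenset((a, b))
            if key in self._lengths:  # two-leaf tree collapses to one edge
                self._lengths[key] += length
            else:
                self._adj[a][b] = 1
                self._adj[b][a] = 1
                self._lengths[key] = length
                self._supports[key] = support

    def _check_connected(self) -> None:
        seen = set()
        stack = [next(iter(self._adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self._adj[v])
        if len(seen) != len(self._adj):
            raise TreeError("tree is not connected")

    def _orient(self, root: int) -> tuple[dict[int, int | None], list[int]]:
        parent: dict[int, int | None] = {root: None}
        order: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for w in self._adj[v]:
                if w != parent[v]:
                    parent[w] = v
                    stack.append(w)
        order.reverse()  # children before parents
        return parent, order

    def _subtree_sizes(self) -> dict[int, int]:
        size: dict[int, int] = {}
        for v in self._postorder:
            size[v] = ((1 if v in self._leaf_label else 0)
                       + sum(size[w] for w in self._adj[v]
                             if w != self._parent[v]))
        return size

    # -------------------------------------------------------------- accessors

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def label_of(self, node: int) -> str | None:
        return self._leaf_label.get(node)

    def node_of_label(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise TreeError(f"no leaf labeled {label!r}") from None

    def postorder(self) -> Sequence[int]:
        return self._postorder

    def parent_of(self, node: int) -> int | None:
        return self._parent[node]

    def children_of(self, node: int) -> list[int]:
        return [w for w in self._adj[node] if w != self._parent[node]]

    def neighbors(self, node: int) -> list[int]:
        return list(self._adj[node])

    def is_leaf(self, node: int) -> bool:
        return node in self._leaf_label

    def edge_length(self, u: int, v: int) -> float:
        return self._lengths[frozenset((u, v))]

    def edge_support(self, u: int, v: int) -> int | None:
        return self._supports[frozenset((u, v))]

    def edges(self) -> Iterator[tuple[int, int]]:
        for key in self._lengths:
            u, v = tuple(key)
            yield (u, v)

    def internal_edges(self) -> Iterator[tuple[int, int]]:
        for u, v in self.edges():
            if u not in self._leaf_label and v not in self._leaf_label:
                yield (u, v)

    def has_branch_lengths(self) -> bool:
        return any(l != 1.0 for l in self._lengths.values())

    def subtree_leaves(self, away_from: int, node: int) -> frozenset:
        """Leaf labels in the component of ``node`` after removing the edge
        between ``away_from`` and ``node``."""
        out = []
        stack = [(away_from, node)]
        while stack:
            prev, v = stack.pop()
            lab = self._leaf_label.get(v)
            if lab is not None:
                out.append(lab)
            stack.extend((v, w) for w in self._adj[v] if w != prev)
        return frozenset(out)

    # ------------------------------------------------------------ clan logic

    def _membership_counts(self, leafset: frozenset) -> dict[int, int]:
        cnt: dict[int, int] = {}
        for v in self._postorder:
            c = sum(cnt[w] for w in self._adj[v] if w != self._parent[v])
            lab = self._leaf_label.get(v)
            if lab is not None and lab in leafset:
                c += 1
            cnt[v] = c
        return cnt

    def clan_edge(self, leafset: frozenset) -> tuple[int, int] | None:
        """Directed edge (u, v) such that the component of v after removing
        {u, v} has exactly ``leafset`` as leaves; None if no such edge.

        The full leaf set is a clan but has no stem edge (returns None);
        use :meth:`is_clan` to test clan-ness.
        """
        leafset = frozenset(leafset)
        if not leafset:
            raise TreeError("empty leaf set")
        unknown = leafset - self._leaves
        if unknown:
            raise TreeError(f"labels not in tree: {sorted(unknown)[:3]}")
        k = len(leafset)
        n = self.n_leaves
        if k == n:
            return None
        cnt = self._membership_counts(leafset)
        for v in self._postorder:
            p = self._parent[v]
            if p is None:
                continue
            if cnt[v] == k and self._subsize[v] == k:
                return (p, v)
            if cnt[v] == 0 and self._subsize[v] == n - k:
                return (v, p)
        return None

    def is_clan(self, leafset: Iterable[str]) -> bool:
        leafset = frozenset(leafset)
        if not leafset:
            raise TreeError("empty leaf set")
        if leafset == self._leaves:
            return True
        return self.clan_edge(leafset) is not None

    def bipartitions(self, include_trivial: bool = False) -> list[Bipartition]:
        out = []
        for v in self._postorder:
            p = self._parent[v]
            if p is None:
                continue
            if not include_trivial and (v in self._leaf_label or p == self._root):
                continue
            side = self.subtree_leaves(p, v)
            out.append(Bipartition.of(side, self._leaves - side))
        return out

    def sister_group(self, clan: Iterable[str]) -> SisterResult:
        """Smaller of the two subtrees adjacent to the clan's stem edge.

        Ties go to the side whose sorted label tuple is lexicographically
        smaller. If the base node is multifurcating the union of all adjacent
        subtrees is returned flagged unresolved. If the rest of the tree is a
        single leaf, that leaf is the sister.
        """
        clan = frozenset(clan)
        if clan == self._leaves:
            raise NotAClanError("the full leaf set has no sister group")
        edge = self.clan_edge(clan)
        if edge is None:
            raise NotAClanError("leaf set is not a clan of this tree")
        base, into_clan = edge
        if base in self._leaf_label:
            return SisterResult(frozenset((self._leaf_label[base],)), True)
        others = [w for w in self._adj[base] if w != into_clan]
        subtrees = [self.subtree_leaves(base, w) for w in others]
        if len(subtrees) != 2:
            return SisterResult(frozenset().union(*subtrees), False)
        a, b = subtrees
        if len(a) != len(b):
            return SisterResult(min(a, b, key=len), True)
        return SisterResult(min(a, b, key=lambda s: tuple(sorted(s))), True)

    def tripartition_at_base(self, clan: Iterable[str]) -> Tripartition:
        """Tripartition {clan, sister, remainder} at the base of the clan's stem."""
        clan = frozenset(clan)
        edge = self.clan_edge(clan)
        if edge is None:
            raise NotAClanError("leaf set is not a clan of this tree")
        base, into_clan = edge
        if base in self._leaf_label:
            raise DegenerateBaseError(
                "clan attaches to a single leaf; no tripartition exists")
        others = [w for w in self._adj[base] if w != into_clan]
        if len(others) != 2:
            raise DegenerateBaseError(
                f"multifurcating base node (degree {len(self._adj[base])})")
        parts = [self.subtree_leaves(base, w) for w in others]
        return Tripartition.of(clan, parts[0], parts[1])

    def contains_tripartition(self, tri: Tripartition) -> bool:
        """True iff the three bipartitions induced by ``tri`` all occur here."""
        union = frozenset().union(*tri.parts)
        if union != self._leaves:
            raise TreeError("tripartition is over a different leaf set")
        return all(self.is_clan(part) for part in tri.parts)

    # --------------------------------------------------------------- editing

    def restrict_to(self, labels: Iterable[str]) -> "GeneTree":
        """Induced subtree on a leaf subset; suppressed nodes sum lengths.

        Supports survive only on edges that are kept intact.
        """
        keep = frozenset(labels)
        if not keep <= self._leaves:
            raise TreeError("labels not in tree")
        if len(keep) < 2:
            raise TreeError("restriction needs at least 2 leaves")
        adj = {n: dict(nb) for n, nb in self._adj.items()}
        lengths = dict(self._lengths)
        supports = dict(self._supports)
        leaf_label = dict(self._leaf_label)

        def remove_leaf(node: int) -> None:
            (nb,) = adj[node]
            del adj[node], adj[nb][node]
            key = frozenset((node, nb))
            del lengths[key], supports[key]
            leaf_label.pop(node, None)

        def suppress(node: int) -> None:
            a, b = adj[node]
            ka, kb = frozenset((node, a)), frozenset((node, b))
            length = lengths.pop(ka) + lengths.pop(kb)
            lengths[frozenset((a, b))] = length
            supports.pop(ka), supports.pop(kb)
            supports[frozenset((a, b))] = None
            del adj[node], adj[a][node], adj[b][node]
            adj[a][b] = 1
            adj[b][a] = 1

        for node, lab in list(self._leaf_label.items()):
            if lab not in keep:
                remove_leaf(node)
        changed = True
        while changed:
            changed = False
            for node in list(adj):
                if node in leaf_label:
                    continue
                deg = len(adj[node])
                if deg == 1:
                    remove_leaf(node)
                    changed = True
                elif deg == 2 and len(adj) > 2:
                    suppress(node)
                    changed = True
        return GeneTree(leaf_label,
                        [(u, v, lengths[frozenset((u, v))],
                          supports[frozenset((u, v))])
                         for u, v in (tuple(k) for k in lengths)])

    # ------------------------------------------------------------------- I/O

    def as_newick(self, with_supports: bool = True,
                  with_lengths: bool = True) -> str:
        # print-root: an internal node if one exists, else the canonical leaf
        start = self._root
        for n in self._adj:
            if n not in self._leaf_label:
                start = n
                break

        def fmt_len(u: int, v: int) -> str:
            if not with_lengths:
                return ""
            return ":%s" % ("%.10g" % self.edge_length(u, v))

        def render(prev: int | None, node: int) -> str:
            lab = self._leaf_label.get(node)
            if lab is not None:
                return lab + ("" if prev is None else fmt_len(prev, node))
            kids = [w for w in self._adj[node] if w != prev]
            inner = ",".join(render(node, w) for w in kids)
            sup = ""
            if with_supports and prev is not None:
                s = self.edge_support(prev, node)
                sup = "" if s is None else str(s)
            tail = "" if prev is None else sup + fmt_len(prev, node)
            return "(" + inner + ")" + tail

        return render(None, start) + ";"

    @staticmethod
    def from_dendropy(tree: dendropy.Tree) -> "GeneTree":
        tree.is_rooted = False
        next_id = [0]
        ids: dict[int, int] = {}

        def nid(node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = next_id[0]
                next_id[0] += 1
            return ids[key]

        leaf_labels: dict[int, str] = {}
        edges: list[tuple[int, int, float, int | None]] = []
        labels_seen: list[str] = []
        for node in tree.preorder_node_iter():
            me = nid(node)
            if node.is_leaf():
                lab = (node.taxon.label if node.taxon is not None
                       else node.label)
                if lab is None:
                    raise NewickParseError("unlabeled leaf")
                labels_seen.append(lab)
                leaf_labels[me] = lab
            if node.parent_node is not None:
                length = node.edge.length
                length = 1.0 if length is None else float(length)
                support = None
                if not node.is_leaf():
                    support = _parse_support(node.label)
                    if support is None:
                        support = _support_from_comments(node)
                edges.append((nid(node.parent_node), me, length, support))
        dups = sorted({x for x in labels_seen if labels_seen.count(x) > 1})
        if dups:
            raise DuplicateLeafError(f"duplicate leaf label {dups[0]!r}")
        return GeneTree(leaf_labels, edges)


def _parse_support(label: str | None) -> int | None:
    if label is None:
        return None
    try:
        val = float(label)
    except ValueError:
        return None
    if math.isnan(val):
        return None
    return int(round(val))


def _support_from_comments(node) -> int | None:
    # secondary dialect: support in a bracket comment on the branch, e.g. ")[90]:0.1"
    for source in (node.comments, node.edge.comments):
        for comment in source or ():
            val = _parse_support(comment.strip())
            if val is not None:
                return val
    return None


def _trees_from_string(text: str, path: str = "<string>") -> list[GeneTree]:
    try:
        tree_list = dendropy.TreeList.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except DuplicateLeafError:
        raise
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            label = str(exc).rsplit(":", 1)[-1].strip()
            raise DuplicateLeafError(f"duplicate leaf label {label!r}") from exc
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if line is not None else ""
        raise NewickParseError(f"{path}: cannot parse Newick{where}: {exc}") from exc
    if not tree_list:
        raise NewickParseError(f"{path}: no trees found")
    # separate namespaces per tree: leaves may repeat across trees, not within
    out = []
    for t in tree_list:
        out.append(GeneTree.from_dendropy(t))
    return out


def read_newick(path, expect_supports: bool = False):
    """Read Newick file; returns a GeneTree, or a list for multi-tree files.

    ``expect_supports`` makes the absence of any internal-edge support a hard
    error (ML trees in this pipeline are expected to carry bootstrap values).
    """
    with open(path, encoding="utf-8") as handle:
        text = handle.read()
    trees = _trees_from_string(text, str(path))
    if expect_supports:
        for i, t in enumerate(trees):
            has = any(t.edge_support(u, v) is not None
                      for u, v in t.internal_edges())
            if not has and t.n_leaves >= 4:
                raise NewickParseError(
                    f"{path}: tree {i + 1} carries no internal-edge supports")
    return trees[0] if len(trees) == 1 else trees


def read_bootstrap_trees(path) -> list[GeneTree]:
    """Read a multi-tree Newick file (one replicate per line)."""
    result = read_newick(path)
    return result if isinstance(result, list) else [result]


def write_newick(trees, path, with_supports: bool = True) -> None:
    if isinstance(trees, GeneTree):
        trees = [trees]
    with open(path, "w", encoding="utf-8") as handle:
        for t in trees:
            handle.write(t.as_newick(with_supports=with_supports) + "\n")


def parse_newick(text: str) -> GeneTree:
    """Parse a single Newick string (convenience, mostly for tests)."""
    trees = _trees_from_string(text)
    if len(trees) != 1:
        raise NewickParseError("expected exactly one tree")
    return trees[0]


def leafset_str(leaves: Iterable[str]) -> str:
    """Canonical serialization of a leaf set: sorted, comma-joined."""
    return ",".join(sorted(leaves))
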