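"""Distance-based phylogeny: neighbor-joining trees from relatedness distances.

The canonical Saitou-Nei agglomeration with the usual practical fix for
non-additive input (ANI-derived distances rarely fit a tree exactly):
a negative branch-length estimate is clamped to zero and transferred to
the sibling branch, keeping the tip-to-tip path lengths intact.  Tie
breaks in the Q-matrix are lexicographic on the pair indices so the
result is deterministic under taxon reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import RelatednessMatrix, ValidationError

__all__ = ["TreeNode", "PhyloTree", "nj_tree"]


@dataclass(eq=False)  # identity semantics: nodes are used as dict keys
class TreeNode:
    name: str | None = None
    length: float = 0.0            # branch length to parent
    original_length: float | None = None  # pre-clamp NJ estimate, if clamped
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, digits: int = 10) -> str:
        if self.is_leaf():
            return f"{_quote(self.name or '')}:{self.length:.{digits}g}"
        inner = ",".join(c.newick(digits) for c in self.children)
        return f"({inner}):{self.length:.{digits}g}"


def _quote(name: str) -> str:
    if any(c in name for c in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


class PhyloTree:
    """Unrooted (or outgroup-rooted) tree over genome identifiers."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self, digits: int = 10) -> str:
        if self.root.is_leaf():
            return f"{_quote(self.root.name or '')};"
        inner = ",".join(c.newick(digits) for c in self.root.children)
        return f"({inner});"

    # -- distances ------------------------------------------------------
    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths along the path between every leaf pair."""
        paths: dict[str, dict[TreeNode, float]] = {}

        def walk(node: TreeNode, trail: list[tuple[TreeNode, float]]) -> None:
            trail = trail + [(node, node.length)]
            if node.is_leaf():
                acc: dict[TreeNode, float] = {}
                total = 0.0
                for anc, ln in reversed(trail):
                    acc[anc] = total
                    total += ln
                paths[node.name] = acc
            for c in node.children:
                walk(c, trail)

        walk(self.root, [])
        out: dict[tuple[str, str], float] = {}
        for a, b in combinations(sorted(paths), 2):
            shared = [n for n in paths[a] if n in paths[b]]
            # the LCA minimizes the summed climb distances
            dist = min(paths[a][n] + paths[b][n] for n in shared)
            out[(a, b)] = dist
        return out

    # -- topology -------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as its smaller-side leaf set."""
        all_leaves = frozenset(self.leaf_names)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(below if len(below) <= len(other) else other)
            return below

        walk(self.root)
        return splits

    def same_topology(self, other: "PhyloTree") -> bool:
        return (set(self.leaf_names) == set(other.leaf_names)
                and self.bipartitions() == other.bipartitions())

    def clade_leafsets(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            out.add(below)
            return below

        walk(self.root)
        return out


def nj_tree(d: RelatednessMatrix, outgroup: str | None = None) -> PhyloTree:
    """Neighbor-joining tree from a symmetric complete distance matrix.

    With ``outgroup`` given, the tree is rooted at the midpoint of the
    branch leading to that taxon; otherwise the root is the final
    three-way NJ join (an unrooted tree in rooted representation).
    """
    if d.scale != "distance":
        raise ValidationError("NJ requires a distance matrix")
    if d.has_missing():
        raise ValidationError("distance matrix has missing entries")
    if not d.is_symmetric(tol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    n = len(d)
    if n < 3:
        raise ValidationError("need at least three taxa")
    if outgroup is not None and outgroup not in d.ids:
        raise ValidationError(f"outgroup {outgroup!r} not in matrix")

    dm = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=g) for g in d.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among minima
        flat = np.argwhere(np.isclose(q, q.min(), atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in flat if a < b)
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dm[i, j] - li
        li, lj = _clamp_pair(li, lj, nodes[i], nodes[j])
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        new_row = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dm = np.vstack([dm[np.ix_(keep, keep)],
                        new_row[keep][None, :]])
        dm = np.hstack([dm, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join
    d01, d02, d12 = dm[0, 1], dm[0, 2], dm[1, 2]
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    for node, ln in zip(nodes, (l0, l1, l2)):
        if ln < 0:
            node.original_length = float(ln)
            ln = 0.0
        node.length = float(ln)
    root = TreeNode(children=list(nodes))
    tree = PhyloTree(root)
    if outgroup is not None:
        tree = _root_at(tree, outgroup)
    return tree


def _clamp_pair(li: float, lj: float, ni: TreeNode, nj_: TreeNode) -> tuple[float, float]:
    """Clamp a negative NJ branch estimate, transferring it to the sibling."""
    if li < 0:
        ni.original_length = float(li)
        lj += li
        li = 0.0
    if lj < 0:
        nj_.original_length = float(lj)
        li += lj
        lj = 0.0
    return float(li), float(max(lj, 0.0))


def _root_at(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Re-root at the midpoint of the outgroup's terminal branch."""
    parent_of: dict[int, TreeNode | None] = {id(tree.root): None}

    def index(node: TreeNode) -> None:
        for c in node.children:
            parent_of[id(c)] = node
            index(c)

    index(tree.root)
    og = next(l for l in tree.root.leaves() if l.name == outgroup)
    half = og.length / 2.0
    og_parent = parent_of[id(og)]
    og_parent.children = [c for c in og_parent.children if c is not og]

    # reverse every edge on the path outgroup-parent -> old root
    path: list[TreeNode] = []
    node: TreeNode | None = og_parent
    while node is not None:
        path.append(node)
        node = parent_of[id(node)]
    orig_len = [n.length for n in path]
    for k in range(len(path) - 1):
        path[k + 1].children = [c for c in path[k + 1].children if c is not path[k]]
        path[k].children.append(path[k + 1])
        path[k + 1].length = orig_len[k]

    og.length = half
    og_parent.length = half
    return PhyloTree(TreeNode(children=[og, og_parent]))
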