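"""Distance-based trees: UPGMA and neighbor-joining, with Newick output.

Both algorithms run on the distance transform d = 1 - similarity of a
species matrix. UPGMA produces a rooted ultrametric tree (all leaves
equidistant from the root); neighbor-joining produces an unrooted tree,
represented here with a trifurcating root, and reconstructs additive
distance matrices exactly. Both are deterministic: ties in the merge
criterion are broken by the lexicographically smallest pair of cluster
representative labels.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import skbio

from .compare import CorrelationMatrix
from .exceptions import InvalidInputError

__all__ = ["TreeNode", "upgma", "neighbor_joining", "write_newick", "read_newick"]

_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


@dataclass
class TreeNode:
    """Weighted rooted tree; leaves carry species labels.

    ``children`` is a list of (child, branch_length) pairs. Unrooted
    (neighbor-joining) trees are stored with a trifurcating root.
    """

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths keyed by leaf label."""
        out: dict[str, float] = {}

        def walk(node: "TreeNode", acc: float):
            if node.is_leaf:
                out[node.label] = acc
            for child, length in node.children:
                walk(child, acc + length)

        walk(self, 0.0)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every unordered pair of leaves."""
        pairs: dict[tuple[str, str], float] = {}

        def walk(node: "TreeNode") -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                d = {l: x + length for l, x in walk(child).items()}
                below.append(d)
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            pairs[tuple(sorted((la, lb)))] = da + db
            merged: dict[str, float] = {}
            for d in below:
                merged.update(d)
            return merged

        walk(self)
        return pairs

    def equals(self, other: "TreeNode", tol: float = 1e-9) -> bool:
        """Structural equality up to child order and branch-length tolerance."""

        def key(node: "TreeNode") -> tuple:
            return tuple(sorted(node.leaf_labels()))

        if sorted(self.leaf_labels()) != sorted(other.leaf_labels()):
            return False
        if self.is_leaf and other.is_leaf:
            return self.label == other.label
        if self.is_leaf != other.is_leaf or len(self.children) != len(other.children):
            return False
        mine = sorted(self.children, key=lambda cl: key(cl[0]))
        theirs = sorted(other.children, key=lambda cl: key(cl[0]))
        for (ca, la), (cb, lb) in zip(mine, theirs):
            if key(ca) != key(cb) or abs(la - lb) > tol or not ca.equals(cb, tol):
                return False
        return True


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize to Newick with branch lengths; labels quoted when needed."""
    leaves = tree.leaf_labels()
    if len(set(leaves)) != len(leaves):
        raise InvalidInputError("duplicate leaf labels cannot be serialized")

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}"

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(
            f"{render(child)}:{fmt(length)}" for child, length in node.children
        )
        return f"({inner})"

    return render(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse Newick text (delegated to scikit-bio) into a TreeNode."""
    sk = skbio.TreeNode.read(io.StringIO(text), format="newick")

    def convert(node) -> TreeNode:
        if not node.children:
            return TreeNode(label=node.name)
        return TreeNode(
            label=node.name,
            children=[
                (convert(c), float(c.length) if c.length is not None else 0.0)
                for c in node.children
            ],
        )

    return convert(sk)


def _check_matrix(matrix: CorrelationMatrix, n_min: int) -> np.ndarray:
    if matrix.n < n_min:
        raise InvalidInputError(f"need at least {n_min} species, got {matrix.n}")
    return matrix.distances()


def upgma(matrix: CorrelationMatrix) -> TreeNode:
    """UPGMA agglomeration on d = 1 - similarity.

    Cluster pairs at minimal average distance are merged; the new node sits
    at height d/2 so the output is ultrametric. Ties are broken by the
    smallest (label, label) pair, making the topology independent of input
    order up to leaf permutation.
    """
    D = _check_matrix(matrix, 2)
    labels = list(matrix.labels)
    nodes = [TreeNode(label=l) for l in labels]
    sizes = [1] * len(labels)
    heights = [0.0] * len(labels)
    reps = [l for l in labels]  # smallest member label, for tie-breaking
    D = D.copy()
    active = list(range(len(labels)))
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                key = (D[i, j], *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = D[i, j] / 2.0
        merged = TreeNode(
            children=[(nodes[i], h - heights[i]), (nodes[j], h - heights[j])]
        )
        # size-weighted average distance to the merged cluster
        for m in active:
            if m in (i, j):
                continue
            d_new = (sizes[i] * D[i, m] + sizes[j] * D[j, m]) / (sizes[i] + sizes[j])
            D[i, m] = D[m, i] = d_new
        nodes[i] = merged
        sizes[i] += sizes[j]
        heights[i] = h
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    return nodes[active[0]]


def neighbor_joining(matrix: CorrelationMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on d = 1 - similarity.

    Iteratively joins the pair minimizing Q(i, j) = (r-2) d(i,j) - R_i -
    R_j; branch lengths follow the canonical formulas, so additive
    matrices are recovered exactly. Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch (total preserved).
    The returned root is the final trifurcation of the unrooted tree.
    """
    D = _check_matrix(matrix, 3).copy()
    nodes = [TreeNode(label=l) for l in matrix.labels]
    reps = [l for l in matrix.labels]
    active = list(range(matrix.n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj, li = lj + li, 0.0
        if lj < 0.0:
            li, lj = li + lj, 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, m] for m in active if m != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        merged = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        for m in active:
            if m in (i, j):
                continue
            d_new = 0.5 * (D[i, m] + D[j, m] - D[i, j])
            D[i, m] = D[m, i] = d_new
        nodes[i] = merged
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    return TreeNode(children=list(zip((nodes[i], nodes[j], nodes[k]), lengths)))
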