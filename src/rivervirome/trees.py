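"""Distance-based trees: UPGMA (rooted, ultrametric) and neighbor joining.

Both operate on a small labelled symmetric distance matrix and emit
Newick strings.  UPGMA follows the classic size-weighted average-linkage
agglomeration with deterministic tie-breaking on the lexicographically
smallest label pair; NJ is the Saitou–Nei algorithm with negative branch
lengths clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class TreeNode:
    """Rooted tree node; ``length`` is the branch to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths keyed by leaf label."""
        out: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            depth += node.length
            if node.is_leaf:
                out[node.label] = depth
            for c in node.children:
                walk(c, depth)

        walk(self, -self.length)  # root's own length does not count
        return out

    def to_newick(self) -> str:
        return f"{self._newick_inner()};"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    At every step the pair of clusters at minimal distance is merged
    (ties broken by the lexicographically smallest pair of cluster
    labels, a cluster being labelled by its smallest member); distances
    to the merged cluster are size-weighted averages, and the merged
    node sits at height d/2 so leaf depths are ultrametric.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    # cluster state: id -> (node, size, height, sort label)
    nodes = {i: TreeNode(label=dm.labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    names = {i: dm.labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (min(dist[(i, j)] if (i, j) in dist else dist[(j, i)], np.inf),
                       tuple(sorted((names[i], names[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d_ij = dist[(i, j)] if (i, j) in dist else dist[(j, i)]
        h = d_ij / 2.0
        node = TreeNode()
        for cid in (i, j):
            child = nodes[cid]
            child.length = h - heights[cid]
            node.children.append(child)
        # deterministic child order: by smallest member label
        node.children.sort(key=lambda c: min(l.label for l in c.leaves()))
        k = next_id
        next_id += 1
        nodes[k] = node
        sizes[k] = sizes[i] + sizes[j]
        heights[k] = h
        names[k] = min(names[i], names[j])
        for m in active:
            if m in (i, j):
                continue
            d_im = dist.get((min(i, m), max(i, m)))
            d_jm = dist.get((min(j, m), max(j, m)))
            d_km = (sizes[i] * d_im + sizes[j] * d_jm) / (sizes[i] + sizes[j])
            dist[(min(k, m), max(k, m))] = d_km
        active.discard(i)
        active.discard(j)
        active.add(k)
    root = nodes[active.pop()]
    root.length = 0.0
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; unrooted tree as a trifurcating root.

    Negative branch length estimates are clamped to 0.  With exactly
    three taxa the closed-form three-point branch lengths are used.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    D = dm.d.astype(float).copy()
    active = list(range(n))
    mat = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_nodes = dict(enumerate(nodes))
    counter = n
    while len(active) > 3:
        r = len(active)
        # net divergence
        R = {i: sum(mat[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * mat[(i, j)] - R[i] - R[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = mat[(i, j)]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = next_nodes[i], next_nodes[j]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]
        k = counter
        counter += 1
        next_nodes[k] = parent
        for m in active:
            if m in (i, j):
                continue
            dkm = 0.5 * (mat[(i, m)] + mat[(j, m)] - dij)
            mat[(k, m)] = mat[(m, k)] = max(dkm, 0.0)
        active = [m for m in active if m not in (i, j)] + [k]
    # join the last three on a trifurcating root
    i, j, k = active
    dij, dik, djk = mat[(i, j)], mat[(i, k)], mat[(j, k)]
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    root = TreeNode()
    for m, lm in ((i, li), (j, lj), (k, lk)):
        child = next_nodes[m]
        child.length = lm
        root.children.append(child)
    return root
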