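"""Distance-based tree construction and tree metric utilities.

Neighbor-joining here is the classic agglomerative algorithm: it exactly
recovers topology and branch lengths from any additive (tree-like) matrix,
and serves as the built-in distance-based companion to externally inferred
ML trees imported via Newick.
"""

from __future__ import annotations

import numpy as np

from seqspace.errors import ValidationError
from seqspace.seqio import DistanceMatrix, PhyloTree, TreeNode


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, moving the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor-joining; returns an unrooted tree.

    At each step the pair minimizing Q(i,j) = (n-2) d_ij - r_i - r_j is
    joined; ties are broken by the lexicographically smallest pair of
    subtree keys (a subtree's key is its smallest leaf label), so the
    output is fully deterministic. Negative branch-length estimates are
    clamped to 0 with the deficit transferred to the sibling branch.
    """
    n = dm.n
    if n < 3:
        raise ValidationError("neighbor-joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValidationError("non-finite distance entry")

    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    keys: list[str] = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)

        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                ka, kb = keys[active[a]], keys[active[b]]
                pair_key = (min(ka, kb), max(ka, kb))
                if q[a, b] < best_q - 1e-12 or (
                    abs(q[a, b] - best_q) <= 1e-12
                    and (best is None or pair_key < best[2])
                ):
                    best_q = q[a, b]
                    best = (a, b, pair_key)
        a, b, _ = best
        i, j = active[a], active[b]

        dij = d[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])

        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0])
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = (d[i, c] + d[j, c] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    li, lj = _clamp_pair(li, lj)
    lj, lk = _clamp_pair(lj, lk)
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# tree metrics
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
    for parent, child in tree.edges():
        if child.length is None:
            raise ValidationError(
                f"missing branch length on node {child.name!r}"
            )
        adj.setdefault(parent, []).append((child, child.length))
        adj.setdefault(child, []).append((parent, child.length))
    adj.setdefault(tree.root, [])
    return adj


def _distances_from(
    start: TreeNode, adj: dict[TreeNode, list[tuple[TreeNode, float]]]
) -> dict[TreeNode, float]:
    dist = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, w in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + w
                stack.append(nbr)
    return dist


def all_node_distances(tree: PhyloTree) -> tuple[list[TreeNode], np.ndarray]:
    """Path-length matrix over every node of the tree (postorder order)."""
    adj = _adjacency(tree)
    nodes = list(tree.postorder())
    index = {node: i for i, node in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)))
    for node in nodes:
        dist = _distances_from(node, adj)
        for other, w in dist.items():
            mat[index[node], index[other]] = w
    return nodes, mat


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    nodes, mat = all_node_distances(tree)
    leaf_idx = [i for i, n in enumerate(nodes) if n.is_leaf]
    labels = tuple(nodes[i].name for i in leaf_idx)
    sub = mat[np.ix_(leaf_idx, leaf_idx)]
    sub = (sub + sub.T) / 2.0
    return DistanceMatrix(labels, sub)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Degree-2 internal nodes left behind by re-rooting are suppressed, so
    re-rooting an already-midpoint-rooted tree is a no-op up to the node
    objects' identity.
    """
    adj = _adjacency(tree)
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValidationError("midpoint rooting needs at least 2 leaves")

    best = (-1.0, None, None)
    dist_cache = {}
    for leaf in leaves:
        dist_cache[leaf] = _distances_from(leaf, adj)
        for other in leaves:
            w = dist_cache[leaf][other]
            if w > best[0]:
                best = (w, leaf, other)
    total, end_a, end_b = best
    if total <= 0:
        raise ValidationError("tree has zero total path length; cannot midpoint-root")

    # path from end_a to end_b
    path = [end_a]
    seen = {end_a}
    found = False

    def walk(node: TreeNode) -> bool:
        nonlocal found
        if node is end_b:
            return True
        for nbr, _w in adj[node]:
            if nbr in seen:
                continue
            seen.add(nbr)
            path.append(nbr)
            if walk(nbr):
                return True
            path.pop()
        return False

    walk(end_a)

    half = total / 2.0
    acc = 0.0
    root_node: TreeNode | None = None
    split: tuple[TreeNode, TreeNode, float] | None = None
    for u, v in zip(path, path[1:]):
        w = next(wt for nbr, wt in adj[u] if nbr is v)
        if abs(acc + w - half) <= 1e-12:
            root_node = v
            break
        if acc + w > half:
            split = (u, v, half - acc)
            break
        acc += w

    new_root = TreeNode()
    if root_node is not None:
        new_root = root_node
    else:
        u, v, x = split
        w = next(wt for nbr, wt in adj[u] if nbr is v)
        adj[u] = [(n, wt) for n, wt in adj[u] if n is not v]
        adj[v] = [(n, wt) for n, wt in adj[v] if n is not u]
        adj[new_root] = [(u, x), (v, w - x)]
        adj[u].append((new_root, x))
        adj[v].append((new_root, w - x))

    # rebuild a rooted structure by directed traversal from the new root
    def build(node: TreeNode, parent: TreeNode | None, length: float | None) -> TreeNode:
        fresh = TreeNode(node.name, length, node.support)
        for nbr, w in adj[node]:
            if nbr is parent:
                continue
            fresh.add(build(nbr, node, w))
        return fresh

    root = build(new_root, None, None)

    # suppress degree-2 internal nodes (merge their single child upward)
    def suppress(node: TreeNode) -> None:
        for child in list(node.children):
            suppress(child)
        for child in list(node.children):
            if not child.is_leaf and len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                node.children[node.children.index(child)] = grand
                grand.parent = node

    suppress(root)
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return PhyloTree(root, rooted=True)
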