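"""Independent reference computations used to validate the implementation.

These deliberately use brute force (grids, repeated squaring, rotation
scans) rather than the code paths they check.
"""

import numpy as np

from seqspace.distances import _pair_counts, encode_row
from seqspace.models import transition_matrices


def grid_ml_distance(a: str, b: str, model, step: float = 1e-3, t_max: float = 10.0):
    """Brute-force likelihood grid search for the pairwise ML divergence."""
    counts = _pair_counts(encode_row(a), encode_row(b))
    ts = np.arange(0.0, t_max + step / 2, step)
    pgrid = transition_matrices(model, ts)          # (T, 20, 20)
    ai, bi = np.nonzero(counts)
    vals = model.pi[ai][None, :] * pgrid[:, ai, bi]  # (T, m)
    with np.errstate(divide="ignore"):
        ll = np.where(
            np.all(vals > 0, axis=1),
            np.sum(counts[ai, bi][None, :] * np.log(np.maximum(vals, 1e-300)), axis=1),
            -np.inf,
        )
    return float(ts[np.argmax(ll)])


def p_by_repeated_squaring(model, t: float = 50.0, doublings: int = 13):
    """P(t) by repeated matrix squaring of P(t / 2^doublings) (no eigensystem)."""
    from scipy.linalg import expm

    p = expm(model.q * (t / 2**doublings))
    for _ in range(doublings):
        p = p @ p
    return p


def best_rotation_rmsd(x: np.ndarray, y: np.ndarray, n_angles: int = 3600) -> float:
    """2D rotation-grid search for the optimal rigid superposition RMSD."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    best = np.inf
    for theta in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        c, s = np.cos(theta), np.sin(theta)
        r = np.array([[c, -s], [s, c]])
        rmsd = np.sqrt(np.mean(np.sum((yc @ r - xc) ** 2, axis=1)))
        best = min(best, rmsd)
    return float(best)


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random binary tree with lengths in [0.1, 2]; returns (tree, labels)."""
    from seqspace.seqio import PhyloTree, TreeNode

    labels = [f"t{i:02d}" for i in range(n)]
    nodes = [TreeNode(name=lbl, length=float(rng.uniform(0.1, 2.0))) for lbl in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        root.add(x)
    return PhyloTree(root, rooted=False), labels
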