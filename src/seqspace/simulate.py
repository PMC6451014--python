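"""Forward simulation of protein families and planted embedding oracles.

Sequences are evolved site-independently along a tree under the
substitution model: the root is drawn from the stationary frequencies and
each branch applies one categorical draw per site from the corresponding
row of P(t * multiplier). No indels are generated — the intended use is
curated, essentially gapless domain alignments, and gap handling is
exercised by hand-written fixtures instead.

Randomness is counter-based: every branch gets its own stream keyed by the
hash of its descendant leaf set, so editing one part of a topology leaves
the draws in unrelated subtrees untouched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from seqspace.errors import ValidationError
from seqspace.models import AA_ORDER, SubstitutionModel, transition_matrix
from seqspace.seqio import DistanceMatrix, GroupAnnotation, Msa, PhyloTree, TreeNode


@dataclass(frozen=True)
class SimulatedFamily:
    """A tree with nominal branch lengths plus the alignment evolved on it.

    The expected number of substitutions on a branch equals its length
    times its rate multiplier (1 unless overridden), so groups with a
    multiplier > 1 emulate a higher mutational rate.
    """

    tree: PhyloTree
    msa: Msa
    model: SubstitutionModel
    seed: int
    rate_multipliers: dict[str, float] | None = None


def _branch_stream(seed: int, leafset: tuple[str, ...]) -> np.random.Generator:
    digest = hashlib.sha256(("|".join(sorted(leafset))).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _sample_children(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.shape[0])
    rows = cum[parent_states]
    return (rows < u[:, None]).sum(axis=1).astype(np.int64)


def _branch_multiplier(
    node: TreeNode, leafsets: dict[int, tuple[str, ...]], mult: dict[str, float]
) -> float:
    leaves = leafsets[id(node)]
    vals = {mult.get(name, 1.0) for name in leaves}
    return vals.pop() if len(vals) == 1 else 1.0


def evolve_sequences(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    rate_multipliers: dict[str, float] | None = None,
) -> SimulatedFamily:
    """Evolve an alignment along a tree under the model.

    ``rate_multipliers`` maps leaf names to rate scalars; a branch is
    scaled by m when every leaf below it carries the same multiplier m
    (clade-wise rates), and left unscaled on mixed branches.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    mult = rate_multipliers or {}
    if any(m <= 0 for m in mult.values()):
        raise ValidationError("rate multipliers must be positive")
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValidationError(f"missing branch length on {node.name!r}")

    leafsets: dict[int, tuple[str, ...]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = (node.name,)
        else:
            acc: list[str] = []
            for child in node.children:
                acc.extend(leafsets[id(child)])
            leafsets[id(node)] = tuple(acc)

    root_rng = _branch_stream(seed, ("__root__",) + leafsets[id(tree.root)])
    cum_pi = np.cumsum(model.pi)
    cum_pi[-1] = 1.0
    u = root_rng.random(n_sites)
    states: dict[int, np.ndarray] = {
        id(tree.root): (cum_pi[None, :] < u[:, None]).sum(axis=1).astype(np.int64)
    }

    for node in tree.preorder():
        if node.parent is None:
            continue
        m = _branch_multiplier(node, leafsets, mult)
        t_eff = node.length * m
        p = transition_matrix(model, t_eff)
        rng = _branch_stream(seed, leafsets[id(node)])
        states[id(node)] = _sample_children(states[id(node.parent)], p, rng)

    taxa: list[str] = []
    rows: list[str] = []
    for leaf in tree.leaves():
        taxa.append(leaf.name)
        rows.append("".join(AA_ORDER[s] for s in states[id(leaf)]))
    msa = Msa(tuple(taxa), tuple(rows))
    return SimulatedFamily(
        tree=tree, msa=msa, model=model, seed=seed, rate_multipliers=mult or None
    )


def planted_configuration(
    n: int, k: int, seed: int, scale: float = 1.0
) -> tuple[np.ndarray, DistanceMatrix]:
    """Seeded spherical point cloud plus its exact Euclidean distances.

    Serves as the embedding oracle: a k-dimensional Sammon map of the
    returned matrix should recover the configuration up to rigid motion.
    Distances are homogeneous in ``scale`` (same seed, doubled scale gives
    doubled distances).
    """
    if n < k + 1:
        raise ValidationError("need n >= k + 1 points")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n, k)) * scale
    labels = tuple(f"pt{i:03d}" for i in range(n))
    dmat = squareform(pdist(coords))
    return coords, DistanceMatrix(labels, dmat)


def _balanced_clade(names: list[str], branch: float) -> TreeNode:
    if len(names) == 1:
        return TreeNode(name=names[0], length=branch)
    mid = len(names) // 2
    node = TreeNode(length=branch)
    node.add(_balanced_clade(names[:mid], branch))
    node.add(_balanced_clade(names[mid:], branch))
    return node


def two_group_family(
    n_per_group: int = 8,
    rate_ratio: float = 5.0,
    depth: float = 0.5,
    n_sites: int = 250,
    seed: int = 0,
    model: SubstitutionModel | None = None,
) -> tuple[SimulatedFamily, GroupAnnotation]:
    """Two balanced clades, the second evolving ``rate_ratio`` times faster.

    ``depth`` is the nominal root-to-leaf path length (substitutions/site)
    in the slow clade; every branch of the fast clade is scaled by
    ``rate_ratio``, emulating a lineage with a much higher mutational
    rate. Leaves are annotated "slow"/"fast".
    """
    if n_per_group < 2:
        raise ValidationError("need at least 2 taxa per group")
    if rate_ratio < 1:
        raise ValidationError("rate_ratio must be >= 1")
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if model is None:
        from seqspace.models import build_dayhoff_model

        model = build_dayhoff_model()

    levels = max(1, int(np.ceil(np.log2(n_per_group))))
    branch = depth / (levels + 1)  # +1 for the clade stem
    slow_names = [f"slow_{i:02d}" for i in range(n_per_group)]
    fast_names = [f"fast_{i:02d}" for i in range(n_per_group)]
    root = TreeNode()
    slow_clade = _balanced_clade(slow_names, branch)
    fast_clade = _balanced_clade(fast_names, branch)
    slow_clade.length = branch
    fast_clade.length = branch
    root.add(slow_clade)
    root.add(fast_clade)
    tree = PhyloTree(root, rooted=True)

    mult = {name: 1.0 for name in slow_names}
    mult.update({name: float(rate_ratio) for name in fast_names})
    fam = evolve_sequences(tree, model, n_sites, seed, rate_multipliers=mult)
    ann = GroupAnnotation(
        groups={**{n: "slow" for n in slow_names}, **{n: "fast" for n in fast_names}},
        colors={"slow": "#1f77b4", "fast": "#d62728"},
    )
    return fam, ann
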