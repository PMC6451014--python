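"""Figure object: a phylogenetic tree drawn over a sequence-space embedding.

The scene combines three ingredients — leaf coordinates from a Sammon
embedding, a tree whose edges are drawn as links between points, and a
taxon->group annotation — plus quantitative diagnostics: per-group spread
(RMS pairwise embedded distance) and Procrustes superposition for
comparing configurations modulo translation/rotation/reflection, the
invariances under which such maps must be read.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd
from scipy.spatial.distance import pdist

from seqspace.errors import ValidationError
from seqspace.sammon import EmbeddingResult, _sammon_descent
from seqspace.seqio import DistanceMatrix, GroupAnnotation, PhyloTree
from seqspace.treebuild import all_node_distances

SCENE_SCHEMA_VERSION = 1

#: display convention: blue = monofunctional/slow group, red = bifunctional/fast
_DEFAULT_COLORS = {
    "monofunctional": "#1f77b4",
    "slow": "#1f77b4",
    "bifunctional": "#d62728",
    "fast": "#d62728",
}
_PALETTE = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e", "#8c564b"]


@dataclass(frozen=True)
class SceneNode:
    id: str
    name: str | None
    kind: str  # "leaf" | "internal"
    coords: tuple[float, ...]
    group: str | None = None
    color: str | None = None
    saturated: bool = False


@dataclass(frozen=True)
class OverlayScene:
    nodes: tuple[SceneNode, ...]
    edges: tuple[tuple[str, str], ...]  # (parent id, child id)
    provenance: dict = field(default_factory=dict)

    def node(self, node_id: str) -> SceneNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def leaf_coords(self) -> dict[str, tuple[float, ...]]:
        return {n.name: n.coords for n in self.nodes if n.kind == "leaf"}


def _group_colors(ann: GroupAnnotation | None) -> dict[str, str]:
    if ann is None:
        return {}
    colors = dict(ann.colors)
    palette = iter(_PALETTE)
    for g in ann.group_names():
        if g not in colors:
            colors[g] = _DEFAULT_COLORS.get(g.lower()) or next(palette)
    return colors


def overlay_tree(
    emb: EmbeddingResult,
    tree: PhyloTree,
    method: str = "centroid",
    dm: DistanceMatrix | None = None,
    ann: GroupAnnotation | None = None,
    saturated: frozenset[frozenset[str]] = frozenset(),
) -> OverlayScene:
    """Place a tree's edges over an embedding; leaf coordinates never move.

    ``centroid`` puts each internal node at the unweighted mean of its
    descendant leaves' coordinates (deterministic, parameter-free).
    ``joint`` embeds internal nodes by Sammon descent on an augmented
    matrix — leaf-leaf entries from the original distances ``dm``, any
    pair involving an internal node from patristic path lengths — with the
    leaf coordinates frozen at their input values.
    """
    leaf_names = set(tree.leaf_names())
    missing = sorted(leaf_names - set(emb.labels))
    if missing:
        raise ValidationError(f"tree leaves absent from embedding: {missing}")
    if method not in ("centroid", "joint"):
        raise ValueError(f"unknown overlay method {method!r}")
    if method == "joint" and dm is None:
        raise ValidationError("joint overlay requires the original distance matrix")

    nodes_po = list(tree.postorder())
    internal_ids: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        if not node.is_leaf:
            internal_ids[id(node)] = f"I{counter}"
            counter += 1

    def node_id(node) -> str:
        return node.name if node.is_leaf else internal_ids[id(node)]

    emb_index = {lbl: i for i, lbl in enumerate(emb.labels)}
    coords: dict[str, np.ndarray] = {}
    for node in nodes_po:
        if node.is_leaf:
            coords[node.name] = emb.coords[emb_index[node.name]]

    # centroid placement (also the joint method's initialization)
    leafsets: dict[int, list[str]] = {}
    for node in nodes_po:
        if node.is_leaf:
            leafsets[id(node)] = [node.name]
        else:
            acc: list[str] = []
            for child in node.children:
                acc.extend(leafsets[id(child)])
            leafsets[id(node)] = acc
            coords[internal_ids[id(node)]] = np.mean(
                [emb.coords[emb_index[nm]] for nm in acc], axis=0
            )

    if method == "joint":
        coords = _joint_placement(emb, tree, dm, internal_ids, coords)

    saturated_taxa = {t for pair in saturated for t in pair}
    groups = ann.groups if ann else {}
    colors = _group_colors(ann)
    scene_nodes: list[SceneNode] = []
    for node in tree.preorder():
        nid = node_id(node)
        g = groups.get(node.name) if node.is_leaf else None
        scene_nodes.append(
            SceneNode(
                id=nid,
                name=node.name,
                kind="leaf" if node.is_leaf else "internal",
                coords=tuple(float(v) for v in coords[nid]),
                group=g,
                color=colors.get(g) if g else None,
                saturated=node.is_leaf and node.name in saturated_taxa,
            )
        )
    edges = tuple(
        (node_id(parent), node_id(child)) for parent, child in tree.edges()
    )
    provenance = {
        "embedding_seed": emb.seed,
        "embedding_stress": emb.stress,
        "overlay_method": method,
    }
    return OverlayScene(tuple(scene_nodes), edges, provenance)


def _joint_placement(emb, tree, dm, internal_ids, init_coords):
    tnodes, tmat = all_node_distances(tree)
    order = [n for n in tnodes]  # postorder
    ids = [n.name if n.is_leaf else internal_ids[id(n)] for n in order]
    n_all = len(order)
    aug = np.zeros((n_all, n_all))
    dm_index = {lbl: i for i, lbl in enumerate(dm.labels)}
    for i in range(n_all):
        for j in range(i + 1, n_all):
            a, b = order[i], order[j]
            if a.is_leaf and b.is_leaf:
                v = dm.values[dm_index[a.name], dm_index[b.name]]
            else:
                v = tmat[i, j]
            v = max(v, 1e-9)  # Sammon weights require positive distances
            aug[i, j] = aug[j, i] = v
    x0 = np.array([init_coords[i_] for i_ in ids])
    free = np.array([not n.is_leaf for n in order])
    x, _trace, _conv = _sammon_descent(
        x0, aug, alpha=0.3, max_iter=200, tol=1e-9, free_mask=free
    )
    out = dict(init_coords)
    for pos, i_ in enumerate(ids):
        if free[pos]:
            out[i_] = x[pos]
        else:
            out[i_] = x0[pos]  # frozen leaves, bit-exact
    return out


# ---------------------------------------------------------------------------
# group spread
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpread:
    group: str
    n: int
    spread: float | None          # RMS pairwise embedded distance; None if n < 2
    relative: float | None        # spread / global RMS


@dataclass(frozen=True)
class SpreadReport:
    groups: tuple[GroupSpread, ...]
    global_rms: float

    def by_group(self) -> dict[str, GroupSpread]:
        return {g.group: g for g in self.groups}


def group_spread(emb: EmbeddingResult, ann: GroupAnnotation) -> SpreadReport:
    """Per-group RMS pairwise embedded distance, relative to the global RMS.

    The relative spread is invariant to rigid motion and global rescaling
    of the embedding. Singleton groups are reported with undefined spread
    rather than dropped.
    """
    unknown = sorted(set(ann.groups) - set(emb.labels))
    if unknown:
        raise ValidationError(f"annotation references unknown taxa: {unknown}")
    sizes = [len(ann.members(g)) for g in ann.group_names()]
    if not any(s >= 2 for s in sizes):
        raise ValidationError("need at least one group with >= 2 taxa")

    all_d = pdist(emb.coords)
    global_rms = float(np.sqrt(np.mean(all_d**2)))
    index = {lbl: i for i, lbl in enumerate(emb.labels)}
    out: list[GroupSpread] = []
    for g in ann.group_names():
        members = ann.members(g)
        if len(members) < 2:
            out.append(GroupSpread(g, len(members), None, None))
            continue
        pts = emb.coords[[index[m] for m in members]]
        d = pdist(pts)
        spread = float(np.sqrt(np.mean(d**2)))
        rel = spread / global_rms if global_rms > 0 else math.nan
        out.append(GroupSpread(g, len(members), spread, rel))
    return SpreadReport(tuple(out), global_rms)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_align(
    x: np.ndarray, y: np.ndarray, allow_reflection: bool = True
) -> tuple[np.ndarray, float]:
    """Rigid superposition of configuration Y onto X (no scaling fitted).

    Finds the translation plus orthogonal map (rotation, and reflection if
    allowed) of Y minimizing the RMSD to X. Scale is deliberately not
    fitted: Sammon output units approximate substitutions/site and are
    meaningful. Returns ``(aligned_y, rmsd)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, _s, vt = svd(yc.T @ xc)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.ones(x.shape[1])
        d[-1] = -1.0  # flip the smallest singular direction
        r = u @ np.diag(d) @ vt
    aligned = yc @ r + x.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - x) ** 2, axis=1))))
    return aligned, rmsd


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _scene_doc(scene: OverlayScene) -> dict:
    return {
        "schema_version": SCENE_SCHEMA_VERSION,
        "nodes": [
            {
                "id": n.id,
                "name": n.name,
                "kind": n.kind,
                "coords": list(n.coords),
                "group": n.group,
                "color": n.color,
                "saturated": n.saturated,
            }
            for n in scene.nodes
        ],
        "edges": [list(e) for e in scene.edges],
        "provenance": scene.provenance,
    }


def export_scene(scene: OverlayScene, path: str, format: str = "json") -> None:
    """Write a scene as JSON, a TSV bundle, or a self-contained 3D HTML view.

    ``tsv_bundle`` treats ``path`` as a directory and writes points.tsv
    (one row per tree node), edges.tsv and groups.tsv. Scenes without any
    annotation export with the single default group "all".
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_scene_doc(scene), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv_bundle":
        os.makedirs(path, exist_ok=True)
        k = len(scene.nodes[0].coords)
        axes = ["x", "y", "z"][:k]
        with open(os.path.join(path, "points.tsv"), "w") as fh:
            fh.write("id\tname\tkind\t" + "\t".join(axes) + "\tsaturated\n")
            for n in scene.nodes:
                cs = "\t".join(f"{v:.17g}" for v in n.coords)
                fh.write(
                    f"{n.id}\t{n.name or ''}\t{n.kind}\t{cs}\t{int(n.saturated)}\n"
                )
        with open(os.path.join(path, "edges.tsv"), "w") as fh:
            fh.write("parent\tchild\n")
            for a, b in scene.edges:
                fh.write(f"{a}\t{b}\n")
        with open(os.path.join(path, "groups.tsv"), "w") as fh:
            fh.write("taxon\tgroup\tcolor\n")
            for n in scene.nodes:
                if n.kind == "leaf":
                    fh.write(
                        f"{n.name}\t{n.group or 'all'}\t{n.color or _PALETTE[0]}\n"
                    )
    elif format == "html3d":
        _export_html3d(scene, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_scene(path: str) -> OverlayScene:
    with open(path) as fh:
        doc = json.load(fh)
    nodes = tuple(
        SceneNode(
            id=n["id"],
            name=n["name"],
            kind=n["kind"],
            coords=tuple(n["coords"]),
            group=n["group"],
            color=n["color"],
            saturated=n["saturated"],
        )
        for n in doc["nodes"]
    )
    edges = tuple((a, b) for a, b in doc["edges"])
    return OverlayScene(nodes, edges, doc.get("provenance", {}))


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>sequence space</title>
<style>body{margin:0;font-family:sans-serif}#c{display:block}</style></head>
<body><canvas id="c"></canvas><script>
const scene = __SCENE__;
const cv = document.getElementById('c'), ctx = cv.getContext('2d');
cv.width = innerWidth; cv.height = innerHeight;
let ax = 0.5, ay = 0.4, drag = null;
const pts = scene.nodes.map(n => ({p: n.coords.concat([0,0,0]).slice(0,3), n: n}));
const ctr = [0,1,2].map(q => pts.reduce((s,o)=>s+o.p[q],0)/pts.length);
const span = Math.max(...pts.map(o => Math.hypot(o.p[0]-ctr[0],o.p[1]-ctr[1],o.p[2]-ctr[2])), 1e-9);
function proj(p){
  let x=p[0]-ctr[0], y=p[1]-ctr[1], z=p[2]-ctr[2];
  let x1=x*Math.cos(ax)+z*Math.sin(ax), z1=-x*Math.sin(ax)+z*Math.cos(ax);
  let y1=y*Math.cos(ay)+z1*Math.sin(ay), z2=-y*Math.sin(ay)+z1*Math.cos(ay);
  const s = 0.35*Math.min(cv.width,cv.height)/span;
  return [cv.width/2+x1*s, cv.height/2-y1*s, z2];
}
function draw(){
  ctx.clearRect(0,0,cv.width,cv.height);
  const pos = new Map(pts.map(o=>[o.n.id, proj(o.p)]));
  ctx.strokeStyle='#999';
  for(const [a,b] of scene.edges){
    const pa=pos.get(a), pb=pos.get(b);
    ctx.beginPath(); ctx.moveTo(pa[0],pa[1]); ctx.lineTo(pb[0],pb[1]); ctx.stroke();
  }
  for(const o of pts){
    const p=pos.get(o.n.id);
    if(o.n.kind==='leaf'){
      ctx.fillStyle=o.n.color||'#1f77b4';
      ctx.beginPath(); ctx.arc(p[0],p[1],4,0,6.283); ctx.fill();
      ctx.fillStyle='#222'; ctx.fillText(o.n.name||'', p[0]+6, p[1]+3);
    } else {
      ctx.fillStyle='#bbb';
      ctx.beginPath(); ctx.arc(p[0],p[1],2,0,6.283); ctx.fill();
    }
  }
}
cv.onmousedown=e=>drag=[e.clientX,e.clientY];
cv.onmousemove=e=>{if(drag){ax+=(e.clientX-drag[0])*0.01;ay+=(e.clientY-drag[1])*0.01;drag=[e.clientX,e.clientY];draw();}};
cv.onmouseup=()=>drag=null;
draw();
</script></body></html>
"""


def _export_html3d(scene: OverlayScene, path: str) -> None:
    doc = json.dumps(_scene_doc(scene))
    with open(path, "w") as fh:
        fh.write(_HTML_TEMPLATE.replace("__SCENE__", doc))
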