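import json

import numpy as np
import pytest
from scipy.stats import ortho_group

from seqspace.errors import ValidationError
from seqspace.sammon import EmbeddingResult
from seqspace.scene import (
    export_scene,
    group_spread,
    import_scene,
    overlay_tree,
    procrustes_align,
)
from seqspace.seqio import DistanceMatrix, GroupAnnotation, read_newick
from seqspace.treebuild import patristic_distances

from oracles import best_rotation_rmsd


def make_emb(labels, coords, seed=0):
    coords = np.asarray(coords, float)
    return EmbeddingResult(
        labels=tuple(labels),
        coords=coords,
        stress=0.0,
        n_iter=0,
        converged=True,
        restart_stresses=(0.0,),
        seed=seed,
    )


class TestOverlay:
    def test_cherry_centroid_midpoint(self):
        tree = read_newick("(A:1,B:1);")
        emb = make_emb(["A", "B"], [[0, 0, 0], [2, 0, 0]])
        scene = overlay_tree(emb, tree)
        internal = [n for n in scene.nodes if n.kind == "internal"]
        assert internal[0].coords == (1.0, 0.0, 0.0)

    def test_star_root_at_centroid(self):
        tree = read_newick("(A:1,B:1,C:1);")
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        scene = overlay_tree(make_emb(["A", "B", "C"], pts), tree)
        root = [n for n in scene.nodes if n.kind == "internal"][0]
        assert np.allclose(root.coords, pts.mean(axis=0))

    @pytest.mark.parametrize("method", ["centroid", "joint"])
    def test_leaf_coords_bit_exact(self, method, rng):
        tree = read_newick("((A:1,B:2):1,(C:3,D:4):1);")
        coords = rng.normal(size=(4, 3))
        emb = make_emb(["A", "B", "C", "D"], coords)
        dm = patristic_distances(tree)
        scene = overlay_tree(emb, tree, method=method, dm=dm)
        got = scene.leaf_coords()
        for i, lbl in enumerate(emb.labels):
            assert got[lbl] == tuple(coords[i])

    def test_edges_match_tree(self):
        tree = read_newick("((A:1,B:2):1,C:3);")
        emb = make_emb(["A", "B", "C"], np.eye(3))
        scene = overlay_tree(emb, tree)
        assert len(scene.edges) == len(tree.edges())
        ids = {n.id for n in scene.nodes}
        assert all(a in ids and b in ids for a, b in scene.edges)

    def test_centroid_commutes_with_rigid_motion(self, rng):
        tree = read_newick("((A:1,B:2):1,(C:3,D:4):1);")
        coords = rng.normal(size=(4, 3))
        r = ortho_group.rvs(3, random_state=rng)
        shift = rng.normal(size=3)
        s1 = overlay_tree(make_emb(list("ABCD"), coords), tree)
        s2 = overlay_tree(make_emb(list("ABCD"), coords @ r + shift), tree)
        for n1, n2 in zip(s1.nodes, s2.nodes):
            if n1.kind == "internal":
                moved = np.array(n1.coords) @ r + shift
                assert np.allclose(moved, n2.coords, atol=1e-12)

    def test_missing_leaf_listed(self):
        tree = read_newick("(A:1,Z:1);")
        emb = make_emb(["A", "B"], np.zeros((2, 2)))
        with pytest.raises(ValidationError, match="Z"):
            overlay_tree(emb, tree)


class TestGroupSpread:
    def test_coincident_group_zero(self):
        emb = make_emb(["a", "b", "c"], [[1, 1], [1, 1], [0, 0]])
        ann = GroupAnnotation({"a": "g1", "b": "g1", "c": "g2"})
        rep = group_spread(emb, ann).by_group()
        assert rep["g1"].spread == 0.0
        assert rep["g2"].n == 1 and rep["g2"].spread is None

    def test_two_point_group(self):
        emb = make_emb(["a", "b"], [[0, 0], [2, 0]])
        ann = GroupAnnotation({"a": "g", "b": "g"})
        assert group_spread(emb, ann).by_group()["g"].spread == pytest.approx(2.0)

    def test_unit_square_hand_value(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        emb = make_emb(list("abcd"), pts)
        ann = GroupAnnotation({t: "sq" for t in "abcd"})
        rep = group_spread(emb, ann)
        # RMS of {1,1,1,1,sqrt2,sqrt2} = sqrt(8/6)
        assert rep.by_group()["sq"].spread == pytest.approx(np.sqrt(8 / 6))
        assert rep.by_group()["sq"].relative == pytest.approx(1.0)

    def test_relative_spread_scale_and_rigid_invariant(self, rng):
        coords = rng.normal(size=(8, 3))
        ann = GroupAnnotation(
            {f"t{i}": ("g1" if i < 4 else "g2") for i in range(8)}
        )
        labels = [f"t{i}" for i in range(8)]
        base = group_spread(make_emb(labels, coords), ann)
        r = ortho_group.rvs(3, random_state=rng)
        moved = group_spread(make_emb(labels, 3.7 * coords @ r + 5), ann)
        for g1, g2 in zip(base.groups, moved.groups):
            assert g1.relative == pytest.approx(g2.relative, abs=1e-12)

    def test_unknown_taxon_rejected(self):
        emb = make_emb(["a", "b"], np.zeros((2, 2)))
        ann = GroupAnnotation({"a": "g", "zz": "g"})
        with pytest.raises(ValidationError, match="zz"):
            group_spread(emb, ann)


class TestProcrustes:
    def test_rotated_copy_recovered(self, rng):
        x = rng.normal(size=(6, 3))
        r = ortho_group.rvs(3, random_state=rng)
        while np.linalg.det(r) < 0:
            r = ortho_group.rvs(3, random_state=rng)
        _, rmsd = procrustes_align(x, x @ r + 1.5, allow_reflection=False)
        assert rmsd < 1e-10

    def test_mirror_needs_reflection(self, rng):
        x = rng.normal(size=(6, 2))
        y = x.copy()
        y[:, 0] *= -1
        _, rmsd_ref = procrustes_align(x, y, allow_reflection=True)
        _, rmsd_rot = procrustes_align(x, y, allow_reflection=False)
        assert rmsd_ref < 1e-10
        assert rmsd_rot > 1e-3

    def test_scaled_square_matches_rotation_grid_oracle(self):
        x = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        y = 2 * x
        _, rmsd = procrustes_align(x, y, allow_reflection=False)
        oracle = best_rotation_rmsd(x, y)
        assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            procrustes_align(np.zeros((3, 2)), np.zeros((4, 2)))


class TestExport:
    @pytest.fixture()
    def scene(self, rng):
        tree = read_newick("((A:1,B:2):1,C:3);")
        emb = make_emb(["A", "B", "C"], rng.normal(size=(3, 3)))
        ann = GroupAnnotation({"A": "slow", "B": "slow", "C": "fast"})
        return overlay_tree(emb, tree, ann=ann)

    def test_json_roundtrip(self, scene, tmp_path):
        p = str(tmp_path / "scene.json")
        export_scene(scene, p, "json")
        back = import_scene(p)
        assert back.nodes == scene.nodes
        assert back.edges == scene.edges

    def test_tsv_bundle_counts(self, scene, tmp_path):
        d = str(tmp_path / "bundle")
        export_scene(scene, d, "tsv_bundle")
        points = open(f"{d}/points.tsv").read().splitlines()
        assert len(points) - 1 == len(scene.nodes)
        edges = open(f"{d}/edges.tsv").read().splitlines()
        assert len(edges) - 1 == len(scene.edges)

    def test_unannotated_scene_gets_default_group(self, tmp_path, rng):
        tree = read_newick("(A:1,B:1);")
        scene = overlay_tree(make_emb(["A", "B"], rng.normal(size=(2, 2))), tree)
        d = str(tmp_path / "bundle")
        export_scene(scene, d, "tsv_bundle")
        groups = [ln.split("\t")[1] for ln in
                  open(f"{d}/groups.tsv").read().splitlines()[1:]]
        assert set(groups) == {"all"}

    def test_html_is_selfcontained(self, scene, tmp_path):
        p = str(tmp_path / "scene.html")
        export_scene(scene, p, "html3d")
        text = open(p).read()
        assert "<canvas" in text and "http" not in text.split("charset")[1][:2000]
        doc = json.loads(text.split("const scene = ")[1].split(";\n")[0])
        assert len(doc["nodes"]) == len(scene.nodes)
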