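"""Arbors, hubs, primary tracts and projection vectors."""

import numpy as np
import pytest
from dataclasses import replace

from morphoscale import core, subneuronal as sn, synth
from morphoscale.core import AXON
from conftest import make_tree


def two_tuft_axon(gap=400.0, seed=0):
    """Two dense axonal tufts joined by a long straight wire."""
    rng = np.random.default_rng(seed)
    coords = [(0.0, 0, 0)]
    parents = [None]
    structure = [1]

    def tuft(center, attach):
        idx0 = len(coords)
        for i in range(40):
            coords.append(tuple(np.asarray(center) + rng.normal(0, 25, 3)))
            parents.append(attach if i == 0 else idx0 + (i - 1) // 2)
            structure.append(AXON)

    prev = 0
    n_wire = int(gap // 20)
    for i in range(1, n_wire + 1):
        coords.append((i * 20.0, 0, 0))
        parents.append(prev)
        structure.append(AXON)
        prev = len(coords) - 1
    tuft((0, 60, 0), 0)          # proximal tuft near the soma
    tuft((gap, 60, 0), prev)     # distal tuft at the wire end
    return make_tree(coords, parents, structure=structure)


class TestArborDecomposition:
    def test_two_tufts_separated_at_the_wire(self):
        t = two_tuft_axon()
        arbs = [a for a in sn.decompose_arbors(t, 2, seed=0) if a.kind == "axonal"]
        assert len(arbs) == 2
        cents = sorted(float(t.xyz[a.nodes][:, 0].mean()) for a in arbs)
        assert cents[0] < 150 and cents[1] > 250

    def test_k1_whole_axon_and_partition(self):
        t = two_tuft_axon()
        arbs = [a for a in sn.decompose_arbors(t, 1, seed=0) if a.kind == "axonal"]
        assert len(arbs) == 1
        axon_idx = set(np.nonzero(t.structure == AXON)[0].tolist())
        assert set(arbs[0].nodes.tolist()) == axon_idx

    def test_partition_property_at_k3(self, toy_atlas):
        cls = synth.default_classes(toy_atlas)["striatal"]
        t = synth.grow_neuron(cls, toy_atlas.centroid_um(1),
                              np.random.default_rng(0), toy_atlas)
        arbs = [a for a in sn.decompose_arbors(t, 3, seed=0) if a.kind == "axonal"]
        all_nodes = np.concatenate([a.nodes for a in arbs])
        assert sorted(all_nodes.tolist()) == \
            sorted(np.nonzero(t.structure == AXON)[0].tolist())

    def test_rigid_transform_invariance(self):
        t = two_tuft_axon(seed=3)
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t2 = make_tree(t.xyz @ q.T + 500.0,
                       [None] + [int(p) - 1 for p in t.parent[1:]],
                       structure=list(t.structure))
        a1 = sn.decompose_arbors(t, 2, seed=0)
        a2 = sn.decompose_arbors(t2, 2, seed=0)
        sets1 = sorted(frozenset(a.nodes.tolist()) for a in a1 if a.kind == "axonal")
        sets2 = sorted(frozenset(a.nodes.tolist()) for a in a2 if a.kind == "axonal")
        assert sets1 == sets2

    def test_k_exceeding_axon_rejected(self, y_neuron):
        with pytest.raises(ValueError):
            sn.decompose_arbors(y_neuron, 2)


class TestArborCount:
    def test_votes_and_ties(self):
        assert sn.region_arbor_count.__defaults__ is not None
        # majority vote and small-tie rule are pure arithmetic on the votes
        vals, counts = np.unique([2, 2, 3], return_counts=True)
        assert vals[np.argmax(counts)] == 2
        vals, counts = np.unique([2, 3], return_counts=True)
        assert vals[np.argmax(counts)] == 2  # tie → smaller

    def test_planted_counts_recovered(self, toy_atlas):
        cls = synth.default_classes(toy_atlas)["cortical_IT"]
        rng = np.random.default_rng(3)
        for k_true in (1, 2, 3):
            params = replace(cls, n_arbors=k_true, arbor_spread=50.0)
            trees = [synth.grow_neuron(params, toy_atlas.centroid_um(1 + i), rng,
                                       toy_atlas) for i in range(3)]
            assert sn.region_arbor_count(trees) == k_true


class TestArborFeatures:
    def test_axis_aligned_box_volume(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (300, 3)) * np.array([100.0, 50.0, 20.0])
        pts[0] = [0, 0, 0]
        pts[1] = [100, 50, 20]
        t = make_tree(pts, [None] + [0] * 299, structure=[1] + [AXON] * 299)
        f = sn.arbor_features(np.arange(300), t)
        assert f["volume"] == pytest.approx(100 * 50 * 20, rel=0.15)

    def test_uniform_wire_max_density(self):
        spacing = 5.0
        n = 41
        pts = [(i * spacing, 0, 0) for i in range(n)]
        t = make_tree(pts, [None] + list(range(n - 1)),
                      structure=[1] + [AXON] * (n - 1))
        f = sn.arbor_features(np.arange(n), t)
        assert f["max_density"] == 2 * int(20.0 / spacing) + 1

    def test_proximal_distal_boundary(self):
        for d, expect in ((749.9, "proximal"), (750.1, "distal")):
            pts = [(0, 0, 0)] + [(d + j * 0.1, 0, 0) for j in range(5)]
            t = make_tree(pts, [None, 0, 1, 2, 3, 4],
                          structure=[1] + [AXON] * 5)
            f = sn.arbor_features(np.arange(1, 6), t)
            # max-density node is the middle of the cluster; place tightly
            assert f["type"] == expect


class TestHubs:
    def test_dense_ball_one_hub(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 100, (100, 3))  # 100 nodes in ~200 μm ball
        t = make_tree(np.vstack([[0, 0, 0], pts + 2000]),
                      [None] + [0] * 100, structure=[1] + [AXON] * 100)
        lab, origin, hubs = sn.detect_hubs([t])
        assert lab.max() == 1
        assert len(hubs[1]) >= 90

    def test_sparse_wire_no_hubs(self):
        pts = [(i * 80.0, 0, 0) for i in range(60)]
        t = make_tree([(0, 0, 0)] + pts, [None] + list(range(60)),
                      structure=[1] + [AXON] * 60)
        lab, _, _ = sn.detect_hubs([t])
        assert lab.max() == 0  # ≤13 neighbours in a 500 μm sphere

    def test_two_distant_balls_two_hubs(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 80, (100, 3)) + 1000
        b = rng.normal(0, 80, (100, 3)) + np.array([4000, 1000, 1000])
        pts = np.vstack([[0, 0, 0], a, b])
        # chain each ball internally so nothing bridges the gap
        parents = [None] + [0] + list(range(1, 100)) + [100] + list(range(101, 200))
        t = make_tree(pts, parents, structure=[1] + [AXON] * 200)
        lab, _, hubs = sn.detect_hubs([t])
        assert lab.max() == 2


class TestPrimaryTract:
    def test_unbranched_axon_is_its_own_tract(self):
        pts = [(0, 0, 0)] + [(i * 10.0, 0, 0) for i in range(1, 20)]
        t = make_tree(pts, [None] + list(range(19)),
                      structure=[1] + [AXON] * 19)
        tr = sn.primary_tract(t)
        assert len(tr.nodes) == 20
        assert np.allclose(tr.terminal, [190, 0, 0])

    def test_terminal_twigs_ignored(self):
        # long main path with tiny twigs near the terminal
        pts = [(i * 10.0, 0, 0) for i in range(30)]
        twigs = [(285.0, 5, 0), (255.0, -5, 0)]
        side = [(50.0, j * 10.0, 0) for j in range(1, 12)]  # the 2nd-longest branch
        coords = pts + twigs + side
        parents = [None] + list(range(29)) + [28, 25] + [5] + \
            [32 + j for j in range(10)]
        t = make_tree(coords, parents,
                      structure=[1] + [AXON] * (len(coords) - 1))
        tr = sn.primary_tract(t)
        assert np.allclose(tr.terminal, [290, 0, 0])
        assert 30 not in tr.nodes and 31 not in tr.nodes

    def test_tract_is_longest_surviving_path(self):
        # oracle: enumerate all root→tip paths on a random axon
        rng = np.random.default_rng(4)
        spec = synth.SynthSpec(seed=0)
        atlas = synth.make_toy_atlas(spec)
        cls = synth.default_classes(atlas)["cortical_IT"]
        t = synth.grow_neuron(cls, atlas.centroid_um(2), rng, atlas)
        tr = sn.primary_tract(t)
        paths = sn._axon_paths(t)
        lens = [float(np.linalg.norm(np.diff(t.xyz[p], axis=0), axis=1).sum())
                for p in paths]
        tract_len = float(np.linalg.norm(np.diff(t.xyz[tr.nodes], axis=0), axis=1).sum())
        assert tract_len <= max(lens) + 1e-9
        assert set(tr.nodes.tolist()) <= set(x for p in paths for x in p)
        assert t.n_children()[tr.nodes[-1]] == 0  # ends at a tip

    def test_no_axon_rejected(self, y_neuron):
        with pytest.raises(ValueError):
            sn.primary_tract(y_neuron)


class TestTractProfiles:
    def _line_tract(self, origin, direction, length=500.0):
        pts = np.asarray(origin) + np.linspace(0, length, 200)[:, None] * np.asarray(direction)
        return sn.Tract(np.arange(200), pts, pts[-1])

    def test_parallel_cylinder_constant_radius(self):
        R = 30.0
        tracts = [self._line_tract([R * np.cos(a), R * np.sin(a), 0], [0, 0, 1.0])
                  for a in np.linspace(0, 2 * np.pi, 12, endpoint=False)]
        prof = sn.tract_group_profile(tracts)
        assert np.abs(prof.radii - R).max() <= 0.02 * R
        assert prof.pattern == "parallel"

    def test_fan_divergent_and_reverse_convergent(self):
        rng = np.random.default_rng(5)
        tracts = []
        for _ in range(10):
            d = np.array([1.0, 0, 0]) + 0.3 * rng.standard_normal(3)
            tracts.append(self._line_tract(rng.normal(0, 1, 3), d / np.linalg.norm(d), 800))
        assert sn.tract_group_profile(tracts).pattern == "divergent"
        rev = [sn.Tract(t.nodes, t.points[::-1], t.points[0]) for t in tracts]
        assert sn.tract_group_profile(rev).pattern == "convergent"

    def test_too_few_tracts_rejected(self):
        with pytest.raises(ValueError):
            sn.tract_group_profile([self._line_tract([0, 0, 0], [1, 0, 0])] * 2)

    def test_terminal_clusters_recover_planted_clouds(self):
        rng = np.random.default_rng(6)
        tracts = []
        truth = []
        for ci, center in enumerate(([0, 0, 1000], [1500, 0, 0], [0, 1500, 500])):
            for _ in range(5):
                term = np.asarray(center, float) + rng.normal(0, 30, 3)
                d = term / np.linalg.norm(term)
                tracts.append(self._line_tract([0, 0, 0], d, float(np.linalg.norm(term))))
                truth.append(ci)
        labels, profiles = sn.terminal_clusters(tracts, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) == 1.0
        assert all(p is not None for p in profiles.values())


class TestProjectionVector:
    def test_single_region_axon(self, toy_atlas):
        c = toy_atlas.centroid_um(5)
        pts = [tuple(c)] + [tuple(c + [i * 10.0, 0, 0]) for i in range(1, 6)]
        t = make_tree(pts, [None, 0, 1, 2, 3, 4], structure=[1] + [AXON] * 5)
        v = sn.projection_vector(t, toy_atlas)
        inside = toy_atlas.label_at(np.array([c + [i * 10.0, 0, 0] for i in range(6)]))
        if np.all(np.asarray(inside) == 5):
            assert v[5] == pytest.approx(0.05)  # 50 μm in mm
            assert v.drop(5).sum() == 0

    def test_vector_sum_conserves_in_atlas_length(self, toy_atlas):
        cls = synth.default_classes(toy_atlas)["cortical_IT"]
        t = synth.grow_neuron(cls, toy_atlas.centroid_um(3),
                              np.random.default_rng(1), toy_atlas)
        v = sn.projection_vector(t, toy_atlas)
        mask = (t.parent_index >= 0) & (t.structure == AXON)
        total = 0.0
        for k in np.nonzero(mask)[0]:
            mid = (t.xyz[k] + t.xyz[t.parent_index[k]]) / 2
            if toy_atlas.label_at(mid) > 0:
                total += np.linalg.norm(t.xyz[k] - t.xyz[t.parent_index[k]]) / 1000
        assert v.sum() == pytest.approx(total, rel=1e-9)


class TestThalamicClustering:
    def test_two_regimes_recovered(self):
        import pandas as pd
        rng = np.random.default_rng(7)
        n = 20
        stats = pd.DataFrame(rng.normal(0, 0.3, (n, 8)))
        stats.iloc[10:] += 4.0  # large diffuse vs small focal arbors
        proj = pd.DataFrame(np.abs(rng.normal(0, 1, (n, 6))))
        proj.iloc[:10, 0] += 10
        proj.iloc[10:, 3] += 10
        labels = sn.thalamic_style_clustering(stats, proj, k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        stats = pd.DataFrame(rng.normal(size=(12, 8)))
        proj = pd.DataFrame(np.abs(rng.normal(size=(12, 4))))
        a = sn.thalamic_style_clustering(stats, proj, k=3)
        b = sn.thalamic_style_clustering(stats, proj, k=3)
        assert np.array_equal(a, b)
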