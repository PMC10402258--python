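"""Bouton detection, TEB/EPB typing and branch-level statistics."""

import numpy as np
import pandas as pd
import pytest

from morphoscale import boutons as bt, core, synth
from morphoscale.boutons import BoutonConfig
from morphoscale.core import AXON
from conftest import make_tree


def axon_line(n=101, spacing=1.0):
    pts = [(i * spacing, 0, 0) for i in range(n)]
    return make_tree(pts, [None] + list(range(n - 1)),
                     radii=[3.0] + [0.5] * (n - 1),
                     structure=[1] + [AXON] * (n - 1))


def flat_profiles(tree, intensity=150.0, radius=0.5):
    return pd.DataFrame({
        "intensity": np.full(tree.n_nodes, intensity),
        "radius": np.full(tree.n_nodes, radius),
        "axonal": tree.structure == AXON,
    })


def bump_profiles(tree, arcs, amp=100.0, rfactor=2.5, base_r=0.5):
    prof = flat_profiles(tree, 100.0, base_r)
    d = tree.path_dist_to_root()
    for a in arcs:
        bump = np.exp(-0.5 * ((d - a) / 1.5) ** 2)
        prof["intensity"] += amp * bump
        prof["radius"] += base_r * (rfactor - 1) * bump
    return prof


class TestDetection:
    def test_flat_profiles_no_boutons(self):
        t = axon_line()
        bs = bt.detect_boutons(t, flat_profiles(t))
        assert len(bs) == 0

    def test_planted_bumps_found_at_positions(self):
        t = axon_line()
        arcs = [20.0, 45.0, 70.0]
        bs = bt.detect_boutons(t, bump_profiles(t, arcs))
        assert len(bs) == 3
        got = sorted(bs.boutons["path_dist"])
        assert np.allclose(got, arcs, atol=1.0)

    def test_dim_bumps_filtered_by_intensity(self):
        t = axon_line()
        prof = bump_profiles(t, [50.0], amp=10.0)  # peak 110 ≤ 120
        bs = bt.detect_boutons(t, prof)
        assert len(bs) == 0

    def test_thin_bumps_filtered_by_radius_ratio(self):
        t = axon_line()
        prof = bump_profiles(t, [50.0], rfactor=1.3)
        bs = bt.detect_boutons(t, prof)
        assert len(bs) == 0

    def test_close_pair_deduplicated(self):
        t = axon_line(spacing=0.5, n=201)
        cfg = BoutonConfig(voxel_um=1.0)  # dedupe window 5 μm
        bs = bt.detect_boutons(t, bump_profiles(t, [50.0, 53.0]), cfg)
        assert len(bs) == 1

    def test_monotone_in_intensity_floor(self):
        t = axon_line()
        prof = bump_profiles(t, [20.0, 45.0, 70.0])
        lo = bt.detect_boutons(t, prof, BoutonConfig(intensity_min=120))
        hi = bt.detect_boutons(t, prof, BoutonConfig(intensity_min=190))
        assert len(hi) <= len(lo)
        assert set(hi.boutons["node"]) <= set(lo.boutons["node"])

    def test_missing_profiles_rejected(self):
        with pytest.raises(ValueError):
            bt.detect_boutons(axon_line(), None)


class TestTyping:
    def test_tip_bouton_is_teb_midshaft_is_epb(self):
        t = axon_line()
        bs = bt.detect_boutons(t, bump_profiles(t, [50.0, 99.0]))
        by_pos = bs.boutons.sort_values("path_dist")
        assert list(by_pos["type"]) == ["EPB", "TEB"]

    def test_tau_zero_only_exact_tips(self):
        t = axon_line()
        cfg = BoutonConfig(teb_tau_um=0.0)
        bs = bt.detect_boutons(t, bump_profiles(t, [97.0]), cfg)
        assert (bs.boutons["type"] == "EPB").all()


class TestRadialDistribution:
    def test_histogram_sums_to_one(self):
        t = axon_line()
        bs = bt.detect_boutons(t, bump_profiles(t, [20.0, 45.0, 70.0]))
        out = bt.radial_distribution(bs)
        assert out["hist"].sum() == pytest.approx(1.0)
        assert not out["empty"]

    def test_zero_boutons_flagged_empty(self):
        t = axon_line()
        bs = bt.detect_boutons(t, flat_profiles(t))
        assert bt.radial_distribution(bs)["empty"]

    def test_uniform_boutons_quarter_shares(self):
        t = axon_line(n=1001)
        arcs = list(np.arange(10.0, 991.0, 10.0))
        bs = bt.detect_boutons(t, bump_profiles(t, arcs))
        share = bt.radial_distribution(bs)["quartile_share"]
        assert np.allclose(share, 0.25, atol=0.05)


class TestRadar:
    def _sets(self):
        out = []
        for arcs in ([20.0, 45.0], [20.0, 45.0, 70.0, 95.0]):
            t = axon_line()
            out.append(bt.detect_boutons(t, bump_profiles(t, arcs)))
        return out

    def test_group_extremes_scale_to_0_and_100(self):
        sets = self._sets()
        scaled, raw = bt.radar_features(sets, ["g1", "g2"])
        assert scaled.loc["g2", "avg_n_boutons"] == 100.0
        assert scaled.loc["g1", "avg_n_boutons"] == 0.0
        assert not scaled.attrs["degenerate"]

    def test_single_group_degenerate(self):
        sets = self._sets()
        scaled, _ = bt.radar_features(sets, ["g", "g"])
        assert scaled.attrs["degenerate"]
        assert (scaled.to_numpy() == 0).all()

    def test_teb_ratio_bounded(self):
        sets = self._sets()
        _, raw = bt.radar_features(sets, ["g1", "g2"])
        assert ((raw["teb_ratio"] >= 0) & (raw["teb_ratio"] <= 1)).all()


class TestBranchStats:
    def _forked_axon(self):
        """Axon bifurcating into two 50 μm children."""
        pts = [(0, 0, 0)] + [(i * 1.0, 0, 0) for i in range(1, 51)] + \
            [(50 + i, 5, 0) for i in range(1, 51)] + \
            [(50 + i, -5, 0) for i in range(1, 51)]
        parents = [None] + list(range(50)) + [50] + list(range(51, 100)) + \
            [50] + list(range(101, 150))
        return make_tree(pts, parents, radii=[3.0] + [0.5] * 150,
                         structure=[1] + [AXON] * 150)

    def test_bifurcation_types(self):
        t = self._forked_axon()
        d = t.path_dist_to_root()
        cases = {
            "B0": [60.0, 60.5],  # a bouton on each child — arc positions
            "B2": [20.0],
        }
        # boutons on both children (they run parallel; plant by node index)
        prof = flat_profiles(t, 100.0, 0.5)
        for node in (70, 120):  # one node on each child branch
            bump = np.exp(-0.5 * ((d - d[node]) / 1.5) ** 2)
            mask = np.arange(t.n_nodes)
            # restrict bump to the child's own subtree path
            prof.loc[:, "intensity"] += 0
        # simpler: craft per-branch profiles directly
        prof = flat_profiles(t, 100.0, 0.5)
        for node in (70, 120):
            prof.loc[node - 2:node + 2, "intensity"] = [160, 220, 250, 220, 160]
            prof.loc[node - 2:node + 2, "radius"] = [0.7, 1.1, 1.3, 1.1, 0.7]
        bs = bt.detect_boutons(t, prof)
        out = bt.branch_bouton_stats([bs], [t])
        assert out["bifurcation_types"]["B0"] == 1.0
        # and with a single-child bouton
        prof1 = flat_profiles(t, 100.0, 0.5)
        prof1.loc[68:72, "intensity"] = [160, 220, 250, 220, 160]
        prof1.loc[68:72, "radius"] = [0.7, 1.1, 1.3, 1.1, 0.7]
        bs1 = bt.detect_boutons(t, prof1)
        out1 = bt.branch_bouton_stats([bs1], [t])
        assert out1["bifurcation_types"]["B1"] == 1.0

    def test_curviness_straight_and_semicircle(self):
        t = axon_line()
        bs = bt.detect_boutons(t, bump_profiles(t, [50.0]))
        out = bt.branch_bouton_stats([bs], [t])
        assert out["branches"]["curviness"].iloc[0] == pytest.approx(0.0)
        theta = np.linspace(0, np.pi, 41)
        pts = [(10 * np.cos(a), 10 * np.sin(a), 0) for a in theta]
        arc_t = make_tree(pts, [None] + list(range(40)),
                          structure=[1] + [AXON] * 40)
        bs2 = bt.detect_boutons(arc_t, flat_profiles(arc_t))
        out2 = bt.branch_bouton_stats([bs2], [arc_t])
        assert out2["branches"]["curviness"].iloc[0] == pytest.approx(1 - 2 / np.pi, abs=0.01)

    def test_branch_partition_bouton_plus_null(self):
        t = self._forked_axon()
        prof = flat_profiles(t, 100.0, 0.5)
        prof.loc[18:22, "intensity"] = [160, 220, 250, 220, 160]
        prof.loc[18:22, "radius"] = [0.7, 1.1, 1.3, 1.1, 0.7]
        bs = bt.detect_boutons(t, prof)
        out = bt.branch_bouton_stats([bs], [t])
        br = out["branches"]
        assert br["has_bouton"].sum() + (~br["has_bouton"]).sum() == len(br)
        assert br["has_bouton"].sum() == 1

    def test_quartile_null_model_centered(self):
        """Uniformly planted boutons occupy branch quarters evenly."""
        rng = np.random.default_rng(0)
        devs = []
        for seed in range(30):
            t = axon_line(n=401)
            arcs = np.sort(rng.uniform(5, 395, 8))
            arcs = arcs[np.diff(np.concatenate([[0], arcs])) > 8]
            bs = bt.detect_boutons(t, bump_profiles(t, list(arcs)))
            q = bt.branch_bouton_stats([bs], [t])["quartile_occupancy"]
            if np.isfinite(q).all():
                devs.append(q - 0.25)
        assert abs(np.mean(devs)) < 0.05


class TestInterBoutonDistance:
    def test_chain_distances_to_predecessor(self):
        t = axon_line()
        bs = bt.detect_boutons(t, bump_profiles(t, [20.0, 50.0, 90.0]))
        inter = bt._inter_bouton_distances(bs, t)
        finite = np.sort(inter[np.isfinite(inter)])
        assert np.allclose(finite, [30.0, 40.0], atol=1.0)
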