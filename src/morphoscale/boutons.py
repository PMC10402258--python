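"""Axonal bouton detection and branch-level statistics.

Boutons (putative synaptic varicosities) appear as overlapping peaks in the
intensity and radius profiles along axonal shafts. Candidates must be at
least 1.5× thicker than the surrounding shaft and brighter than an 8-bit
intensity floor; near-duplicates are merged. Detected boutons are typed as
terminaux (TEB, near a branch tip) or en passant (EPB), and summarised by
radial distributions, six radar features and per-branch statistics
(bouton vs null branches, bifurcation types, within-branch quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import NeuronTree, AXON, branch_decompose

__all__ = [
    "BoutonConfig", "BoutonSet", "detect_boutons", "classify_teb_epb",
    "radial_distribution", "radar_features", "branch_bouton_stats",
    "RADAR_FEATURES",
]


@dataclass
class BoutonConfig:
    radius_factor: float = 1.5        # bouton vs surrounding shaft radius
    intensity_min: float = 120.0      # 8-bit floor
    peak_overlap_um: float = 2.0      # intensity/radius peak coincidence
    surround_um: float = 10.0         # shaft window (± arc) for the baseline
    core_um: float = 2.0              # excluded core around the candidate
    dedupe_vox: float = 5.0           # duplicate distance, voxels
    voxel_um: float = 0.3             # imaging voxel size
    teb_tau_um: float = 5.0           # tip distance for TEB typing
    fragment_um: float = 20.0         # minimum branch length considered


@dataclass
class BoutonSet:
    neuron_id: object
    boutons: pd.DataFrame             # node, branch, arc, path_dist, type, ...
    summary: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.boutons)


def _branch_profiles(tree, branches, profiles):
    """Per-axonal-branch (nodes, arc, intensity, radius) arrays."""
    intensity = np.asarray(profiles["intensity"], dtype=np.float64)
    radius = np.asarray(profiles["radius"], dtype=np.float64)
    out = []
    for bi, b in enumerate(branches):
        if not np.all(tree.structure[b.nodes[1:]] == AXON):
            continue
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(tree.xyz[b.nodes], axis=0), axis=1))])
        out.append((bi, b, arc, intensity[b.nodes], radius[b.nodes]))
    return out


def detect_boutons(tree: NeuronTree, profiles, cfg: BoutonConfig = BoutonConfig(),
                   neuron_id=None) -> BoutonSet:
    """Detect boutons from per-node intensity and radius profiles.

    Candidates are radius-profile peaks with an intensity peak within
    ``peak_overlap_um`` of arc length, at least ``radius_factor`` times the
    median surrounding shaft radius (±``surround_um`` arc excluding the
    ±``core_um`` core), with 8-bit intensity above ``intensity_min``;
    duplicates closer than ``dedupe_vox`` voxels keep the brighter one.
    """
    if profiles is None:
        raise ValueError("bouton detection requires intensity/radius profiles")
    branches = branch_decompose(tree)
    pathd = tree.path_dist_to_root()
    rows = []
    for bi, b, arc, inten, rad in _branch_profiles(tree, branches, profiles):
        if arc[-1] < cfg.fragment_um or len(arc) < 5:
            continue
        spacing = max(np.median(np.diff(arc)), 1e-6)
        min_sep = max(1, int(round(2.0 / spacing)))
        shaft = float(np.median(rad))
        ip, _ = find_peaks(inten, distance=min_sep, height=cfg.intensity_min)
        rp, _ = find_peaks(rad, distance=min_sep,
                           prominence=max(1e-6, 0.2 * shaft))
        if len(ip) == 0 or len(rp) == 0:
            continue
        for j in rp:
            if np.min(np.abs(arc[ip] - arc[j])) > cfg.peak_overlap_um:
                continue
            sur = (np.abs(arc - arc[j]) <= cfg.surround_um) & (np.abs(arc - arc[j]) > cfg.core_um)
            if not sur.any():
                continue
            base = float(np.median(rad[sur]))
            if base <= 0 or rad[j] < cfg.radius_factor * base:
                continue
            if inten[j] <= cfg.intensity_min:
                continue
            node = int(b.nodes[j])
            rows.append({
                "node": node, "branch": bi, "arc": float(arc[j]),
                "path_dist": float(pathd[node]), "amplitude": float(inten[j]),
                "radius_ratio": float(rad[j] / base),
                "x": tree.xyz[node, 0], "y": tree.xyz[node, 1], "z": tree.xyz[node, 2],
            })
    df = pd.DataFrame(rows, columns=["node", "branch", "arc", "path_dist",
                                     "amplitude", "radius_ratio", "x", "y", "z"])
    # dedupe by spatial distance, brighter wins
    if len(df):
        df = df.sort_values("amplitude", ascending=False).reset_index(drop=True)
        keep = []
        P = df[["x", "y", "z"]].to_numpy()
        lim = cfg.dedupe_vox * cfg.voxel_um
        for i in range(len(df)):
            if all(np.linalg.norm(P[i] - P[j]) >= lim for j in keep):
                keep.append(i)
        df = df.iloc[keep].sort_values(["branch", "arc"]).reset_index(drop=True)
    bs = BoutonSet(neuron_id or tree.metadata.get("neuron_id"), df)
    classify_teb_epb(bs, tree, cfg)
    bs.summary = _summarise(bs, tree)
    return bs


def classify_teb_epb(bouton_set: BoutonSet, tree: NeuronTree,
                     cfg: BoutonConfig = BoutonConfig()) -> BoutonSet:
    """TEB when the bouton lies within ``teb_tau_um`` of a terminal tip along
    its branch; EPB otherwise."""
    branches = branch_decompose(tree)
    nch = tree.n_children()
    types = []
    for _, row in bouton_set.boutons.iterrows():
        b = branches[int(row["branch"])]
        is_term = nch[b.end] == 0
        tip_dist = b.path_length - row["arc"]
        types.append("TEB" if (is_term and tip_dist <= cfg.teb_tau_um) else "EPB")
    bouton_set.boutons["type"] = types
    return bouton_set


def _inter_bouton_distances(bouton_set, tree):
    """Arc length from each bouton to its preceding bouton towards the soma
    (NaN when none exists)."""
    df = bouton_set.boutons
    if len(df) == 0:
        return np.empty(0)
    bnodes = set(int(n) for n in df["node"])
    pathd = tree.path_dist_to_root()
    out = []
    for n in df["node"]:
        k = int(n)
        p = tree.parent_index[k]
        found = np.nan
        while p >= 0:
            if int(p) in bnodes:
                found = float(pathd[k] - pathd[p])
                break
            p = tree.parent_index[p]
        out.append(found)
    return np.array(out)


RADAR_FEATURES = ["avg_n_boutons", "teb_ratio", "inter_bouton_mean",
                  "inter_bouton_sd", "dist2soma_mean", "dist2soma_max"]


def _summarise(bouton_set: BoutonSet, tree: NeuronTree) -> dict:
    df = bouton_set.boutons
    inter = _inter_bouton_distances(bouton_set, tree)
    inter = inter[np.isfinite(inter)]
    n = len(df)
    return {
        "avg_n_boutons": float(n),
        "teb_ratio": float((df["type"] == "TEB").mean()) if n else 0.0,
        "inter_bouton_mean": float(inter.mean()) if len(inter) else 0.0,
        "inter_bouton_sd": float(inter.std()) if len(inter) else 0.0,
        "dist2soma_mean": float(df["path_dist"].mean()) if n else 0.0,
        "dist2soma_max": float(df["path_dist"].max()) if n else 0.0,
    }


def radial_distribution(bouton_set: BoutonSet, bins=10):
    """Normalised histogram of bouton distance-to-soma plus the share in
    each quarter of the distance range."""
    d = bouton_set.boutons["path_dist"].to_numpy(dtype=np.float64)
    if len(d) == 0:
        return {"hist": np.empty(0), "edges": np.empty(0),
                "quartile_share": np.full(4, np.nan), "empty": True}
    dmax = max(d.max(), 1e-9)
    hist, edges = np.histogram(d, bins=bins, range=(0, dmax))
    hist = hist / hist.sum()
    q = np.clip((d / dmax * 4).astype(int), 0, 3)
    share = np.bincount(q, minlength=4) / len(d)
    return {"hist": hist, "edges": edges, "quartile_share": share, "empty": False}


def radar_features(bouton_sets, groups):
    """Six per-group mean features min-max scaled to 0–100.

    ``groups`` assigns a group label per bouton set. With a single group the
    scaled values are all 0 and ``degenerate`` is flagged.
    """
    groups = np.asarray(groups)
    raw = pd.DataFrame([bs.summary for bs in bouton_sets])
    raw["group"] = groups
    means = raw.groupby("group")[RADAR_FEATURES].mean()
    lo, hi = means.min(axis=0), means.max(axis=0)
    rng = (hi - lo).replace(0, np.nan)
    scaled = (100 * (means - lo) / rng).fillna(0.0)
    scaled.attrs["degenerate"] = len(means) < 2
    return scaled, means


def branch_bouton_stats(bouton_sets, trees):
    """Per-branch bouton/null classes with geometry, bifurcation types and
    within-branch quartile occupancy.

    Branch curviness is 1 − Euclidean/path length. Bifurcation types count
    bouton-bearing child branches: B0 both, B1 one, B2 none. The quartile
    table gives the share of boutons in each quarter of their branch's arc
    (uniform expectation 0.25).
    """
    rows = []
    bif_counts = {"B0": 0, "B1": 0, "B2": 0}
    quartiles = np.zeros(4)
    nq = 0
    for bs, tree in zip(bouton_sets, trees):
        branches = branch_decompose(tree)
        have = set(int(b) for b in bs.boutons["branch"]) if len(bs.boutons) else set()
        for bi, b in enumerate(branches):
            if not np.all(tree.structure[b.nodes[1:]] == AXON):
                continue
            rows.append({
                "neuron": bs.neuron_id, "branch": bi,
                "length": b.path_length, "order": b.order,
                "curviness": 1.0 - b.contraction,
                "has_bouton": bi in have,
                "terminal": int(len([o for o in branches if o.start == b.end]) == 0),
            })
        by_start = {}
        for bi, b in enumerate(branches):
            by_start.setdefault(int(b.start), []).append(bi)
        for bp in tree.branch_points():
            kids = by_start.get(int(bp), [])
            axon_kids = [kk for kk in kids if tree.structure[branches[kk].end] == AXON]
            if len(axon_kids) < 2:
                continue
            nb = sum(1 for kk in axon_kids[:2] if kk in have)
            bif_counts[{2: "B0", 1: "B1", 0: "B2"}[nb]] += 1
        for _, row in bs.boutons.iterrows():
            L = branches[int(row["branch"])].path_length
            if L > 0:
                quartiles[min(3, int(row["arc"] / L * 4))] += 1
                nq += 1
    branch_table = pd.DataFrame(rows)
    total_bifs = sum(bif_counts.values())
    bif_props = {k: (v / total_bifs if total_bifs else np.nan) for k, v in bif_counts.items()}
    qshare = quartiles / nq if nq else np.full(4, np.nan)
    return {"branches": branch_table, "bifurcation_types": bif_props,
            "quartile_occupancy": qshare}
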