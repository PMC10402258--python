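"""Sub-neuronal structures: arbors, structural hubs, primary axonal tracts.

Arbors are densely packed axonal subtrees recovered by spectral clustering
on an exponential node-distance affinity, with connectivity enforced on the
tree; dendritic (basal/apical) arbors are kept whole. Hubs are connected
components of high axonal-node density across a neuron population in atlas
space. The primary tract is the longest axonal path after iterative
removal of short terminal-side branches; grouped tracts are summarised by
a 200-point cross-sectional radius profile and classified as convergent,
divergent or parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .core import NeuronTree, AXON, BASAL, APICAL, branch_decompose, resample_tree
from .morphotype import eigengap_k

__all__ = [
    "Arbor", "Tract", "TractGroupProfile",
    "decompose_arbors", "region_arbor_count", "arbor_features",
    "detect_hubs", "primary_tract", "tract_group_profile",
    "terminal_clusters", "projection_vector", "thalamic_style_clustering",
]

ARBOR_SIGMA = 50.0        # μm affinity length scale
DENSITY_RADIUS = 20.0     # μm sphere for max_density
PROXIMAL_CUT = 750.0      # μm proximal/distal boundary


@dataclass
class Arbor:
    nodes: np.ndarray                 # node indices into the source tree
    kind: str                         # axonal | basal | apical
    order_label: str = ""             # A1/A2/... by distance to soma
    features: dict = field(default_factory=dict)
    type: str = ""                    # proximal | distal


@dataclass
class Tract:
    nodes: np.ndarray                 # soma→terminal node indices
    points: np.ndarray                # 200 arc-uniform xyz samples
    terminal: np.ndarray


@dataclass
class TractGroupProfile:
    label: object
    radii: np.ndarray                 # 200 cross-sectional radii
    pattern: str                      # convergent | divergent | parallel


# -- arbors -----------------------------------------------------------------

def _axon_affinity(tree, idx, sigma=ARBOR_SIGMA):
    P = tree.xyz[idx]
    D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    return np.exp(-D / sigma)


def _enforce_connectivity(tree, idx, labels):
    """Reassign minority components so every label forms one connected piece
    of the axon forest."""
    pos = {int(k): i for i, k in enumerate(idx)}
    children = tree.children_lists()
    for _ in range(len(idx)):
        # components per label via union over tree edges within the label
        parent_of = {}
        comp = {int(k): int(k) for k in idx}

        def find(a):
            while comp[a] != a:
                comp[a] = comp[comp[a]]
                a = comp[a]
            return a

        for k in idx:
            p = tree.parent_index[k]
            if p >= 0 and int(p) in pos and labels[pos[int(p)]] == labels[pos[int(k)]]:
                comp[find(int(k))] = find(int(p))
        groups = {}
        for k in idx:
            groups.setdefault((labels[pos[int(k)]], find(int(k))), []).append(int(k))
        per_label = {}
        for (lab, root), nodes in groups.items():
            per_label.setdefault(lab, []).append(nodes)
        changed = False
        for lab, comps in per_label.items():
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for minority in comps[1:]:
                # attach to the label of the tree-parent of the component head
                heads = [k for k in minority
                         if tree.parent_index[k] < 0 or int(tree.parent_index[k]) not in pos
                         or int(tree.parent_index[k]) not in minority]
                new_lab = None
                for h in heads:
                    p = tree.parent_index[h]
                    if p >= 0 and int(p) in pos and int(p) not in minority:
                        new_lab = labels[pos[int(p)]]
                        break
                if new_lab is None:
                    for k in minority:
                        for c in children[k]:
                            if int(c) in pos and int(c) not in minority:
                                new_lab = labels[pos[int(c)]]
                                break
                        if new_lab is not None:
                            break
                if new_lab is not None and new_lab != lab:
                    for k in minority:
                        labels[pos[k]] = new_lab
                    changed = True
        if not changed:
            break
    return labels


def decompose_arbors(tree: NeuronTree, k: int, seed=0, sigma=ARBOR_SIGMA) -> list:
    """Split the axon into ``k`` connected arbors by spectral clustering on
    exp(−distance/σ) affinities; basal and apical dendrites are returned
    whole as additional arbors."""
    axon_idx = np.nonzero(tree.structure == AXON)[0]
    if k > (tree.structure == AXON).sum():
        raise ValueError("k exceeds the number of axonal nodes")
    arbors = []
    if len(axon_idx):
        if k == 1:
            labels = np.zeros(len(axon_idx), dtype=int)
        else:
            A = _axon_affinity(tree, axon_idx, sigma)
            sc = SpectralClustering(n_clusters=k, affinity="precomputed", random_state=seed)
            labels = sc.fit_predict(A)
            labels = _enforce_connectivity(tree, axon_idx, labels)
        for lab in sorted(np.unique(labels)):
            arbors.append(Arbor(axon_idx[labels == lab], "axonal"))
    for st, kind in ((BASAL, "basal"), (APICAL, "apical")):
        idx = np.nonzero(tree.structure == st)[0]
        if len(idx):
            arbors.append(Arbor(idx, kind))
    for a in arbors:
        a.features = arbor_features(a.nodes, tree)
        a.type = "distal" if a.features["dist2soma"] > PROXIMAL_CUT else "proximal"
    ax = [a for a in arbors if a.kind == "axonal"]
    for rank, a in enumerate(sorted(ax, key=lambda a: a.features["dist2soma"]), 1):
        a.order_label = f"A{rank}"
    return arbors


def auto_arbor_count(tree, k_max=4, sigma=30.0, density_radius=50.0,
                     dense_frac=0.3, spacing=10.0) -> int:
    """Per-neuron arbor count from the Laplacian eigengap of the dense axon.

    The axon is resampled to uniform ``spacing`` and thinned to dense-packed
    nodes (neighbour count within ``density_radius`` at least ``dense_frac``
    of the maximum) — arbors are dense by definition, and the pre-screen
    keeps the sparse connecting tract from mimicking extra clusters. The
    eigengap of exp(−d/σ) affinities over these nodes gives k ∈ [1, k_max].
    """
    idx = np.nonzero(tree.structure == AXON)[0]
    if len(idx) < 3:
        return 1
    rt = resample_tree(tree, spacing, mode="uniform")
    ridx = np.nonzero(rt.structure == AXON)[0]
    P = rt.xyz[ridx]
    kd = cKDTree(P)
    cnt = np.array([len(kd.query_ball_point(p, density_radius)) for p in P])
    dense = ridx[cnt >= dense_frac * cnt.max()]
    if len(dense) < 3:
        return 1
    A = _axon_affinity(rt, dense, sigma)
    return eigengap_k(A, k_max=min(k_max, len(dense) - 1))


def region_arbor_count(trees, k_max=4, **kwargs) -> int:
    """Majority-vote dominant arbor number over neurons of one region; the
    per-neuron count comes from :func:`auto_arbor_count`; ties break small."""
    if not trees:
        raise ValueError("need at least one neuron")
    votes = [auto_arbor_count(t, k_max=k_max, **kwargs) for t in trees]
    vals, counts = np.unique(votes, return_counts=True)
    return int(vals[np.argmax(counts)])  # np.unique is sorted → ties break small


def arbor_features(nodes, tree: NeuronTree, density_radius=DENSITY_RADIUS) -> dict:
    """(n_branch, volume, max_density, dist2soma, type) of an arbor.

    Volume is the PCA-rotated 3-D bounding box of the arbor's nodes;
    max_density the maximum per-node count of arbor nodes within a 20 μm
    sphere; dist2soma the Euclidean soma distance of the max-density node.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    P = tree.xyz[nodes]
    branches = branch_decompose(tree)
    node_set = set(int(n) for n in nodes)
    n_branch = sum(1 for b in branches if int(b.end) in node_set)
    X = P - P.mean(axis=0)
    if len(P) >= 3:
        _, v = np.linalg.eigh(X.T @ X)
        proj = X @ v
    else:
        proj = X
    ext = proj.max(axis=0) - proj.min(axis=0) if len(P) else np.zeros(3)
    volume = float(np.prod(ext))
    kd = cKDTree(P)
    density = np.array([len(kd.query_ball_point(p, density_radius)) for p in P])
    imax = int(np.argmax(density))
    d2s = float(np.linalg.norm(P[imax] - tree.soma_xyz))
    return {
        "n_branch": int(n_branch), "volume": volume,
        "max_density": int(density[imax]), "dist2soma": d2s,
        "type": "distal" if d2s > PROXIMAL_CUT else "proximal",
    }


# -- structural hubs --------------------------------------------------------

def detect_hubs(trees, voxel_um=25.0, spacing_um=80.0, sphere_um=500.0,
                min_neighbors=70, dilate_vox=10):
    """Population-level hubs: axonal skeletons resampled to ~``spacing_um``
    node spacing, per-node neighbour counts in a ``sphere_um`` sphere,
    thresholding (count > ``min_neighbors``, self included), cubic dilation
    and connected-component labelling.

    Returns ``(label_image, origin_um, hubs)`` with ``hubs`` mapping hub id
    → array of node positions (μm).
    """
    pts = []
    for t in trees:
        rt = resample_tree(t, spacing_um, mode="uniform")
        pts.append(rt.xyz[rt.structure == AXON])
    pts = np.vstack([p for p in pts if len(p)]) if pts else np.empty((0, 3))
    if len(pts) == 0:
        return np.zeros((1, 1, 1), dtype=np.int32), np.zeros(3), {}
    kd = cKDTree(pts)
    counts = np.array([len(kd.query_ball_point(p, sphere_um)) for p in pts])
    dense = pts[counts > min_neighbors]
    lo = pts.min(axis=0)
    shape = np.ceil((pts.max(axis=0) - lo) / voxel_um).astype(int) + 1
    img = np.zeros(shape, dtype=np.uint8)
    if len(dense):
        v = np.floor((dense - lo) / voxel_um).astype(int)
        img[v[:, 0], v[:, 1], v[:, 2]] = 255
        img = ndimage.grey_dilation(img, size=(dilate_vox,) * 3)
    lab, n = ndimage.label(img > 0)
    hubs = {}
    if n and len(dense):
        v = np.floor((dense - lo) / voxel_um).astype(int)
        ids = lab[v[:, 0], v[:, 1], v[:, 2]]
        for h in range(1, n + 1):
            hubs[h] = dense[ids == h]
    return lab.astype(np.int32), lo, hubs


# -- primary tracts ---------------------------------------------------------

def _axon_paths(tree):
    """Root-to-tip node paths through axonal nodes (soma root included)."""
    children = tree.children_lists()
    keep = (tree.structure == AXON)
    keep[tree.root] = True
    paths = []

    def walk(k, acc):
        acc = acc + [k]
        kids = [c for c in children[k] if keep[c]]
        if not kids:
            if len(acc) > 1:
                paths.append(acc)
            return
        for c in kids:
            walk(c, acc)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes + 100))
    try:
        walk(tree.root, [])
    finally:
        sys.setrecursionlimit(old)
    return paths


def primary_tract(tree: NeuronTree, n_points=200) -> Tract:
    """Longest axonal path after iterative removal of terminal branches
    shorter than the second-longest axonal branch."""
    if not (tree.structure == AXON).any():
        raise ValueError("neuron has no axon")
    branches = [b for b in branch_decompose(tree)
                if tree.structure[b.end] == AXON]
    lens = sorted((b.path_length for b in branches), reverse=True)
    thresh = lens[1] if len(lens) > 1 else 0.0
    kids_of = {}
    for i, b in enumerate(branches):
        kids_of.setdefault(int(b.start), []).append(i)
    alive = [True] * len(branches)
    paths = _axon_paths(tree)
    plens = [float(np.linalg.norm(np.diff(tree.xyz[p], axis=0), axis=1).sum())
             for p in paths]

    def longest_alive():
        dead = set()
        for i, b in enumerate(branches):
            if not alive[i]:
                dead.update(int(x) for x in b.nodes[1:])
        best, best_len = None, -1.0
        for p, plen in zip(paths, plens):
            if any(x in dead for x in p) or plen <= best_len:
                continue
            best, best_len = p, plen
        return best

    # iteratively trim terminal-side branches shorter than the frozen
    # second-longest-branch threshold; the current longest path is protected
    # so the trunk itself is never dismantled
    while True:
        spine = set(longest_alive() or [])
        changed = False
        for i, b in enumerate(branches):
            if not alive[i] or int(b.end) in spine:
                continue
            has_kids = any(alive[j] for j in kids_of.get(int(b.end), []))
            if not has_kids and b.path_length < thresh:
                alive[i] = False
                changed = True
        if not changed:
            break
    nodes = np.array(longest_alive(), dtype=np.int64)
    pts = tree.xyz[nodes]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, arc[-1], n_points)
    samples = np.stack([np.interp(targets, arc, pts[:, d]) for d in range(3)], axis=1)
    return Tract(nodes, samples, pts[-1].copy())


def tract_group_profile(tracts, label=None, percentile=75.0,
                        conv_cut=0.8, div_cut=1.25) -> TractGroupProfile:
    """Per-percentile cross-sectional radius of a tract group.

    At each of the 200 arc percentiles the tract points are projected onto
    their top-2 PCA plane; the radius is the 75th percentile of distances to
    the centre. The pattern compares terminal-end vs soma-end mean radii
    (first/last 10% of arc): ratio < ``conv_cut`` → convergent,
    > ``div_cut`` → divergent, else parallel.
    """
    if len(tracts) < 3:
        raise ValueError("need at least 3 tracts for a radius profile")
    P = np.stack([t.points for t in tracts])       # (m, 200, 3)
    m, n, _ = P.shape
    radii = np.zeros(n)
    for i in range(n):
        pts = P[:, i, :]
        X = pts - pts.mean(axis=0)
        _, v = np.linalg.eigh(X.T @ X)
        proj = X @ v[:, -2:]
        radii[i] = float(np.percentile(np.linalg.norm(proj, axis=1), percentile))
    tenth = max(1, n // 10)
    r_soma = float(radii[:tenth].mean())
    r_term = float(radii[-tenth:].mean())
    eps = 1e-9
    if r_soma < eps and r_term < eps:
        pattern = "parallel"
    elif r_soma < eps:
        pattern = "divergent"
    else:
        ratio = r_term / r_soma
        pattern = "convergent" if ratio < conv_cut else ("divergent" if ratio > div_cut else "parallel")
    return TractGroupProfile(label, radii, pattern)


def terminal_clusters(tracts, k, seed=0):
    """K-Means on tract terminal points; returns (labels, per-cluster
    profiles — None for clusters with fewer than 3 tracts)."""
    if k > len(tracts):
        raise ValueError("k exceeds the number of tracts")
    T = np.stack([t.terminal for t in tracts])
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(T)
    profiles = {}
    for lab in sorted(np.unique(labels)):
        grp = [t for t, l in zip(tracts, labels) if l == lab]
        profiles[int(lab)] = tract_group_profile(grp, lab) if len(grp) >= 3 else None
    return labels, profiles


# -- projections ------------------------------------------------------------

def projection_vector(tree: NeuronTree, atlas) -> pd.Series:
    """Per-region total axonal length (mm); edges are assigned to the region
    of their midpoint, background excluded."""
    rids = atlas.region_table["region_id"].to_numpy()
    acc = pd.Series(0.0, index=rids)
    mask = (tree.parent_index >= 0) & (tree.structure == AXON)
    for k in np.nonzero(mask)[0]:
        p = tree.parent_index[k]
        mid = (tree.xyz[k] + tree.xyz[p]) / 2
        lab = atlas.label_at(mid)
        if lab > 0:
            acc[lab] += np.linalg.norm(tree.xyz[k] - tree.xyz[p]) / 1000.0
    return acc


def thalamic_style_clustering(arbor_stats: pd.DataFrame, projections: pd.DataFrame,
                              k=2) -> np.ndarray:
    """Agglomerative (average linkage) clustering on z-scored per-neuron
    arbor statistics concatenated with L1-normalised projection vectors."""
    X = arbor_stats.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    V = projections.to_numpy(dtype=np.float64)
    s = V.sum(axis=1, keepdims=True)
    V = V / np.where(s > 0, s, 1.0)
    Z = np.concatenate([X, V], axis=1)
    return AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(Z)
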