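"""Dendritic microenvironments.

A microenvironment fuses a target neuron's 24-dim local-dendrite feature
vector with its (up to) five most feature-similar neighbours inside a
249 μm sphere, weighting each member by exp(−d/D) normalised to sum to 1.
The module also provides mRMR selection of the most discriminating
features, the RGB whole-brain feature map, K-Means clustering of regions on
microenvironment summary statistics, and mean-feature profiles along region
sequences or radial axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import mutual_info_score

from .core import NeuronTree, lmeasure_features, pca_shape_features, LMEASURE_NAMES

__all__ = [
    "Microenvironment", "FEATURES24_NAMES", "features24",
    "build_microenvironment", "estimate_radius", "mrmr_select",
    "rgb_map", "region_clusters", "path_profile",
]

_EXCLUDED = {"Nodes", "SomaSurface", "AverageDiameter", "Surface"}
_PCA_NAMES = ["pc1_var", "pc2_var", "pc3_var", "pc1_x", "pc1_y", "pc1_z"]
FEATURES24_NAMES = [n for n in LMEASURE_NAMES if n not in _EXCLUDED] + _PCA_NAMES
LM18_NAMES = [n for n in LMEASURE_NAMES if n not in _EXCLUDED]


def features24(tree: NeuronTree) -> pd.Series:
    """18 whole-neuron morphometrics (size-count features excluded) plus the
    six PCA shape descriptors, as a named 24-vector."""
    lm = lmeasure_features(tree)
    pca = pca_shape_features(tree)
    vals = {n: lm[n] for n in LM18_NAMES}
    vals.update(pca)
    return pd.Series(vals, index=FEATURES24_NAMES)


@dataclass
class Microenvironment:
    target: object
    members: list
    distances: np.ndarray
    weights: np.ndarray
    features: pd.Series


def estimate_radius(positions, k=5, percentile=50.0):
    """Data-driven sphere radius: the given percentile of the distance to
    the k-th closest neuron, over all neurons."""
    from scipy.spatial import cKDTree
    P = np.asarray(positions, dtype=np.float64)
    kd = cKDTree(P)
    d, _ = kd.query(P, k=k + 1)
    return float(np.percentile(d[:, k], percentile))


def build_microenvironment(target, features: pd.DataFrame, positions,
                           D=249.0, k=5) -> Microenvironment:
    """Fuse the target with its up-to-``k`` most similar neighbours within a
    sphere of radius ``D`` μm.

    Similarity is the Euclidean distance between population z-scored feature
    vectors; fusion weights are ``exp(-d_i/D)`` normalised over the members
    (target included at distance 0). The fused feature is the weighted sum
    of the raw member features.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if target not in features.index:
        raise KeyError(f"target {target!r} not in feature table")
    P = pd.DataFrame(np.asarray(positions, dtype=np.float64), index=features.index)
    mu, sd = features.mean(axis=0), features.std(axis=0).replace(0, 1.0)
    Z = (features - mu) / sd
    p0 = P.loc[target].to_numpy()
    d_space = np.linalg.norm(P.to_numpy() - p0, axis=1)
    in_sphere = (d_space <= D) & (features.index != target)
    cand = features.index[in_sphere]
    if len(cand):
        fsim = np.linalg.norm(Z.loc[cand].to_numpy() - Z.loc[target].to_numpy(), axis=1)
        chosen = list(cand[np.argsort(fsim, kind="stable")][:k])
    else:
        chosen = []
    members = [target] + chosen
    d = np.array([0.0] + [float(np.linalg.norm(P.loc[m].to_numpy() - p0)) for m in chosen])
    w = np.exp(-d / D)
    w = w / w.sum()
    fused = pd.Series(np.einsum("i,ij->j", w, features.loc[members].to_numpy()),
                      index=features.columns)
    return Microenvironment(target, members, d, w, fused)


def mrmr_select(features: pd.DataFrame, labels, k=3, bins=5) -> list:
    """Greedy max-relevance min-redundancy feature ranking (MID variant).

    Features are z-scored and discretised into ``bins`` equal-width bins;
    relevance and redundancy are mutual information against the labels and
    the already-selected features. Constant features are excluded with a
    warning.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 label values")
    if k > features.shape[1]:
        raise ValueError("k exceeds feature count")
    cols = []
    disc = {}
    for c in features.columns:
        x = features[c].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0 or not np.isfinite(x).all():
            warnings.warn(f"constant or non-finite feature {c!r} excluded from mRMR")
            continue
        z = (x - x.mean()) / x.std()
        edges = np.linspace(z.min(), z.max(), bins + 1)
        disc[c] = np.clip(np.digitize(z, edges[1:-1]), 0, bins - 1)
        cols.append(c)
    rel = {c: mutual_info_score(labels, disc[c]) for c in cols}
    selected = []
    while len(selected) < min(k, len(cols)):
        best, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            red = np.mean([mutual_info_score(disc[c], disc[s]) for s in selected]) if selected else 0.0
            score = rel[c] - red
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
    return selected


def rgb_map(features: pd.DataFrame, top3, positions, atlas, mirror=True,
            mip_halfwidth_um=1000.0):
    """Sparse RGB feature volume plus middle-section maximum projections.

    Each neuron's three selected features are min-max scaled to 0–255 and
    written at its soma voxel; with ``mirror`` on, somas in the
    high-coordinate half along axis 0 are reflected to the other side.
    Projections take the channel-wise maximum over slabs of
    ``±mip_halfwidth_um`` around the three middle sections.
    """
    shape = atlas.shape
    vol = np.zeros(shape + (3,), dtype=np.uint8)
    F = features[list(top3)].to_numpy(dtype=np.float64)
    lo, hi = F.min(axis=0), F.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    scaled = np.round(255 * (F - lo) / rng).astype(np.uint8)
    vox = np.floor(np.asarray(positions, dtype=np.float64) / atlas.voxel_size).astype(int)
    vox = np.clip(vox, 0, np.array(shape) - 1)
    mid0 = shape[0] // 2
    for i in range(len(vox)):
        v = vox[i].copy()
        if mirror and v[0] >= mid0:
            v[0] = shape[0] - 1 - v[0]
        vol[v[0], v[1], v[2]] = np.maximum(vol[v[0], v[1], v[2]], scaled[i])
    hw = max(1, int(round(mip_halfwidth_um / atlas.voxel_size)))
    mips = {}
    for ax, name in enumerate(("sagittal", "coronal", "axial")):
        mid = shape[ax] // 2
        sl = [slice(None)] * 3
        sl[ax] = slice(max(0, mid - hw), min(shape[ax], mid + hw + 1))
        mips[name] = vol[tuple(sl)].max(axis=ax)
    return vol, mips


def region_clusters(features: pd.DataFrame, regions, k, seed=0) -> dict:
    """K-Means over regions on the concatenated mean and variance of the
    supplied (top-three) microenvironment features."""
    regions = pd.Series(np.asarray(regions), index=features.index)
    uniq = sorted(regions.unique())
    if k > len(uniq):
        raise ValueError("k exceeds the number of regions")
    rows = []
    for r in uniq:
        sub = features[regions == r].to_numpy(dtype=np.float64)
        rows.append(np.concatenate([sub.mean(axis=0), sub.var(axis=0)]))
    X = np.array(rows)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    return {r: int(c) for r, c in zip(uniq, km.labels_)}


def path_profile(features: pd.DataFrame, regions, sequence):
    """Mean feature vectors ordered along a given region sequence; regions
    with no data yield NaN rows flagged in the ``empty`` column."""
    regions = pd.Series(np.asarray(regions), index=features.index)
    rows = []
    for r in sequence:
        sub = features[regions == r]
        row = sub.mean(axis=0) if len(sub) else pd.Series(np.nan, index=features.columns)
        row["empty"] = float(len(sub) == 0)
        rows.append(row.rename(r))
    return pd.DataFrame(rows)


def radial_profile(features: pd.DataFrame, positions, axis, n_bins=5, origin=None):
    """Mean features binned by projection along ``axis`` (unit-normalised),
    for intra-region gradients."""
    P = np.asarray(positions, dtype=np.float64)
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    origin = P.mean(axis=0) if origin is None else np.asarray(origin, float)
    t = (P - origin) @ a
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sub = features[idx == b]
        row = sub.mean(axis=0) if len(sub) else pd.Series(np.nan, index=features.columns)
        rows.append(row.rename(0.5 * (edges[b] + edges[b + 1])))
    return pd.DataFrame(rows)
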