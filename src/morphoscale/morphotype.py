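"""Full-morphology typing.

Neurons are summarised by a 47-dim vector (7 global features plus
min/max/mean/sd of 10 local branch and bifurcation features), compared by
the product of cosine feature similarity and an exponential soma-distance
factor, and grouped by spectral clustering on that affinity. Cluster pairs
are characterised by soma-position silhouettes, mRMR discriminating
features with hit rates, and branch-count-vs-distance profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score

from .core import NeuronTree, lmeasure_features, local_branch_features
from .microenv import mrmr_select

__all__ = [
    "features47", "FEATURES47_NAMES", "similarity_matrix", "spectral_cluster",
    "eigengap_k", "silhouette_separation", "pairwise_discriminators",
    "branch_distance_profile",
]

_GLOBAL = ["Stems", "Branches", "OverallWidth", "OverallHeight", "OverallDepth",
           "OverallVolume", "Length"]
_LOCAL = ["br_length", "br_order", "br_contraction", "bif_EucDist2soma",
          "bif_PathDist2soma", "asymmetry", "ampl_local", "ampl_remote",
          "tilt_local", "tilt_remote"]
_STATS = ["min", "max", "mean", "std"]
FEATURES47_NAMES = _GLOBAL + [f"{f}_{s}" for f in _LOCAL for s in _STATS]


def features47(tree: NeuronTree, overall_volume="bbox") -> pd.Series:
    """The 47-dim full-morphology vector.

    ``overall_volume`` selects the bounding-box sense (width×height×depth,
    default) or the summed-compartment ``Volume``. Trees without
    bifurcations report 0 for the bifurcation statistics (flagged via the
    ``no_bifurcations`` attribute on the returned Series).
    """
    lm = lmeasure_features(tree)
    vals = {n: lm[n] for n in _GLOBAL if n != "OverallVolume"}
    if overall_volume == "bbox":
        vals["OverallVolume"] = lm["OverallWidth"] * lm["OverallHeight"] * lm["OverallDepth"]
    else:
        vals["OverallVolume"] = lm["Volume"]
    local = local_branch_features(tree)
    tables = {f: local["branch"][f] for f in _LOCAL[:3]}
    bif = local["bifurcation"]
    no_bif = len(bif) == 0
    for f in _LOCAL[3:]:
        tables[f] = bif[f] if not no_bif else pd.Series(dtype=float)
    for f in _LOCAL:
        x = tables[f].to_numpy(dtype=np.float64)
        if len(x) == 0:
            stats = dict.fromkeys(_STATS, 0.0)
        else:
            stats = {"min": float(x.min()), "max": float(x.max()),
                     "mean": float(x.mean()), "std": float(x.std())}
        for s in _STATS:
            vals[f"{f}_{s}"] = stats[s]
    out = pd.Series(vals, index=FEATURES47_NAMES)
    out.attrs["no_bifurcations"] = no_bif
    return out


def similarity_matrix(features: pd.DataFrame, positions, d_norm=None) -> pd.DataFrame:
    """S_ij = cosine(f_i, f_j) × exp(−d_ij / d_norm) on z-scored features.

    ``d_norm`` defaults to the maximum pairwise soma distance in the
    dataset. Zero-norm (fully average) feature vectors are an error.
    """
    X = features.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm feature vector after z-scoring")
    U = Z / norms[:, None]
    cos = U @ U.T
    P = np.asarray(positions, dtype=np.float64)
    D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    if d_norm is None:
        d_norm = D.max()
    d_norm = max(d_norm, 1e-12)
    S = cos * np.exp(-D / d_norm)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=features.index, columns=features.index)


def _affinity(S):
    A = np.clip(np.asarray(S, dtype=np.float64), 0, None)  # affinities must be >= 0
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2


def eigengap_k(S, k_max=4):
    """Largest-eigengap cluster count from the normalised Laplacian
    spectrum, searched in 1..k_max."""
    A = _affinity(S)
    d = A.sum(axis=1)
    Dm = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    L = np.eye(len(A)) - (A * Dm[:, None]) * Dm[None, :]
    w = np.sort(np.linalg.eigvalsh(L))
    k_max = min(k_max, len(w) - 1)
    gaps = [w[k] - w[k - 1] for k in range(1, k_max + 1)]
    return int(np.argmax(gaps) + 1)


def spectral_cluster(S, k, seed=0) -> np.ndarray:
    """Spectral clustering on the neuron similarity graph.

    Disconnected affinity graphs are clustered component-wise (with a
    warning), allocating clusters proportionally to component size.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    A = _affinity(S)
    n_comp, comp = connected_components((A > 1e-12).astype(np.int8), directed=False)
    labels = np.zeros(len(A), dtype=int)
    if n_comp == 1:
        sc = SpectralClustering(n_clusters=k, affinity="precomputed", random_state=seed)
        return sc.fit_predict(A)
    warnings.warn(f"similarity graph has {n_comp} components; clustering each separately")
    sizes = np.bincount(comp)
    alloc = np.maximum(1, np.round(k * sizes / sizes.sum()).astype(int))
    while alloc.sum() > k:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < k:
        alloc[np.argmax(sizes - alloc)] += 1
    offset = 0
    for ci in range(n_comp):
        idx = np.nonzero(comp == ci)[0]
        kc = min(alloc[ci], len(idx))
        if kc <= 1 or len(idx) <= kc:
            labels[idx] = offset
            offset += max(1, kc)
            continue
        sc = SpectralClustering(n_clusters=kc, affinity="precomputed", random_state=seed)
        labels[idx] = sc.fit_predict(A[np.ix_(idx, idx)]) + offset
        offset += kc
    return labels


def silhouette_separation(positions, labels) -> pd.DataFrame:
    """Mean soma-position silhouette for every cluster pair
    ((b−a)/max(a,b) convention); singleton clusters score 0."""
    P = np.asarray(positions, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    out = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            m = (labels == a) | (labels == b)
            if (labels == a).sum() < 2 or (labels == b).sum() < 2:
                val = 0.0
            else:
                val = float(silhouette_score(P[m], labels[m]))
            out.loc[a, b] = out.loc[b, a] = val
    return out


def pairwise_discriminators(features: pd.DataFrame, labels, k=3):
    """Per-cluster-pair top-``k`` mRMR features and per-cluster hit rates
    (frequency of a feature entering the top-``k`` across the cluster's
    pairs)."""
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    pair_top = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            m = (labels == a) | (labels == b)
            pair_top[(a, b)] = mrmr_select(features[m], labels[m], k=k)
    hit = pd.DataFrame(0.0, index=uniq, columns=features.columns)
    for (a, b), names in pair_top.items():
        for n in names:
            hit.loc[a, n] += 1
            hit.loc[b, n] += 1
    hit /= max(1, len(uniq) - 1)
    return pair_top, hit


def branch_distance_profile(trees, labels, bin_um=30.0):
    """Per-cluster mean ± sd of bifurcation counts in soma-distance bins.

    Distances are Euclidean bifurcation-to-soma; the binning is shared
    across clusters. Returns ``{label: DataFrame(bin_left, mean, sd)}``.
    """
    if bin_um <= 0:
        raise ValueError("bin must be positive")
    labels = np.asarray(labels)
    dists = []
    for t in trees:
        bp = t.branch_points()
        dists.append(np.linalg.norm(t.xyz[bp] - t.soma_xyz, axis=1) if len(bp) else np.empty(0))
    dmax = max((d.max() for d in dists if len(d)), default=bin_um)
    edges = np.arange(0.0, dmax + bin_um, bin_um)
    out = {}
    for lab in sorted(np.unique(labels)):
        counts = np.array([np.histogram(dists[i], bins=edges)[0]
                           for i in np.nonzero(labels == lab)[0]])
        out[lab] = pd.DataFrame({
            "bin_left": edges[:-1],
            "mean": counts.mean(axis=0),
            "sd": counts.std(axis=0),
        })
    return out
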