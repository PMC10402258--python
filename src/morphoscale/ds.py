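"""Cross-scale features and the Diversity-and-Stereotypy (DS) matrix.

Each neuron is described by an 84-dim vector concatenating z-scored blocks
from five morphometric scales — microenvironment (18), full morphology
(18), arbors (4 arbors × 4 features = 16), boutons (6) and primary-tract
motif (26). The DS matrix entry for two neuron types is the average Pearson
correlation over all cross-type neuron pairs; the diagonal (intra-type,
self-pairs excluded) measures stereotypy, off-diagonal entries diversity.
Derived summaries: per-scale DS matrices and intra-type correlation
distributions, inter-scale DS distances, distribution moments, and the
pairwise correlation versus soma/axon distance relationship.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BLOCK_COMPOSITION", "cross_scale_table", "ds_matrix", "per_scale_ds",
    "scale_distances", "moment_summary", "distance_vs_correlation",
]

BLOCK_COMPOSITION = {
    "microenviron": 18,
    "fullMorpho": 18,
    "arbor": 16,
    "bouton": 6,
    "motif": 26,
}


def composition_hash(composition=None):
    composition = composition or BLOCK_COMPOSITION
    s = ",".join(f"{k}:{v}" for k, v in sorted(composition.items()))
    return hashlib.sha1(s.encode()).hexdigest()[:12]


def cross_scale_table(blocks: dict, composition=None) -> pd.DataFrame:
    """Concatenate per-scale feature blocks into the cross-scale table.

    ``blocks`` maps block name → DataFrame (same neuron index everywhere).
    Every column is z-scored over the population (zero-variance columns
    become 0); a missing or mis-sized block raises an error naming the
    stage. Column names are prefixed with their block; the composition hash
    is stored in ``attrs``.
    """
    composition = composition or BLOCK_COMPOSITION
    missing = [k for k in composition if k not in blocks]
    if missing:
        raise ValueError(f"missing cross-scale block(s): {', '.join(missing)}")
    index = None
    parts = []
    for name, dim in composition.items():
        df = blocks[name]
        if df.shape[1] != dim:
            raise ValueError(f"block {name!r} has {df.shape[1]} dims, expected {dim}")
        if index is None:
            index = df.index
        elif not df.index.equals(index):
            raise ValueError(f"block {name!r} index disagrees with the other blocks")
        X = df.to_numpy(dtype=np.float64)
        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        Z[:, sd == 0] = 0.0
        parts.append(pd.DataFrame(Z, index=index,
                                  columns=[f"{name}.{c}" for c in df.columns]))
    out = pd.concat(parts, axis=1)
    out.attrs["composition"] = dict(composition)
    out.attrs["composition_hash"] = composition_hash(composition)
    return out


def _pair_correlations(X):
    """Row-wise Pearson correlation matrix; zero-variance rows → NaN."""
    X = np.asarray(X, dtype=np.float64)
    sd = X.std(axis=1)
    ok = sd > 0
    R = np.full((len(X), len(X)), np.nan)
    if ok.sum() >= 1:
        Z = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        C = Z @ Z.T / X.shape[1]
        R[np.ix_(ok, ok)] = np.clip(C, -1, 1)
    return R


def ds_matrix(vectors: pd.DataFrame, labels) -> pd.DataFrame:
    """Type × type DS matrix of average pairwise Pearson correlations.

    Intra-type (diagonal) averages exclude self-pairs; types with a single
    member get a NaN diagonal. Undefined correlations (zero-variance
    vectors) are excluded from the averages with a warning.
    """
    labels = np.asarray(labels)
    R = _pair_correlations(vectors.to_numpy())
    if np.isnan(np.diag(R)).any():
        warnings.warn("zero-variance cross-scale vectors excluded from DS averages")
    uniq = sorted(pd.unique(labels))
    out = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    for i, u in enumerate(uniq):
        iu = np.nonzero(labels == u)[0]
        for v in uniq[i:]:
            iv = np.nonzero(labels == v)[0]
            sub = R[np.ix_(iu, iv)]
            if u == v:
                if len(iu) < 2:
                    continue
                vals = sub[np.triu_indices(len(iu), 1)]
            else:
                vals = sub.ravel()
            vals = vals[np.isfinite(vals)]
            if len(vals):
                out.loc[u, v] = out.loc[v, u] = float(vals.mean())
    return out


def per_scale_ds(vectors: pd.DataFrame, labels, composition=None):
    """One DS matrix per block plus per-type intra-type correlation
    distributions: ``(matrices, distributions)`` with
    ``distributions[scale][type]`` an array of n(n−1)/2 pair values."""
    composition = composition or vectors.attrs.get("composition") or BLOCK_COMPOSITION
    labels = np.asarray(labels)
    matrices, dists = {}, {}
    for name in composition:
        cols = [c for c in vectors.columns if c.startswith(f"{name}.")]
        sub = vectors[cols]
        matrices[name] = ds_matrix(sub, labels)
        R = _pair_correlations(sub.to_numpy())
        dd = {}
        for u in sorted(pd.unique(labels)):
            iu = np.nonzero(labels == u)[0]
            vals = R[np.ix_(iu, iu)][np.triu_indices(len(iu), 1)]
            dd[u] = vals[np.isfinite(vals)]
        dists[name] = dd
    return matrices, dists


def scale_distances(matrices: dict) -> pd.DataFrame:
    """Scale × scale distances: 1 − Pearson correlation of the vectorised
    upper triangles (diagonal included) of the DS matrices."""
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 scales")
    vecs = {}
    n = len(next(iter(matrices.values())))
    iu = np.triu_indices(n)
    for k, m in matrices.items():
        vecs[k] = m.to_numpy()[iu]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = vecs[a], vecs[b]
            ok = np.isfinite(va) & np.isfinite(vb)
            r = float(np.corrcoef(va[ok], vb[ok])[0, 1]) if ok.sum() > 1 else np.nan
            out.loc[a, b] = out.loc[b, a] = 1.0 - r
    return out


def moment_summary(distributions: dict) -> pd.DataFrame:
    """Type × scale table of mean, sd, skewness and excess kurtosis of the
    intra-type correlation distributions; higher moments of tiny or
    degenerate samples are flagged unstable (NaN)."""
    rows = []
    for scale, per_type in distributions.items():
        for t, vals in per_type.items():
            vals = np.asarray(vals, dtype=np.float64)
            row = {"type": t, "scale": scale, "n": len(vals),
                   "mean": np.nan, "sd": np.nan, "skew": np.nan, "kurtosis": np.nan,
                   "unstable": True}
            if len(vals):
                row["mean"] = float(vals.mean())
                row["sd"] = float(vals.std())
            if len(vals) >= 4 and vals.std() > 0:
                row["skew"] = float(stats.skew(vals))
                row["kurtosis"] = float(stats.kurtosis(vals))
                row["unstable"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def distance_vs_correlation(vectors: pd.DataFrame, positions, projections=None,
                            max_range=None, n_bins=10):
    """Pairwise cross-scale correlation versus pair distance.

    Soma-to-soma distance always; axon-to-axon distance (Euclidean between
    projection vectors) when ``projections`` is given. For each distance
    kind: binned mean ± sd of the pair correlations and the slope /
    correlation of a linear fit restricted to pairs within ``max_range``.
    """
    R = _pair_correlations(vectors.to_numpy())
    n = len(R)
    iu = np.triu_indices(n, 1)
    r = R[iu]
    P = np.asarray(positions, dtype=np.float64)
    soma_d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)[iu]
    kinds = {"soma": soma_d}
    if projections is not None:
        V = np.asarray(projections, dtype=np.float64)
        kinds["axon"] = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=-1)[iu]
    out = {}
    for kind, d in kinds.items():
        ok = np.isfinite(r) & np.isfinite(d)
        dd, rr = d[ok], r[ok]
        lim = max_range if max_range is not None else dd.max()
        edges = np.linspace(0, max(lim, 1e-9), n_bins + 1)
        idx = np.clip(np.digitize(dd, edges) - 1, 0, n_bins - 1)
        means = np.full(n_bins, np.nan)
        sds = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = (idx == b) & (dd <= lim)
            if m.any():
                means[b], sds[b] = rr[m].mean(), rr[m].std()
        fit_mask = dd <= lim
        if fit_mask.sum() > 2 and dd[fit_mask].std() > 0:
            slope, intercept = np.polyfit(dd[fit_mask], rr[fit_mask], 1)
            corr = float(np.corrcoef(dd[fit_mask], rr[fit_mask])[0, 1])
        else:
            slope, intercept, corr = np.nan, np.nan, np.nan
        out[kind] = {
            "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
            "mean": means, "sd": sds,
            "slope": float(slope), "intercept": float(intercept), "fit_corr": corr,
        }
    return out
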