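"""Region co-occurrence analysis across brains.

From a regions × brains neurite-density matrix (columns sum to 1) this
module derives the pairwise Spearman correlation map, per-compound-area
consistency distributions, target-correlated region sets (ρ ≥ 0.8 by
default), initial modules from a dendrogram walk constrained to 3–15
regions, and tight modules obtained by discarding regions that rarely occur
in the target-correlated sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

__all__ = [
    "ModuleSet", "correlation_map", "intra_area_consistency",
    "target_correlated_sets", "initial_modules", "tight_modules",
]


@dataclass
class ModuleSet:
    modules: list                      # list of lists of region ids
    consistency: list = field(default_factory=list)
    stage: str = "initial"

    def __len__(self):
        return len(self.modules)


def correlation_map(md: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of regions over the brain axis.

    Constant rows have no defined rank correlation; their entries are set to
    0 with a warning. The diagonal is 1.
    """
    X = md.to_numpy(dtype=np.float64)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 brains")
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant region rows: correlation set to 0")
        sd = np.where(const, 1.0, sd)
    Z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    C = Z @ Z.T / X.shape[1]
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2, -1, 1)
    return pd.DataFrame(C, index=md.index, columns=md.index)


def intra_area_consistency(mc: pd.DataFrame, region_to_area: dict) -> dict:
    """Per compound area, the list of pairwise correlations between its
    regions (empty for single-region areas)."""
    out = {}
    areas = {}
    for r, a in region_to_area.items():
        areas.setdefault(a, []).append(r)
    for a, regions in sorted(areas.items()):
        regions = [r for r in regions if r in mc.index]
        vals = []
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                vals.append(float(mc.loc[regions[i], regions[j]]))
        out[a] = vals
    return out


def target_correlated_sets(mc: pd.DataFrame, cutoff=0.8, region_to_area=None):
    """For each target region, the set of other regions with ρ ≥ ``cutoff``.

    Returns a DataFrame with columns target, partners (tuple), kind
    (intra_ca / cross_ca / empty) when a hierarchy is supplied.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    rows = []
    for r in mc.index:
        s = mc.loc[r].drop(r)
        partners = tuple(s.index[s >= cutoff])
        kind = "empty"
        if partners:
            if region_to_area is not None:
                same = all(region_to_area.get(p) == region_to_area.get(r) for p in partners)
                kind = "intra_ca" if same else "cross_ca"
            else:
                kind = "nonempty"
        rows.append({"target": r, "partners": partners, "kind": kind})
    return pd.DataFrame(rows)


def initial_modules(mc: pd.DataFrame, min_size=3, max_size=15,
                    linkage_method="average") -> ModuleSet:
    """Disjoint cover of all regions by dendrogram clusters of 3–15 regions.

    Agglomerative clustering (average linkage by default) on distance 1−ρ,
    cut where consecutive merge heights jump the most (the first diverging
    level of the dendrogram). Clusters above ``max_size`` are re-cut
    recursively; clusters below ``min_size`` are merged into their
    most-correlated module, so the result is a disjoint exhaustive cover.
    """
    regions = list(mc.index)
    if len(regions) < min_size:
        raise ValueError("need at least min_size regions")
    C = mc.to_numpy()

    def cut(idx):
        """Split index subset at the largest merge-height gap; returns a
        list of clusters each within max_size (recursing as needed)."""
        if len(idx) <= max_size:
            return [list(idx)]
        D = 1.0 - C[np.ix_(idx, idx)]
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(D[np.triu_indices(len(idx), 1)], method=linkage_method)
        h = Z[:, 2]
        gaps = np.diff(h)
        if len(gaps) == 0 or gaps.max() <= 0:
            labels = hierarchy.fcluster(Z, 2, criterion="maxclust")
        else:
            t = 0.5 * (h[np.argmax(gaps)] + h[np.argmax(gaps) + 1])
            labels = hierarchy.fcluster(Z, t, criterion="distance")
        if len(np.unique(labels)) == 1:
            # degenerate (all distances equal): split in dendrogram leaf order
            order = hierarchy.leaves_list(Z)
            half = len(order) // 2
            labels = np.zeros(len(idx), dtype=int)
            labels[order[half:]] = 1
        out = []
        for lab in np.unique(labels):
            sub = [idx[i] for i in np.nonzero(labels == lab)[0]]
            out.extend(cut(sub))
        return out

    clusters = cut(list(range(len(regions))))
    modules = [c for c in clusters if len(c) >= min_size]
    rest = [i for c in clusters if len(c) < min_size for i in c]
    if not modules:  # degenerate: everything tiny — chunk in order
        modules, rest = [rest[:max_size]], rest[max_size:]
    for i in rest:  # attach stragglers to their most-correlated module
        best, best_val = 0, -np.inf
        for mi, m in enumerate(modules):
            if len(m) >= max_size:
                continue
            val = float(np.mean(C[i, m]))
            if val > best_val:
                best, best_val = mi, val
        modules[best].append(i)
    return ModuleSet([sorted(regions[i] for i in m) for m in modules],
                     stage="initial")


def _consistency(mc, module):
    vals = [float(mc.loc[a, b]) for i, a in enumerate(module) for b in module[i + 1:]]
    return float(np.mean(vals)) if vals else np.nan


def tight_modules(initial: ModuleSet, target_sets: pd.DataFrame, mc: pd.DataFrame,
                  min_occurrence=2, min_regions=2) -> ModuleSet:
    """Refine initial modules: drop regions occurring fewer than
    ``min_occurrence`` times across the target-correlated sets, keep modules
    with at least ``min_regions`` left, and attach the mean within-module
    Spearman correlation as the consistency score."""
    occur = {}
    for partners in target_sets["partners"]:
        for p in partners:
            occur[p] = occur.get(p, 0) + 1
    mods, cons = [], []
    for m in initial.modules:
        kept = [r for r in m if occur.get(r, 0) >= min_occurrence]
        if len(kept) >= min_regions:
            mods.append(kept)
            cons.append(_consistency(mc, kept))
    return ModuleSet(mods, cons, stage="tight")
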