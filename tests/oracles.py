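"""Naive per-definition oracle implementations used to validate the fast
library code. Everything here is written with plain loops and explicit
formulas, independent of the implementation under test."""

import math

import numpy as np


def build_maps(tree):
    children = {int(i): [] for i in tree.ids}
    parent = {}
    for k in range(tree.n_nodes):
        i = int(tree.ids[k])
        p = int(tree.parent[k])
        parent[i] = p
        if p != -1:
            children[p].append(i)
    return children, parent


def _xyz(tree, i):
    return tree.xyz[np.nonzero(tree.ids == i)[0][0]]


def _radius(tree, i):
    return float(tree.radius[np.nonzero(tree.ids == i)[0][0]])


def _root_id(tree):
    return int(tree.ids[np.nonzero(tree.parent == -1)[0][0]])


def naive_branches(tree):
    """Branches as id-paths between critical points, with orders."""
    children, parent = build_maps(tree)
    root = _root_id(tree)
    out = []

    def walk(start, first, order):
        path = [start, first]
        cur = first
        while len(children[cur]) == 1:
            cur = children[cur][0]
            path.append(cur)
        out.append((path, order))
        for c in sorted(children[cur]):
            walk(cur, c, order + 1)

    for c in sorted(children[root]):
        walk(root, c, 1)
    return out


def _path_length(tree, path):
    return sum(float(np.linalg.norm(_xyz(tree, a) - _xyz(tree, b)))
               for a, b in zip(path[:-1], path[1:]))


def _angle(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(u, v)) / (nu * nv)))))


def _tips_below(tree, i, children):
    if not children[i]:
        return 1
    return sum(_tips_below(tree, c, children) for c in children[i])


def naive_lmeasure(tree, hausdorff_fn=None):
    """The 22 whole-neuron features from first principles."""
    children, parent = build_maps(tree)
    root = _root_id(tree)
    ids = [int(i) for i in tree.ids]
    length = sum(float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, parent[i])))
                 for i in ids if parent[i] != -1)
    surface = sum(2 * math.pi * _radius(tree, i) *
                  float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, parent[i])))
                  for i in ids if parent[i] != -1)
    volume = sum(math.pi * _radius(tree, i) ** 2 *
                 float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, parent[i])))
                 for i in ids if parent[i] != -1)

    def path_dist(i):
        d = 0.0
        while parent[i] != -1:
            d += float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, parent[i])))
            i = parent[i]
        return d

    branches = naive_branches(tree)
    contractions = []
    frags = []
    for path, order in branches:
        pl = _path_length(tree, path)
        span = float(np.linalg.norm(_xyz(tree, path[-1]) - _xyz(tree, path[0])))
        if pl > 0:
            contractions.append(span / pl)
        frags.append(len(path) - 1)

    ratios = []
    loc_angles, rem_angles = [], []
    branch_of_first = {path[1]: (path, order) for path, order in branches}
    for i in ids:
        if i == root or len(children[i]) < 2:
            continue
        rp = _radius(tree, i)
        if rp > 0:
            for c in children[i]:
                ratios.append(_radius(tree, c) / rp)
        kids = sorted(children[i])
        for a, b in zip(kids[:-1], kids[1:]):
            pa, _ = branch_of_first[a]
            pb, _ = branch_of_first[b]
            loc_angles.append(_angle(_xyz(tree, a) - _xyz(tree, i),
                                     _xyz(tree, b) - _xyz(tree, i)))
            rem_angles.append(_angle(_xyz(tree, pa[-1]) - _xyz(tree, i),
                                     _xyz(tree, pb[-1]) - _xyz(tree, i)))

    xs = tree.xyz
    out = {
        "Nodes": float(len(ids)),
        "SomaSurface": 4 * math.pi * _radius(tree, root) ** 2,
        "Stems": float(len(children[root])),
        "Bifurcations": float(sum(len(children[i]) - 1 for i in ids
                                  if i != root and len(children[i]) >= 2)),
        "Branches": float(len(branches)),
        "Tips": float(sum(1 for i in ids if not children[i])),
        "OverallWidth": float(xs[:, 0].max() - xs[:, 0].min()),
        "OverallHeight": float(xs[:, 1].max() - xs[:, 1].min()),
        "OverallDepth": float(xs[:, 2].max() - xs[:, 2].min()),
        "AverageDiameter": float(np.mean([2 * _radius(tree, i) for i in ids])),
        "Length": length,
        "Surface": surface,
        "Volume": volume,
        "MaxEuclideanDistance": max(float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, root)))
                                    for i in ids),
        "MaxPathDistance": max(path_dist(i) for i in ids),
        "MaxBranchOrder": float(max((o for _, o in branches), default=0)),
        "AverageContraction": float(np.mean(contractions)) if contractions else 1.0,
        "AverageFragmentation": float(np.mean(frags)) if frags else 0.0,
        "AverageParent-daughterRatio": float(np.mean(ratios)) if ratios else 0.0,
        "AverageBifurcationAngleLocal": float(np.mean(loc_angles)) if loc_angles else 0.0,
        "AverageBifurcationAngleRemote": float(np.mean(rem_angles)) if rem_angles else 0.0,
    }
    if hausdorff_fn is not None:
        out["HausdorffDimension"] = hausdorff_fn(tree)
    return out


def naive_local_features(tree):
    """The 10 local features per branch / per bifurcation pair."""
    children, parent = build_maps(tree)
    root = _root_id(tree)
    branches = naive_branches(tree)
    br = [{"br_length": _path_length(tree, p),
           "br_order": float(o),
           "br_contraction": (float(np.linalg.norm(_xyz(tree, p[-1]) - _xyz(tree, p[0])))
                              / _path_length(tree, p)) if _path_length(tree, p) > 0 else 1.0}
          for p, o in branches]
    branch_of_first = {p[1]: p for p, _ in branches}
    branch_ending_at = {p[-1]: p for p, _ in branches}

    def path_dist(i):
        d = 0.0
        while parent[i] != -1:
            d += float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, parent[i])))
            i = parent[i]
        return d

    bif = []
    for i in [int(x) for x in tree.ids]:
        if i == root or len(children[i]) < 2:
            continue
        kids = sorted(children[i])
        for a, b in zip(kids[:-1], kids[1:]):
            pa, pb = branch_of_first[a], branch_of_first[b]
            n1 = _tips_below(tree, a, children)
            n2 = _tips_below(tree, b, children)
            asym = abs(n1 - n2) / (n1 + n2 - 2) if n1 + n2 > 2 else 0.0
            row = {
                "bif_EucDist2soma": float(np.linalg.norm(_xyz(tree, i) - _xyz(tree, root))),
                "bif_PathDist2soma": path_dist(i),
                "asymmetry": asym,
                "ampl_local": _angle(_xyz(tree, a) - _xyz(tree, i),
                                     _xyz(tree, b) - _xyz(tree, i)),
                "ampl_remote": _angle(_xyz(tree, pa[-1]) - _xyz(tree, i),
                                      _xyz(tree, pb[-1]) - _xyz(tree, i)),
            }
            if parent[i] != -1:
                pbr = branch_ending_at[i]
                u_loc = _xyz(tree, parent[i]) - _xyz(tree, i)
                u_rem = _xyz(tree, pbr[0]) - _xyz(tree, i)
                row["tilt_local"] = min(_angle(u_loc, _xyz(tree, a) - _xyz(tree, i)),
                                        _angle(u_loc, _xyz(tree, b) - _xyz(tree, i)))
                row["tilt_remote"] = min(_angle(u_rem, _xyz(tree, pa[-1]) - _xyz(tree, i)),
                                         _angle(u_rem, _xyz(tree, pb[-1]) - _xyz(tree, i)))
            else:
                row["tilt_local"] = row["tilt_remote"] = 0.0
            bif.append(row)
    return br, bif


def naive_silhouette(points, labels):
    """Mean silhouette (b−a)/max(a,b), directly per point."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    vals = []
    for i in range(len(points)):
        same = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(np.mean([np.linalg.norm(points[i] - points[j])
                         for j in range(len(points)) if labels[j] == lab])
                for lab in set(labels) - {labels[i]})
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def naive_ds_entry(X, idx_u, idx_v):
    """Average pairwise Pearson correlation between two index groups,
    self-pairs excluded for the intra case."""
    vals = []
    same = list(idx_u) == list(idx_v)
    for ii, i in enumerate(idx_u):
        for jj, j in enumerate(idx_v):
            if same and jj <= ii:
                continue
            xi, xj = np.asarray(X[i], float), np.asarray(X[j], float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            vals.append(float(np.corrcoef(xi, xj)[0, 1]))
    return float(np.mean(vals)) if vals else np.nan


def naive_moments(vals):
    vals = np.asarray(vals, float)
    n = len(vals)
    mu = vals.mean()
    sd = vals.std()
    skew = np.mean(((vals - mu) / sd) ** 3) if sd > 0 else np.nan
    kurt = np.mean(((vals - mu) / sd) ** 4) - 3 if sd > 0 else np.nan
    return mu, sd, skew, kurt
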