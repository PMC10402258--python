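"""Curation of automatically traced local dendrites.

A raw tracer output is cleaned by a consensus merge against a second
tracer's reconstruction and four geometric pruning filters (branch angle /
radius jumps, crossover resolution, foreign-soma cuts, winding paths). Each
filter is an independent pass over the raw tree; the curated tree is the
intersection of all surviving node sets, reconnected from the root, and
discarded outright when fewer than 20 nodes survive.

All filters iterate their rule to a fixed point, so running a filter on its
own output changes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import NeuronTree, branch_decompose

__all__ = [
    "PruningReport", "soma_neighborhood_filter", "consensus_merge",
    "prune_geometry", "prune_crossovers", "prune_foreign_somas",
    "prune_winding", "curate",
]

MIN_NODES = 20


@dataclass
class PruningReport:
    removed: dict = field(default_factory=dict)   # filter name -> nodes removed
    final_nodes: int = 0
    discard: bool = False


def soma_neighborhood_filter(somas, radius=128.0, max_neighbors=5):
    """Keep somas with at most ``max_neighbors`` others within ``radius`` μm."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    somas = np.atleast_2d(np.asarray(somas, dtype=np.float64))
    if len(somas) == 0:
        return somas
    tree = cKDTree(somas)
    counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in somas])
    return somas[counts <= max_neighbors]


def _drop_with_descendants(tree: NeuronTree, bad_indices):
    """Surviving node index set after removing ``bad_indices`` and all their
    descendants."""
    bad = set(int(b) for b in bad_indices)
    if not bad:
        return set(range(tree.n_nodes))
    children = tree.children_lists()
    stack = list(bad)
    while stack:
        k = stack.pop()
        for c in children[k]:
            if c not in bad:
                bad.add(c)
                stack.append(c)
    return set(range(tree.n_nodes)) - bad


def _rebuild(tree: NeuronTree, keep_set):
    keep = sorted(keep_set)
    if tree.root not in keep_set:
        keep = [tree.root] + keep
    return tree.select(np.array(keep, dtype=np.int64))


def consensus_merge(primary: NeuronTree, reference: NeuronTree, tol=5.0) -> NeuronTree:
    """Prune primary nodes lacking a reference node within ``tol`` (plus
    descendants). Roots farther apart than ``tol`` trigger a warning and no
    merge."""
    if np.linalg.norm(primary.soma_xyz - reference.soma_xyz) > tol:
        warnings.warn("tracer roots disagree beyond tolerance; skipping consensus merge")
        return primary
    ref = cKDTree(reference.xyz)
    d, _ = ref.query(primary.xyz, k=1)
    bad = np.nonzero(d > tol)[0]
    bad = bad[bad != primary.root]
    return _rebuild(primary, _drop_with_descendants(primary, bad))


# -- angle conventions ------------------------------------------------------
# branch angle = angle between (parent branch end->start) and (child branch
# start->end): a straight continuation reads 180 deg, a double-back ~0 deg.

def _angle(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 180.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1, 1)
    return float(np.degrees(np.arccos(c)))


def _fixed_point(tree, one_pass):
    """Iterate ``one_pass`` (tree -> tree or None) until stable."""
    while True:
        nxt = one_pass(tree)
        if nxt is None or nxt.n_nodes == tree.n_nodes:
            return nxt if nxt is not None else tree
        tree = nxt


def prune_geometry(tree: NeuronTree, angle_min=80.0, radius_factor=1.5) -> NeuronTree:
    """Remove branches turning more sharply than ``angle_min`` against their
    parent or whose mean radius exceeds ``radius_factor`` times the parent
    branch's mean radius (subtrees included)."""

    def one_pass(t):
        branches = branch_decompose(t)
        bad_nodes = []
        for b in branches:
            if b.parent_branch < 0:
                continue
            pb = branches[b.parent_branch]
            u = t.xyz[pb.start] - t.xyz[pb.end]
            v = t.xyz[b.end] - t.xyz[b.start]
            r_child = float(np.mean(t.radius[b.nodes[1:]]))
            r_parent = float(np.mean(t.radius[pb.nodes[1:]])) if len(pb.nodes) > 1 else r_child
            if _angle(u, v) < angle_min or (r_parent > 0 and r_child > radius_factor * r_parent):
                bad_nodes.append(b.nodes[1])
        if not bad_nodes:
            return None
        return _rebuild(t, _drop_with_descendants(t, bad_nodes))

    return _fixed_point(tree, one_pass)


def _crossover_structures(t, branches, fuse_dist):
    """Crossovers: (parent_branch_idx, [child_branch_idx...]) with children
    from multifurcations or from two consecutive bifurcations closer than
    ``fuse_dist``."""
    by_start = {}
    for i, b in enumerate(branches):
        by_start.setdefault(b.start, []).append(i)
    nch = t.n_children()
    structures = []
    used = set()
    for i, b in enumerate(branches):
        end = b.end
        kids = by_start.get(end, [])
        if len(kids) > 2:  # multifurcation
            structures.append((i, list(kids)))
            used.add(end)
        elif len(kids) == 2 and nch[end] == 2:
            # consecutive bifurcations within fuse_dist
            for j in kids:
                e2 = branches[j].end
                if len(by_start.get(e2, [])) >= 2 and \
                        np.linalg.norm(t.xyz[e2] - t.xyz[end]) < fuse_dist:
                    others = [x for x in kids if x != j]
                    structures.append((i, others + by_start[e2]))
                    break
    return structures


def prune_crossovers(tree: NeuronTree, angle_small=80.0, angle_mid=100.0,
                     angle_large=150.0, fuse_dist=5.0) -> NeuronTree:
    """Resolve crossover structures (multifurcations and near-coincident
    bifurcation pairs) via three angle bands.

    Children turning < ``angle_small`` against the parent are removed.
    A mediocre child (``angle_small``–``angle_mid``) that subtends more than
    ``angle_large`` with a sibling is part of a through-going line crossing
    the structure; the pair belongs to a different process and is removed.
    """

    def one_pass(t):
        branches = branch_decompose(t)
        bad = []
        for pi, kids in _crossover_structures(t, branches, fuse_dist):
            pb = branches[pi]
            u = t.xyz[pb.start] - t.xyz[pb.end]
            ang = {}
            vecs = {}
            for k in kids:
                cb = branches[k]
                origin = t.xyz[cb.start]
                v = t.xyz[cb.end] - origin
                vecs[k] = v
                ang[k] = _angle(u, v)
            for k in kids:
                if ang[k] < angle_small:
                    bad.append(branches[k].nodes[1])
                elif ang[k] <= angle_mid:
                    partners = [o for o in kids if o != k and _angle(vecs[k], vecs[o]) > angle_large]
                    if partners:
                        bad.append(branches[k].nodes[1])
        if not bad:
            return None
        return _rebuild(t, _drop_with_descendants(t, bad))

    return _fixed_point(tree, one_pass)


def _deviation(t, branch, soma_xyz):
    """Angle between a branch and the radial line from ``soma_xyz`` to the
    branch end nearer to that soma."""
    a, b = t.xyz[branch.start], t.xyz[branch.end]
    if np.linalg.norm(a - soma_xyz) <= np.linalg.norm(b - soma_xyz):
        radial, direction = a - soma_xyz, b - a
    else:
        radial, direction = b - soma_xyz, a - b
    if np.linalg.norm(radial) == 0:
        return 0.0
    return _angle(radial, direction)


def prune_foreign_somas(tree: NeuronTree, radius_px=5.0, area_px2=500.0,
                        guard_px=50.0) -> NeuronTree:
    """Cut paths leading to putative foreign somas.

    Large-radius nodes (projected xy area of nearby candidates above
    ``area_px2``) away from the guarded neighbourhood of the true soma mark
    a foreign soma. The root→foreign path is cut at the branch boundary
    minimising the length-weighted deviation-angle integral of each side
    towards its soma; ties keep the side with more nodes.
    """

    def one_pass(t):
        big = np.nonzero((t.radius > radius_px) &
                         (np.linalg.norm(t.xyz - t.soma_xyz, axis=1) >= guard_px))[0]
        big = big[big != t.root]
        if len(big) == 0:
            return None
        # cluster candidate nodes within 10 px; total projected area per cluster
        kd = cKDTree(t.xyz[big])
        seen = np.zeros(len(big), bool)
        foreign = None
        for i in range(len(big)):
            if seen[i]:
                continue
            grp = kd.query_ball_point(t.xyz[big[i]], 10.0)
            seen[grp] = True
            area = float(np.sum(np.pi * t.radius[big[grp]] ** 2))
            if area > area_px2:
                grp_idx = big[np.asarray(grp)]
                foreign = grp_idx[np.argmax(t.radius[grp_idx])]
                break
        if foreign is None:
            return None
        f_xyz = t.xyz[foreign]
        # root→foreign node path; the deviation integral is evaluated per
        # edge so the cut can land anywhere along the fibre
        path = [int(foreign)]
        while path[-1] != t.root:
            path.append(int(t.parent_index[path[-1]]))
        path = path[::-1]
        edges = list(zip(path[:-1], path[1:]))
        lens = np.array([np.linalg.norm(t.xyz[b] - t.xyz[a]) for a, b in edges])

        def edge_dev(a, b, soma, toward_root):
            if toward_root:
                radial, direction = t.xyz[a] - soma, t.xyz[b] - t.xyz[a]
            else:
                radial, direction = t.xyz[b] - soma, t.xyz[a] - t.xyz[b]
            if np.linalg.norm(radial) == 0:
                return 0.0
            return _angle(radial, direction)

        dev_true = np.array([edge_dev(a, b, t.soma_xyz, True) for a, b in edges])
        dev_for = np.array([edge_dev(a, b, f_xyz, False) for a, b in edges])
        soma_d = np.linalg.norm(t.xyz[path] - t.soma_xyz, axis=1)
        n = len(edges)
        best_cost, best_cut = np.inf, None
        for cut in range(n):  # removing path[cut+1:] (edge `cut` crosses the cut)
            if soma_d[cut + 1] < guard_px:  # guarded neighbourhood never cut
                continue
            cost = float((lens[:cut] * dev_true[:cut]).sum() +
                         (lens[cut:] * dev_for[cut:]).sum())
            if best_cost - cost > 1e-9 or (abs(cost - best_cost) <= 1e-9 and
                                           best_cut is not None and cut > best_cut):
                best_cost, best_cut = cost, cut
        keep_cost = float((lens * dev_true).sum())
        if best_cut is None or keep_cost < best_cost - 1e-9:
            return None
        return _rebuild(t, _drop_with_descendants(t, [path[best_cut + 1]]))

    return _fixed_point(tree, one_pass)


def prune_winding(tree: NeuronTree, max_ratio=3.0, mode="to_soma") -> NeuronTree:
    """Remove circuitous branches: path/Euclidean ratio strictly above
    ``max_ratio``, measured per branch (``mode='branch'``) or over the
    root→branch-end path (``mode='to_soma'``, default)."""

    def one_pass(t):
        branches = branch_decompose(t)
        pathd = t.path_dist_to_root()
        bad = []
        for b in branches:
            if mode == "branch":
                p, e = b.path_length, b.euclidean_span
            else:
                p = pathd[b.end]
                e = float(np.linalg.norm(t.xyz[b.end] - t.soma_xyz))
            if e > 0 and p / e > max_ratio:
                bad.append(b.nodes[1])
        if not bad:
            return None
        return _rebuild(t, _drop_with_descendants(t, bad))

    return _fixed_point(tree, one_pass)


def _surviving_ids(original: NeuronTree, filtered: NeuronTree):
    return set(int(i) for i in filtered.ids) if filtered is not None else set()


def curate(tree: NeuronTree, reference: NeuronTree | None = None, block=None,
           min_nodes=MIN_NODES):
    """Full curation: independent filter passes intersected by node id, then
    reconnected from the root; trees below ``min_nodes`` are flagged for
    discard. Returns ``(tree, PruningReport)``."""
    passes = {}
    if reference is not None:
        passes["consensus"] = consensus_merge(tree, reference)
    passes["geometry"] = prune_geometry(tree)
    passes["crossover"] = prune_crossovers(tree)
    passes["foreign_soma"] = prune_foreign_somas(tree)
    passes["winding"] = prune_winding(tree)

    all_ids = set(int(i) for i in tree.ids)
    keep_ids = set(all_ids)
    report = PruningReport()
    for name, ft in passes.items():
        ids = _surviving_ids(tree, ft)
        report.removed[name] = len(all_ids) - len(ids)
        keep_ids &= ids
    keep_ids.add(int(tree.ids[tree.root]))
    # largest rooted component: walk from root through surviving nodes only
    id_to_idx = {int(i): k for k, i in enumerate(tree.ids)}
    keep_idx = {id_to_idx[i] for i in keep_ids}
    children = tree.children_lists()
    reach = set()
    stack = [tree.root]
    while stack:
        k = stack.pop()
        reach.add(k)
        for c in children[k]:
            if c in keep_idx and c not in reach:
                stack.append(c)
    curated = tree.select(np.array(sorted(reach), dtype=np.int64))
    report.final_nodes = curated.n_nodes
    report.discard = curated.n_nodes < min_nodes
    return curated, report
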