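"""Core neuron-morphology data model and morphometric features.

The central object is :class:`NeuronTree`, a rooted skeleton read from the
7-column SWC format (id, structure, x, y, z, radius, parent), with
coordinates in micrometres. On top of it this module provides branch
decomposition, the 22 whole-neuron morphometric features popularised by
L-Measure, the 10 per-branch/per-bifurcation local features, arc-length
resampling and PCA shape descriptors. Everything downstream (detectors,
microenvironments, typing, arbors, boutons) consumes these primitives.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "Branch",
    "SWCError",
    "read_swc",
    "write_swc",
    "load_dataset",
    "save_dataset",
    "branch_decompose",
    "lmeasure_features",
    "LMEASURE_NAMES",
    "local_branch_features",
    "LOCAL_FEATURE_NAMES",
    "resample_tree",
    "pca_shape_features",
]

# SWC structure codes
SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4


class SWCError(ValueError):
    """Raised on malformed or inconsistent SWC input."""


@dataclass
class NeuronNode:
    """A single SWC node (convenience view; bulk storage is array-based)."""

    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


class NeuronTree:
    """Rooted neuron skeleton backed by flat numpy arrays.

    Parameters
    ----------
    ids, structure, xyz, radius, parent
        Per-node columns. ``parent`` holds node *ids* (-1 for the root);
        ids are arbitrary positive integers.
    metadata
        Free-form dict (brain id, soma region, projection class, layer...).
    """

    def __init__(self, ids, structure, xyz, radius, parent, metadata=None, validate=True):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.structure = np.asarray(structure, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=np.float64).reshape(-1, 3)
        self.radius = np.asarray(radius, dtype=np.float64)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.metadata = dict(metadata or {})
        n = len(self.ids)
        if not (len(self.structure) == n == len(self.radius) == len(self.parent) == self.xyz.shape[0]):
            raise SWCError("column lengths disagree")
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise SWCError("duplicate node ids")
        # parent index per node (-1 for root)
        pidx = np.empty(n, dtype=np.int64)
        roots = []
        for k in range(n):
            p = int(self.parent[k])
            if p == -1:
                pidx[k] = -1
                roots.append(k)
            else:
                if p not in self._index:
                    raise SWCError(f"dangling parent id {p} (node {int(self.ids[k])})")
                pidx[k] = self._index[p]
        self.parent_index = pidx
        self._children = None
        self._order = None
        if validate:
            if len(roots) != 1:
                raise SWCError(f"expected exactly one root, found {len(roots)}")
            self.root = roots[0]
            self._check_connected()
        else:
            self.root = roots[0] if roots else -1

    # -- structural helpers -------------------------------------------------

    def _check_connected(self):
        n = len(self.ids)
        depth = np.full(n, -1, dtype=np.int64)
        depth[self.root] = 0
        order = self.topo_order()
        if len(order) != n:
            raise SWCError("tree contains a cycle or unreachable nodes")

    def topo_order(self):
        """Node indices ordered root-first (parents before children)."""
        if self._order is None:
            n = len(self.ids)
            children = self.children_lists()
            order = []
            stack = [self.root]
            seen = np.zeros(n, dtype=bool)
            while stack:
                k = stack.pop()
                if seen[k]:
                    continue
                seen[k] = True
                order.append(k)
                stack.extend(sorted(children[k], reverse=True))
            self._order = np.array(order, dtype=np.int64)
        return self._order

    def children_lists(self):
        if self._children is None:
            ch = [[] for _ in range(len(self.ids))]
            for k, p in enumerate(self.parent_index):
                if p >= 0:
                    ch[p].append(k)
            self._children = ch
        return self._children

    def n_children(self):
        return np.array([len(c) for c in self.children_lists()])

    @property
    def n_nodes(self):
        return len(self.ids)

    @property
    def soma_xyz(self):
        return self.xyz[self.root]

    def tips(self):
        return np.nonzero(self.n_children() == 0)[0]

    def branch_points(self):
        """Indices with >= 2 children, root excluded."""
        idx = np.nonzero(self.n_children() >= 2)[0]
        return idx[idx != self.root]

    def edge_lengths(self):
        """Length of the edge to the parent per node (0 at root)."""
        ell = np.zeros(self.n_nodes)
        mask = self.parent_index >= 0
        d = self.xyz[mask] - self.xyz[self.parent_index[mask]]
        ell[mask] = np.linalg.norm(d, axis=1)
        return ell

    def path_dist_to_root(self):
        ell = self.edge_lengths()
        dist = np.zeros(self.n_nodes)
        for k in self.topo_order():
            p = self.parent_index[k]
            if p >= 0:
                dist[k] = dist[p] + ell[k]
        return dist

    def subtree_indices(self, k):
        """All node indices in the subtree rooted at index ``k`` (inclusive)."""
        children = self.children_lists()
        out, stack = [], [k]
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(children[j])
        return np.array(sorted(out), dtype=np.int64)

    def select(self, keep_indices, metadata=None, validate=True):
        """Subtree restricted to ``keep_indices``; parents outside become -1."""
        keep = np.zeros(self.n_nodes, dtype=bool)
        keep[np.asarray(keep_indices, dtype=np.int64)] = True
        idx = np.nonzero(keep)[0]
        new_parent = []
        for k in idx:
            p = self.parent_index[k]
            new_parent.append(int(self.ids[p]) if (p >= 0 and keep[p]) else -1)
        return NeuronTree(
            self.ids[idx], self.structure[idx], self.xyz[idx], self.radius[idx],
            new_parent, metadata=metadata or self.metadata, validate=validate,
        )

    def node_table(self):
        return pd.DataFrame({
            "id": self.ids, "structure": self.structure,
            "x": self.xyz[:, 0], "y": self.xyz[:, 1], "z": self.xyz[:, 2],
            "radius": self.radius, "parent": self.parent,
        })

    def copy(self):
        return NeuronTree(self.ids.copy(), self.structure.copy(), self.xyz.copy(),
                          self.radius.copy(), self.parent.copy(), dict(self.metadata))

    def __repr__(self):
        return f"NeuronTree(n_nodes={self.n_nodes}, root_id={int(self.ids[self.root])})"


# -- SWC I/O ----------------------------------------------------------------

def read_swc(path, metadata=None) -> NeuronTree:
    """Read a 7-column SWC file ('#' comments allowed); coordinates in μm."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 7:
                raise SWCError(f"{path.name}:{ln}: expected 7 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                             float(parts[4]), float(parts[5]), int(parts[6])))
            except ValueError as e:
                raise SWCError(f"{path.name}:{ln}: {e}") from None
    if not rows:
        raise SWCError(f"{path.name}: no nodes")
    arr = np.array(rows, dtype=np.float64)
    return NeuronTree(arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2:5],
                      arr[:, 5], arr[:, 6].astype(np.int64), metadata=metadata)


def write_swc(tree: NeuronTree, path):
    buf = io.StringIO()
    buf.write("# id structure x y z radius parent\n")
    for k in range(tree.n_nodes):
        buf.write("%d %d %.17g %.17g %.17g %.17g %d\n" % (
            tree.ids[k], tree.structure[k], tree.xyz[k, 0], tree.xyz[k, 1],
            tree.xyz[k, 2], tree.radius[k], tree.parent[k]))
    Path(path).write_text(buf.getvalue())


def load_dataset(directory):
    """Load a directory of SWC files with a ``metadata.csv`` sidecar.

    The sidecar must have a ``neuron_id`` column matching the SWC basenames;
    further columns (brain_id, region, projection_class, layer, ...) become
    tree metadata. Returns a list of NeuronTree.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    meta = pd.read_csv(meta_path) if meta_path.exists() else None
    trees = []
    for swc in sorted(directory.glob("*.swc")):
        md = {"neuron_id": swc.stem}
        if meta is not None:
            row = meta[meta["neuron_id"].astype(str) == swc.stem]
            if len(row):
                md.update(row.iloc[0].to_dict())
        trees.append(read_swc(swc, metadata=md))
    return trees


def save_dataset(trees, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, t in enumerate(trees):
        nid = str(t.metadata.get("neuron_id", f"neuron_{i:04d}"))
        t.metadata["neuron_id"] = nid
        write_swc(t, directory / f"{nid}.swc")
        records.append(dict(t.metadata))
    pd.DataFrame(records).to_csv(directory / "metadata.csv", index=False)


# -- branch decomposition ---------------------------------------------------

@dataclass
class Branch:
    """Path between consecutive critical points (root/bifurcation/tip).

    ``nodes`` runs start→end where start is the parent-side critical node.
    Root branches have order 1.
    """

    nodes: np.ndarray          # node indices, start..end inclusive
    order: int
    path_length: float
    euclidean_span: float
    parent_branch: int = -1    # index into the branch list

    @property
    def start(self):
        return int(self.nodes[0])

    @property
    def end(self):
        return int(self.nodes[-1])

    @property
    def contraction(self):
        return self.euclidean_span / self.path_length if self.path_length > 0 else 1.0


def branch_decompose(tree: NeuronTree) -> list[Branch]:
    """Partition the tree's edges into branches between critical points.

    The decomposition is cached on the tree (trees are treated as
    immutable once built).
    """
    cached = getattr(tree, "_branches", None)
    if cached is not None:
        return cached
    children = tree.children_lists()
    nch = tree.n_children()
    branches = []
    # stack of (start_node, first_child, order, parent_branch_index)
    stack = [(tree.root, c, 1, -1) for c in sorted(children[tree.root], reverse=True)]
    while stack:
        start, nxt, order, pb = stack.pop()
        path = [start]
        k = nxt
        while True:
            path.append(k)
            if nch[k] != 1:
                break
            k = children[k][0]
        pts = tree.xyz[path]
        plen = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        span = float(np.linalg.norm(pts[-1] - pts[0]))
        bi = len(branches)
        branches.append(Branch(np.array(path, dtype=np.int64), order, plen, span, pb))
        for c in sorted(children[k], reverse=True):
            stack.append((k, c, order + 1, bi))
    tree._branches = branches
    return branches


# -- whole-neuron (L-Measure style) features --------------------------------

LMEASURE_NAMES = [
    "Nodes", "SomaSurface", "Stems", "Bifurcations", "Branches", "Tips",
    "OverallWidth", "OverallHeight", "OverallDepth", "AverageDiameter",
    "Length", "Surface", "Volume", "MaxEuclideanDistance", "MaxPathDistance",
    "MaxBranchOrder", "AverageContraction", "AverageFragmentation",
    "AverageParent-daughterRatio", "AverageBifurcationAngleLocal",
    "AverageBifurcationAngleRemote", "HausdorffDimension",
]


def _angle_deg(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _bifurcation_child_pairs(tree, branches):
    """(branch_point, child_branch_a, child_branch_b) triples.

    A k-furcation is expanded into k-1 stacked pairs over the children sorted
    by node id (deterministic).
    """
    by_start = {}
    for i, b in enumerate(branches):
        by_start.setdefault(b.start, []).append(i)
    pairs = []
    for bp in tree.branch_points():
        kids = sorted(by_start.get(int(bp), []), key=lambda i: int(tree.ids[branches[i].nodes[1]]))
        for a, b in zip(kids[:-1], kids[1:]):
            pairs.append((int(bp), a, b))
    return pairs


def _hausdorff_dimension(tree, n_scales=4):
    """Box-counting dimension over ``n_scales`` dyadic box sizes.

    The skeleton polyline is densely sampled so counts follow the curve, not
    the node placement; the slope of log N vs log(1/s) is fit by least squares.
    """
    lo = tree.xyz.min(axis=0)
    hi = tree.xyz.max(axis=0)
    L = float(np.max(hi - lo))
    if L <= 0:
        return 0.0
    # dense sampling of every edge at the finest box scale / 2
    step = L / 2 ** (n_scales + 1)
    pts = [tree.xyz]
    mask = tree.parent_index >= 0
    a = tree.xyz[mask]
    b = tree.xyz[tree.parent_index[mask]]
    seg = b - a
    ell = np.linalg.norm(seg, axis=1)
    for i in np.nonzero(ell > step)[0]:
        m = int(np.ceil(ell[i] / step))
        t = np.arange(1, m)[:, None] / m
        pts.append(a[i] + t * seg[i])
    pts = np.vstack(pts)
    logs, logn = [], []
    for k in range(1, n_scales + 1):
        s = L / 2 ** k
        cells = np.floor((pts - lo) / s).astype(np.int64)
        np.minimum(cells, 2 ** k - 1, out=cells)
        n = len(np.unique(cells, axis=0))
        logs.append(np.log(1.0 / s))
        logn.append(np.log(n))
    slope = np.polyfit(logs, logn, 1)[0]
    return float(slope)


def lmeasure_features(tree: NeuronTree) -> dict:
    """The 22 whole-neuron morphometric scalars (angles in degrees)."""
    if tree.n_nodes < 2:
        raise ValueError("need at least 2 nodes for morphometric features")
    branches = branch_decompose(tree)
    nch = tree.n_children()
    ell = tree.edge_lengths()
    pathd = tree.path_dist_to_root()
    eucd = np.linalg.norm(tree.xyz - tree.soma_xyz, axis=1)
    span = tree.xyz.max(axis=0) - tree.xyz.min(axis=0)

    nb = nch.copy()
    nb[tree.root] = 0
    bifurcations = int(np.maximum(nb - 1, 0).sum())  # k-furcation = k-1

    mask = tree.parent_index >= 0
    surface = float((2 * np.pi * tree.radius[mask] * ell[mask]).sum())
    volume = float((np.pi * tree.radius[mask] ** 2 * ell[mask]).sum())

    contractions = [b.contraction for b in branches if b.path_length > 0]
    fragmentation = [len(b.nodes) - 1 for b in branches]  # compartments per branch

    # parent-daughter radius ratio at branch points
    ratios = []
    children = tree.children_lists()
    for bp in tree.branch_points():
        rp = tree.radius[bp]
        if rp <= 0:
            continue
        for c in children[bp]:
            ratios.append(tree.radius[c] / rp)

    pairs = _bifurcation_child_pairs(tree, branches)
    loc, rem = [], []
    for bp, ia, ib in pairs:
        ba, bb = branches[ia], branches[ib]
        loc.append(_angle_deg(tree.xyz[ba.nodes[1]] - tree.xyz[bp], tree.xyz[bb.nodes[1]] - tree.xyz[bp]))
        rem.append(_angle_deg(tree.xyz[ba.end] - tree.xyz[bp], tree.xyz[bb.end] - tree.xyz[bp]))

    return {
        "Nodes": float(tree.n_nodes),
        "SomaSurface": float(4 * np.pi * tree.radius[tree.root] ** 2),
        "Stems": float(len(children[tree.root])),
        "Bifurcations": float(bifurcations),
        "Branches": float(len(branches)),
        "Tips": float((nch == 0).sum()),
        "OverallWidth": float(span[0]),
        "OverallHeight": float(span[1]),
        "OverallDepth": float(span[2]),
        "AverageDiameter": float(np.mean(2 * tree.radius)),
        "Length": float(ell.sum()),
        "Surface": surface,
        "Volume": volume,
        "MaxEuclideanDistance": float(eucd.max()),
        "MaxPathDistance": float(pathd.max()),
        "MaxBranchOrder": float(max((b.order for b in branches), default=0)),
        "AverageContraction": float(np.mean(contractions)) if contractions else 1.0,
        "AverageFragmentation": float(np.mean(fragmentation)) if fragmentation else 0.0,
        "AverageParent-daughterRatio": float(np.mean(ratios)) if ratios else 0.0,
        "AverageBifurcationAngleLocal": float(np.mean(loc)) if loc else 0.0,
        "AverageBifurcationAngleRemote": float(np.mean(rem)) if rem else 0.0,
        "HausdorffDimension": _hausdorff_dimension(tree),
    }


# -- local (per-branch / per-bifurcation) features --------------------------

LOCAL_FEATURE_NAMES = [
    "br_length", "br_order", "br_contraction",
    "bif_EucDist2soma", "bif_PathDist2soma", "asymmetry",
    "ampl_local", "ampl_remote", "tilt_local", "tilt_remote",
]


def _tip_counts(tree):
    """Number of terminal tips in the subtree of every node."""
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    nch = tree.n_children()
    for k in tree.topo_order()[::-1]:
        if nch[k] == 0:
            counts[k] = 1
        p = tree.parent_index[k]
        if p >= 0:
            counts[p] += counts[k]
    return counts


def local_branch_features(tree: NeuronTree) -> dict:
    """Per-branch and per-bifurcation local features.

    Returns ``{"branch": DataFrame, "bifurcation": DataFrame}``. Trees
    without bifurcations yield an empty bifurcation table. Tilt angles use
    reversed parent direction, so a straight continuation reads 180°.
    """
    branches = branch_decompose(tree)
    br = pd.DataFrame({
        "br_length": [b.path_length for b in branches],
        "br_order": [float(b.order) for b in branches],
        "br_contraction": [b.contraction for b in branches],
    })
    pairs = _bifurcation_child_pairs(tree, branches)
    pathd = tree.path_dist_to_root()
    tipc = _tip_counts(tree)
    rows = []
    for bp, ia, ib in pairs:
        ba, bb = branches[ia], branches[ib]
        p_bp = tree.parent_index[bp]
        a_loc = tree.xyz[ba.nodes[1]] - tree.xyz[bp]
        b_loc = tree.xyz[bb.nodes[1]] - tree.xyz[bp]
        a_rem = tree.xyz[ba.end] - tree.xyz[bp]
        b_rem = tree.xyz[bb.end] - tree.xyz[bp]
        n1, n2 = tipc[ba.nodes[1]], tipc[bb.nodes[1]]
        asym = abs(n1 - n2) / (n1 + n2 - 2) if n1 + n2 > 2 else 0.0
        row = {
            "bif_node": int(tree.ids[bp]),
            "bif_EucDist2soma": float(np.linalg.norm(tree.xyz[bp] - tree.soma_xyz)),
            "bif_PathDist2soma": float(pathd[bp]),
            "asymmetry": float(asym),
            "ampl_local": _angle_deg(a_loc, b_loc),
            "ampl_remote": _angle_deg(a_rem, b_rem),
        }
        if p_bp >= 0:
            # parent branch start for remote tilt
            pb = branches[ba.parent_branch] if ba.parent_branch >= 0 else None
            u_loc = tree.xyz[p_bp] - tree.xyz[bp]
            u_rem = (tree.xyz[pb.start] - tree.xyz[bp]) if pb is not None else u_loc
            row["tilt_local"] = min(_angle_deg(u_loc, a_loc), _angle_deg(u_loc, b_loc))
            row["tilt_remote"] = min(_angle_deg(u_rem, a_rem), _angle_deg(u_rem, b_rem))
        else:
            row["tilt_local"] = 0.0
            row["tilt_remote"] = 0.0
        rows.append(row)
    cols = ["bif_node", "bif_EucDist2soma", "bif_PathDist2soma", "asymmetry",
            "ampl_local", "ampl_remote", "tilt_local", "tilt_remote"]
    bif = pd.DataFrame(rows, columns=cols)
    return {"branch": br, "bifurcation": bif}


# -- resampling -------------------------------------------------------------

def resample_tree(tree: NeuronTree, spacing: float, mode: str = "subdivide") -> NeuronTree:
    """Return a tree whose consecutive node spacing is <= ``spacing``.

    mode="subdivide" (default) keeps every original node and splits edges
    longer than ``spacing`` into equal pieces — exactly idempotent.
    mode="uniform" redistributes nodes at uniform arc length along every
    branch (critical points kept) — use when node *density* must reflect
    geometry, e.g. for spatial density counts.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ids, structure, xyz, radius, parent = [], [], [], [], []
    next_id = [1]

    def add(st, p3, r, par):
        nid = next_id[0]
        next_id[0] += 1
        ids.append(nid); structure.append(int(st)); xyz.append(np.asarray(p3, float))
        radius.append(float(r)); parent.append(int(par))
        return nid

    new_id_of = {}
    root = tree.root
    new_id_of[root] = add(tree.structure[root], tree.xyz[root], tree.radius[root], -1)
    branches = branch_decompose(tree)
    for b in branches:
        start_new = new_id_of[b.start]
        if mode == "subdivide":
            prev = start_new
            for j in range(1, len(b.nodes)):
                k0, k1 = b.nodes[j - 1], b.nodes[j]
                p0, p1 = tree.xyz[k0], tree.xyz[k1]
                ell = float(np.linalg.norm(p1 - p0))
                m = max(1, int(np.ceil(ell / spacing - 1e-12)))
                for s in range(1, m):
                    t = s / m
                    prev = add(tree.structure[k1], p0 + t * (p1 - p0),
                               (1 - t) * tree.radius[k0] + t * tree.radius[k1], prev)
                prev = add(tree.structure[k1], p1, tree.radius[k1], prev)
            new_id_of[b.end] = prev
        elif mode == "uniform":
            pts = tree.xyz[b.nodes]
            rads = tree.radius[b.nodes]
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            total = arc[-1]
            m = max(1, int(np.ceil(total / spacing - 1e-12)))
            targets = np.linspace(0, total, m + 1)[1:]
            prev = start_new
            st = tree.structure[b.end]
            for t in targets[:-1]:
                x = np.array([np.interp(t, arc, pts[:, d]) for d in range(3)])
                r = np.interp(t, arc, rads)
                prev = add(st, x, r, prev)
            prev = add(st, pts[-1], rads[-1], prev)
            new_id_of[b.end] = prev
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return NeuronTree(ids, structure, np.array(xyz), radius, parent, dict(tree.metadata))


# -- PCA shape descriptors --------------------------------------------------

def pca_shape_features(tree: NeuronTree) -> dict:
    """Explained-variance ratios of PC1–3 plus sum-normalised |PC1| loadings.

    Degenerate (zero total variance) point sets yield ratios (1,0,0) and
    loadings (1,0,0).
    """
    X = tree.xyz - tree.xyz.mean(axis=0)
    cov = X.T @ X / max(1, len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0, None)
    v = v[:, order]
    tot = w.sum()
    if tot <= 1e-30:
        ratios = np.array([1.0, 0.0, 0.0])
        pc1 = np.array([1.0, 0.0, 0.0])
    else:
        ratios = w / tot
        pc1 = np.abs(v[:, 0])
        pc1 = pc1 / pc1.sum()
    return {
        "pc1_var": float(ratios[0]), "pc2_var": float(ratios[1]), "pc3_var": float(ratios[2]),
        "pc1_x": float(pc1[0]), "pc1_y": float(pc1[1]), "pc1_z": float(pc1[2]),
    }
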