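"""Synthetic data generation for every pipeline input.

The study-scale inputs (whole-brain light-microscopy volumes, hundreds of
thousands of somas, thousands of full reconstructions) are emulated here at
desk scale with seeded generators:

* a labelled toy atlas with a two-level region/compound-area hierarchy,
* stochastically grown neuron skeletons with per-class parameter regimes
  (branch length, bifurcation rate, arbor count, projection target),
* rendered 3-D image volumes with bright somas, tube-like neurites,
  Gaussian bouton bumps and additive noise,
* per-node intensity/radius profiles with planted bouton bumps,
* region × brain neurite-density matrices with planted correlated modules.

Every generator is a pure function of its spec and seed, and every dataset
is accompanied by a ground-truth ledger (class labels, soma centres, bouton
arc-lengths, module labels) for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import NeuronTree, SOMA, AXON, BASAL, APICAL, branch_decompose

__all__ = [
    "ToyAtlas", "SynthSpec", "ClassParams", "default_classes",
    "make_toy_atlas", "grow_neuron", "grow_population", "render_volume",
    "make_soma_field", "synth_profiles", "make_density_matrix",
]


# -- atlas ------------------------------------------------------------------

@dataclass
class ToyAtlas:
    """Labelled 3-D volume (voxels at ``voxel_size`` μm) + region hierarchy.

    Label 0 is background. ``region_table`` maps region id → name and
    compound-area id; regions are connected (convex cells in a convex mask).
    """

    volume: np.ndarray
    region_table: pd.DataFrame
    voxel_size: float = 25.0

    @property
    def shape(self):
        return self.volume.shape

    def region_ids(self):
        return self.region_table["region_id"].to_numpy()

    def area_of(self, region_id):
        row = self.region_table[self.region_table["region_id"] == region_id]
        return int(row["area_id"].iloc[0])

    def label_at(self, xyz_um):
        """Region label at μm coordinates (0 outside)."""
        xyz_um = np.atleast_2d(xyz_um)
        v = np.floor(xyz_um / self.voxel_size).astype(np.int64)
        ok = np.all((v >= 0) & (v < np.array(self.shape)), axis=1)
        out = np.zeros(len(v), dtype=np.int64)
        out[ok] = self.volume[v[ok, 0], v[ok, 1], v[ok, 2]]
        return out if len(out) > 1 else int(out[0])

    def centroid_um(self, region_id):
        idx = np.argwhere(self.volume == region_id)
        return (idx.mean(axis=0) + 0.5) * self.voxel_size

    def sample_point_um(self, region_id, rng, jitter=0.5):
        idx = np.argwhere(self.volume == region_id)
        v = idx[rng.integers(len(idx))]
        return (v + rng.uniform(0.5 - jitter, 0.5 + jitter, 3)) * self.voxel_size


# -- specs ------------------------------------------------------------------

@dataclass
class ClassParams:
    """Growth regime of one planted morphology class."""

    name: str
    mean_branch_length: float = 50.0   # μm, Gamma mean
    branch_length_sd: float = 20.0     # μm
    bifurcation_rate: float = 0.012    # per μm; branch-end split prob = min(1, rate*len)
    max_order: int = 5
    n_arbors: int = 2                  # planted axonal arbor count
    arbor_spread: float = 60.0         # μm, arbor local extent
    projection_targets: tuple = ()     # region ids the axon steers towards
    tract_length: float = 600.0        # μm, primary tract span when no target region
    n_basal_stems: int = 3
    has_apical: bool = False
    step: float = 10.0                 # μm growth step
    persistence: float = 3.0           # direction stiffness (higher = straighter)
    radius: float = 0.6                # μm neurite radius
    soma_radius: float = 6.0           # μm


@dataclass
class SynthSpec:
    """All knobs of the synthetic study, with seeded randomness."""

    seed: int = 0
    # atlas
    n_regions: int = 12
    n_areas: int = 4
    atlas_shape: tuple = (64, 64, 64)
    voxel_size: float = 25.0
    # population / density matrix
    n_brains: int = 50
    n_density_regions: int = 40        # region count of the density matrix
    n_module_regions: tuple = (3, 6)   # planted module size range
    n_modules: int = 8
    density_snr: float = 10.0
    # imaging
    image_snr: float = 8.0
    image_amplitude: float = 20000.0   # 16-bit peak above baseline
    image_baseline: float = 100.0
    soma_radius_vox: float = 8.0
    # boutons
    bouton_density_per_mm: float = 40.0
    bouton_amplitude: float = 100.0    # 8-bit intensity bump over shaft
    bouton_radius_factor: float = 2.5  # peak/shaft radius ratio
    profile_spacing: float = 0.5       # μm along-skeleton sampling
    profile_voxel_um: float = 0.3      # imaging voxel for "5 voxel" style rules


def default_classes(atlas: ToyAtlas | None = None) -> dict:
    """Four planted regimes loosely mirroring cortical ET/IT, thalamic and
    striatal archetypes (long-range sparse vs local dense axons)."""
    rids = list(atlas.region_ids()) if atlas is not None else []

    def tgt(i):
        return (rids[i % len(rids)],) if rids else ()

    # targets are offset so no class projects to its own home region
    return {
        "cortical_ET": ClassParams("cortical_ET", mean_branch_length=90.0, branch_length_sd=18.0,
                                   bifurcation_rate=0.006, max_order=5, n_arbors=2,
                                   arbor_spread=80.0, tract_length=900.0, has_apical=True,
                                   persistence=4.0, n_basal_stems=3, projection_targets=tgt(4)),
        "cortical_IT": ClassParams("cortical_IT", mean_branch_length=45.0, branch_length_sd=9.0,
                                   bifurcation_rate=0.015, max_order=5, n_arbors=3,
                                   arbor_spread=60.0, tract_length=500.0, has_apical=True,
                                   persistence=2.5, n_basal_stems=4, projection_targets=tgt(6)),
        "thalamic": ClassParams("thalamic", mean_branch_length=25.0, branch_length_sd=5.0,
                                bifurcation_rate=0.04, max_order=7, n_arbors=1,
                                arbor_spread=50.0, tract_length=700.0, has_apical=False,
                                persistence=1.5, n_basal_stems=5, projection_targets=tgt(8)),
        "striatal": ClassParams("striatal", mean_branch_length=60.0, branch_length_sd=12.0,
                                bifurcation_rate=0.02, max_order=6, n_arbors=4,
                                arbor_spread=50.0, tract_length=400.0, has_apical=False,
                                persistence=2.0, n_basal_stems=6, projection_targets=tgt(10)),
    }


# -- toy atlas --------------------------------------------------------------

def make_toy_atlas(spec: SynthSpec) -> ToyAtlas:
    """Voronoi-tile an ellipsoidal brain mask into connected regions grouped
    into compound areas. Deterministic for a fixed spec seed."""
    if spec.n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(spec.atlas_shape)
    if np.prod(shape) > 256 ** 3:
        raise ValueError("atlas too large")
    rng = np.random.default_rng(spec.seed)
    zi, yi, xi = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack([zi, yi, xi], axis=-1).astype(np.float64) + 0.5
    c = np.array(shape) / 2.0
    radii = np.array(shape) * 0.45
    mask = (((coords - c) / radii) ** 2).sum(axis=-1) <= 1.0
    if mask.sum() < spec.n_regions * 8:
        raise ValueError("mask too small to tile the requested regions")
    pts = np.argwhere(mask) + 0.5
    centers = pts[rng.choice(len(pts), spec.n_regions, replace=False)]
    d2 = ((coords[mask][:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = d2.argmin(axis=1) + 1
    # voxelisation can shear off slivers at cell boundaries: reattach every
    # minority component to its dominant neighbouring region
    from scipy import ndimage as ndi
    for _ in range(4):
        moved = False
        for r in range(1, spec.n_regions + 1):
            comp, n = ndi.label(labels == r)
            if n <= 1:
                continue
            sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n + 1):
                if c == keep:
                    continue
                sliver = comp == c
                ring = ndi.binary_dilation(sliver) & ~sliver & (labels > 0)
                if ring.any():
                    vals, cnts = np.unique(labels[ring], return_counts=True)
                    labels[sliver] = vals[np.argmax(cnts)]
                    moved = True
        if not moved:
            break
    # compound areas: coarse Voronoi over the region centres
    area_centers = centers[rng.choice(spec.n_regions, min(spec.n_areas, spec.n_regions), replace=False)]
    a2 = ((centers[:, None, :] - area_centers[None, :, :]) ** 2).sum(axis=-1)
    area_of_region = a2.argmin(axis=1) + 1
    table = pd.DataFrame({
        "region_id": np.arange(1, spec.n_regions + 1),
        "name": [f"R{i:03d}" for i in range(1, spec.n_regions + 1)],
        "area_id": area_of_region,
        "area_name": [f"CA{a}" for a in area_of_region],
    })
    return ToyAtlas(labels, table, spec.voxel_size)


# -- neuron growth ----------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _jittered(direction, persistence, rng):
    return _unit(persistence * direction + rng.standard_normal(3))


class _Builder:
    def __init__(self, soma_xyz, soma_radius):
        self.x = [np.asarray(soma_xyz, float)]
        self.s = [SOMA]
        self.r = [soma_radius]
        self.p = [-1]

    def add(self, xyz, structure, radius, parent):
        self.x.append(np.asarray(xyz, float))
        self.s.append(structure)
        self.r.append(radius)
        self.p.append(parent)
        return len(self.x) - 1

    def tree(self, metadata=None):
        n = len(self.x)
        ids = np.arange(1, n + 1)
        parent = np.array([(self.p[k] + 1) if self.p[k] >= 0 else -1 for k in range(n)])
        return NeuronTree(ids, self.s, np.array(self.x), self.r, parent, metadata)


def _grow_subtree(b, rng, params, root_idx, direction, structure, order=1,
                  max_span=None, origin=None, step=None):
    """Recursive stochastic branch growth from node index ``root_idx``."""
    step = step or params.step
    origin = b.x[root_idx] if origin is None else origin
    stack = [(root_idx, np.asarray(direction, float), order)]
    while stack:
        node, d, o = stack.pop()
        mean = params.mean_branch_length
        sd = max(1e-6, params.branch_length_sd)
        shape = (mean / sd) ** 2
        length = float(rng.gamma(shape, mean / shape))
        length = max(step, length)
        n_steps = max(1, int(round(length / step)))
        cur = node
        for _ in range(n_steps):
            d = _jittered(d, params.persistence, rng)
            nxt = b.x[cur] + d * step
            if max_span is not None and np.linalg.norm(nxt - origin) > max_span:
                break
            cur = b.add(nxt, structure, params.radius, cur)
        if cur == node:
            continue
        p_split = min(1.0, params.bifurcation_rate * length)
        if o < params.max_order and rng.random() < p_split:
            for _ in range(2):
                child_d = _jittered(d, params.persistence * 0.5, rng)
                stack.append((cur, child_d, o + 1))


def grow_neuron(params: ClassParams, soma_xyz, rng, atlas: ToyAtlas | None = None) -> NeuronTree:
    """Grow one neuron: local dendrites plus an axon laid out as a primary
    tract towards the class's projection target with ``n_arbors`` dense
    arbors planted at waypoints along/at the end of the tract.

    ``rng`` may be a seed or a Generator. The returned tree's metadata
    records the planted class, arbor count and arbor centres.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if params.bifurcation_rate * params.mean_branch_length >= 1.0 and params.max_order <= 0:
        raise ValueError("growth cannot terminate: certain splits with no order cap")
    soma_xyz = np.asarray(soma_xyz, float)
    b = _Builder(soma_xyz, params.soma_radius)

    # basal dendrites: local subtrees in random directions
    dend = replace(params, mean_branch_length=min(40.0, params.mean_branch_length),
                   branch_length_sd=10.0, bifurcation_rate=0.03, max_order=4)
    for _ in range(params.n_basal_stems):
        d = _unit(rng.standard_normal(3))
        _grow_subtree(b, rng, dend, 0, d, BASAL, max_span=150.0)
    if params.has_apical:
        d = _unit(rng.standard_normal(3) + np.array([0, 0, 2.0]))
        api = replace(dend, mean_branch_length=60.0, bifurcation_rate=0.015)
        _grow_subtree(b, rng, api, 0, d, APICAL, max_span=300.0)

    # axon: primary tract towards the target centroid (or a random direction)
    if params.projection_targets and atlas is not None:
        target = atlas.centroid_um(params.projection_targets[0])
    else:
        target = soma_xyz + _unit(rng.standard_normal(3)) * params.tract_length
    tract_dir = _unit(target - soma_xyz)
    total = float(np.linalg.norm(target - soma_xyz))
    step = params.step
    n_steps = max(2, int(round(total / step)))
    # waypoints where arbors attach: spread along the distal half of the tract
    k = max(1, params.n_arbors)
    way_fracs = np.linspace(0.35, 1.0, k) if k > 1 else np.array([1.0])
    waypoints = set((way_fracs * n_steps).astype(int) - 1)
    cur = 0
    d = tract_dir
    arbor_centers = []
    arb = replace(params, mean_branch_length=min(30.0, params.mean_branch_length),
                  branch_length_sd=8.0, bifurcation_rate=0.06, max_order=4,
                  persistence=1.5)
    for i in range(n_steps):
        d = _unit(params.persistence * 2 * tract_dir + 0.6 * rng.standard_normal(3))
        cur = b.add(b.x[cur] + d * step, AXON, params.radius, cur)
        if i in waypoints:
            arbor_centers.append(np.array(b.x[cur]))
            for _ in range(5):
                _grow_subtree(b, rng, arb, cur, _unit(rng.standard_normal(3)),
                              AXON, max_span=params.arbor_spread)
    md = {
        "class": params.name,
        "n_arbors_planted": int(params.n_arbors),
        "arbor_centers": np.array(arbor_centers),
        "soma_xyz": soma_xyz,
    }
    return b.tree(md)


def grow_population(spec: SynthSpec, atlas: ToyAtlas, classes=None,
                    n_per_class=15, region_assignment=None) -> list:
    """Grow ``n_per_class`` neurons per class, soma positions spatially
    clustered in a per-class home region."""
    rng = np.random.default_rng(spec.seed + 1)
    classes = classes or default_classes(atlas)
    rids = list(atlas.region_ids())
    trees = []
    for ci, (cname, params) in enumerate(classes.items()):
        home = region_assignment[cname] if region_assignment else rids[ci % len(rids)]
        anchor = atlas.centroid_um(home)
        for j in range(n_per_class):
            soma = anchor + rng.normal(0, 60.0, 3)
            t = grow_neuron(params, soma, rng, atlas)
            t.metadata.update({
                "neuron_id": f"{cname}_{j:03d}", "region": int(home),
                "class_index": ci, "brain_id": f"B{j % max(1, spec.n_brains):03d}",
            })
            trees.append(t)
    return trees


# -- image rendering --------------------------------------------------------

def _splat_ball(img, center, radius, amplitude, profile="parabolic"):
    """Add a radially-decaying ball; profile peaks at the centre."""
    shape = np.array(img.shape)
    lo = np.maximum(0, np.floor(center - radius - 1).astype(int))
    hi = np.minimum(shape, np.ceil(center + radius + 2).astype(int))
    if np.any(lo >= hi):
        return
    gz, gy, gx = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
    r2 = ((gz + 0.5 - center[0]) ** 2 + (gy + 0.5 - center[1]) ** 2 + (gx + 0.5 - center[2]) ** 2)
    if profile == "parabolic":
        val = amplitude * np.clip(1.0 - r2 / radius ** 2, 0, None)
    else:  # gaussian
        val = amplitude * np.exp(-r2 / (2 * (radius / 2.0) ** 2))
    region = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, val, out=region)


def render_volume(trees, shape, spec: SynthSpec, rng=None, voxel_um=1.0,
                  bouton_arcs=None):
    """Render neurons into a 16-bit volume.

    Somas become bright parabolic spheres, neurites Gaussian-profile tubes,
    boutons local amplitude+radius bumps; additive Gaussian noise at
    ``image_amplitude / image_snr``. Returns ``(image, ledger)`` where the
    ledger holds soma centres (voxels) and planted bouton positions.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    img = np.zeros(shape, dtype=np.float64)
    ledger = {"soma_centers_vox": [], "bouton_vox": []}
    A = spec.image_amplitude
    for t in trees:
        cv = t.soma_xyz / voxel_um
        sr = max(2.0, t.radius[t.root] / voxel_um)
        _splat_ball(img, cv, sr, A)
        ledger["soma_centers_vox"].append(cv)
        mask = t.parent_index >= 0
        for k in np.nonzero(mask)[0]:
            p = t.parent_index[k]
            a, bb = t.xyz[p] / voxel_um, t.xyz[k] / voxel_um
            ell = np.linalg.norm(bb - a)
            n = max(1, int(np.ceil(ell / 0.7)))
            for s in range(n + 1):
                pt = a + (bb - a) * (s / n)
                _splat_ball(img, pt, max(1.0, t.radius[k] / voxel_um) * 1.5,
                            0.6 * A, profile="gaussian")
    if bouton_arcs:
        for pt in bouton_arcs:
            pv = np.asarray(pt) / voxel_um
            _splat_ball(img, pv, 2.5, 0.9 * A, profile="gaussian")
            ledger["bouton_vox"].append(pv)
    noise_sd = A / spec.image_snr if spec.image_snr > 0 else 0.0
    img = img + spec.image_baseline + rng.normal(0, noise_sd, shape)
    ledger["soma_centers_vox"] = np.array(ledger["soma_centers_vox"]).reshape(-1, 3)
    return np.clip(img, 0, 65535).astype(np.uint16), ledger


def make_soma_field(spec: SynthSpec, n_somas=30, shape=(128, 128, 128), rng=None):
    """Scatter ``n_somas`` non-overlapping bright spheres in a noisy volume;
    returns ``(image, centers_vox)``. Minimum pairwise separation 24 voxels."""
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    shape = tuple(shape)
    margin = spec.soma_radius_vox + 6
    centers = []
    attempts = 0
    while len(centers) < n_somas and attempts < 20000:
        attempts += 1
        c = rng.uniform(margin, np.array(shape) - margin)
        if all(np.linalg.norm(c - o) >= 24 for o in centers):
            centers.append(c)
    if len(centers) < n_somas:
        raise ValueError("could not place the requested somas")
    centers = np.array(centers)
    img = np.zeros(shape, dtype=np.float64)
    for c in centers:
        _splat_ball(img, c, spec.soma_radius_vox, spec.image_amplitude)
    noise_sd = spec.image_amplitude / spec.image_snr
    img = img + spec.image_baseline + rng.normal(0, noise_sd, shape)
    return np.clip(img, 0, 65535).astype(np.uint16), centers


# -- synthetic profiles with planted boutons --------------------------------

def synth_profiles(tree: NeuronTree, spec: SynthSpec, rng=None, n_boutons=None):
    """Per-node intensity (8-bit) and radius profiles along the axon with
    Gaussian bouton bumps planted at seeded arc-length positions.

    Returns ``(profiles, planted)``: ``profiles`` is a DataFrame indexed like
    the node array with columns intensity/radius/axonal; ``planted`` is a
    DataFrame of ground-truth boutons (node index, xyz, arc position).
    Intended for a tree resampled at ``spec.profile_spacing``.
    """
    rng = np.random.default_rng(spec.seed + 4) if rng is None else rng
    pathd = tree.path_dist_to_root()
    axonal = tree.structure == AXON
    base_r = np.median(tree.radius[axonal]) if axonal.any() else 0.5
    intensity = np.full(tree.n_nodes, 100.0)
    radius = np.where(axonal, base_r, tree.radius).astype(float)
    branches = branch_decompose(tree)
    planted = []
    for bi, br in enumerate(branches):
        nodes = br.nodes
        if not np.all(axonal[nodes[1:]]):
            continue
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(tree.xyz[nodes], axis=0), axis=1))])
        if n_boutons is None:
            lam = spec.bouton_density_per_mm * br.path_length / 1000.0
            nb = rng.poisson(lam)
        else:
            nb = 0  # placement handled globally below
        pos = np.sort(rng.uniform(2.0, max(2.0, br.path_length - 2.0), nb)) if nb else []
        # enforce minimal separation of 8 μm
        kept = []
        for p in pos:
            if not kept or p - kept[-1] >= 8.0:
                kept.append(p)
        for p in kept:
            j = int(np.argmin(np.abs(arc - p)))
            bump = np.exp(-0.5 * ((arc - p) / 1.5) ** 2)
            intensity[nodes] += spec.bouton_amplitude * bump
            radius[nodes] += base_r * (spec.bouton_radius_factor - 1.0) * bump
            planted.append({"node": int(nodes[j]), "branch": bi, "arc": float(p),
                            "x": tree.xyz[nodes[j], 0], "y": tree.xyz[nodes[j], 1],
                            "z": tree.xyz[nodes[j], 2],
                            "path_dist": float(pathd[nodes[j]])})
    if n_boutons is not None:
        # fixed global count: well-separated interior positions of axonal
        # branches long enough to carry an arc-length ground truth
        arcs = {}
        cand = []
        for bi, br in enumerate(branches):
            nodes = br.nodes
            if not np.all(axonal[nodes[1:]]) or br.path_length < 20.0:
                continue
            arc = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(tree.xyz[nodes], axis=0), axis=1))])
            arcs[bi] = arc
            interior = (arc >= 3.0) & (arc <= br.path_length - 3.0)
            cand.extend(int(nodes[j]) for j in np.nonzero(interior)[0])
        order = rng.permutation(np.array(sorted(set(cand)), dtype=np.int64))
        chosen = []
        for k in order:
            if len(chosen) >= n_boutons:
                break
            if all(np.linalg.norm(tree.xyz[k] - tree.xyz[c]) >= 10.0 for c in chosen):
                chosen.append(k)
        for bi, br in enumerate(branches):
            if bi not in arcs:
                continue
            nodes = br.nodes
            arc = arcs[bi]
            for k in chosen:
                hits = np.nonzero(nodes == k)[0]
                if len(hits):
                    j = int(hits[0])
                    bump = np.exp(-0.5 * ((arc - arc[j]) / 1.5) ** 2)
                    intensity[nodes] += spec.bouton_amplitude * bump
                    radius[nodes] += base_r * (spec.bouton_radius_factor - 1.0) * bump
                    planted.append({"node": int(k), "branch": bi, "arc": float(arc[j]),
                                    "x": tree.xyz[k, 0], "y": tree.xyz[k, 1],
                                    "z": tree.xyz[k, 2], "path_dist": float(pathd[k])})
    intensity = intensity + rng.normal(0, 4.0, tree.n_nodes)
    radius = np.clip(radius + rng.normal(0, 0.03, tree.n_nodes), 0.05, None)
    profiles = pd.DataFrame({
        "intensity": np.clip(intensity, 0, 255),
        "radius": radius,
        "axonal": axonal,
    })
    return profiles, pd.DataFrame(planted, columns=["node", "branch", "arc", "x", "y", "z", "path_dist"])


# -- density matrices with planted modules ----------------------------------

def make_density_matrix(spec: SynthSpec, rng=None):
    """Regions × brains neurite-density fractions with planted modules.

    Rows in a planted module share a per-brain latent loading scaled by a
    per-region gain, plus independent Gaussian noise at ``1/density_snr`` of
    the signal sd; remaining rows are independent. Columns are normalised to
    sum to 1. Returns ``(df, module_of_region)`` where ``module_of_region``
    maps region id → planted module index (absent = unassigned).
    """
    rng = np.random.default_rng(spec.seed + 5) if rng is None else rng
    n_regions = spec.n_density_regions
    if spec.n_brains < 2 or n_regions < 2:
        raise ValueError("need at least 2 brains and 2 regions")
    lo, hi = spec.n_module_regions
    sizes = [lo + (i % (hi - lo + 1)) for i in range(spec.n_modules)]
    if sum(sizes) > n_regions:
        raise ValueError("modules do not fit in the region set")
    region_ids = np.arange(1, n_regions + 1)
    module_of = {}
    pos = 0
    for m, s in enumerate(sizes):
        for r in region_ids[pos:pos + s]:
            module_of[int(r)] = m
        pos += s
    X = np.zeros((n_regions, spec.n_brains))
    latents = {m: np.abs(rng.normal(1.0, 0.5, spec.n_brains)) for m in range(spec.n_modules)}
    for i, r in enumerate(region_ids):
        gain = rng.uniform(0.5, 1.5)
        if int(r) in module_of:
            sig = gain * latents[module_of[int(r)]]
        else:
            sig = gain * np.abs(rng.normal(1.0, 0.5, spec.n_brains))
        noise_sd = sig.std() / spec.density_snr if spec.density_snr > 0 else 0.0
        X[i] = np.clip(sig + rng.normal(0, noise_sd, spec.n_brains), 1e-9, None)
    X = X / X.sum(axis=0, keepdims=True)
    df = pd.DataFrame(X, index=region_ids,
                      columns=[f"brain_{b:03d}" for b in range(spec.n_brains)])
    df.index.name = "region_id"
    return df, module_of
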