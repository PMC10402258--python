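"""Image-domain detectors at desk scale.

Three detector families operate on small 3-D grayscale blocks (≤256³):

* neurite segmentation — empirical foreground threshold, adaptive denoise,
  block-wise anisotropy salience and thresholding, summarised per atlas
  region into a neurite-density vector;
* soma detection — z-score 8-bit normalisation, 99th-percentile
  binarisation, a grayscale distance transform (GSDT), candidate windowing,
  non-maximum suppression and mean-shift refinement with a duplicate rule;
* skeleton profile sampling — per-node image intensity and local radius
  estimates feeding bouton detection.

The numeric constants of the protocol (250/300/400/1000, the 99th
percentile, the 5–30 candidate window, 15-voxel windows, 0.1×thresh) are
defaults on :class:`DetectorConfig`, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageBlock", "SomaCandidate", "DetectorConfig",
    "foreground_threshold", "adaptive_denoise", "anisotropy_salience",
    "segment_neurites", "neurite_density_vector", "gsdt",
    "detect_somas", "refine_somas", "sample_profiles",
    "read_tiff", "write_tiff",
]


@dataclass
class ImageBlock:
    """3-D intensity block with physical voxel size (μm) and origin (μm)."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 8:
            raise ValueError("ImageBlock requires a 3-D array with dims >= 8")


@dataclass
class SomaCandidate:
    center: np.ndarray            # voxel coordinates (z,y,x order of the array)
    score: float
    refined: bool = False
    removed: bool = False


@dataclass
class DetectorConfig:
    """Protocol constants; defaults follow the published pipeline."""

    # neurite segmentation
    thresh_floor: float = 400.0
    thresh_ceil: float = 1000.0
    thresh_scale: float = 0.9
    salience_cut_scale: float = 0.1
    neurite_prefilter_max: float = 300.0
    cuboid: tuple = (16, 16, 16)
    denoise_window: int = 5
    denoise_sigma: float = 1.0
    # soma detection
    soma_prefilter_max: float = 250.0
    binarize_percentile: float = 99.0
    gsdt_lo: float = 5.0
    gsdt_hi: float = 30.0
    nms_radius: float = 8.0
    meanshift_window: int = 15
    duplicate_dist: float = 15.0
    # profiles
    radius_max_vox: float = 10.0


def _data(block):
    return block.data if isinstance(block, ImageBlock) else np.asarray(block)


# -- neurite segmentation ---------------------------------------------------

def foreground_threshold(block, cfg: DetectorConfig = DetectorConfig()) -> float:
    """Empirical per-brain foreground threshold
    ``scale * min(max(mu + 1.5*sigma, floor), ceil)`` from the global
    intensity mean and standard deviation (16-bit convention)."""
    data = _data(block)
    if data.size == 0:
        raise ValueError("empty block")
    mu, sigma = float(data.mean()), float(data.std())
    return cfg.thresh_scale * min(max(mu + 1.5 * sigma, cfg.thresh_floor), cfg.thresh_ceil)


def adaptive_denoise(block, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Gaussian smooth then subtract the local mean (window ``denoise_window``),
    clamped at zero — a small-footprint stand-in for adaptive thresholding."""
    data = _data(block).astype(np.float64)
    sm = ndimage.gaussian_filter(data, cfg.denoise_sigma)
    local = ndimage.uniform_filter(sm, cfg.denoise_window)
    return np.clip(sm - local, 0, None)


def anisotropy_salience(block, thresh=None, cfg: DetectorConfig = DetectorConfig(),
                        return_scores=False):
    """Anisotropy-weighted salience map.

    The denoised block is split into cuboids; in each, the intensity-weighted
    PCA eigenvalues ``S1 >= S2 >= S3`` of foreground-voxel coordinates give
    the score ``(S1-S2)/(S1+S2) * (S1-S3)/(S1+S3)`` (→1 for a line, →0 for a
    ball; 0 when fewer than 3 foreground voxels). The salience is the
    denoised image times the per-cuboid score, so isotropic noise cuboids are
    strongly suppressed.
    """
    data = _data(block)
    if thresh is None:
        thresh = foreground_threshold(data, cfg)
    den = adaptive_denoise(data, cfg)
    cut = cfg.salience_cut_scale * thresh
    cz, cy, cx = cfg.cuboid
    nz = int(np.ceil(data.shape[0] / cz))
    ny = int(np.ceil(data.shape[1] / cy))
    nx = int(np.ceil(data.shape[2] / cx))
    scores = np.zeros((nz, ny, nx))
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                sub = den[iz * cz:(iz + 1) * cz, iy * cy:(iy + 1) * cy, ix * cx:(ix + 1) * cx]
                fg = np.argwhere(sub >= cut)
                if len(fg) < 3:
                    continue
                w = sub[fg[:, 0], fg[:, 1], fg[:, 2]]
                mu = np.average(fg, axis=0, weights=w)
                X = (fg - mu) * np.sqrt(w)[:, None]
                ev = np.linalg.eigvalsh(X.T @ X / w.sum())[::-1]
                s1, s2, s3 = np.clip(ev, 0, None)
                if s1 <= 0:
                    continue
                scores[iz, iy, ix] = ((s1 - s2) / (s1 + s2)) * ((s1 - s3) / (s1 + s3))
    up = np.repeat(np.repeat(np.repeat(scores, cz, 0), cy, 1), cx, 2)
    up = up[:data.shape[0], :data.shape[1], :data.shape[2]]
    sal = den * up
    return (sal, scores) if return_scores else sal


def segment_neurites(block, thresh=None, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Binary neurite mask: salience thresholded at ``0.1 × thresh``.
    Blocks whose maximum intensity is below the pre-filter return empty."""
    data = _data(block)
    if data.max() < cfg.neurite_prefilter_max:
        return np.zeros(data.shape, dtype=bool)
    if thresh is None:
        thresh = foreground_threshold(data, cfg)
    sal = anisotropy_salience(data, thresh, cfg)
    return sal > cfg.salience_cut_scale * thresh


def neurite_density_vector(mask, atlas, region_ids=None):
    """Per-region fraction of neurite voxels; sums to 1 (all-zero if empty).

    ``atlas`` may be a label volume or an object with ``.volume`` and
    ``.region_table``. Background (label 0) is excluded.
    """
    labels = atlas.volume if hasattr(atlas, "volume") else np.asarray(atlas)
    mask = np.asarray(mask, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError("mask and atlas shapes disagree")
    if region_ids is None:
        if hasattr(atlas, "region_table"):
            region_ids = atlas.region_table["region_id"].to_numpy()
        else:
            region_ids = np.unique(labels)
            region_ids = region_ids[region_ids > 0]
    hit = labels[mask]
    hit = hit[hit > 0]
    counts = np.array([(hit == r).sum() for r in region_ids], dtype=np.float64)
    total = counts.sum()
    return counts / total if total > 0 else counts


# -- grayscale distance transform & soma detection --------------------------

def gsdt(intensity, binary, level=None):
    """Grayscale distance transform.

    For each foreground voxel, the Euclidean distance to the nearest
    background voxel is weighted by the mean intensity (relative to
    ``level``, default the mean foreground intensity) sampled along the
    straight path to that voxel. Bright interiors therefore score higher
    than their geometric depth, while with uniform foreground intensity all
    weights are 1 and the transform equals the plain Euclidean distance
    transform exactly. Normalising by the foreground mean keeps the value
    scale distance-like no matter where the binarisation threshold falls.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return np.zeros(binary.shape)
    if level is None:
        level = float(intensity[binary].mean())
    level = max(level, 1e-12)
    edt, inds = ndimage.distance_transform_edt(binary, return_indices=True)
    out = np.zeros(binary.shape)
    fg = np.argwhere(binary)
    d = edt[binary]
    near = np.stack([inds[a][binary] for a in range(3)], axis=1).astype(np.float64)
    # background contributes the neutral weight 1 so the uniform case reduces
    # to the plain EDT exactly
    eff = np.where(binary, intensity, level)
    m = np.maximum(1, np.ceil(d).astype(np.int64))
    mmax = int(m.max())
    acc = np.zeros(len(fg))
    fgf = fg.astype(np.float64)
    for i in range(mmax):
        active = m > i
        t = (i + 0.5) / m[active]
        pts = fgf[active] + (near[active] - fgf[active]) * t[:, None]
        acc[active] += ndimage.map_coordinates(eff, pts.T, order=1)
    vals = (acc / m) / level * d
    out[binary] = vals
    return out


def _to_8bit(data):
    """Z-score then linear map to the 0–255 range."""
    data = np.asarray(data, dtype=np.float64)
    sd = data.std()
    z = (data - data.mean()) / (sd if sd > 0 else 1.0)
    zmin, zmax = z.min(), z.max()
    if zmax <= zmin:
        return np.zeros(data.shape)
    return 255.0 * (z - zmin) / (zmax - zmin)


def detect_somas(block, cfg: DetectorConfig = DetectorConfig()) -> list:
    """Soma candidates from the GSDT of the binarised, normalised block.

    16-bit blocks with maximum below the pre-filter are skipped (empty
    list). Candidates are local GSDT maxima inside the ``[gsdt_lo, gsdt_hi]``
    window, thinned by non-maximum suppression at ``nms_radius`` voxels.
    """
    data = _data(block)
    if data.max() < cfg.soma_prefilter_max:
        return []
    d8 = _to_8bit(data)
    sm = ndimage.gaussian_filter(d8, cfg.denoise_sigma)
    level = np.percentile(sm, cfg.binarize_percentile)
    binary = sm > level
    g = gsdt(sm, binary)
    local_max = (g == ndimage.maximum_filter(g, size=3))
    cand = np.argwhere((g >= cfg.gsdt_lo) & (g <= cfg.gsdt_hi) & local_max)
    if len(cand) == 0:
        return []
    scores = g[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(scores)[::-1]
    kept = []
    for i in order:
        c = cand[i].astype(np.float64)
        if all(np.linalg.norm(c - k.center) > cfg.nms_radius for k in kept):
            kept.append(SomaCandidate(c, float(scores[i])))
    return kept


def refine_somas(candidates, block, cfg: DetectorConfig = DetectorConfig()) -> list:
    """Mean-shift refinement plus the duplicate rule.

    Voxels below μ+σ are zero-clipped; each candidate iterates to the
    intensity centroid of a ``meanshift_window``-voxel cube. Two refined
    somas within ``duplicate_dist`` voxels whose midpoint intensity is below
    their mean centre intensity are merged (the dimmer one dropped).
    """
    data = _data(block).astype(np.float64)
    clipped = np.where(data >= data.mean() + data.std(), data, 0.0)
    h = cfg.meanshift_window // 2
    shape = np.array(data.shape)
    refined = []
    for c in candidates:
        y = np.array(c.center, dtype=np.float64)
        for _ in range(60):
            lo = np.maximum(0, np.round(y).astype(int) - h)
            hi = np.minimum(shape, np.round(y).astype(int) + h + 1)
            sub = clipped[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            w = sub.sum()
            if w <= 0:
                break
            gz, gy, gx = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
            new = np.array([(sub * g).sum() / w for g in (gz, gy, gx)]) + 0.5
            if np.linalg.norm(new - y) < 0.05:
                y = new
                break
            y = new
        refined.append(SomaCandidate(y, c.score, refined=True))

    def center_val(p):
        v = np.clip(np.round(p).astype(int), 0, shape - 1)
        return data[v[0], v[1], v[2]]

    refined.sort(key=lambda s: -center_val(s.center))
    for i, a in enumerate(refined):
        if a.removed:
            continue
        for b in refined[i + 1:]:
            if b.removed:
                continue
            if np.linalg.norm(a.center - b.center) <= cfg.duplicate_dist:
                mid = (a.center + b.center) / 2
                if center_val(mid) < (center_val(a.center) + center_val(b.center)) / 2:
                    b.removed = True
    return [s for s in refined if not s.removed]


# -- skeleton profiles ------------------------------------------------------

_SPHERE_DIRS = None


def _sphere_dirs(n=42):
    global _SPHERE_DIRS
    if _SPHERE_DIRS is None:
        # Fibonacci sphere, deterministic
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5 ** 0.5) * i
        _SPHERE_DIRS = np.stack([np.cos(phi), np.sin(phi) * np.sin(theta),
                                 np.sin(phi) * np.cos(theta)], axis=1)
    return _SPHERE_DIRS


def sample_profiles(tree, block, voxel_um=1.0, cfg: DetectorConfig = DetectorConfig()):
    """Per-node trilinear intensity and local radius along a skeleton.

    The radius estimate is the largest sphere radius whose mean surface
    intensity stays at or above half the centre intensity. Nodes outside the
    volume are flagged and report 0.
    """
    data = _data(block).astype(np.float64)
    shape = np.array(data.shape)
    pts = tree.xyz / voxel_um
    inside = np.all((pts >= 0) & (pts <= shape - 1), axis=1)
    intensity = np.zeros(tree.n_nodes)
    radius = np.zeros(tree.n_nodes)
    coords = pts[inside].T
    intensity[inside] = ndimage.map_coordinates(data, coords, order=1)
    dirs = _sphere_dirs()
    radii = np.arange(0.5, cfg.radius_max_vox + 0.25, 0.5)
    for k in np.nonzero(inside)[0]:
        c = pts[k]
        half = intensity[k] / 2.0
        best = 0.0
        for r in radii:
            sp = c[None, :] + dirs * r
            ok = np.all((sp >= 0) & (sp <= shape - 1), axis=1)
            if not ok.any():
                break
            mean = ndimage.map_coordinates(data, sp[ok].T, order=1).mean()
            if mean >= half:
                best = r
            else:
                break
        radius[k] = best * voxel_um
    return {"intensity": intensity, "radius": radius, "inside": inside}


# -- TIFF I/O ---------------------------------------------------------------

def read_tiff(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


def write_tiff(path, data):
    import tifffile
    tifffile.imwrite(path, data)
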