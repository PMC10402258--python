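"""End-to-end orchestration on synthetic data.

``run_pipeline`` chains every stage — synthetic data generation, soma
detection, density-matrix module discovery, microenvironment construction,
full-morphology typing, arbor/tract analysis, bouton detection and the
cross-scale DS analysis — into a run directory of CSV/JSON outputs with a
manifest. All randomness derives from the single config seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, synth, imaging, curation, popmodules, microenv as me, \
    morphotype as mt, subneuronal as sn, boutons as bt, ds as dsm
from .core import NeuronTree, AXON

__all__ = ["PipelineConfig", "run_pipeline", "dendrite_subtree",
           "build_cross_scale_blocks", "tract_motif_features"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_class: int = 10
    atlas_regions: int = 12
    atlas_shape: tuple = (48, 48, 48)
    n_brains: int = 40
    n_somas: int = 12
    soma_field_shape: tuple = (96, 96, 96)
    microenv_radius: float = 249.0
    microenv_k: int = 5
    morphotype_k: int = 4
    axon_arbors: int = 2
    bouton_spacing: float = 1.0
    stages: tuple = ("synth", "detect", "modules", "microenv", "morphotype",
                     "subneuronal", "boutons", "ds")


def dendrite_subtree(tree: NeuronTree) -> NeuronTree:
    """Soma + dendrites (axon removed), for local-morphology features."""
    keep = np.nonzero(tree.structure != AXON)[0]
    return tree.select(keep)


def tract_motif_features(tree: NeuronTree, n_profile=20) -> pd.Series:
    """Per-neuron primary-tract motif block (26 dims): tract length,
    tortuosity, terminal-to-soma distance, terminal xyz, and the
    distance-to-soma trajectory profile at 20 uniform arc fractions."""
    tr = sn.primary_tract(tree)
    pts = tr.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    term = pts[-1]
    soma = tree.soma_xyz
    euc = float(np.linalg.norm(term - soma))
    vals = {
        "tract_length": length,
        "tortuosity": length / euc if euc > 0 else 1.0,
        "terminal_dist": euc,
        "terminal_x": float(term[0] - soma[0]),
        "terminal_y": float(term[1] - soma[1]),
        "terminal_z": float(term[2] - soma[2]),
    }
    idx = np.linspace(0, len(pts) - 1, n_profile).astype(int)
    d2s = np.linalg.norm(pts[idx] - soma, axis=1)
    for i, v in enumerate(d2s):
        vals[f"traj_{i:02d}"] = float(v)
    return pd.Series(vals)


def build_cross_scale_blocks(trees, spec: synth.SynthSpec, seed=0,
                             microenv_radius=249.0, microenv_k=5,
                             axon_arbors=2, bouton_spacing=1.0):
    """Assemble the five per-neuron cross-scale feature blocks.

    The microenvironment block fuses each neuron's dendritic 24-vector with
    its most similar in-sphere neighbours and keeps the 18 morphometric
    components; arbors are forced to ``axon_arbors`` axonal arbors for
    comparability (apical block zero when absent); boutons come from
    synthetic profiles planted on a resampled copy.
    """
    rng = np.random.default_rng(seed)
    ids = [t.metadata.get("neuron_id", f"n{i}") for i, t in enumerate(trees)]
    dend = [dendrite_subtree(t) for t in trees]
    f24 = pd.DataFrame([me.features24(d) for d in dend], index=ids)
    positions = np.array([t.soma_xyz for t in trees])
    fused = []
    for nid in ids:
        m = me.build_microenvironment(nid, f24, positions, D=microenv_radius, k=microenv_k)
        fused.append(m.features[me.LM18_NAMES])
    micro = pd.DataFrame(fused, index=ids)

    lm = pd.DataFrame([core.lmeasure_features(t) for t in trees], index=ids)
    full = lm[me.LM18_NAMES]

    arbor_rows = []
    arbor_feats = ["n_branch", "volume", "max_density", "dist2soma"]
    for t in trees:
        k_eff = min(axon_arbors, max(1, int((t.structure == AXON).sum())))
        arbs = sn.decompose_arbors(t, k_eff, seed=seed)
        row = {}
        by_kind = {"apical": [], "basal": [], "axonal": []}
        for a in arbs:
            by_kind[a.kind].append(a)
        for kind in ("apical", "basal"):
            f = by_kind[kind][0].features if by_kind[kind] else dict.fromkeys(arbor_feats, 0.0)
            for n in arbor_feats:
                row[f"{kind}_{n}"] = float(f[n])
        ax = sorted(by_kind["axonal"], key=lambda a: a.features["dist2soma"])
        for j in range(axon_arbors):
            f = ax[j].features if j < len(ax) else dict.fromkeys(arbor_feats, 0.0)
            for n in arbor_feats:
                row[f"A{j + 1}_{n}"] = float(f[n])
        arbor_rows.append(row)
    arbor = pd.DataFrame(arbor_rows, index=ids)

    bsets = []
    for t in trees:
        rt = core.resample_tree(t, bouton_spacing)
        prof, _ = synth.synth_profiles(rt, spec, rng=np.random.default_rng(rng.integers(2**31)))
        bsets.append(bt.detect_boutons(rt, prof, bt.BoutonConfig(),
                                       neuron_id=t.metadata.get("neuron_id")))
    bouton = pd.DataFrame([bs.summary for bs in bsets], index=ids)[bt.RADAR_FEATURES]

    motif = pd.DataFrame([tract_motif_features(t) for t in trees], index=ids)
    blocks = {"microenviron": micro, "fullMorpho": full, "arbor": arbor,
              "bouton": bouton, "motif": motif}
    return blocks, bsets


def _write_csv(df, path):
    df.to_csv(path, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run all enabled stages; outputs land in ``outdir`` with a manifest.
    Disabled upstream stages make dependent stages fail with a clear
    missing-input message."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(cfg).items()},
                "stages": {}}
    state = {}

    def stage(name):
        return name in cfg.stages

    def record(name, t0):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}

    def need(name, key):
        if key not in state:
            raise RuntimeError(f"stage '{name}' needs missing upstream output "
                               f"'{key}'; enable the stage that produces it")
        return state[key]

    spec = synth.SynthSpec(seed=cfg.seed, n_regions=cfg.atlas_regions,
                           atlas_shape=cfg.atlas_shape, n_brains=cfg.n_brains)

    if stage("synth"):
        t0 = time.time()
        atlas = synth.make_toy_atlas(spec)
        trees = synth.grow_population(spec, atlas, n_per_class=cfg.n_per_class)
        md, module_of = synth.make_density_matrix(spec)
        field_img, centers = synth.make_soma_field(spec, n_somas=cfg.n_somas,
                                                   shape=cfg.soma_field_shape)
        state.update(atlas=atlas, trees=trees, density=md, module_of=module_of,
                     soma_field=field_img, soma_centers=centers, spec=spec)
        core.save_dataset(
            [t.copy() for t in trees], out / "swc")
        _write_csv(md, out / "density_matrix.csv")
        atlas.region_table.to_csv(out / "regions.csv", index=False)
        record("synth", t0)

    if stage("detect"):
        t0 = time.time()
        img = need("detect", "soma_field")
        cands = imaging.detect_somas(img)
        refined = imaging.refine_somas(cands, img)
        pd.DataFrame([{"z": c.center[0], "y": c.center[1], "x": c.center[2],
                       "score": c.score} for c in refined]).to_csv(
            out / "soma_candidates.csv", index=False, float_format="%.6g")
        state["somas"] = refined
        record("detect", t0)

    if stage("modules"):
        t0 = time.time()
        md = need("modules", "density")
        mc = popmodules.correlation_map(md)
        tsets = popmodules.target_correlated_sets(mc)
        init = popmodules.initial_modules(mc)
        tight = popmodules.tight_modules(init, tsets, mc)
        with open(out / "modules.json", "w") as fh:
            json.dump({"initial": init.modules,
                       "tight": tight.modules,
                       "consistency": tight.consistency}, fh, indent=1, default=int)
        state.update(mc=mc, tight=tight)
        record("modules", t0)

    if stage("microenv"):
        t0 = time.time()
        trees = need("microenv", "trees")
        atlas = state["atlas"]
        ids = [t.metadata["neuron_id"] for t in trees]
        dend = [dendrite_subtree(t) for t in trees]
        f24 = pd.DataFrame([me.features24(d) for d in dend], index=ids)
        pos = np.array([t.soma_xyz for t in trees])
        fused = pd.DataFrame(
            [me.build_microenvironment(n, f24, pos, D=cfg.microenv_radius,
                                       k=cfg.microenv_k).features for n in ids],
            index=ids)
        regions = [t.metadata["region"] for t in trees]
        top3 = me.mrmr_select(fused, regions, k=3)
        vol, mips = me.rgb_map(fused, top3, pos, atlas)
        clusters = me.region_clusters(fused[top3], regions,
                                      k=min(3, len(set(regions))), seed=cfg.seed)
        _write_csv(fused, out / "microenv_features.csv")
        with open(out / "microenv_summary.json", "w") as fh:
            json.dump({"top3": top3, "region_clusters": {str(k): v for k, v in clusters.items()}},
                      fh, indent=1)
        state.update(f24=f24, fused=fused, positions=pos, ids=ids, regions=regions)
        record("microenv", t0)

    if stage("morphotype"):
        t0 = time.time()
        trees = need("morphotype", "trees")
        ids = state["ids"]
        f47 = pd.DataFrame([mt.features47(t) for t in trees], index=ids)
        S = mt.similarity_matrix(f47, state["positions"])
        labels = mt.spectral_cluster(S, k=cfg.morphotype_k, seed=cfg.seed)
        sil = mt.silhouette_separation(state["positions"], labels)
        _write_csv(f47, out / "morphology_features.csv")
        pd.DataFrame({"neuron_id": ids, "cluster": labels}).to_csv(
            out / "morphotype_labels.csv", index=False)
        _write_csv(sil, out / "morphotype_silhouette.csv")
        state.update(f47=f47, type_labels=labels)
        record("morphotype", t0)

    if stage("subneuronal"):
        t0 = time.time()
        trees = need("subneuronal", "trees")
        atlas = state["atlas"]
        rows = []
        tracts = []
        for t in trees:
            arbs = sn.decompose_arbors(t, min(cfg.axon_arbors,
                                              int((t.structure == AXON).sum())),
                                      seed=cfg.seed)
            for a in arbs:
                rows.append({"neuron_id": t.metadata["neuron_id"], "kind": a.kind,
                             "order": a.order_label, "type": a.type, **a.features})
            tracts.append(sn.primary_tract(t))
        pd.DataFrame(rows).to_csv(out / "arbors.csv", index=False, float_format="%.8g")
        hub_img, origin, hubs = sn.detect_hubs(trees)
        prof = sn.tract_group_profile(tracts) if len(tracts) >= 3 else None
        proj = pd.DataFrame([sn.projection_vector(t, atlas) for t in trees],
                            index=state["ids"])
        _write_csv(proj, out / "projection_vectors.csv")
        with open(out / "subneuronal_summary.json", "w") as fh:
            json.dump({"n_hubs": int(hub_img.max()),
                       "tract_pattern": prof.pattern if prof else None}, fh, indent=1)
        state.update(tracts=tracts, projections=proj)
        record("subneuronal", t0)

    if stage("boutons"):
        t0 = time.time()
        trees = need("boutons", "trees")
        spec_b = state["spec"]
        rng = np.random.default_rng(cfg.seed + 11)
        bsets = []
        for t in trees:
            rt = core.resample_tree(t, cfg.bouton_spacing)
            prof, _ = synth.synth_profiles(rt, spec_b,
                                           rng=np.random.default_rng(rng.integers(2**31)))
            bsets.append(bt.detect_boutons(rt, prof,
                                           neuron_id=t.metadata["neuron_id"]))
        allb = pd.concat([bs.boutons.assign(neuron_id=bs.neuron_id) for bs in bsets],
                         ignore_index=True)
        allb.to_csv(out / "boutons.csv", index=False, float_format="%.8g")
        state["bouton_sets"] = bsets
        record("boutons", t0)

    if stage("ds"):
        t0 = time.time()
        trees = need("ds", "trees")
        if "bouton_sets" not in state:
            raise RuntimeError("stage 'ds' needs the bouton block; "
                               "enable the 'boutons' stage")
        blocks, _ = build_cross_scale_blocks(trees, state["spec"], seed=cfg.seed,
                                             microenv_radius=cfg.microenv_radius,
                                             microenv_k=cfg.microenv_k,
                                             axon_arbors=cfg.axon_arbors,
                                             bouton_spacing=cfg.bouton_spacing)
        vectors = dsm.cross_scale_table(blocks)
        labels = [t.metadata["class"] for t in trees]
        D = dsm.ds_matrix(vectors, labels)
        mats, dists = dsm.per_scale_ds(vectors, labels)
        sd = dsm.scale_distances(mats)
        mom = dsm.moment_summary(dists)
        _write_csv(vectors, out / "cross_scale_vectors.csv")
        _write_csv(D, out / "ds_matrix.csv")
        _write_csv(sd, out / "scale_distances.csv")
        mom.to_csv(out / "ds_moments.csv", index=False, float_format="%.8g")
        record("ds", t0)

    manifest["composition_hash"] = dsm.composition_hash()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
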