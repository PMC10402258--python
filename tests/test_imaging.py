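"""Image detectors: thresholds, anisotropy salience, GSDT, somas, profiles."""

import numpy as np
import pytest
from scipy import ndimage

from morphoscale import imaging, synth
from morphoscale.imaging import DetectorConfig


class TestForegroundThreshold:
    def test_printed_formula_hand_values(self):
        # mu=100, sigma=100 → 0.9·min(max(250,400),1000) = 360
        rng = np.random.default_rng(0)
        assert imaging.foreground_threshold(_const_block(100, 100)) == pytest.approx(360.0, rel=1e-6)
        # mu=1000, sigma=400 → 0.9·min(max(1600,400),1000) = 900
        assert imaging.foreground_threshold(_const_block(1000, 400)) == pytest.approx(900.0, rel=1e-6)

    def test_constant_image(self):
        img = np.full((16, 16, 16), 700.0)
        assert imaging.foreground_threshold(img) == pytest.approx(0.9 * 700.0)


def _const_block(mu, sigma):
    """Deterministic block with exact mean mu and sd sigma."""
    img = np.full((16, 16, 16), float(mu))
    flat = img.ravel()
    half = flat.size // 2
    flat[:half] += sigma
    flat[half:] -= sigma
    return img


class TestAnisotropy:
    def test_line_scores_high_ball_scores_low(self):
        img = np.zeros((16, 16, 16))
        img[8, 8, :] = 5000.0  # bright straight line
        _, s_line = imaging.anisotropy_salience(img, thresh=400.0, return_scores=True)
        ball = np.zeros((16, 16, 16))
        zz, yy, xx = np.mgrid[:16, :16, :16]
        ball[(zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2 <= 25] = 5000.0
        _, s_ball = imaging.anisotropy_salience(ball, thresh=400.0, return_scores=True)
        assert s_line.max() > 0.8
        assert s_ball.max() < 0.3

    def test_rotated_line_scores_similarly(self):
        def line_img(direction):
            img = np.zeros((16, 16, 16))
            c = np.array([8.0, 8.0, 8.0])
            for t in np.linspace(-7, 7, 80):
                p = np.round(c + t * np.asarray(direction)).astype(int)
                if np.all((p >= 0) & (p < 16)):
                    img[tuple(p)] = 5000.0
            return img
        _, s0 = imaging.anisotropy_salience(line_img([0, 0, 1.0]), 400.0, return_scores=True)
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        _, s1 = imaging.anisotropy_salience(line_img(d), 400.0, return_scores=True)
        assert abs(s0.max() - s1.max()) < 0.05

    def test_no_foreground_scores_zero(self):
        img = np.full((16, 16, 16), 30.0)  # everything below the 0.1·thresh cut
        _, s = imaging.anisotropy_salience(img, thresh=400.0, return_scores=True)
        assert s.max() == 0.0


class TestSegmentNeurites:
    def test_prefilter_returns_empty(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 20, (32, 32, 32)).clip(0)
        assert img.max() < 300
        assert not imaging.segment_neurites(img).any()

    def test_mask_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.normal(150, 80, (32, 32, 32)).clip(0)
        img[16, 16, :] = 2000.0
        lo = imaging.segment_neurites(img, thresh=300.0)
        hi = imaging.segment_neurites(img, thresh=900.0)
        assert not (hi & ~lo).any()  # raising thresh never adds voxels

    def test_rendered_tube_recovery(self):
        # straight tube, SNR 10 (peak amplitude / noise sd)
        rng = np.random.default_rng(2)
        amp, noise_sd, base = 1000.0, 100.0, 100.0
        img = np.zeros((48, 48, 48))
        zz, yy = np.mgrid[:48, :48]
        r2 = (zz - 24.0) ** 2 + (yy - 24.0) ** 2
        prof = amp * np.exp(-r2 / (2 * 1.5 ** 2))
        img += prof[:, :, None]
        core_truth = img > amp / 2        # unambiguous tube core
        support = img > 0.1 * amp         # full physical extent of the tube
        noisy = img + base + rng.normal(0, noise_sd, img.shape)
        mask = imaging.segment_neurites(noisy.clip(0))
        recall = (mask & core_truth).sum() / core_truth.sum()
        precision = (mask & support).sum() / max(1, mask.sum())
        assert recall >= 0.9
        assert precision >= 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        img = rng.normal(150, 80, (32, 32, 32)).clip(0)
        img[10, 10, :] = 2000.0
        a = imaging.segment_neurites(img)
        b = imaging.segment_neurites(img.copy())
        assert np.array_equal(a, b)


class TestDensityVector:
    def test_mask_inside_single_region(self, toy_atlas):
        mask = np.zeros(toy_atlas.shape, dtype=bool)
        mask[toy_atlas.volume == 3] = True
        v = imaging.neurite_density_vector(mask, toy_atlas)
        rids = list(toy_atlas.region_ids())
        assert v[rids.index(3)] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_sixty_forty_split(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[:, :, :5] = 1
        labels[:, :, 5:] = 2
        mask = np.zeros_like(labels, dtype=bool)
        mask[0, 0, :5] = True        # 5 voxels region 1
        mask[0, 1, 5:8] = True       # 3 voxels region 2 → wait 5/3; use 6/4
        mask[0, 2, 5] = True
        v = imaging.neurite_density_vector(mask, labels)
        assert v[0] == pytest.approx(5 / 9)
        assert v[1] == pytest.approx(4 / 9)

    def test_shape_mismatch_rejected(self, toy_atlas):
        with pytest.raises(ValueError):
            imaging.neurite_density_vector(np.zeros((4, 4, 4), bool), toy_atlas)


class TestGSDT:
    def test_equals_edt_on_uniform_foreground(self):
        rng = np.random.default_rng(4)
        binary = rng.random((24, 24, 24)) < 0.3
        binary = ndimage.binary_dilation(binary)
        img = np.where(binary, 777.0, 0.0)
        got = imaging.gsdt(img, binary)
        want = ndimage.distance_transform_edt(binary)
        assert np.allclose(got, want, atol=1e-9)

    def test_brighter_interior_raises_values(self):
        binary = np.zeros((21, 21, 21), bool)
        binary[5:16, 5:16, 5:16] = True
        flat = np.where(binary, 100.0, 0.0)
        graded = flat.copy()
        graded[8:13, 8:13, 8:13] = 300.0
        g_flat = imaging.gsdt(flat, binary, level=100.0)
        g_graded = imaging.gsdt(graded, binary, level=100.0)
        assert g_graded[10, 10, 10] > g_flat[10, 10, 10]


class TestSomaDetection:
    def test_single_sphere_one_candidate_near_center(self):
        spec = synth.SynthSpec(seed=5)
        img, centers = synth.make_soma_field(spec, n_somas=1, shape=(64, 64, 64))
        cands = imaging.detect_somas(img)
        assert len(cands) == 1
        assert np.linalg.norm(cands[0].center - centers[0]) <= 2.0

    def test_empty_volume_no_candidates(self):
        rng = np.random.default_rng(6)
        img = rng.normal(100, 10, (32, 32, 32)).clip(0).astype(np.uint16)
        assert imaging.detect_somas(img) == []

    def test_close_pair_merged_far_pair_kept(self):
        spec = synth.SynthSpec(seed=7, image_snr=50)
        img = np.zeros((64, 64, 64))
        for c in ([20, 32, 32], [60 - 20 + 20, 32, 32]):
            pass
        from morphoscale.synth import _splat_ball
        far = np.zeros((96, 64, 64))
        _splat_ball(far, np.array([20.0, 32, 32]), 8, 20000)
        _splat_ball(far, np.array([60.0, 32, 32]), 8, 20000)
        far += 100 + np.random.default_rng(7).normal(0, 400, far.shape)
        cands = imaging.detect_somas(far.clip(0))
        assert len(cands) == 2
        near = np.zeros((64, 64, 64))
        _splat_ball(near, np.array([30.0, 32, 32]), 8, 20000)
        _splat_ball(near, np.array([35.0, 32, 32]), 8, 20000)
        near += 100 + np.random.default_rng(8).normal(0, 400, near.shape)
        cands = imaging.detect_somas(near.clip(0))
        assert len(cands) == 1

    def test_meanshift_refines_offset_candidate(self):
        from morphoscale.synth import _splat_ball
        img = np.zeros((48, 48, 48))
        _splat_ball(img, np.array([24.0, 24, 24]), 8, 20000)
        img += 100
        cand = imaging.SomaCandidate(np.array([29.0, 24.0, 24.0]), 1.0)
        ref = imaging.refine_somas([cand], img)
        assert np.linalg.norm(ref[0].center - np.array([24.5, 24.5, 24.5])) <= 1.0

    def test_duplicate_rule_merges_dim_midpoint_pair(self):
        from morphoscale.synth import _splat_ball
        img = np.zeros((48, 48, 48))
        _splat_ball(img, np.array([17.0, 24, 24]), 4, 20000)
        _splat_ball(img, np.array([29.0, 24, 24]), 4, 20000)
        img += 100
        cands = [imaging.SomaCandidate(np.array([17.0, 24.0, 24.0]), 1.0),
                 imaging.SomaCandidate(np.array([29.0, 24.0, 24.0]), 1.0)]
        ref = imaging.refine_somas(cands, img)
        assert len(ref) == 1


class TestProfiles:
    def test_constant_tube_radius_profile(self):
        # tube of Gaussian cross-section along x at y=z=24
        img = np.zeros((48, 48, 48))
        zz, yy = np.mgrid[:48, :48]
        img += (1000 * np.exp(-((zz - 24.0) ** 2 + (yy - 24.0) ** 2) / (2 * 2.0 ** 2)))[None, :, :] \
            .transpose(1, 2, 0) * 0
        prof2d = 1000 * np.exp(-((zz - 24.0) ** 2 + (yy - 24.0) ** 2) / (2 * 2.0 ** 2))
        img = np.repeat(prof2d[:, :, None], 48, axis=2)
        from conftest import make_tree
        pts = [(24.0, 24.0, 8.0 + i) for i in range(32)]
        t = make_tree(pts, [None] + list(range(31)), structure=[1] + [2] * 31)
        out = imaging.sample_profiles(t, img)
        mid = out["radius"][4:-4]
        assert mid.std() <= 0.5
        assert np.all(out["inside"])

    def test_node_outside_flagged_zero(self):
        from conftest import make_tree
        img = np.full((16, 16, 16), 50.0)
        t = make_tree([(8, 8, 8), (100, 8, 8)], [None, 0])
        out = imaging.sample_profiles(t, img)
        assert not out["inside"][1]
        assert out["intensity"][1] == 0.0
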