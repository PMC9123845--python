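import numpy as np
import pytest

import flairtex as fx
from flairtex.texture import (DIRECTIONS, GLCM, QuantizedVolume,
                              extract_roi_features, haralick_features,
                              make_texture_maps, patch_glcm, quantize,
                              transform_features)
from flairtex.volumes import ImageVolume, MaskVolume

from oracles import oracle_haralick, oracle_patch_glcm


def _img_mask(values3d):
    data = np.asarray(values3d, dtype=float)
    img = ImageVolume(data, (1, 1, 1))
    mask = MaskVolume(data != 0, "brain", (1, 1, 1))
    return img, mask


class TestQuantize:
    def test_unit_span_bins(self):
        data = np.zeros((4, 4, 1))
        data[0, :3, 0] = [0.0, 0.5, 1.0]  # min, middle, max of foreground
        mask = np.zeros_like(data, dtype=bool)
        mask[0, :3, 0] = True             # brain mask may include zeros
        q = quantize(ImageVolume(data, (1, 1, 1)),
                     MaskVolume(mask, "brain", (1, 1, 1)), 8)
        assert q.data[0, 0, 0] == 1      # minimum -> level 1
        assert q.data[0, 1, 0] == 5      # 0.5 -> floor(0.5*8)+1 (edge: up)
        assert q.data[0, 2, 0] == 8      # maximum clamped into top bin

    def test_two_levels(self):
        data = np.zeros((4, 4, 1))
        data[0, :4, 0] = [1, 2, 3, 4]
        img, mask = _img_mask(data)
        q = quantize(img, mask, 2)
        assert list(q.data[0, :4, 0]) == [1, 1, 2, 2]

    def test_extremes_always_hit_levels_1_and_n(self):
        rng = np.random.default_rng(3)
        data = np.zeros((10, 10, 3))
        data[2:8, 2:8, :] = rng.uniform(40, 200, size=(6, 6, 3))
        img, mask = _img_mask(data)
        q = quantize(img, mask, 8)
        inb = q.data[mask.data]
        assert inb.min() == 1 and inb.max() == 8

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        data = np.zeros((8, 8, 2))
        data[1:7, 1:7, :] = rng.uniform(10, 90, size=(6, 6, 2))
        img, mask = _img_mask(data)
        scaled = np.where(data != 0, 2.5 * data + 30.0, 0.0)
        q1 = quantize(img, mask)
        q2 = quantize(ImageVolume(scaled, (1, 1, 1)), mask)
        assert (q1.data == q2.data).all()

    def test_constant_foreground_rejected(self):
        data = np.zeros((4, 4, 1))
        data[1:3, 1:3, 0] = 7.0
        img, mask = _img_mask(data)
        with pytest.raises(ValueError, match="constant"):
            quantize(img, mask)


class TestPatchGLCM:
    def test_constant_patch_single_diagonal_entry(self):
        q = QuantizedVolume(np.full((5, 5, 1), 3), 8)
        g = patch_glcm(q, (2, 2, 0))
        assert g.normalized
        assert g.table[2, 2] == 1.0
        assert g.table.sum() == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = QuantizedVolume(rng.integers(0, 9, size=(7, 7, 2)), 8)
        for z in range(2):
            for x in range(1, 6):
                for y in range(1, 6):
                    counts = oracle_patch_glcm(q.data, (x, y, z), 8)
                    mine = patch_glcm(q, (x, y, z), normalize=False)
                    assert (mine.table == counts).all()

    def test_direction_order_irrelevant(self):
        rng = np.random.default_rng(11)
        q = QuantizedVolume(rng.integers(1, 9, size=(5, 5, 1)), 8)
        perm = tuple(reversed(DIRECTIONS))
        a = patch_glcm(q, (2, 2, 0), directions=DIRECTIONS)
        b = patch_glcm(q, (2, 2, 0), directions=perm)
        assert (a.table == b.table).all()

    def test_symmetric_when_all_directions_summed(self):
        rng = np.random.default_rng(12)
        q = QuantizedVolume(rng.integers(0, 9, size=(5, 5, 1)), 8)
        g = patch_glcm(q, (2, 2, 0), normalize=False)
        assert (g.table == g.table.T).all()

    def test_heterogeneous_patch_scatters_more(self):
        hetero = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        homog = np.full((3, 3), 4)
        pad = np.zeros((5, 5, 1), dtype=int)
        pad[1:4, 1:4, 0] = hetero
        qa = QuantizedVolume(pad, 8)
        pad2 = np.zeros((5, 5, 1), dtype=int)
        pad2[1:4, 1:4, 0] = homog
        qb = QuantizedVolume(pad2, 8)
        na = (patch_glcm(qa, (2, 2, 0)).table > 0).sum()
        nb = (patch_glcm(qb, (2, 2, 0)).table > 0).sum()
        assert na > nb

    def test_edge_center_rejected(self):
        q = QuantizedVolume(np.ones((5, 5, 1), dtype=int), 8)
        with pytest.raises(ValueError, match="neighbourhood"):
            patch_glcm(q, (0, 2, 0))


class TestHaralick:
    def test_degenerate_distribution(self):
        t = np.zeros((8, 8))
        t[3, 3] = 1.0
        f = haralick_features(GLCM(t, normalized=True))
        assert f == (0.0, 1.0, 0.0, 1.0)

    def test_uniform_glcm_closed_form(self):
        t = np.full((8, 8), 1 / 64)
        f = haralick_features(GLCM(t, normalized=True))
        ref = oracle_haralick(t)
        assert f.energy == pytest.approx(1 / 64)
        assert f.entropy == pytest.approx(np.log(64))
        assert f.contrast == pytest.approx(ref["contrast"])
        assert f.homogeneity == pytest.approx(ref["homog"])

    def test_same_entropy_energy_different_contrast(self):
        """Two-entry tables equally concentrated but placed near vs far
        from the diagonal share entropy/energy while contrast and
        homogeneity separate them."""
        near = np.zeros((8, 8))
        near[0, 1] = near[1, 0] = 0.5
        far = np.zeros((8, 8))
        far[0, 7] = far[7, 0] = 0.5
        fn = haralick_features(GLCM(near, normalized=True))
        ff = haralick_features(GLCM(far, normalized=True))
        assert fn.entropy == ff.entropy and fn.energy == ff.energy
        assert ff.contrast > fn.contrast
        assert ff.homogeneity < fn.homogeneity

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(GLCM(np.ones((8, 8))))


class TestTextureMaps:
    def test_constant_volume_degenerate_maps(self):
        data = np.zeros((10, 10, 2), dtype=int)
        data[1:9, 1:9, :] = 5
        maps = make_texture_maps(QuantizedVolume(data, 8))
        v = maps.valid & (data > 0)
        # interior of a constant region: one co-occurrence level pair only
        inner = np.zeros_like(v)
        inner[2:8, 2:8, :] = True
        assert (maps.contrast[inner] == 0).all()
        assert (maps.energy[inner] == 1).all()
        assert (maps.entropy[inner] == 0).all()
        assert (maps.homogeneity[inner] == 1).all()

    def test_checkerboard_has_positive_contrast(self):
        xx, yy = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        data = np.where((xx + yy) % 2 == 0, 2, 6)[:, :, None]
        maps = make_texture_maps(QuantizedVolume(data, 8))
        inner = np.zeros_like(data, dtype=bool)
        inner[1:9, 1:9, :] = True
        assert (maps.contrast[inner] > 0).all()
        assert (maps.homogeneity[inner] < 1).all()

    def test_borders_and_background_invalid(self):
        data = np.zeros((8, 8, 1), dtype=int)
        data[2:6, 2:6, 0] = 4
        maps = make_texture_maps(QuantizedVolume(data, 8))
        assert not maps.valid[0, :, 0].any()
        assert not maps.valid[7, :, 0].any()
        # far corner: patch entirely background
        assert not maps.valid[1, 1, 0] or data[0:3, 0:3, 0].any()

    @pytest.mark.parametrize("seed", range(3))
    def test_bounds_hold_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        q = QuantizedVolume(rng.integers(0, 9, size=(15, 15, 2)), 8)
        maps = make_texture_maps(q)
        v = maps.valid
        assert ((maps.energy[v] > 0) & (maps.energy[v] <= 1)).all()
        assert ((maps.homogeneity[v] > 0) & (maps.homogeneity[v] <= 1)).all()
        assert ((maps.contrast[v] >= 0) & (maps.contrast[v] <= 49)).all()
        assert ((maps.entropy[v] >= 0)
                & (maps.entropy[v] <= 2 * np.log(8))).all()


class TestROIFeatures:
    @pytest.fixture()
    def setting(self):
        rng = np.random.default_rng(8)
        data = np.zeros((12, 12, 2))
        data[1:11, 1:11, :] = rng.uniform(10, 100, size=(10, 10, 2))
        img = ImageVolume(data, (1, 1, 1))
        brain = MaskVolume(data != 0, "brain", (1, 1, 1))
        norm = fx.normalize_intensities(img)
        maps = make_texture_maps(quantize(img, brain))
        return norm, maps

    def test_single_voxel_roi(self, setting):
        norm, maps = setting
        roi = np.zeros(norm.shape, dtype=bool)
        roi[5, 5, 0] = True
        f = extract_roi_features(norm, maps, MaskVolume(roi, "wmh",
                                                        (1, 1, 1)))
        assert f["mean"] == norm.data[5, 5, 0]
        assert np.isnan(f["std"])

    def test_empty_roi_yields_nans(self, setting):
        norm, maps = setting
        roi = MaskVolume(np.zeros(norm.shape, dtype=bool), "wmh", (1, 1, 1))
        f = extract_roi_features(norm, maps, roi)
        assert all(np.isnan(v) for v in f.values())

    def test_pooled_mean_is_weighted_mean(self, setting):
        norm, maps = setting
        a = np.zeros(norm.shape, dtype=bool)
        b = np.zeros(norm.shape, dtype=bool)
        a[2:5, 2:5, 0] = True
        b[6:8, 6:10, 1] = True
        fa = extract_roi_features(norm, maps, MaskVolume(a, "a", (1, 1, 1)))
        fb = extract_roi_features(norm, maps, MaskVolume(b, "b", (1, 1, 1)))
        fu = extract_roi_features(norm, maps,
                                  MaskVolume(a | b, "u", (1, 1, 1)))
        na, nb = a.sum(), b.sum()
        pooled = (na * fa["mean"] + nb * fb["mean"]) / (na + nb)
        assert fu["mean"] == pytest.approx(pooled)

    def test_constant_region_roi_is_textureless(self):
        data = np.zeros((12, 12, 1))
        data[1:11, 1:11, 0] = 50.0
        data[1, 1, 0] = 10.0  # one off voxel so quantization has a range
        img = ImageVolume(data, (1, 1, 1))
        brain = MaskVolume(data != 0, "brain", (1, 1, 1))
        maps = make_texture_maps(quantize(img, brain))
        roi = np.zeros_like(data, dtype=bool)
        roi[4:9, 4:9, 0] = True   # interior, far from the off voxel
        f = extract_roi_features(fx.normalize_intensities(img), maps,
                                 MaskVolume(roi, "wmh", (1, 1, 1)))
        assert f["contrast"] == 0.0 and f["homog"] == 1.0


class TestTransform:
    @pytest.mark.parametrize("raw,expected", [(0.125, 0.5), (0.0, 0.0),
                                              (1.0, 1.0), (-0.008, -0.2)])
    def test_signed_cube_root(self, raw, expected):
        out = transform_features({"contrast": raw})
        assert out["contrast"] == pytest.approx(expected)
        assert out["contrast_raw"] == raw


def test_heterogeneity_monotonically_drives_contrast_and_homogeneity():
    """Across seeds, raising within-lesion heterogeneity raises expected
    interior WMH contrast and lowers expected homogeneity.

    The ROI is the in-plane-eroded lesion so every 3x3 patch lies fully
    inside lesional tissue: boundary patches mix lesion and WM levels and
    would swamp the within-lesion signal.
    """
    from scipy import ndimage

    levels = (0.0, 6.0, 15.0)
    means = {"contrast": [], "homog": []}
    for het in levels:
        cs, hs = [], []
        for seed in range(20):
            spec = fx.PhantomSpec(grid_shape=(44, 44, 8), noise_sd=2.0,
                                  bias_amplitude=0.0, rng_seed=seed)
            lesions = fx.LesionSpec(centers=[(35, 22, 4)], radii_mm=[4.0],
                                    intensity_offset=40.0, heterogeneity=het)
            img, masks = fx.generate_phantom(spec, lesions)
            maps = make_texture_maps(quantize(img, masks["brain"]))
            interior = ndimage.binary_erosion(
                masks["wmh"].data, structure=np.ones((3, 3, 1), dtype=bool))
            f = extract_roi_features(
                fx.normalize_intensities(img), maps,
                MaskVolume(interior, "wmh-interior", img.voxel_size_mm))
            cs.append(f["contrast"])
            hs.append(f["homog"])
        means["contrast"].append(np.mean(cs))
        means["homog"].append(np.mean(hs))
    assert means["contrast"][0] < means["contrast"][1] < means["contrast"][2]
    assert means["homog"][0] > means["homog"][1] > means["homog"][2]
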