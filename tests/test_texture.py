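"""Texture branch: quantization, GLDM/GLSZM vs brute force, pruning."""
import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_volume
from levoresp import texture as tx
from levoresp.grids import AtlasLabels


def quantized_from_array(levels):
    """Wrap a raw level array (0 = outside ROI) as a QuantizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    return tx.QuantizedROI(
        levels=levels,
        n_levels=max(int(levels.max()), 1),
        raw=levels[levels > 0].astype(float),
        voxel_volume=1.0,
    )


class TestQuantize:
    def _single_roi(self, data):
        data = np.asarray(data, dtype=np.float32)
        atlas = AtlasLabels(np.ones(data.shape, dtype=np.int32))
        return make_volume(data), atlas

    def test_constant_roi_single_level(self):
        v, atlas = self._single_roi(np.full((3, 3, 3), 7.0))
        q = tx.quantize(v, atlas, 1, 32)
        assert set(np.unique(q.levels)) == {1}

    def test_integer_ramp_identity_mapping(self):
        data = np.arange(32, dtype=np.float32).reshape(2, 4, 4)
        v, atlas = self._single_roi(data)
        q = tx.quantize(v, atlas, 1, 32)
        assert np.array_equal(np.sort(q.levels.ravel()), np.arange(1, 33))

    def test_affine_intensity_invariance(self, rng):
        data = rng.normal(size=(4, 4, 4))
        v1, atlas = self._single_roi(data)
        v2, _ = self._single_roi(3.0 * data + 11.0)
        q1 = tx.quantize(v1, atlas, 1, 16)
        q2 = tx.quantize(v2, atlas, 1, 16)
        assert np.array_equal(q1.levels, q2.levels)

    def test_empty_roi_rejected(self):
        v, atlas = self._single_roi(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            tx.quantize(v, atlas, 9)


class TestMatrixHandCases:
    def test_gldm_uniform_2x2_slab(self):
        levels = np.zeros((2, 2, 1), dtype=int) + 2
        m = tx.gldm(quantized_from_array(levels))
        assert m.Nz == 4
        assert m.P[1, 3] == 4  # level 2, dependence size 4 (3 neighbors + 1)
        assert m.P.sum() == 4

    def test_gldm_single_voxel(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 5
        m = tx.gldm(quantized_from_array(levels))
        assert m.P[4, 0] == 1 and m.Nz == 1

    def test_glszm_uniform_2x2_slab(self):
        levels = np.zeros((2, 2, 1), dtype=int) + 2
        m = tx.glszm(quantized_from_array(levels))
        assert m.Nz == 1 and m.P[1, 3] == 1

    def test_glszm_all_distinct(self):
        levels = np.arange(1, 9).reshape(2, 2, 2)
        m = tx.glszm(quantized_from_array(levels))
        assert m.Nz == 8
        assert m.P[:, 0].sum() == 8 and m.P[:, 1:].sum() == 0

    def test_ldhgle_hand_values(self):
        P = np.zeros((2, 4))
        P[1, 3] = 4  # P(2,4)=4
        assert tx.ldhgle(tx.GLDMatrix(P, 4)) == pytest.approx(64.0)
        P1 = np.zeros((1, 1)); P1[0, 0] = 1
        assert tx.ldhgle(tx.GLDMatrix(P1, 1)) == pytest.approx(1.0)
        assert tx.ldhgle(tx.GLDMatrix(2 * P, 8)) == pytest.approx(64.0)  # scale-free

    def test_lahgle_hand_values(self):
        P = np.zeros((2, 4)); P[1, 3] = 1
        assert tx.lahgle(tx.GLSZMatrix(P, 1)) == pytest.approx(64.0)
        P1 = np.zeros((1, 1)); P1[0, 0] = 1
        assert tx.lahgle(tx.GLSZMatrix(P1, 1)) == pytest.approx(1.0)

    def test_lahgle_monotone_in_zone_size(self):
        Pa = np.zeros((3, 2)); Pa[2, 0] = 5
        Pb = np.zeros((3, 2)); Pb[2, 0] = 4; Pb[2, 1] = 1
        assert tx.lahgle(tx.GLSZMatrix(Pb, 5)) > tx.lahgle(tx.GLSZMatrix(Pa, 5))


class TestOracleEquivalence:
    def _random_levels(self, rng):
        shape = tuple(rng.integers(2, 7, size=3))
        levels = rng.integers(0, 5, size=shape)  # 0 = outside ROI
        if (levels > 0).sum() == 0:
            levels.flat[0] = 1
        return levels

    def test_gldm_matches_brute_force_on_random_rois(self, rng):
        for _ in range(100):
            levels = self._random_levels(rng)
            q = quantized_from_array(levels)
            m = tx.gldm(q, alpha=0)
            expected, n_vox = oracles.brute_gldm(levels, alpha=0)
            assert m.Nz == n_vox
            got = {
                (i + 1, j + 1): int(m.P[i, j])
                for i, j in zip(*np.nonzero(m.P))
            }
            assert got == expected

    def test_gldm_alpha_tolerance_matches_brute_force(self, rng):
        for _ in range(20):
            levels = self._random_levels(rng)
            m = tx.gldm(quantized_from_array(levels), alpha=1)
            expected, _ = oracles.brute_gldm(levels, alpha=1)
            got = {(i + 1, j + 1): int(m.P[i, j]) for i, j in zip(*np.nonzero(m.P))}
            assert got == expected

    def test_glszm_matches_flood_fill_on_random_rois(self, rng):
        for _ in range(100):
            levels = self._random_levels(rng)
            m = tx.glszm(quantized_from_array(levels))
            zones = oracles.flood_fill_zones(levels)
            expected = {}
            for lv, s in zones:
                expected[(lv, s)] = expected.get((lv, s), 0) + 1
            got = {(i + 1, j + 1): int(m.P[i, j]) for i, j in zip(*np.nonzero(m.P))}
            assert got == expected and m.Nz == len(zones)

    def test_zone_mass_conservation(self, rng):
        for _ in range(20):
            levels = self._random_levels(rng)
            m = tx.glszm(quantized_from_array(levels))
            s = np.arange(1, m.P.shape[1] + 1)
            assert (m.P * s[None, :]).sum() == (levels > 0).sum()

    def test_translation_invariance(self, rng):
        core = rng.integers(1, 5, size=(3, 3, 3))
        a = np.zeros((9, 9, 9), dtype=int); a[1:4, 1:4, 1:4] = core
        b = np.zeros((9, 9, 9), dtype=int); b[5:8, 4:7, 3:6] = core
        qa, qb = quantized_from_array(a), quantized_from_array(b)
        assert np.array_equal(tx.gldm(qa).P, tx.gldm(qb).P)
        assert np.array_equal(tx.glszm(qa).P, tx.glszm(qb).P)


class TestRoiInventory:
    def test_cardinality_and_unique_names(self, tiny_atlas, rng):
        v = make_volume(rng.normal(size=tiny_atlas.shape))
        feats = tx.extract_roi_textures(v, tiny_atlas)
        per_roi = 19 + 13 + 14  # first-order + GLDM family + GLSZM family
        assert len(feats) == 3 * per_roi
        assert feats.index.is_unique

    def test_constant_roi_zero_variance_features(self, tiny_atlas):
        data = np.zeros(tiny_atlas.shape, dtype=np.float32)
        data[tiny_atlas.labels == 1] = 4.0
        data[tiny_atlas.labels == 2] = 7.0
        feats = tx.extract_roi_textures(make_volume(data), tiny_atlas, roi_ids=[1])
        assert feats["ROI_1 First Order Variance"] == 0.0
        assert feats["ROI_1 First Order StandardDeviation"] == 0.0
        assert feats["ROI_1 First Order Skewness"] == 0.0

    def test_missing_roi_named_in_error(self, tiny_atlas, rng):
        v = make_volume(rng.normal(size=tiny_atlas.shape))
        with pytest.raises(ValueError, match="9"):
            tx.extract_roi_textures(v, tiny_atlas, roi_ids=[1, 9])


class TestPruneCorrelated:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept = tx.prune_correlated(X, 0.9)
        assert "c" in kept and len([k for k in kept if k in ("a", "b")]) == 1

    def test_orthogonal_features_all_retained(self):
        X = pd.DataFrame(np.eye(4), columns=list("abcd"))
        assert tx.prune_correlated(X, 0.9) == list("abcd")

    def test_three_identical_copies_one_survivor(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy(), "d": rng.normal(size=30)})
        kept = tx.prune_correlated(X, 0.9)
        assert len([k for k in kept if k in "abc"]) == 1 and "d" in kept
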