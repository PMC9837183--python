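"""Radiomics: discretization, per-family features, brute-force oracle equivalence."""

import numpy as np
import pytest

import oracles
from bcseg.radiomics import (
    FAMILIES,
    FAMILY_SIZES,
    N_FEATURES,
    RadiomicsConfig,
    discretize,
    extract_all,
    first_order_features,
    shape_features,
)
from bcseg.radiomics.texture import (
    ANGLES_13,
    dependence_matrix,
    glcm_features,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    ngtdm_table,
    run_length_matrix,
    size_zone_matrix,
)


def _roi(values, mask=None, bin_width=0.005):
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return discretize(values, mask, bin_width=bin_width)


def _random_roi(rng, shape=(4, 5, 5), ng_scale=0.02):
    vol = rng.normal(1.0, ng_scale, size=shape)
    mask = rng.random(shape) < 0.8
    mask[tuple(s // 2 for s in shape)] = True  # never empty
    return vol, mask


class TestDiscretize:
    def test_floor_rule_on_stated_example(self):
        """Values {1.000, 1.004, 1.005} at W=0.005 discretize to {1, 1, 2}."""
        d = _roi(np.array([[[1.000, 1.004, 1.005]]]))
        assert d.levels[d.mask].tolist() == [1, 1, 2]
        assert d.ng == 2

    def test_constant_roi_single_level(self):
        d = _roi(np.full((2, 2, 2), 3.7))
        assert d.ng == 1
        assert (d.levels[d.mask] == 1).all()

    def test_shift_invariance(self, rng):
        vol, mask = _random_roi(rng)
        a = discretize(vol, mask)
        b = discretize(vol + 0.42, mask)
        assert (a.levels == b.levels).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestFirstOrder:
    def test_mean_of_small_set(self):
        out = first_order_features(np.array([1.0, 2.0, 3.0]))
        assert out["Mean"] == 2.0

    def test_shifted_energy_hand_computed(self):
        """Energy of {1,2,3} with shift 1 is 2²+3²+4² = 29."""
        out = first_order_features(np.array([1.0, 2.0, 3.0]), shift=1.0)
        assert out["Energy"] == 29.0
        assert abs(out["RootMeanSquared"] - np.sqrt(29.0 / 3.0)) < 1e-12

    def test_emits_exactly_18_names(self, rng):
        out = first_order_features(rng.normal(1, 0.1, 50))
        assert len(out) == 18

    def test_matches_naive_oracle(self, rng):
        vals = rng.normal(1.0, 0.05, 200)
        ours = first_order_features(vals, shift=1.0, bin_width=0.005, voxel_volume=2.5)
        ref = oracles.naive_first_order(vals, shift=1.0, bin_width=0.005, voxel_volume=2.5)
        for name, v in ref.items():
            assert abs(ours[name] - v) < 1e-9 * max(1.0, abs(v)), name

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([]))


class TestShape:
    def test_voxel_volume_counts_voxels(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        out = shape_features(mask, (1.0, 1.0, 1.0))
        assert out["VoxelVolume"] == 8.0

    def test_digital_ball_against_analytic_sphere(self):
        """Mesh volume and diameter of a digital ball converge to the analytic
        sphere; surface area keeps the known ~8% voxelization excess, so
        sphericity sits in a band just below 1."""
        r = 11
        n = 2 * r + 3
        zz, yy, xx = np.mgrid[:n, :n, :n]
        c = n // 2
        ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
        out = shape_features(ball, (1.0, 1.0, 1.0))
        v_analytic = 4.0 / 3.0 * np.pi * r**3
        a_analytic = 4.0 * np.pi * r**2
        assert abs(out["MeshVolume"] - v_analytic) / v_analytic < 0.02
        assert 1.0 <= out["SurfaceArea"] / a_analytic < 1.12
        assert 0.90 < out["Sphericity"] <= 1.0
        assert abs(out["Maximum3DDiameter"] - 2 * r) / (2 * r) < 0.06

    def test_emits_exactly_14_names(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, :] = True
        assert len(shape_features(mask, (1, 1, 1))) == 14

    def test_single_voxel_degenerate_axes(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        out = shape_features(mask, (1.0, 1.0, 1.0))
        assert out["MajorAxisLength"] == 0.0
        assert out["Elongation"] == 0.0
        assert np.isfinite(list(out.values())).all()

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        out = shape_features(mask, (3.0, 1.5, 1.5))
        assert abs(out["VoxelVolume"] - 8 * 3.0 * 1.5 * 1.5) < 1e-9


class TestGLCM:
    def test_single_level_roi_zero_contrast(self):
        d = _roi(np.full((2, 3, 3), 2.0))
        out = glcm_features(d)
        assert out["Contrast"] == 0.0
        assert out["Correlation"] == 1.0

    def test_hand_enumerated_2x2_matrix(self):
        """Levels [[1,2],[1,2]] in one slice: pair counts checked by hand."""
        vol = np.array([[[1.0, 1.006], [1.0, 1.006]]])  # levels 1,2,1,2
        d = _roi(vol)
        # horizontal offset (0,0,1): pairs (1,2),(1,2) -> symmetric counts
        m = glcm_matrix(d, (0, 0, 1))
        assert m.tolist() == [[0, 2], [2, 0]]
        # vertical offset (0,1,0): pairs (1,1),(2,2)
        m = glcm_matrix(d, (0, 1, 0))
        assert m.tolist() == [[2, 0], [0, 2]]

    def test_matrices_match_brute_force_on_random_rois(self, rng):
        for _ in range(5):
            vol, mask = _random_roi(rng, shape=(3, 4, 4))
            d = discretize(vol, mask)
            for off in ((0, 0, 1), (1, -1, 0), (1, 1, 1)):
                ours = glcm_matrix(d, off)
                ref = oracles.naive_glcm(d.levels, d.mask, off, d.ng)
                assert (ours == ref).all(), off

    def test_emits_exactly_24_names(self, rng):
        vol, mask = _random_roi(rng)
        out = glcm_features(discretize(vol, mask))
        assert len(out) == 24
        assert np.isfinite(list(out.values())).all()


class TestGLRLM:
    def test_constant_line_single_run(self):
        vol = np.full((1, 1, 4), 5.0)
        d = _roi(vol)
        m = run_length_matrix(d, (0, 0, 1))
        assert m.shape == (1, 4)
        assert m[0, 3] == 1 and m.sum() == 1

    def test_all_distinct_levels_short_runs(self):
        vol = np.array([[[1.0, 1.01, 1.02, 1.03]]])
        d = _roi(vol)
        out = glrlm_features(d)
        assert abs(out["ShortRunEmphasis"] - 1.0) < 1e-12

    def test_matches_brute_force_runs(self, rng):
        for _ in range(5):
            vol, mask = _random_roi(rng, shape=(3, 4, 4))
            d = discretize(vol, mask)
            for off in ((0, 0, 1), (0, 1, 1), (1, 0, -1)):
                ours = run_length_matrix(d, off)
                ref = oracles.naive_glrlm(d.levels, d.mask, off, d.ng)
                r = min(ours.shape[1], ref.shape[1])
                assert (ours[:, :r] == ref[:, :r]).all()
                assert ours.sum() == ref.sum()

    def test_emits_exactly_16_names(self, rng):
        vol, mask = _random_roi(rng)
        assert len(glrlm_features(discretize(vol, mask))) == 16


class TestGLSZM:
    def test_constant_roi_one_zone(self):
        vol = np.full((2, 3, 3), 1.0)
        d = _roi(vol)
        m = size_zone_matrix(d)
        assert m.shape == (1, 18)
        assert m[0, 17] == 1 and m.sum() == 1

    def test_two_disconnected_zones(self):
        vol = np.full((1, 1, 7), 1.0)
        vol[0, 0, 2:5] = 1.1  # splits level-1 into sizes 2 and 2, middle zone size 3
        d = _roi(vol, bin_width=0.05)
        m = size_zone_matrix(d)
        ref = oracles.naive_glszm(d.levels, d.mask, d.ng)
        assert (m == ref).all()

    def test_zone_sizes_sum_to_roi_voxels(self, rng):
        vol, mask = _random_roi(rng)
        d = discretize(vol, mask)
        m = size_zone_matrix(d)
        sizes = np.arange(1, m.shape[1] + 1)
        assert int((m * sizes).sum()) == d.n_voxels

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            vol, mask = _random_roi(rng, shape=(3, 4, 4))
            d = discretize(vol, mask)
            ours = size_zone_matrix(d)
            ref = oracles.naive_glszm(d.levels, d.mask, d.ng)
            assert (ours == ref).all()

    def test_emits_exactly_16_names(self, rng):
        vol, mask = _random_roi(rng)
        assert len(glszm_features(discretize(vol, mask))) == 16


class TestNGTDM:
    def test_constant_roi_zero_contrast(self):
        d = _roi(np.full((2, 3, 3), 1.0))
        out = ngtdm_features(d)
        assert out["Contrast"] == 0.0
        assert out["Busyness"] == 0.0

    def test_hand_worked_neighborhood_table(self, rng):
        vol, mask = _random_roi(rng, shape=(1, 3, 3))
        d = discretize(vol, mask)
        n, s, nvp = ngtdm_table(d)
        rn, rs, rnvp = oracles.naive_ngtdm(d.levels, d.mask, d.ng)
        assert (n == rn).all()
        assert np.allclose(s, rs, atol=1e-10)
        assert nvp == rnvp

    def test_matches_oracle_on_3d_roi(self, rng):
        vol, mask = _random_roi(rng, shape=(3, 3, 3))
        d = discretize(vol, mask)
        n, s, nvp = ngtdm_table(d)
        rn, rs, rnvp = oracles.naive_ngtdm(d.levels, d.mask, d.ng)
        assert (n == rn).all() and np.allclose(s, rs) and nvp == rnvp

    def test_emits_exactly_5_names(self, rng):
        vol, mask = _random_roi(rng)
        assert len(ngtdm_features(discretize(vol, mask))) == 5


class TestGLDM:
    def test_constant_interior_voxel_dependence_26(self):
        d = _roi(np.full((3, 3, 3), 1.0))
        m = dependence_matrix(d, alpha=0)
        # the center voxel of a constant 3x3x3 ROI depends on all 26 neighbors
        assert m.shape[1] == 27
        assert m[0, 26] == 1

    def test_single_voxel_dependence_zero(self):
        vol = np.ones((1, 1, 1))
        d = _roi(vol)
        m = dependence_matrix(d)
        assert m.shape == (1, 1)
        assert m[0, 0] == 1

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            vol, mask = _random_roi(rng, shape=(3, 4, 4))
            d = discretize(vol, mask)
            ours = dependence_matrix(d, alpha=0)
            ref = oracles.naive_gldm(d.levels, d.mask, d.ng, alpha=0)
            c = min(ours.shape[1], ref.shape[1])
            assert (ours[:, :c] == ref[:, :c]).all()
            assert ours.sum() == ref.sum() == d.n_voxels

    def test_emits_exactly_14_names(self, rng):
        vol, mask = _random_roi(rng)
        assert len(gldm_features(discretize(vol, mask))) == 14


class TestExtractAll:
    def test_full_vector_and_family_counts(self, small_case):
        fv = extract_all(small_case.adc, small_case.reference_mask, small_case.spacing)
        assert len(fv) == N_FEATURES == 107
        for fam, size in FAMILY_SIZES.items():
            assert len(fv.by_family(fam)) == size

    def test_deterministic_repeat(self, small_case):
        a = extract_all(small_case.adc, small_case.reference_mask, small_case.spacing)
        b = extract_all(small_case.adc, small_case.reference_mask, small_case.spacing)
        assert a.values == b.values

    def test_all_finite_on_random_roi(self, rng):
        vol, mask = _random_roi(rng, shape=(6, 6, 3))
        fv = extract_all(vol, mask, (1.0, 1.0, 1.0))
        assert np.isfinite(list(fv.values.values())).all()

    def test_constant_roi_still_107_finite(self):
        vol = np.full((4, 4, 4), 2.0)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        fv = extract_all(vol, mask, (1.0, 1.0, 1.0))
        assert len(fv) == 107
        assert np.isfinite(list(fv.values.values())).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_all(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), (1, 1, 1))

    def test_intensity_shift_moves_mean_not_texture(self, rng):
        """Adding a constant to the ADC shifts first-order location features
        but leaves the min-anchored texture families unchanged."""
        vol, mask = _random_roi(rng)
        a = extract_all(vol, mask, (1, 1, 1))
        b = extract_all(vol + 0.7, mask, (1, 1, 1))
        assert abs((b["firstorder_Mean"] - a["firstorder_Mean"]) - 0.7) < 1e-9
        for fam in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            for name, v in a.by_family(fam).items():
                assert abs(b[name] - v) < 1e-9, name

    def test_translation_invariance_of_texture(self, rng):
        vol, mask = _random_roi(rng, shape=(4, 5, 5))
        big_vol = np.zeros((8, 9, 9))
        big_mask = np.zeros((8, 9, 9), dtype=bool)
        big_vol[2:6, 3:8, 1:6] = vol
        big_mask[2:6, 3:8, 1:6] = mask
        a = extract_all(vol, mask, (1, 1, 1))
        b = extract_all(big_vol, big_mask, (1, 1, 1))
        for name, v in a.values.items():
            if name.startswith("shape_"):
                continue
            assert abs(b[name] - v) < 1e-9, name


class TestNormalizedMatrixInvariants:
    def test_glcm_normalizations_sum_to_one(self, rng):
        vol, mask = _random_roi(rng)
        d = discretize(vol, mask)
        for off in ANGLES_13:
            m = glcm_matrix(d, off)
            if m.sum() > 0:
                assert abs((m / m.sum()).sum() - 1.0) < 1e-12

    def test_glrlm_run_voxels_sum_to_roi(self, rng):
        vol, mask = _random_roi(rng)
        d = discretize(vol, mask)
        for off in ((0, 0, 1), (1, 1, 1)):
            m = run_length_matrix(d, off)
            lengths = np.arange(1, m.shape[1] + 1)
            assert int((m * lengths).sum()) == d.n_voxels
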