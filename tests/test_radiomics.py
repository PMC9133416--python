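"""Radiomic features: hand-worked examples, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_all_features
from scarpipe.radiomics import (
    ALL_FEATURE_NAMES,
    COARSENESS_CAP,
    FAMILY_NAMES,
    EmptyRegionError,
    RadiomicsConfig,
    compute_features,
    discretize,
    first_order,
    gldm_features,
    gldm_matrix,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
)


def region(values, mask=None, bw=1.0):
    x = np.asarray(values, dtype=float)
    m = np.ones(x.shape, bool) if mask is None else np.asarray(mask, bool)
    return discretize(x, m, bw)


class TestDiscretize:
    def test_constant_region_single_level(self):
        d = region([[5.0, 5.0], [5.0, 5.0]], bw=5.0)
        assert d.n_levels == 1
        assert set(d.levels) == {1}

    def test_bin_arithmetic(self):
        d = region([[0.0, 4.9, 5.0, 10.0]], bw=5.0)
        assert list(d.levels) == [1, 1, 2, 3]
        assert d.n_levels == 3

    def test_shift_invariance(self):
        x = np.random.default_rng(5).uniform(0, 20, (6, 6))
        a = region(x, bw=3.0)
        b = region(x + 137.0, bw=3.0)
        assert np.array_equal(a.gray_image, b.gray_image)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            discretize(np.ones((2, 2)), np.zeros((2, 2), bool), 1.0)


class TestFirstOrder:
    def test_small_sample_arithmetic(self):
        d = region([[1.0, 2.0, 3.0]])
        vals, undef = first_order(np.array([1.0, 2.0, 3.0]), d)
        assert vals["mean"] == 2.0
        assert vals["energy"] == 14.0
        assert vals["range"] == 2.0
        assert not undef

    def test_constant_region_degenerate(self):
        d = region([[7.0, 7.0, 7.0]])
        vals, undef = first_order(np.array([7.0, 7.0, 7.0]), d)
        assert vals["entropy"] == 0.0
        assert vals["uniformity"] == 1.0
        assert vals["variance"] == 0.0
        assert undef == {"skewness", "kurtosis"}

    def test_entropy_matches_histogram_recomputation(self):
        x = np.random.default_rng(0).uniform(0, 50, 100)
        d = discretize(x.reshape(1, -1), np.ones((1, 100), bool), 5.0)
        vals, _ = first_order(x, d)
        counts = np.bincount(d.levels)[1:]
        p = counts[counts > 0] / 100
        assert vals["entropy"] == pytest.approx(-np.sum(p * np.log2(p)), abs=1e-12)


class TestGLCM:
    def test_single_row_hand_enumeration(self):
        d = region([[1.0, 1.0, 2.0, 2.0]], bw=1.0)
        P = glcm_matrix(d, offsets=[(0, 1)])
        np.testing.assert_allclose(P, [[2 / 6, 1 / 6], [1 / 6, 2 / 6]])

    def test_hand_contrast(self):
        P = np.array([[2 / 6, 1 / 6], [1 / 6, 2 / 6]])
        vals, _ = glcm_features(P)
        assert vals["contrast"] == pytest.approx(2 / 6)

    def test_constant_region(self):
        d = region([[3.0, 3.0], [3.0, 3.0]])
        vals, undef = glcm_features(glcm_matrix(d))
        assert vals["joint_energy"] == 1.0
        assert vals["joint_entropy"] == 0.0
        assert vals["maximum_probability"] == 1.0
        assert vals["contrast"] == 0.0
        assert {"correlation", "imc1", "imc2", "mcc"} <= undef

    def test_checkerboard_no_diagonal_mass(self):
        x = np.indices((6, 6)).sum(axis=0) % 2
        d = region(x.astype(float), bw=1.0)
        P = glcm_matrix(d, offsets=[(0, 1), (1, 0)])
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0

    def test_invalid_offsets(self):
        d = region([[1.0, 2.0]])
        with pytest.raises(ValueError):
            glcm_matrix(d, offsets=[(0, 0)])
        with pytest.raises(ValueError):
            glcm_matrix(d, offsets=[])


class TestGLDM:
    def test_constant_3x3_hand_enumeration(self):
        """Centre has 8 dependent neighbours, edges 5, corners 3; one gray
        level means GLN equals the pixel count."""
        d = region(np.full((3, 3), 4.0))
        P = gldm_matrix(d, alpha=0)
        assert P.shape == (1, 9)
        assert P[0, 8] == 1  # centre
        assert P[0, 5] == 4  # edges
        assert P[0, 3] == 4  # corners
        vals, _ = gldm_features(d)
        assert vals["gray_level_non_uniformity"] == pytest.approx(9.0)

    def test_single_pixel(self):
        d = discretize(np.array([[5.0]]), np.ones((1, 1), bool), 1.0)
        P = gldm_matrix(d)
        assert P.shape == (1, 1)
        assert P[0, 0] == 1.0


class TestGLSZM:
    def test_constant_region_single_zone(self):
        d = region(np.full((4, 4), 2.0))
        P = glszm_matrix(d)
        assert P.shape == (1, 16)
        assert P[0, 15] == 1.0
        vals, _ = glszm_features(d)
        assert vals["size_zone_non_uniformity"] == pytest.approx(1.0)

    def test_constructed_zones_entropy(self):
        """Two 2-pixel zones of level 1 plus one single pixel of level 2."""
        x = np.array(
            [
                [1.0, 1.0, 5.0, 2.0],
                [5.0, 5.0, 5.0, 5.0],
                [1.0, 1.0, 5.0, 5.0],
            ]
        )
        mask = x != 5.0
        d = discretize(x, mask, 1.0)
        P = glszm_matrix(d)
        assert P[0, 1] == 2  # level 1, size 2 (twice)
        assert P[1, 0] == 1  # level 2, size 1
        vals, _ = glszm_features(d)
        expected = -(2 / 3 * np.log2(2 / 3) + 1 / 3 * np.log2(1 / 3))
        assert vals["zone_entropy"] == pytest.approx(expected)


class TestGLRLM:
    def test_single_row_runs(self):
        d = region([[1.0, 1.0, 2.0]])
        P = glrlm_matrix(d, directions=[(0, 1)])
        assert P[0, 1] == 1  # level 1, length 2
        assert P[1, 0] == 1  # level 2, length 1

    def test_constant_row_features(self):
        n = 7
        d = region([[3.0] * n])
        vals, _ = glrlm_features(d, directions=[(0, 1)])
        assert vals["run_length_non_uniformity"] == pytest.approx(1.0)
        assert vals["run_percentage"] == pytest.approx(1.0 / n)

    def test_mask_gap_breaks_run(self):
        x = np.array([[1.0, 1.0, 1.0, 1.0]])
        mask = np.array([[True, True, False, True]])
        d = discretize(x, mask, 1.0)
        P = glrlm_matrix(d, directions=[(0, 1)])
        assert P[0, 1] == 1 and P[0, 0] == 1


class TestNGTDM:
    def test_constant_region_coarseness_cap(self):
        d = region(np.full((3, 3), 1.0))
        vals, _ = ngtdm_features(d)
        assert vals["coarseness"] == COARSENESS_CAP

    def test_center_surround_hand_arithmetic(self):
        x = np.full((3, 3), 1.0)
        x[1, 1] = 2.0
        d = region(x, bw=1.0)
        n = [0.0, 0.0]
        s = [0.0, 0.0]
        # centre: level 2, neighbours all 1 -> s(2) = 1
        # border pixels: mean of neighbours includes the centre
        for r in range(3):
            for c in range(3):
                nb = [
                    d.gray_image[rr, cc]
                    for rr in range(max(0, r - 1), min(3, r + 2))
                    for cc in range(max(0, c - 1), min(3, c + 2))
                    if (rr, cc) != (r, c)
                ]
                lvl = d.gray_image[r, c]
                n[lvl - 1] += 1
                s[lvl - 1] += abs(lvl - np.mean(nb))
        assert s[1] == pytest.approx(1.0)
        vals, _ = ngtdm_features(d)
        p = [n[0] / 9, n[1] / 9]
        coarse = 1.0 / (p[0] * s[0] + p[1] * s[1])
        assert vals["coarseness"] == pytest.approx(coarse)


class TestFeatureVectorContract:
    def test_family_counts(self):
        counts = {f: len(n) for f, n in FAMILY_NAMES.items()}
        assert counts == {
            "firstorder": 18, "glcm": 24, "gldm": 14,
            "glszm": 16, "glrlm": 16, "ngtdm": 5,
        }
        assert len(ALL_FEATURE_NAMES) == 93

    def test_any_valid_region_emits_93(self, rng):
        x = rng.uniform(0, 100, (20, 20))
        fv = compute_features(x, np.ones((20, 20), bool))
        assert len(fv.values) == 93
        assert list(fv.values) == ALL_FEATURE_NAMES
        assert not fv.undefined

    def test_constant_region_all_defined_or_flagged(self):
        fv = compute_features(np.full((5, 5), 42.0), np.ones((5, 5), bool))
        assert len(fv.values) == 93
        finite = {k for k, v in fv.values.items() if np.isfinite(v)}
        assert finite | fv.undefined == set(ALL_FEATURE_NAMES)
        assert fv.values["firstorder.entropy"] == 0.0
        assert fv.values["firstorder.uniformity"] == 1.0
        assert fv.values["glcm.joint_energy"] == 1.0

    def test_intensity_shift_moves_first_order_only(self, rng):
        x = rng.uniform(0, 60, (15, 15))
        mask = np.ones((15, 15), bool)
        a = compute_features(x, mask)
        b = compute_features(x + 50.0, mask)
        for fam in ("glcm", "gldm", "glszm", "glrlm", "ngtdm"):
            for name in FAMILY_NAMES[fam]:
                key = f"{fam}.{name}"
                assert b.values[key] == pytest.approx(a.values[key], rel=1e-12), key
        assert b.values["firstorder.mean"] == pytest.approx(
            a.values["firstorder.mean"] + 50.0
        )

    def test_rotation_consistency(self, rng):
        """90-degree rotation leaves features unchanged for the symmetric
        offset/direction sets."""
        x = rng.uniform(0, 30, (10, 10))
        mask = rng.random((10, 10)) < 0.9
        a = compute_features(x, mask)
        b = compute_features(np.rot90(x).copy(), np.rot90(mask).copy())
        for key in ALL_FEATURE_NAMES:
            va, vb = a.values[key], b.values[key]
            if np.isnan(va) and np.isnan(vb):
                continue
            assert vb == pytest.approx(va, rel=1e-9), key

    def test_matrix_normalizations(self, rng):
        """GLCM sums to 1; GLSZM zone sizes and GLRLM run lengths account
        for every masked pixel."""
        x = rng.uniform(0, 25, (9, 9))
        mask = rng.random((9, 9)) < 0.85
        d = discretize(x, mask, 5.0)
        assert glcm_matrix(d).sum() == pytest.approx(1.0)
        P = glszm_matrix(d)
        sizes = np.arange(1, P.shape[1] + 1)
        assert (P * sizes).sum() == pytest.approx(mask.sum())
        R = glrlm_matrix(d, directions=[(0, 1)])
        lengths = np.arange(1, R.shape[1] + 1)
        assert (R * lengths).sum() == pytest.approx(mask.sum())


@given(st.integers(0, 10_000))
def test_oracle_equivalence_property(seed):
    """Every feature matches the independent brute-force oracle on random
    small regions."""
    rng = np.random.default_rng(seed)
    h, w = rng.integers(3, 13, 2)
    x = np.floor(rng.uniform(0, 6, (h, w))) * 4.0  # N_g <= 6
    mask = rng.random((h, w)) < 0.8
    if mask.sum() < 2:
        return
    fv = compute_features(x, mask, RadiomicsConfig(bin_width=4.0))
    ref = oracle_all_features(x, mask, 4.0)
    for name in ALL_FEATURE_NAMES:
        v, r = fv.values[name], ref[name]
        if np.isnan(v) and np.isnan(r):
            continue
        assert v == pytest.approx(r, rel=1e-10, abs=1e-12), name


def test_multi_slice_region_pools_consistently(rng):
    """A region split across two slices with a shared bin anchor gives the
    same first-order values as the pooled samples."""
    x1 = rng.uniform(10, 40, (8, 8))
    x2 = rng.uniform(10, 40, (8, 8))
    m1 = rng.random((8, 8)) < 0.7
    m2 = rng.random((8, 8)) < 0.7
    fv = compute_features([x1, x2], [m1, m2])
    pooled = np.concatenate([x1[m1], x2[m2]])
    assert fv.values["firstorder.mean"] == pytest.approx(pooled.mean())
    assert fv.values["firstorder.energy"] == pytest.approx(np.sum(pooled**2))
    assert len(fv.values) == 93
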