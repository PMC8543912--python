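"""Feature extraction: structural counts, closed-form cases, small oracles."""

import numpy as np
import pandas as pd
import pytest

from mbdwi.radiomics import (
    FEATURE_GROUPS,
    N_FEATURES,
    build_feature_matrix,
    extract_features,
    icc,
    mean_metric,
    mean_metric_vector,
    reproducible_features,
)
from mbdwi.radiomics._texture import (
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
)

SPACING = (1.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def random_map_and_mask():
    rng = np.random.default_rng(11)
    values = rng.normal(1.2e-3, 2e-4, (16, 16, 10))
    z, y, x = np.ogrid[:16, :16, :10]
    mask = ((z - 8) ** 2 / 25 + (y - 8) ** 2 / 16 + (x - 5) ** 2 / 9) <= 1
    return values, mask


class TestStructure:
    def test_exactly_100_features_with_group_counts(self, random_map_and_mask):
        values, mask = random_map_and_mask
        fv = extract_features(values, mask, SPACING, map_id="D")
        assert len(fv.features) == N_FEATURES == 100
        expected = {"firstorder": 18, "shape": 14, "glcm": 22,
                    "glrlm": 16, "glszm": 16, "gldm": 14}
        for group, count in expected.items():
            assert len(fv.group(group)) == count

    def test_extraction_is_deterministic(self, random_map_and_mask):
        values, mask = random_map_and_mask
        a = extract_features(values, mask, SPACING, map_id="D")
        b = extract_features(values, mask, SPACING, map_id="D")
        assert a.features == b.features

    def test_translation_by_whole_voxels_is_invariant(self, random_map_and_mask):
        values, mask = random_map_and_mask
        a = extract_features(values, mask, SPACING, map_id="D")
        b = extract_features(np.roll(values, 3, axis=1),
                             np.roll(mask, 3, axis=1), SPACING, map_id="D")
        for k in a.features:
            # mesh-based shape features accumulate float error at different
            # absolute coordinates; everything else is exactly invariant
            assert a.features[k] == pytest.approx(b.features[k], rel=1e-6)

    def test_single_voxel_mask_names_offending_groups(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="shape and texture"):
            extract_features(np.ones((5, 5, 5)), mask, SPACING)

    def test_900_column_matrix_across_nine_maps(self, malignant_phantom):
        from mbdwi.fitting import MAP_NAMES, ParameterMap
        from mbdwi.radiomics import feature_row

        vol, mask, truth = malignant_phantom
        rng = np.random.default_rng(0)
        maps = {name: ParameterMap("X", name,
                                   truth["D"].values * rng.uniform(0.9, 1.1),
                                   "mm^2/s")
                for name in MAP_NAMES}
        row = feature_row(maps, mask, vol.spacing)
        assert len(row) == 900
        assert row.index[0] == "ADC_all-b__firstorder__Energy"


class TestFirstOrder:
    def test_constant_map_collapses_location_features(self, random_map_and_mask):
        _, mask = random_map_and_mask
        fv = extract_features(np.full(mask.shape, 7.5), mask, SPACING,
                              map_id="K")
        fo = fv.group("firstorder")
        assert fo["Mean"] == fo["Median"] == fo["10Percentile"] == 7.5
        assert fo["Variance"] == 0.0
        assert fo["Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert fo["Uniformity"] == 1.0

    def test_firstorder_mean_equals_mean_metric(self, random_map_and_mask):
        values, mask = random_map_and_mask
        fv = extract_features(values, mask, SPACING, map_id="D")
        assert fv.features["firstorder__Mean"] == pytest.approx(
            mean_metric(values, mask), rel=1e-12)


class TestShape:
    def test_sphere_sphericity_approaches_one(self):
        z, y, x = np.ogrid[:26, :26, :26]
        sphere = ((z - 12.5) ** 2 + (y - 12.5) ** 2 + (x - 12.5) ** 2) <= 100
        fv = extract_features(np.ones((26, 26, 26)), sphere, SPACING,
                              map_id="q")
        assert fv.features["shape__Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert fv.features["shape__Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_voxel_volume_is_count_times_voxel_size(self, random_map_and_mask):
        values, mask = random_map_and_mask
        fv = extract_features(values, mask, (1.5, 1.5, 2.5), map_id="D")
        assert fv.features["shape__VoxelVolume"] == pytest.approx(
            mask.sum() * 1.5 * 1.5 * 2.5)


class TestTextureMatrices:
    """Hand-computed oracles on tiny gray-level arrays."""

    def test_glcm_counts_on_a_2x2_plane(self):
        disc = np.array([[[1], [2]], [[1], [2]]])
        mask = np.ones((2, 2, 1), bool)
        mat = glcm_matrix(disc, mask, (0, 1, 0))  # along the second axis
        # two symmetric (1,2) pairs -> counts 2 each side
        np.testing.assert_array_equal(mat, [[0, 2], [2, 0]])
        mat_row = glcm_matrix(disc, mask, (1, 0, 0))
        # pairs (1,1) and (2,2)
        np.testing.assert_array_equal(mat_row, [[2, 0], [0, 2]])

    def test_glrlm_runs_along_a_line(self):
        # line of levels 1 1 1 2 2 -> runs: (1,len3), (2,len2)
        disc = np.array([1, 1, 1, 2, 2]).reshape(5, 1, 1)
        mask = np.ones((5, 1, 1), bool)
        mat = glrlm_matrix(disc, mask, (1, 0, 0))
        assert mat.shape == (2, 3)
        assert mat[0, 2] == 1  # level 1, length 3
        assert mat[1, 1] == 1  # level 2, length 2
        assert mat.sum() == 2

    def test_glszm_zone_sizes(self):
        disc = np.zeros((4, 4, 1), int)
        mask = np.zeros((4, 4, 1), bool)
        mask[:2, :2] = True   # 4-voxel zone of level 1
        disc[:2, :2] = 1
        mask[3, 3] = True     # isolated single voxel of level 2
        disc[3, 3] = 2
        mat = glszm_matrix(disc, mask)
        assert mat[0, 3] == 1  # level 1, size 4
        assert mat[1, 0] == 1  # level 2, size 1
        assert mat.sum() == 2

    def test_constant_region_texture_degenerates(self, random_map_and_mask):
        _, mask = random_map_and_mask
        fv = extract_features(np.full(mask.shape, 3.0), mask, SPACING,
                              map_id="alpha")
        # one gray level: co-occurrence fully concentrated
        assert fv.features["glcm__JointEnergy"] == 1.0
        assert fv.features["glcm__Contrast"] == 0.0
        assert fv.features["glszm__ZonePercentage"] == pytest.approx(
            1.0 / mask.sum())


class TestMeanMetrics:
    def test_two_voxel_mean(self):
        vals = np.zeros((3, 3, 1))
        mask = np.zeros((3, 3, 1), bool)
        vals[0, 0, 0], vals[1, 1, 0] = 1.0, 3.0
        mask[0, 0, 0] = mask[1, 1, 0] = True
        assert mean_metric(vals, mask) == 2.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            mean_metric(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_vector_covers_all_nine_maps(self, malignant_phantom):
        from mbdwi.fitting import MAP_NAMES, ParameterMap

        vol, mask, truth = malignant_phantom
        maps = {name: ParameterMap("X", name, truth["D"].values, "mm^2/s")
                for name in MAP_NAMES}
        mm = mean_metric_vector(maps, mask)
        assert set(mm) == {f"m{n}" for n in MAP_NAMES}

    def test_phantom_truth_round_trip(self, malignant_phantom):
        vol, mask, truth = malignant_phantom
        assert mean_metric(truth["D"].values, mask) == pytest.approx(
            truth["D"].values[mask].mean())


class TestICC:
    def _features(self, rng, n=200, f=6):
        base = rng.normal(0, 1, (n, f))
        return pd.DataFrame(base, columns=[f"feat{i}" for i in range(f)])

    def test_identical_readings_give_icc_one(self):
        rng = np.random.default_rng(0)
        a = self._features(rng)
        vals = icc(a, a.copy())
        assert np.allclose(vals.to_numpy(), 1.0)

    def test_independent_noise_gives_icc_near_zero(self):
        rng = np.random.default_rng(1)
        a = self._features(rng)
        b = self._features(rng)  # fresh independent draws
        vals = icc(a, b)
        assert np.all(np.abs(vals.to_numpy()) < 0.15)

    def test_matches_pingouin_two_way_absolute_single(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        subj = rng.normal(0, 1, 40)
        a = subj + rng.normal(0, 0.3, 40)
        b = subj + 0.1 + rng.normal(0, 0.3, 40)
        ours = icc(pd.DataFrame({"f": a}), pd.DataFrame({"f": b}))["f"]
        long = pd.DataFrame({
            "subject": np.r_[np.arange(40), np.arange(40)],
            "rater": ["a"] * 40 + ["b"] * 40,
            "score": np.r_[a, b],
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-10)

    def test_zero_between_subject_variance_flagged_nan(self):
        a = pd.DataFrame({"f": np.ones(10)})
        b = pd.DataFrame({"f": np.ones(10)})
        assert np.isnan(icc(a, b)["f"])

    def test_threshold_flagging(self):
        vals = pd.Series({"good": 0.92, "borderline": 0.80, "poor": 0.4})
        flags = reproducible_features(vals, 0.80)
        assert flags["good"] and not flags["borderline"] and not flags["poor"]
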