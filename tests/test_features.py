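"""Feature operators vs direct-summation oracles and analytic shapes."""

import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse

import mritex as mx
from mritex.errors import EmptyMaskError
from mritex.features import (
    Family,
    FeatureConfig,
    family_features,
    first_order,
    glcm_features,
    shape_features,
)
from mritex.matrices import CooccurrenceMatrix, glcm
from mritex.quantize import quantize
from oracles import first_order_oracle, glcm_features_oracle


def roi_of(values):
    arr = np.asarray(values, dtype=float)[None, :]
    return quantize(arr, np.ones_like(arr, bool), 2)


def test_first_order_hand_values():
    fo = first_order(roi_of([1, 2, 3]))
    assert fo["j_mean"] == 2.0
    assert fo["j_std"] == pytest.approx(math.sqrt(2 / 3), abs=1e-12)
    assert fo["j_skewness"] == pytest.approx(0.0, abs=1e-12)


def test_symmetric_sample_zero_skewness():
    fo = first_order(roi_of([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
    assert fo["j_skewness"] == pytest.approx(0.0, abs=1e-12)


def test_gaussian_sample_excess_kurtosis_near_zero():
    rng = np.random.default_rng(2024)
    vals = rng.standard_normal(100_000)
    img = vals[None, :]
    fo = first_order(quantize(img, np.ones_like(img, bool), 2))
    assert abs(fo["j_kurtosis"]) < 0.1


def test_constant_region_undefined_sentinels():
    fo = first_order(roi_of([0.4, 0.4, 0.4]))
    assert math.isnan(fo["j_skewness"]) and math.isnan(fo["j_kurtosis"])
    assert fo["j_std"] == 0.0


def test_first_order_matches_direct_summation(rng):
    for _ in range(100):
        vals = rng.random(int(rng.integers(3, 50)))
        got = first_order(roi_of(vals))
        want = first_order_oracle(vals)
        for k, v in want.items():
            if math.isnan(v):
                assert math.isnan(got[k])
            else:
                assert got[k] == pytest.approx(v, rel=1e-9)


def two_cell_matrix():
    counts = np.array([[0.5, 0.5], [0.0, 0.0]])
    return CooccurrenceMatrix(counts=counts, offsets=((0, 1),), symmetric=False)


def test_glcm_feature_micro_examples():
    feats = glcm_features(two_cell_matrix())
    assert feats["t_contrast"] == pytest.approx(0.5)
    assert feats["t_entropy"] == pytest.approx(1.0)  # 1 bit


def test_diagonal_matrix_zero_contrast():
    M = CooccurrenceMatrix(counts=np.diag([0.25, 0.5, 0.25]), offsets=((0, 1),), symmetric=True)
    assert glcm_features(M)["t_contrast"] == 0.0


def test_gradient_image_correlation_bounded():
    img = np.tile(np.linspace(0, 1, 16), (16, 1))
    roi = quantize(img, np.ones((16, 16), bool), 8)
    feats = glcm_features(glcm(roi))
    assert -1.0 <= feats["t_correlation"] <= 1.0


def test_constant_image_correlation_sentinel():
    M = CooccurrenceMatrix(counts=np.array([[1.0, 0], [0, 0]]), offsets=((0, 1),), symmetric=True)
    assert math.isnan(glcm_features(M)["t_correlation"])


def test_glcm_features_match_direct_summation(rng):
    for _ in range(100):
        L = int(rng.integers(2, 8))
        counts = rng.random((L, L))
        M = CooccurrenceMatrix(counts=counts, offsets=((0, 1),), symmetric=False)
        got = glcm_features(M)
        want = glcm_features_oracle(M.P)
        for k in got:
            assert got[k] == pytest.approx(want[k], rel=1e-9)


def test_disc_circularity_near_analytic():
    mask = np.zeros((64, 64), bool)
    mask[disk((32, 32), 20)] = True
    s = shape_features(mask)
    assert 0.9 <= s["s_circularity"] <= 1.05
    assert s["s_area"] == mask.sum()


def test_ellipse_elongation_near_half():
    mask = np.zeros((64, 64), bool)
    mask[ellipse(32, 32, 10, 20)] = True
    s = shape_features(mask)
    assert s["s_elongation"] == pytest.approx(0.5, abs=0.05)


def test_bar_elongation_monotone_decreasing():
    vals = []
    for k in (5, 10, 20, 40):
        mask = np.zeros((6, 50), bool)
        mask[2:4, :k] = True  # 2 x k bar
        vals.append(shape_features(mask)["s_elongation"])
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 0.15


def test_form_factor_consistent_with_parts():
    mask = np.zeros((40, 40), bool)
    mask[disk((20, 20), 12)] = True
    s = shape_features(mask)
    assert s["s_form"] == pytest.approx(s["s_perimeter"] * s["s_elongation"] / (8 * s["s_area"]))


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        shape_features(np.zeros((8, 8), bool))


def test_multi_component_uses_largest_with_warning():
    mask = np.zeros((30, 30), bool)
    mask[disk((10, 10), 6)] = True
    mask[25:27, 25:27] = True
    with pytest.warns(UserWarning, match="largest"):
        s = shape_features(mask)
    assert s["s_area"] == np.count_nonzero(mask[disk((10, 10), 6)]) + 0  # largest only
    assert s["s_area"] < mask.sum()


def test_single_family_config_reduces_all(phantom):
    cfg = FeatureConfig(families=(Family.GLCM,))
    fs = family_features(phantom.image, phantom.lesion_mask, cfg)
    assert fs.all_features == fs.families[Family.GLCM]


def test_constant_image_family_behaviour():
    img = np.full((32, 32), 0.5)
    mask = np.zeros((32, 32), bool)
    mask[8:24, 8:24] = True
    fs = family_features(img, mask)
    fo = fs.families[Family.FIRST_ORDER]
    assert math.isnan(fo["j_skewness"]) and fo["j_std"] == 0.0
    assert fs.families[Family.GLCM]["t_contrast"] == 0.0


def test_texture_features_invariant_to_affine_intensity(phantom):
    cfg = FeatureConfig(families=(Family.GLCM, Family.GLRLM, Family.GLSZM))
    a = family_features(phantom.image, phantom.lesion_mask, cfg)
    b = family_features(0.4 * phantom.image + 0.2, phantom.lesion_mask, cfg)
    for fam in cfg.families:
        for k in a.families[fam]:
            assert a.families[fam][k] == pytest.approx(b.families[fam][k], rel=1e-9)


def test_rotation_90_leaves_pooled_glcm_features_unchanged(phantom):
    cfg = FeatureConfig(families=(Family.GLCM,))
    a = family_features(phantom.image, phantom.lesion_mask, cfg)
    b = family_features(np.rot90(phantom.image), np.rot90(phantom.lesion_mask), cfg)
    for k in a.all_features:
        assert a.all_features[k] == pytest.approx(b.all_features[k], rel=1e-9)


def test_all_vector_is_concatenation(phantom):
    fs = family_features(phantom.image, phantom.lesion_mask)
    assert len(fs.all_features) == sum(len(v) for v in fs.families.values())
    # names unique across families
    names = [k for v in fs.families.values() for k in v]
    assert len(names) == len(set(names))


def test_all_can_exclude_nontexture(phantom):
    cfg = FeatureConfig(all_includes_nontexture=False)
    fs = family_features(phantom.image, phantom.lesion_mask, cfg)
    assert not any(k.startswith(("j_", "s_")) for k in fs.all_features)


def test_cohort_classes_differ_in_some_feature(small_cohort):
    from mritex.features import cohort_feature_table

    table = cohort_feature_table(
        [s.image for s in small_cohort], [s.lesion_mask for s in small_cohort]
    )
    labels = np.array([s.label for s in small_cohort])
    diffs = table[labels == "A"].mean() - table[labels == "B"].mean()
    assert np.abs(diffs.to_numpy()).max() > 0
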