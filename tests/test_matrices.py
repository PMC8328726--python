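"""Texture-matrix construction vs hand examples and brute-force oracles."""

import numpy as np
import pytest

from mritex.errors import DegenerateMatrixError
from mritex.matrices import DEFAULT_OFFSETS, glcm, glrlm, glszm, mglszm
from mritex.quantize import QuantizedROI, quantize
from oracles import glcm_counts_oracle, glrlm_counts_oracle, glszm_counts_oracle


def roi_from_grid(grid):
    grid = np.asarray(grid, dtype=np.int64)
    mask = grid > 0
    return QuantizedROI(
        levels=int(grid.max()), grid=grid, mask=mask, raw_values=grid[mask].astype(float)
    )


def test_glcm_hand_example_two_pairs():
    M = glcm(roi_from_grid([[1, 1], [1, 2]]), offsets=[(0, 1)], symmetric=False)
    np.testing.assert_allclose(M.P, [[0.5, 0.5], [0.0, 0.0]])


def test_glcm_constant_roi_concentrates_on_diagonal():
    M = glcm(roi_from_grid([[1, 1], [1, 1]]))
    assert M.P[0, 0] == 1.0


def test_glcm_symmetrization_contract(rng):
    grid = rng.integers(1, 5, size=(8, 8))
    M = glcm(roi_from_grid(grid), symmetric=True)
    np.testing.assert_allclose(M.P, M.P.T)


def test_glcm_normalization_and_marginals(rng):
    grid = rng.integers(1, 6, size=(10, 10))
    M = glcm(roi_from_grid(grid))
    assert abs(M.P.sum() - 1.0) < 1e-9
    np.testing.assert_allclose(M.p_y.sum(), 1.0)
    np.testing.assert_allclose(M.p_z.sum(), 1.0)


def test_glcm_degenerate_single_pixel_raises():
    grid = np.zeros((3, 3), dtype=np.int64)
    grid[1, 1] = 1
    roi = QuantizedROI(levels=2, grid=grid, mask=grid > 0, raw_values=np.array([1.0]))
    with pytest.raises(DegenerateMatrixError):
        glcm(roi)


def test_glcm_transpose_equivariance(rng):
    grid = rng.integers(1, 5, size=(7, 9))
    roi = roi_from_grid(grid)
    roi_t = roi_from_grid(grid.T)
    offs = [(0, 1), (1, 2)]
    offs_t = [(dc, dr) for dr, dc in offs]
    M = glcm(roi, offsets=offs, symmetric=False)
    Mt = glcm(roi_t, offsets=offs_t, symmetric=False)
    np.testing.assert_allclose(M.P, Mt.P)


def test_glrlm_hand_example():
    R = glrlm(roi_from_grid([[1, 1, 2]]), directions=[(0, 1)])
    assert R.counts[0, 1] == 1  # level 1, length 2
    assert R.counts[1, 0] == 1  # level 2, length 1
    assert R.n_runs == 2


def test_glrlm_constant_row_single_run():
    R = glrlm(roi_from_grid([[3, 3, 3, 3, 3]]), directions=[(0, 1)])
    assert R.counts[2, 4] == 1 and R.n_runs == 1


def test_glrlm_checkerboard_all_runs_length_one():
    grid = np.indices((6, 6)).sum(axis=0) % 2 + 1
    R = glrlm(roi_from_grid(grid), directions=[(0, 1)])
    assert R.max_run_length == 1
    assert R.n_runs == 36


def test_glrlm_pixel_identity(rng):
    grid = rng.integers(1, 4, size=(9, 9))
    mask = rng.random((9, 9)) < 0.7
    grid[~mask] = 0
    if not mask.any():
        pytest.skip("empty mask draw")
    roi = QuantizedROI(levels=3, grid=grid, mask=mask, raw_values=grid[mask].astype(float))
    R = glrlm(roi, directions=DEFAULT_OFFSETS)
    r = np.arange(1, R.max_run_length + 1)
    assert (R.counts * r).sum() == mask.sum() * len(DEFAULT_OFFSETS)


def test_glszm_hand_example():
    Z = glszm(roi_from_grid([[1, 1], [1, 2]]), connectivity=4)
    assert Z.counts[0, 2] == 1  # one 3-pixel zone of level 1
    assert Z.counts[1, 0] == 1  # one 1-pixel zone of level 2


def test_glszm_constant_roi_one_zone():
    Z = glszm(roi_from_grid(np.full((4, 5), 2)))
    assert Z.counts[1, 19] == 1 and Z.n_zones == 1


def test_glszm_mass_conservation(rng):
    grid = rng.integers(1, 5, size=(12, 12))
    roi = roi_from_grid(grid)
    for conn in (4, 8):
        Z = glszm(roi, connectivity=conn)
        s = np.arange(1, Z.max_zone_size + 1)
        assert (Z.counts * s).sum() == roi.m


@pytest.mark.parametrize("conn", [4, 8])
def test_glszm_matches_flood_fill_oracle(rng, conn):
    for _ in range(20):
        grid = rng.integers(1, 4, size=(16, 16))
        mask = rng.random((16, 16)) < 0.75
        grid[~mask] = 0
        if mask.sum() < 2:
            continue
        roi = QuantizedROI(levels=3, grid=grid, mask=mask, raw_values=grid[mask].astype(float))
        Z = glszm(roi, connectivity=conn)
        expect = glszm_counts_oracle(grid, mask, conn, 3, Z.max_zone_size)
        np.testing.assert_array_equal(Z.counts, expect)


def test_glrlm_matches_run_scanner_oracle(rng):
    for _ in range(20):
        grid = rng.integers(1, 5, size=(12, 12))
        mask = rng.random((12, 12)) < 0.8
        grid[~mask] = 0
        if mask.sum() < 2:
            continue
        roi = QuantizedROI(levels=4, grid=grid, mask=mask, raw_values=grid[mask].astype(float))
        R = glrlm(roi, directions=DEFAULT_OFFSETS)
        expect = glrlm_counts_oracle(grid, mask, DEFAULT_OFFSETS, 4, R.max_run_length)
        np.testing.assert_array_equal(R.counts, expect)


def test_glcm_matches_pair_enumeration_oracle(rng):
    for _ in range(20):
        grid = rng.integers(1, 6, size=(10, 10))
        mask = rng.random((10, 10)) < 0.8
        grid[~mask] = 0
        if (mask[:, 1:] & mask[:, :-1]).sum() == 0:
            continue
        roi = QuantizedROI(levels=5, grid=grid, mask=mask, raw_values=grid[mask].astype(float))
        for sym in (False, True):
            M = glcm(roi, offsets=DEFAULT_OFFSETS, symmetric=sym)
            expect = glcm_counts_oracle(grid, mask, DEFAULT_OFFSETS, sym, levels=5)
            np.testing.assert_array_equal(M.counts, expect)


def test_mglszm_single_level_reduces_to_glszm(phantom):
    MZ = mglszm(phantom.image, phantom.lesion_mask, level_set=[8])
    direct = glszm(quantize(phantom.image, phantom.lesion_mask, 8))
    np.testing.assert_array_equal(MZ.members[8].counts, direct.counts)


def test_mglszm_constant_roi_every_member_one_zone():
    img = np.full((20, 20), 0.5)
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    MZ = mglszm(img, mask, level_set=[4, 8, 16])
    for Z in MZ.members.values():
        assert Z.n_zones == 1 and Z.counts[0, mask.sum() - 1] == 1


def test_mglszm_coarser_quantization_fewer_active_levels(phantom):
    MZ = mglszm(phantom.image, phantom.lesion_mask, level_set=[4, 16])
    active = {L: (MZ.members[L].counts.sum(axis=1) > 0).sum() for L in (4, 16)}
    assert active[4] <= active[16]


def test_mglszm_validates_level_set(phantom):
    with pytest.raises(ValueError):
        mglszm(phantom.image, phantom.lesion_mask, level_set=[])
    with pytest.raises(ValueError):
        mglszm(phantom.image, phantom.lesion_mask, level_set=[1])


def test_matrix_csv_serialization(tmp_path, phantom):
    import pandas as pd

    roi = quantize(phantom.image, phantom.lesion_mask, 8)
    M = glcm(roi)
    M.to_csv(tmp_path / "glcm.csv")
    df = pd.read_csv(tmp_path / "glcm.csv", index_col=0)
    np.testing.assert_allclose(df.to_numpy(), M.P)
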