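"""Texture matrices versus exhaustive brute-force enumeration, plus the
invariances the features must satisfy.

The oracles below are written independently of the implementation: plain
Python loops over voxels, neighbour offsets and flood fills.
"""

from itertools import product

import numpy as np
import pytest

from petphantom.radiomics import (
    DiscretizedVolume,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_matrix,
)
from petphantom.radiomics.texture import DIRECTIONS_13

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def random_disc(seed, shape=(5, 5, 4), n_levels=4, p_mask=0.75):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[0, 0, 0] = True
    lv = np.where(mask, levels, 0).astype(np.int32)
    return DiscretizedVolume(lv, mask, n_levels, (0.0, 1.0))


def _in_bounds(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


# ----------------------------------------------------------- brute oracles

def oracle_glcm(disc):
    lv, mask = disc.levels, disc.mask
    n = disc.n_levels
    out = np.zeros((n, n))
    for p in product(*[range(s) for s in lv.shape]):
        if not mask[p]:
            continue
        for d in ALL_26:
            q = tuple(c + o for c, o in zip(p, d))
            if _in_bounds(q, lv.shape) and mask[q]:
                out[lv[p] - 1, lv[q] - 1] += 1
    return out


def oracle_glrlm(disc):
    lv, mask = disc.levels, disc.mask
    runs = []
    for d in DIRECTIONS_13:
        for p in product(*[range(s) for s in lv.shape]):
            if not mask[p]:
                continue
            prev = tuple(c - o for c, o in zip(p, d))
            if _in_bounds(prev, lv.shape) and mask[prev] and lv[prev] == lv[p]:
                continue  # not a run start
            length = 1
            q = tuple(c + o for c, o in zip(p, d))
            while _in_bounds(q, lv.shape) and mask[q] and lv[q] == lv[p]:
                length += 1
                q = tuple(c + o for c, o in zip(q, d))
            runs.append((lv[p], length))
    max_len = max(l for _, l in runs)
    out = np.zeros((disc.n_levels, max_len))
    for g, l in runs:
        out[g - 1, l - 1] += 1
    return out


def oracle_glszm(disc):
    lv, mask = disc.levels, disc.mask
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for p in product(*[range(s) for s in lv.shape]):
        if not mask[p] or seen[p]:
            continue
        g = lv[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                q = tuple(c + o for c, o in zip(cur, d))
                if (_in_bounds(q, lv.shape) and mask[q] and not seen[q]
                        and lv[q] == g):
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((disc.n_levels, max_size))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def oracle_ngtdm(disc):
    lv, mask = disc.levels, disc.mask
    s = np.zeros(disc.n_levels)
    n = np.zeros(disc.n_levels)
    for p in product(*[range(sh) for sh in lv.shape]):
        if not mask[p]:
            continue
        nbrs = []
        for d in ALL_26:
            q = tuple(c + o for c, o in zip(p, d))
            if _in_bounds(q, lv.shape) and mask[q]:
                nbrs.append(lv[q])
        if not nbrs:
            continue
        s[lv[p] - 1] += abs(lv[p] - np.mean(nbrs))
        n[lv[p] - 1] += 1
    return s, n


# ----------------------------------------------------------- oracle suite

@pytest.mark.parametrize("seed", range(8))
def test_glcm_matrix_equals_exhaustive_enumeration(seed):
    disc = random_disc(seed)
    assert np.array_equal(glcm_matrix(disc), oracle_glcm(disc))


@pytest.mark.parametrize("seed", range(8))
def test_glrlm_matrix_equals_exhaustive_enumeration(seed):
    disc = random_disc(seed, shape=(6, 5, 4))
    got = glrlm_matrix(disc)
    want = oracle_glrlm(disc)
    cols = max(got.shape[1], want.shape[1])
    got = np.pad(got, ((0, 0), (0, cols - got.shape[1])))
    want = np.pad(want, ((0, 0), (0, cols - want.shape[1])))
    assert np.array_equal(got, want)


@pytest.mark.parametrize("seed", range(8))
def test_glszm_matrix_equals_flood_fill_oracle(seed):
    disc = random_disc(seed, shape=(6, 6, 3))
    assert np.array_equal(glszm_matrix(disc), oracle_glszm(disc))


@pytest.mark.parametrize("seed", range(8))
def test_ngtdm_equals_hand_neighbourhood_means(seed):
    disc = random_disc(seed, shape=(5, 4, 4))
    s, n = ngtdm_matrix(disc)
    s_o, n_o = oracle_ngtdm(disc)
    assert np.allclose(s, s_o)
    assert np.array_equal(n, n_o)


# ----------------------------------------------------------- worked examples

def test_glcm_constant_region():
    lv = np.ones((3, 3, 3), dtype=np.int32)
    disc = DiscretizedVolume(lv, np.ones((3, 3, 3), bool), 1, (0, 1))
    f = glcm_features(disc)
    assert f["Energy"] == pytest.approx(1.0)
    assert f["Contrast"] == 0.0
    assert f["Entropy"] == pytest.approx(0.0, abs=1e-12)
    assert f["Homogeneity"] == pytest.approx(1.0)


def test_glcm_checkerboard_matches_pair_oracle():
    lv = np.array([[1, 2], [2, 1]], dtype=np.int32).reshape(2, 2, 1)
    disc = DiscretizedVolume(lv, np.ones((2, 2, 1), bool), 2, (0, 1))
    mat = glcm_matrix(disc)
    assert np.array_equal(mat, oracle_glcm(disc))
    p = mat / mat.sum()
    assert p.sum() == pytest.approx(1.0)
    f = glcm_features(disc)
    # diagonal pairs are equal-level, edges differ: contrast from enumeration
    want = ((lv[0, 0, 0] - lv[0, 1, 0]) ** 2)  # = 1 per unequal pair
    assert 0 < f["Contrast"] <= want


def test_glrlm_constant_slab_single_axis():
    lv = np.ones((4, 4, 1), dtype=np.int32)
    disc = DiscretizedVolume(lv, np.ones((4, 4, 1), bool), 1, (0, 1))
    mat = glrlm_matrix(disc, directions=((1, 0, 0),))
    assert mat[0, 3] == 4  # 4 runs of length 4
    assert mat.sum() == 4
    f = glrlm_features(disc, directions=((1, 0, 0),))
    assert f["Long run emphasis (LRE)"] == pytest.approx(16.0)
    assert f["Short run emphasis (SRE)"] == pytest.approx(1.0 / 16.0)


def test_glrlm_alternating_line_max_fragmentation():
    lv = np.array([1, 2, 1, 2, 1], dtype=np.int32).reshape(1, 5, 1)
    disc = DiscretizedVolume(lv, np.ones((1, 5, 1), bool), 2, (0, 1))
    f = glrlm_features(disc, directions=((0, 1, 0),))
    assert f["Run percentage (RP)"] == pytest.approx(1.0)
    assert f["Short run emphasis (SRE)"] == pytest.approx(1.0)


def test_glszm_two_disjoint_blobs_same_level():
    lv = np.zeros((7, 3, 1), dtype=np.int32)
    lv[0:2] = 1
    lv[5:7] = 1
    mask = lv > 0
    disc = DiscretizedVolume(lv, mask, 1, (0, 1))
    mat = glszm_matrix(disc)
    assert mat.sum() == 2  # two zones


def test_glszm_constant_region_single_zone():
    n = 24
    lv = np.ones((4, 3, 2), dtype=np.int32)
    disc = DiscretizedVolume(lv, np.ones((4, 3, 2), bool), 1, (0, 1))
    mat = glszm_matrix(disc)
    assert mat[0, n - 1] == 1
    f = glszm_features(disc)
    assert f["Zone percentage (ZP)"] == pytest.approx(1.0 / n)


def test_ngtdm_constant_region_zero_contrast():
    lv = np.ones((3, 3, 3), dtype=np.int32)
    disc = DiscretizedVolume(lv, np.ones((3, 3, 3), bool), 1, (0, 1))
    f = ngtdm_features(disc)
    assert f["Contrast"] == 0.0
    assert f["Coarseness"] == pytest.approx(1e12)  # capped maximum


def test_ngtdm_single_bright_voxel_hand_computed():
    """3x3x3 toy, center at level 2 amid level 1: the center's 26 neighbours
    average 1 (diff 1); each rim voxel sees one 2 among its in-mask
    neighbours."""
    lv = np.ones((3, 3, 3), dtype=np.int32)
    lv[1, 1, 1] = 2
    disc = DiscretizedVolume(lv, np.ones((3, 3, 3), bool), 2, (0, 1))
    s, n = ngtdm_matrix(disc)
    s_o, n_o = oracle_ngtdm(disc)
    assert np.allclose(s, s_o)
    assert n[1] == 1 and s[1] == pytest.approx(1.0)  # the bright center


# ----------------------------------------------------------- invariances

def test_features_invariant_to_affine_intensity_rescale():
    """Any affine map of raw intensities preserves the discretization and
    hence every texture feature."""
    from petphantom.radiomics import discretize

    rng = np.random.default_rng(7)
    vals = rng.random((6, 6, 5)) * 4 + 1
    mask = rng.random((6, 6, 5)) > 0.25
    d1 = discretize(vals, mask, n_levels=8)
    d2 = discretize(2.0 * vals + 3.0, mask, n_levels=8)
    assert np.array_equal(d1.levels, d2.levels)
    assert glcm_features(d1) == glcm_features(d2)
    assert ngtdm_features(d1) == ngtdm_features(d2)


def test_glcm_invariant_to_translation_and_axis_permutation():
    rng = np.random.default_rng(8)
    lv_core = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)

    def disc_from(lv, mask):
        return DiscretizedVolume(np.where(mask, lv, 0).astype(np.int32),
                                 mask, 4, (0, 1))

    mask = np.ones((4, 4, 4), bool)
    base = glcm_features(disc_from(lv_core, mask))

    shifted = np.zeros((8, 8, 8), dtype=np.int32)
    shifted[2:6, 1:5, 3:7] = lv_core
    f_shift = glcm_features(disc_from(shifted, shifted > 0))
    assert f_shift == base

    permuted = np.transpose(lv_core, (2, 0, 1))
    f_perm = glcm_features(disc_from(permuted, np.ones((4, 4, 4), bool)))
    for k, v in base.items():
        assert f_perm[k] == pytest.approx(v, rel=1e-12)


def test_matrix_conservation_sums():
    disc = random_disc(3)
    n_runs = oracle_glrlm(disc).sum()
    assert glrlm_matrix(disc).sum() == n_runs
    n_zones = oracle_glszm(disc).sum()
    assert glszm_matrix(disc).sum() == n_zones
    assert glcm_matrix(disc).sum() == oracle_glcm(disc).sum()
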