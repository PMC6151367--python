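"""Texture matrices and their features (GLCM, GLRLM, GLSZM, NGTDM).

All four families operate on the 64-level discretized MTV with 26-voxel
connectivity: a voxel's 8 in-slice neighbours plus 9 in each adjacent slice.
Opposite offsets carry the same information once matrices are symmetrized,
so the 26 neighbours collapse to the 13 unique direction vectors below.
GLCM and GLRLM are accumulated over the 13 directions and merged into a
single matrix; GLSZM and NGTDM are orientation-free by construction.

Feature formulas follow the standard definitions of the classical texture
literature (Haralick co-occurrence statistics; Galloway / Chu /
Dasarathy-Holder run-length statistics; Thibault size-zone statistics;
Amadasun-King gray-tone difference statistics), each written out inline.
Degenerate inputs (a single voxel, no pairable neighbours) yield sentinel
vectors flagged by the caller rather than raising.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedVolume

#: 13 unique direction vectors of the 26-neighbourhood (positive half-space)
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_EPS = 1e-12
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shifted_views(arr: np.ndarray, d):
    """Paired views (arr[v], arr[v + d]) over the overlap region."""
    sl_a, sl_b = [], []
    for n, step in zip(arr.shape, d):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        else:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(disc: DiscretizedVolume, directions=DIRECTIONS_13) -> np.ndarray:
    """Symmetric distance-1 co-occurrence counts merged over directions."""
    disc = disc.cropped()
    n = disc.n_levels
    lv = disc.levels
    counts = np.zeros((n, n), dtype=np.float64)
    for d in directions:
        a, b = _shifted_views(lv, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pairs = a[valid] * (n + 1) + b[valid]  # encode (i, j)
        flat = np.bincount(pairs, minlength=(n + 1) * (n + 1)).reshape(n + 1, n + 1)
        counts += flat[1:, 1:]
    return counts + counts.T  # symmetrize


def glcm_features(disc: DiscretizedVolume, directions=DIRECTIONS_13) -> dict[str, float]:
    """The 9 co-occurrence features on the merged, normalized matrix."""
    counts = glcm_matrix(disc, directions)
    total = counts.sum()
    if total == 0:  # single voxel: no pairs
        return {k: np.nan for k in (
            "Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
            "SumAverage", "Variance", "Dissimilarity", "Autocorrelation")}
    p = counts / total
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())  # == mu_y by symmetry
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    pz = p[p > 0]
    if sigma_x > 0:
        correlation = float(((ii - mu_x) * (jj - mu_x) * p).sum() / sigma_x**2)
    else:
        correlation = 0.0  # constant region: undefined, sentinel
    return {
        "Energy": float((p**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Entropy": float(-(pz * np.log2(pz)).sum()),
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Correlation": correlation,
        # expectation of i + j under p: the sum-average of the p_{x+y} histogram
        "SumAverage": float(((ii + jj) * p).sum()),
        "Variance": float(((ii - mu_x) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Autocorrelation": float((ii * jj * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def _runs_one_direction(lv: np.ndarray, d, max_len: int) -> np.ndarray:
    """Run-length counts R[g-1, l-1] along one direction (both orientations
    describe the same runs, so each run is counted once)."""
    n_levels = max_len_g = int(lv.max())
    run = np.zeros((max_len_g, max_len), dtype=np.float64)
    valid = lv > 0
    # length[v]: voxels from v forward along d with the same level
    same_next = np.zeros(lv.shape, dtype=bool)
    a, b = _shifted_views(lv, d)
    va, vb = _shifted_views(valid, d)
    sl_a = tuple(
        slice(0, n - s) if s > 0 else (slice(-s, n) if s < 0 else slice(None))
        for n, s in zip(lv.shape, d)
    )
    same_next[sl_a] = (a == b) & va & vb
    length = valid.astype(np.int64)
    # propagate: length[v] = 1 + length[v+d] where the next voxel matches
    for _ in range(max(lv.shape)):
        _, nxt_len = _shifted_views(length, d)
        new = valid.astype(np.int64)
        new[sl_a] += np.where(same_next[sl_a], nxt_len, 0)
        if np.array_equal(new, length):
            break
        length = new
    # run starts: no same-level predecessor
    has_prev_same = np.zeros(lv.shape, dtype=bool)
    sl_b = tuple(
        slice(s, n) if s > 0 else (slice(0, n + s) if s < 0 else slice(None))
        for n, s in zip(lv.shape, d)
    )
    has_prev_same[sl_b] = same_next[sl_a]
    starts = valid & ~has_prev_same
    g = lv[starts]
    ln = length[starts]
    np.add.at(run, (g - 1, np.minimum(ln, max_len) - 1), 1.0)
    return run


def glrlm_matrix(disc: DiscretizedVolume, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length counts R[g, l] summed over the 13 directions."""
    disc = disc.cropped()
    lv = disc.levels
    max_len = max(int(np.ceil(np.sqrt(3) * max(lv.shape))), 1) + 1
    mat = np.zeros((disc.n_levels, max_len), dtype=np.float64)
    for d in directions:
        r = _runs_one_direction(lv, d, max_len)
        mat[: r.shape[0], :] += r
    # trim empty tail columns
    used = np.nonzero(mat.sum(axis=0))[0]
    if used.size:
        mat = mat[:, : used[-1] + 1]
    return mat


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: str,
                       n_norm: float) -> dict[str, float]:
    """Shared emphasis/nonuniformity/variance formulas for GLRLM and GLSZM.

    ``mat[g-1, s-1]`` counts runs (zones) of gray level g and size s;
    ``n_norm`` normalizes the percentage feature (directions * voxels for
    runs, voxels for zones).
    """
    total = mat.sum()
    names = _RL_NAMES if prefix == "run" else _SZ_NAMES
    if total == 0:
        return {k: np.nan for k in names}
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    gg, ss = np.meshgrid(g, s, indexing="ij")
    p = mat / total
    mu_g = float((gg * p).sum())
    mu_s = float((ss * p).sum())
    vals = [
        float((mat / ss**2).sum() / total),  # short/small emphasis
        float((mat * ss**2).sum() / total),  # long/large emphasis
        float((mat.sum(axis=1) ** 2).sum() / total),  # gray-level nonuniformity
        float((mat.sum(axis=0) ** 2).sum() / total),  # size nonuniformity
        float(total / n_norm),  # percentage
        float((mat / gg**2).sum() / total),  # low gray-level emphasis
        float((mat * gg**2).sum() / total),  # high gray-level emphasis
        float((mat / (gg**2 * ss**2)).sum() / total),
        float((mat * gg**2 / ss**2).sum() / total),
        float((mat * ss**2 / gg**2).sum() / total),
        float((mat * gg**2 * ss**2).sum() / total),
        float(((gg - mu_g) ** 2 * p).sum()),  # gray-level variance
        float(((ss - mu_s) ** 2 * p).sum()),  # size variance
    ]
    return dict(zip(names, vals))


_RL_NAMES = (
    "Short run emphasis (SRE)",
    "Long run emphasis (LRE)",
    "Gray-level nonuniformity (GLN)",
    "Run-length nonuniformity (RLN)",
    "Run percentage (RP)",
    "Low gray-level run emphasis (LGRE)",
    "High gray-level run emphasis (HGRE)",
    "Short run low gray-level emphasis (SRLGE)",
    "Short run high gray-level emphasis (SRHGE)",
    "Long run low gray-level emphasis (LRLGE)",
    "Long run high gray-level emphasis (LRHGE)",
    "Gray-level variance (GLV)",
    "Run-length variance (RLV)",
)

_SZ_NAMES = (
    "Small zone emphasis (SZE)",
    "Large zone emphasis (LZE)",
    "Gray-level nonuniformity (GLN)",
    "Zone-size nonuniformity (ZSN)",
    "Zone percentage (ZP)",
    "Low gray-level zone emphasis (LGZE)",
    "High gray-level zone emphasis (HGZE)",
    "Small zone low gray-level emphasis (SZLGE)",
    "Small zone high gray-level emphasis (SZHGE)",
    "Large zone low gray-level emphasis (LZLGE)",
    "Large zone high gray-level emphasis (LZHGE)",
    "Gray-level variance (GLV)",
    "Zone-size variance (ZSV)",
)


def glrlm_features(disc: DiscretizedVolume, directions=DIRECTIONS_13) -> dict[str, float]:
    """The 13 run-length features; RP is runs / (directions * voxels)."""
    mat = glrlm_matrix(disc, directions)
    n_vox = int(disc.mask.sum())
    return _run_zone_features(mat, n_vox, "run", len(directions) * n_vox)


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone counts Z[g, s]: 26-connected components of equal gray level."""
    disc = disc.cropped()
    lv = disc.levels
    zones: list[tuple[int, int]] = []
    for g in range(1, disc.n_levels + 1):
        region = lv == g
        if not region.any():
            continue
        labels, n = ndimage.label(region, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return np.zeros((disc.n_levels, 1))
    max_size = max(s for _, s in zones)
    mat = np.zeros((disc.n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """The 13 size-zone features; ZP is zones / voxels."""
    mat = glszm_matrix(disc)
    n_vox = int(disc.mask.sum())
    return _run_zone_features(mat, n_vox, "zone", n_vox)


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_matrix(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference sums.

    Returns ``(s, n)`` indexed by gray level - 1: ``s[i]`` is the summed
    absolute difference between level i+1 voxels and the mean of their valid
    26-neighbours (neighbours restricted to the mask), ``n[i]`` the number of
    contributing voxels.
    """
    disc = disc.cropped()
    lv = disc.levels.astype(np.float64)
    mask = disc.mask.astype(np.float64)
    kern = np.ones((3, 3, 3))
    kern[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv * mask, kern, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask, kern, mode="constant", cval=0.0)
    valid = disc.mask & (nbr_cnt > 0)
    n_levels = disc.n_levels
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    g = disc.levels[valid]
    diff = np.abs(disc.levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
    np.add.at(s, g - 1, diff)
    np.add.at(n, g - 1, 1.0)
    return s, n


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """Amadasun-King features with epsilon-guarded denominators.

    Constant regions give Contrast = Busyness = Complexity = Strength = 0
    and Coarseness capped at 1/eps (eps = 1e-12), the documented maximum.
    """
    s, n = ngtdm_matrix(disc)
    n_tot = n.sum()
    if n_tot == 0:
        return {k: np.nan for k in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p = n / n_tot
    act = p > 0  # gray levels present
    i = np.arange(1, len(p) + 1, dtype=np.float64)
    n_g = int(act.sum())

    coarseness = 1.0 / max(float((p * s).sum()), _EPS)
    if n_g > 1:
        pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
        ii, jj = np.meshgrid(i[act], i[act], indexing="ij")
        contrast = (
            float((pi * pj * (ii - jj) ** 2).sum()) / (n_g * (n_g - 1))
        ) * float(s.sum()) / n_tot
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p * s).sum()) / max(denom, _EPS)
        si, sj = np.meshgrid(s[act], s[act], indexing="ij")
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()
        ) / n_tot
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / max(float(s.sum()), _EPS)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
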