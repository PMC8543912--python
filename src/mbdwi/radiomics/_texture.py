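"""Gray-level texture matrices and their features.

All four matrix families operate on the discretized gray-level image
(integer levels 1..Ng) restricted to the lesion mask, with 26-connectivity
(13 unique 3D direction offsets at distance 1).  Per-direction matrices
(GLCM, GLRLM) yield per-direction feature values that are averaged over the
13 directions; GLSZM and GLDM are direction-free by construction.

Feature definitions follow the standard published radiomics formulary
(co-occurrence, run-length, size-zone and dependence statistics).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

#: 13 unique direction offsets of the 26-neighborhood.
OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def _shift_views(arr: np.ndarray, offset):
    """Aligned views (a, b) with b displaced from a by ``offset``."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, arr.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(disc: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset."""
    ng = int(disc[mask].max())
    a, b = _shift_views(disc, offset)
    ma, mb = _shift_views(mask, offset)
    valid = ma & mb
    mat = np.zeros((ng, ng))
    np.add.at(mat, (a[valid] - 1, b[valid] - 1), 1.0)
    return mat + mat.T


def _glcm_features_one(mat: np.ndarray) -> dict[str, float]:
    n = mat.sum()
    if n == 0:
        # no co-occurring pairs in this direction; contribute neutral zeros
        return {k: 0.0 for k in GLCM_NAMES}
    p = mat / n
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())          # == mu_x == mu_y (symmetric)
    sigma = float(np.sqrt(((i - mu) ** 2 * px).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    hxy = float(-np.sum(p * np.log2(p + _EPS)))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))

    da = float((k_diff * p_diff).sum())
    if sigma > 0:
        corr = float((np.sum(ii * jj * p) - mu * mu) / sigma**2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    off = ii != jj
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum((ii - mu) ** 2 * p)),
    }


def glcm_features(disc, mask) -> dict[str, float]:
    per_dir = [_glcm_features_one(glcm_matrix(disc, mask, off))
               for off in OFFSETS_13]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(disc: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Run-length counts R(gray level, run length) along one direction."""
    ng = int(disc[mask].max())
    g = np.where(mask, disc, 0)
    shape = g.shape
    # a voxel starts a run if its predecessor along -offset differs or is out
    prev = np.zeros(shape, dtype=g.dtype)
    sl_a = tuple(slice(0, n - d) if d >= 0 else slice(-d, n)
                 for d, n in zip(offset, shape))
    sl_b = tuple(slice(d, n) if d >= 0 else slice(0, n + d)
                 for d, n in zip(offset, shape))
    prev[sl_b] = g[sl_a]
    starts = np.argwhere((g > 0) & (g != prev))
    counts: dict[tuple[int, int], int] = {}
    step = np.asarray(offset)
    for s in starts:
        level = g[tuple(s)]
        length = 1
        pos = s + step
        while (np.all(pos >= 0) and np.all(pos < shape)
               and g[tuple(pos)] == level):
            length += 1
            pos = pos + step
        key = (int(level), length)
        counts[key] = counts.get(key, 0) + 1
    max_len = max((ln for (_, ln) in counts), default=1)
    mat = np.zeros((ng, max_len))
    for (level, ln), c in counts.items():
        mat[level - 1, ln - 1] = c
    return mat


def _run_zone_features(mat: np.ndarray, n_voxels: int,
                       names) -> dict[str, float]:
    """Shared run-length / size-zone statistics (they differ only in naming)."""
    nr = mat.sum()
    p = mat / nr
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, nl + 1) * pl).sum())
    vals = {
        "short": float(np.sum(p / j**2)),
        "long": float(np.sum(p * j**2)),
        "gln": float(np.sum(mat.sum(axis=1) ** 2) / nr),
        "glnn": float(np.sum(pg**2)),
        "rln": float(np.sum(mat.sum(axis=0) ** 2) / nr),
        "rlnn": float(np.sum(pl**2)),
        "pct": float(nr / n_voxels),
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "rv": float(np.sum(p * (j - mu_j) ** 2)),
        "ent": float(-np.sum(p * np.log2(p + _EPS))),
        "lgl": float(np.sum(p / i**2)),
        "hgl": float(np.sum(p * i**2)),
        "sl": float(np.sum(p / (i**2 * j**2))),
        "sh": float(np.sum(p * i**2 / j**2)),
        "ll": float(np.sum(p * j**2 / i**2)),
        "lh": float(np.sum(p * i**2 * j**2)),
    }
    order = ("short", "long", "gln", "glnn", "rln", "rlnn", "pct",
             "glv", "rv", "ent", "lgl", "hgl", "sl", "sh", "ll", "lh")
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(disc, mask) -> dict[str, float]:
    n_vox = int(mask.sum())
    per_dir = [
        _run_zone_features(glrlm_matrix(disc, mask, off), n_vox,
                           GLRLM_NAMES)
        for off in OFFSETS_13
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(disc: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zone counts Z(gray level, zone size), 26-connected zones."""
    ng = int(disc[mask].max())
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    max_size = 1
    for level in np.unique(disc[mask]):
        labeled, nz = ndimage.label((disc == level) & mask,
                                    structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for size in sizes:
            key = (int(level), int(size))
            zones[key] = zones.get(key, 0) + 1
            max_size = max(max_size, int(size))
    mat = np.zeros((ng, max_size))
    for (level, size), c in zones.items():
        mat[level - 1, size - 1] = c
    return mat


def glszm_features(disc, mask) -> dict[str, float]:
    mat = glszm_matrix(disc, mask)
    return _run_zone_features(mat, int(mask.sum()), GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM

def gldm_matrix(disc: np.ndarray, mask: np.ndarray,
                alpha: int = 0) -> np.ndarray:
    """Dependence counts P(gray level, dependence size).

    A neighbor (26-connectivity) is dependent when |g_n - g_c| <= alpha;
    the dependence size j counts the center voxel plus its dependent
    neighbors, so j ranges 1..27 and small-dependence emphases stay finite.
    """
    ng = int(disc[mask].max())
    dep = np.zeros(disc.shape, dtype=np.int64)
    for off in OFFSETS_13:
        a_sl = tuple(slice(0, n - d) if d >= 0 else slice(-d, n)
                     for d, n in zip(off, disc.shape))
        b_sl = tuple(slice(d, n) if d >= 0 else slice(0, n + d)
                     for d, n in zip(off, disc.shape))
        ok = (mask[a_sl] & mask[b_sl]
              & (np.abs(disc[a_sl] - disc[b_sl]) <= alpha))
        dep[a_sl] += ok
        dep[b_sl] += ok
    sizes = dep[mask] + 1
    levels = disc[mask]
    mat = np.zeros((ng, int(sizes.max())))
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)
    return mat


def gldm_features(disc, mask, alpha: int = 0) -> dict[str, float]:
    mat = gldm_matrix(disc, mask, alpha)
    nz = mat.sum()
    p = mat / nz
    ng, nd = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, nd + 1) * pd).sum())
    return dict(zip(GLDM_NAMES, (
        float(np.sum(p / j**2)),
        float(np.sum(p * j**2)),
        float(np.sum(mat.sum(axis=1) ** 2) / nz),
        float(np.sum(mat.sum(axis=0) ** 2) / nz),
        float(np.sum(pd**2)),
        float(np.sum(p * (i - mu_i) ** 2)),
        float(np.sum(p * (j - mu_j) ** 2)),
        float(-np.sum(p * np.log2(p + _EPS))),
        float(np.sum(p / i**2)),
        float(np.sum(p * i**2)),
        float(np.sum(p / (i**2 * j**2))),
        float(np.sum(p * i**2 / j**2)),
        float(np.sum(p * j**2 / i**2)),
        float(np.sum(p * i**2 * j**2)),
    )))
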