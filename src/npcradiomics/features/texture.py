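"""The five 3-D texture-matrix families on a quantized ROI.

Conventions (fixed across the package so features are comparable between
cases):

* The gray-level axis always spans levels ``1..n_levels`` (default 64),
  not just the observed levels.
* GLCM and GLRLM are built per direction over the 13 unique offsets of the
  26-neighborhood at Chebyshev distance 1; each feature is evaluated per
  direction and then averaged over directions (unweighted).
* GLSZM uses a single rotation-invariant matrix with 26-connected zones.
* GLDM counts 26-neighbors at distance 1 with zero gray-level tolerance;
  the dependence size is the number of dependent neighbors plus one (the
  center voxel), so it is always >= 1.
* NGTDM averages the levels of the in-ROI 26-neighbors of each voxel;
  voxels with no in-ROI neighbor are dropped.
* Logarithms are base 2. Excluded voxels (level 0) never contribute to any
  matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import QuantizedRoi

__all__ = [
    "OFFSETS_13",
    "GLCM_KEYS",
    "GLRLM_KEYS",
    "GLSZM_KEYS",
    "GLDM_KEYS",
    "NGTDM_KEYS",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

# 13 unique direction vectors of the 26-neighborhood (one per +/- pair)
OFFSETS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_KEYS = tuple(
    "glcm_" + k
    for k in (
        "AC", "CP", "CS", "CT", "Contrast", "Correlation", "DA", "DE", "DV",
        "JA", "JE", "JEN", "IMC", "IMC2", "IDM", "IDMN", "ID", "IDN", "IV",
        "MP", "SA", "SEN", "SS",
    )
)
GLRLM_KEYS = tuple(
    "glrlm_" + k
    for k in (
        "SRE", "LRE", "GLN", "GLNN", "RLN", "RLNN", "RP", "GLV", "RV", "RE",
        "LGLRE", "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
    )
)
GLSZM_KEYS = tuple(
    "glszm_" + k
    for k in (
        "SAE", "LAE", "GLN", "GLNN", "SZN", "SZNN", "ZP", "GLV", "ZV", "ZE",
        "LGLZE", "HGLZE", "SALGLE", "SAHGLE", "LALGLE", "LAHGLE",
    )
)
GLDM_KEYS = tuple(
    "gldm_" + k
    for k in (
        "SDE", "LDE", "GLN", "DN", "DNN", "GLV", "DV", "DE",
        "LGLE", "HGLE", "SDLGLE", "SDHGLE", "LDLGLE", "LDHGLE",
    )
)
NGTDM_KEYS = tuple(
    "ngtdm_" + k for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
)


def _cropped_levels(qroi: QuantizedRoi) -> np.ndarray:
    """Level grid cropped to the bounding box of the included voxels."""
    L = qroi.level_grid
    if not (L > 0).any():
        raise ValueError("quantized ROI has no included voxels")
    idx = np.argwhere(L > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return L[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """out[p] = a[p + d] inside the grid, 0 outside."""
    out = np.zeros_like(a)
    src, dst = [], []
    for n, di in zip(a.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(L: np.ndarray, d, ng: int) -> np.ndarray | None:
    nxt = _shift(L, d)
    pair = (L > 0) & (nxt > 0)
    if not pair.any():
        return None
    i = L[pair] - 1
    j = nxt[pair] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    P = counts + counts.T  # symmetric: both orders of every pair
    return P / P.sum()


def _glcm_dir_features(P: np.ndarray, ng: int) -> dict[str, float]:
    lv = np.arange(1, ng + 1, dtype=np.float64)
    i = lv[:, None]
    j = lv[None, :]
    px = P.sum(axis=1)  # == py by symmetry
    mu = float((px * lv).sum())
    sigma2 = float((px * (lv - mu) ** 2).sum())

    diff = np.abs(i - j)
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.array([P[diff == k].sum() for k in range(ng)])
    da = float((k_diff * p_diff).sum())

    ssum = i + j
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([P[ssum == k].sum() for k in range(2, 2 * ng + 1)])

    ac = float((P * i * j).sum())
    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    pxpy = px[:, None] * px[None, :]
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _entropy(pxpy.ravel())

    imc = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = i - j != 0
    return {
        "glcm_AC": ac,
        "glcm_CP": float((P * (i + j - 2 * mu) ** 4).sum()),
        "glcm_CS": float((P * (i + j - 2 * mu) ** 3).sum()),
        "glcm_CT": float((P * (i + j - 2 * mu) ** 2).sum()),
        "glcm_Contrast": float((P * (i - j) ** 2).sum()),
        "glcm_Correlation": (ac - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "glcm_DA": da,
        "glcm_DE": _entropy(p_diff),
        "glcm_DV": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_JA": mu,
        "glcm_JE": float((P**2).sum()),
        "glcm_JEN": hxy,
        "glcm_IMC": imc,
        "glcm_IMC2": imc2,
        "glcm_IDM": float((P / (1.0 + (i - j) ** 2)).sum()),
        "glcm_IDMN": float((P / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "glcm_ID": float((P / (1.0 + diff)).sum()),
        "glcm_IDN": float((P / (1.0 + diff / ng)).sum()),
        "glcm_IV": float((P[off] / (i - j)[off] ** 2).sum()),
        "glcm_MP": float(P.max()),
        "glcm_SA": float((k_sum * p_sum).sum()),
        "glcm_SEN": _entropy(p_sum),
        "glcm_SS": float((P * (i - mu) ** 2).sum()),
    }


def glcm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """23 co-occurrence features, per-direction values averaged over 13 offsets."""
    L = _cropped_levels(qroi)
    ng = qroi.n_levels
    acc: dict[str, float] = {k: 0.0 for k in GLCM_KEYS}
    n_dirs = 0
    for d in OFFSETS_13:
        P = _glcm_matrix(L, d, ng)
        if P is None:
            continue
        for k, v in _glcm_dir_features(P, ng).items():
            acc[k] += v
        n_dirs += 1
    if n_dirs == 0:
        raise ValueError("no valid voxel pair in any GLCM direction")
    return {k: v / n_dirs for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def _glrlm_matrix(L: np.ndarray, d, ng: int) -> np.ndarray:
    nxt = _shift(L, d)
    eq_next = (L > 0) & (nxt == L)
    cont = np.zeros(L.shape, dtype=np.int64)  # equal-run length strictly ahead
    while True:
        nxt_cont = np.where(eq_next, _shift(cont, d) + 1, 0)
        if np.array_equal(nxt_cont, cont):
            break
        cont = nxt_cont
    back = tuple(-x for x in d)
    prev = _shift(L, back)
    starts = (L > 0) & (prev != L)
    lengths = cont[starts] + 1
    levels = L[starts]
    max_len = int(lengths.max())
    counts = np.bincount(
        (levels - 1) * max_len + (lengths - 1), minlength=ng * max_len
    )
    return counts.reshape(ng, max_len).astype(np.float64)


def _run_zone_features(P: np.ndarray, prefix: str, names, n_voxels: int) -> dict[str, float]:
    """Shared run-length / size-zone / dependence feature formulas.

    ``P`` is counts indexed by (gray level - 1, size - 1). ``names`` maps the
    generic slots to family-specific keys in a fixed order: small/large size
    emphasis, gray-level and size nonuniformities (+normalized), percentage,
    variances, entropy, and the four joint emphases.
    """
    ng, ns = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    n = P.sum()
    p = P / n
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    vals = {
        "small": float((P / j**2).sum() / n),
        "large": float((P * j**2).sum() / n),
        "gln": float((pg**2).sum() / n),
        "glnn": float((pg**2).sum() / n**2),
        "sn": float((ps**2).sum() / n),
        "snn": float((ps**2).sum() / n**2),
        "perc": float(n / n_voxels),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "sv": float((p * (j - mu_j) ** 2).sum()),
        "ent": _entropy(p.ravel()),
        "lgl": float((P / i**2).sum() / n),
        "hgl": float((P * i**2).sum() / n),
        "slgl": float((P / (i**2 * j**2)).sum() / n),
        "shgl": float((P * i**2 / j**2).sum() / n),
        "llgl": float((P * j**2 / i**2).sum() / n),
        "lhgl": float((P * i**2 * j**2).sum() / n),
    }
    return {f"{prefix}_{key}": vals[slot] for slot, key in names}


_GLRLM_SLOTS = (
    ("small", "SRE"), ("large", "LRE"), ("gln", "GLN"), ("glnn", "GLNN"),
    ("sn", "RLN"), ("snn", "RLNN"), ("perc", "RP"), ("glv", "GLV"),
    ("sv", "RV"), ("ent", "RE"), ("lgl", "LGLRE"), ("hgl", "HGLRE"),
    ("slgl", "SRLGLE"), ("shgl", "SRHGLE"), ("llgl", "LRLGLE"), ("lhgl", "LRHGLE"),
)
_GLSZM_SLOTS = (
    ("small", "SAE"), ("large", "LAE"), ("gln", "GLN"), ("glnn", "GLNN"),
    ("sn", "SZN"), ("snn", "SZNN"), ("perc", "ZP"), ("glv", "GLV"),
    ("sv", "ZV"), ("ent", "ZE"), ("lgl", "LGLZE"), ("hgl", "HGLZE"),
    ("slgl", "SALGLE"), ("shgl", "SAHGLE"), ("llgl", "LALGLE"), ("lhgl", "LAHGLE"),
)


def glrlm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """16 run-length features, per-direction values averaged over 13 offsets."""
    L = _cropped_levels(qroi)
    ng = qroi.n_levels
    n_voxels = int((L > 0).sum())
    if n_voxels < 2:
        raise ValueError("run-length features need at least 2 included voxels")
    acc = {k: 0.0 for k in GLRLM_KEYS}
    for d in OFFSETS_13:
        P = _glrlm_matrix(L, d, ng)
        for k, v in _run_zone_features(P, "glrlm", _GLRLM_SLOTS, n_voxels).items():
            acc[k] += v
    return {k: v / len(OFFSETS_13) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """16 size-zone features from the single rotation-invariant zone matrix."""
    L = _cropped_levels(qroi)
    ng = qroi.n_levels
    n_voxels = int((L > 0).sum())
    if n_voxels < 2:
        raise ValueError("size-zone features need at least 2 included voxels")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connected zones
    zones: list[tuple[int, int]] = []
    for g in np.unique(L[L > 0]):
        labeled, n_zones = ndimage.label(L == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        P[g - 1, s - 1] += 1.0
    return _run_zone_features(P, "glszm", _GLSZM_SLOTS, n_voxels)


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """14 dependence features; dependence size = matching 26-neighbors + 1."""
    L = _cropped_levels(qroi)
    ng = qroi.n_levels
    included = L > 0
    n_voxels = int(included.sum())
    if n_voxels < 2:
        raise ValueError("dependence features need at least 2 included voxels")
    dep = np.zeros(L.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        nbr = _shift(L, d)
        dep += (included & (nbr == L)).astype(np.int64)
    sizes = dep[included] + 1  # center voxel counts itself
    levels = L[included]
    max_size = int(sizes.max())
    counts = np.bincount(
        (levels - 1) * max_size + (sizes - 1), minlength=ng * max_size
    )
    P = counts.reshape(ng, max_size).astype(np.float64)

    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_size + 1, dtype=np.float64)[None, :]
    n = P.sum()
    p = P / n
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "gldm_SDE": float((P / j**2).sum() / n),
        "gldm_LDE": float((P * j**2).sum() / n),
        "gldm_GLN": float((pg**2).sum() / n),
        "gldm_DN": float((pd_**2).sum() / n),
        "gldm_DNN": float((pd_**2).sum() / n**2),
        "gldm_GLV": float((p * (i - mu_i) ** 2).sum()),
        "gldm_DV": float((p * (j - mu_j) ** 2).sum()),
        "gldm_DE": _entropy(p.ravel()),
        "gldm_LGLE": float((P / i**2).sum() / n),
        "gldm_HGLE": float((P * i**2).sum() / n),
        "gldm_SDLGLE": float((P / (i**2 * j**2)).sum() / n),
        "gldm_SDHGLE": float((P * i**2 / j**2).sum() / n),
        "gldm_LDLGLE": float((P * j**2 / i**2).sum() / n),
        "gldm_LDHGLE": float((P * i**2 * j**2).sum() / n),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """5 neighboring gray-tone difference features (3x3x3 neighborhood)."""
    L = _cropped_levels(qroi)
    ng = qroi.n_levels
    included = L > 0
    if included.sum() < 2:
        raise ValueError("NGTDM features need at least 2 included voxels")

    nbr_sum = np.zeros(L.shape, dtype=np.float64)
    nbr_cnt = np.zeros(L.shape, dtype=np.float64)
    for d in _OFFSETS_26:
        nbr = _shift(L, d)
        nbr_sum += nbr
        nbr_cnt += nbr > 0
    valid = included & (nbr_cnt > 0)
    if not valid.any():
        raise ValueError("no ROI voxel has an in-ROI neighbor")

    levels = L[valid].astype(np.float64)
    a_mean = nbr_sum[valid] / nbr_cnt[valid]
    absdiff = np.abs(levels - a_mean)

    n_i = np.bincount(L[valid] - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(L[valid] - 1, weights=absdiff, minlength=ng)
    n_tot = n_i.sum()
    p_i = n_i / n_tot
    occupied = p_i > 0
    n_gp = int(occupied.sum())
    lv = np.arange(1, ng + 1, dtype=np.float64)

    coarse_denom = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6

    if n_gp > 1:
        io = lv[occupied][:, None]
        jo = lv[occupied][None, :]
        pio = p_i[occupied][:, None]
        pjo = p_i[occupied][None, :]
        sio = s_i[occupied][:, None]
        sjo = s_i[occupied][None, :]
        contrast = float(
            (pio * pjo * (io - jo) ** 2).sum() / (n_gp * (n_gp - 1)) * s_i.sum() / n_tot
        )
        busy_denom = float(np.abs(io * pio - jo * pjo).sum())
        busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0
        complexity = float(
            (np.abs(io - jo) * (pio * sio + pjo * sjo) / (pio + pjo)).sum() / n_tot
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pio + pjo) * (io - jo) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }
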