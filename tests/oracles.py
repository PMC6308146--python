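"""Independent brute-force oracles for the test suite.

Everything here is written loop-style, straight from the defining formulas,
sharing no code with the package implementation. The texture oracles
enumerate voxel pairs / walk runs / flood-fill zones explicitly.
Level grids use 0 for voxels outside the ROI.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= pi < ni for pi, ni in zip(p, shape))


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix_oracle(levels, d, ng):
    shape = levels.shape
    C = np.zeros((ng, ng))
    for p in np.argwhere(levels > 0):
        q = tuple(p + d)
        if _inside(shape, q) and levels[q] > 0:
            i, j = levels[tuple(p)] - 1, levels[q] - 1
            C[i, j] += 1
            C[j, i] += 1
    total = C.sum()
    if total == 0:
        return None
    return C / total


def _glcm_dir_oracle(P, ng):
    cells = [(i, j, P[i, j]) for i in range(ng) for j in range(ng) if P[i, j] > 0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum(px[i] * (i + 1 - mu) ** 2 for i in range(ng))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng + 1)
    for i, j, v in cells:
        p_diff[abs(i - j)] += v
        p_sum[i + j + 2] += v
    da = sum(k * p_diff[k] for k in range(ng))

    ac = sum(v * (i + 1) * (j + 1) for i, j, v in cells)
    hxy = -sum(v * _log2(v) for _, _, v in cells)
    hx = -sum(q * _log2(q) for q in px if q > 0)
    hxy1 = -sum(v * _log2(px[i] * px[j]) for i, j, v in cells)
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0
    )
    out = {
        "glcm_AC": ac,
        "glcm_CP": sum(v * (i + j + 2 - 2 * mu) ** 4 for i, j, v in cells),
        "glcm_CS": sum(v * (i + j + 2 - 2 * mu) ** 3 for i, j, v in cells),
        "glcm_CT": sum(v * (i + j + 2 - 2 * mu) ** 2 for i, j, v in cells),
        "glcm_Contrast": sum(v * (i - j) ** 2 for i, j, v in cells),
        "glcm_Correlation": (ac - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "glcm_DA": da,
        "glcm_DE": -sum(q * _log2(q) for q in p_diff if q > 0),
        "glcm_DV": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "glcm_JA": mu,
        "glcm_JE": sum(v * v for _, _, v in cells),
        "glcm_JEN": hxy,
        "glcm_IMC": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_IMC2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "glcm_IDM": sum(v / (1.0 + (i - j) ** 2) for i, j, v in cells),
        "glcm_IDMN": sum(v / (1.0 + ((i - j) / ng) ** 2) for i, j, v in cells),
        "glcm_ID": sum(v / (1.0 + abs(i - j)) for i, j, v in cells),
        "glcm_IDN": sum(v / (1.0 + abs(i - j) / ng) for i, j, v in cells),
        "glcm_IV": sum(v / (i - j) ** 2 for i, j, v in cells if i != j),
        "glcm_MP": max(v for _, _, v in cells),
        "glcm_SA": sum((i + j + 2) * v for i, j, v in cells),
        "glcm_SEN": -sum(q * _log2(q) for q in p_sum if q > 0),
        "glcm_SS": sum(v * (i + 1 - mu) ** 2 for i, j, v in cells),
    }
    return out


def oracle_glcm(levels, ng=64):
    acc = None
    n = 0
    for d in OFFSETS_13:
        P = _glcm_matrix_oracle(levels, d, ng)
        if P is None:
            continue
        f = _glcm_dir_oracle(P, ng)
        if acc is None:
            acc = {k: 0.0 for k in f}
        for k, v in f.items():
            acc[k] += v
        n += 1
    return {k: v / n for k, v in acc.items()}


# ---------------------------------------------------------------------------
# shared run/zone/dependence formulas (loop style)


def _rz_features(counts, prefix, slots, n_voxels):
    """counts: dict (level, size) -> count, level/size 1-based."""
    n = sum(counts.values())
    items = [(i, j, c) for (i, j), c in counts.items() if c > 0]
    pg = {}
    ps = {}
    for i, j, c in items:
        pg[i] = pg.get(i, 0.0) + c
        ps[j] = ps.get(j, 0.0) + c
    mu_i = sum(i * c for i, j, c in items) / n
    mu_j = sum(j * c for i, j, c in items) / n
    vals = {
        "small": sum(c / j**2 for i, j, c in items) / n,
        "large": sum(c * j**2 for i, j, c in items) / n,
        "gln": sum(v**2 for v in pg.values()) / n,
        "glnn": sum(v**2 for v in pg.values()) / n**2,
        "sn": sum(v**2 for v in ps.values()) / n,
        "snn": sum(v**2 for v in ps.values()) / n**2,
        "perc": n / n_voxels,
        "glv": sum(c / n * (i - mu_i) ** 2 for i, j, c in items),
        "sv": sum(c / n * (j - mu_j) ** 2 for i, j, c in items),
        "ent": -sum(c / n * _log2(c / n) for _, _, c in items),
        "lgl": sum(c / i**2 for i, j, c in items) / n,
        "hgl": sum(c * i**2 for i, j, c in items) / n,
        "slgl": sum(c / (i**2 * j**2) for i, j, c in items) / n,
        "shgl": sum(c * i**2 / j**2 for i, j, c in items) / n,
        "llgl": sum(c * j**2 / i**2 for i, j, c in items) / n,
        "lhgl": sum(c * i**2 * j**2 for i, j, c in items) / n,
    }
    return {f"{prefix}_{name}": vals[slot] for slot, name in slots}


GLRLM_SLOTS = [
    ("small", "SRE"), ("large", "LRE"), ("gln", "GLN"), ("glnn", "GLNN"),
    ("sn", "RLN"), ("snn", "RLNN"), ("perc", "RP"), ("glv", "GLV"),
    ("sv", "RV"), ("ent", "RE"), ("lgl", "LGLRE"), ("hgl", "HGLRE"),
    ("slgl", "SRLGLE"), ("shgl", "SRHGLE"), ("llgl", "LRLGLE"), ("lhgl", "LRHGLE"),
]
GLSZM_SLOTS = [
    ("small", "SAE"), ("large", "LAE"), ("gln", "GLN"), ("glnn", "GLNN"),
    ("sn", "SZN"), ("snn", "SZNN"), ("perc", "ZP"), ("glv", "GLV"),
    ("sv", "ZV"), ("ent", "ZE"), ("lgl", "LGLZE"), ("hgl", "HGLZE"),
    ("slgl", "SALGLE"), ("shgl", "SAHGLE"), ("llgl", "LALGLE"), ("lhgl", "LAHGLE"),
]
GLDM_SLOTS = [
    ("small", "SDE"), ("large", "LDE"), ("gln", "GLN"), ("sn", "DN"),
    ("snn", "DNN"), ("glv", "GLV"), ("sv", "DV"), ("ent", "DE"),
    ("lgl", "LGLE"), ("hgl", "HGLE"),
    ("slgl", "SDLGLE"), ("shgl", "SDHGLE"), ("llgl", "LDLGLE"), ("lhgl", "LDHGLE"),
]


# ---------------------------------------------------------------------------
# GLRLM: explicit run walking


def oracle_glrlm(levels, ng=64):
    shape = levels.shape
    n_voxels = int((levels > 0).sum())
    acc = None
    for d in OFFSETS_13:
        counts: dict[tuple[int, int], int] = {}
        for p in np.argwhere(levels > 0):
            prev = tuple(p - d)
            if _inside(shape, prev) and levels[prev] == levels[tuple(p)]:
                continue  # not a run start
            g = int(levels[tuple(p)])
            length = 1
            q = p + d
            while _inside(shape, tuple(q)) and levels[tuple(q)] == g:
                length += 1
                q = q + d
            counts[(g, length)] = counts.get((g, length), 0) + 1
        f = _rz_features(counts, "glrlm", GLRLM_SLOTS, n_voxels)
        if acc is None:
            acc = {k: 0.0 for k in f}
        for k, v in f.items():
            acc[k] += v
    return {k: v / len(OFFSETS_13) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM: explicit flood fill


def oracle_glszm(levels, ng=64):
    shape = levels.shape
    n_voxels = int((levels > 0).sum())
    visited = np.zeros(shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for p0 in map(tuple, np.argwhere(levels > 0)):
        if visited[p0]:
            continue
        g = int(levels[p0])
        stack = [p0]
        visited[p0] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(np.add(p, d))
                if _inside(shape, q) and not visited[q] and levels[q] == g:
                    visited[q] = True
                    stack.append(q)
        counts[(g, size)] = counts.get((g, size), 0) + 1
    return _rz_features(counts, "glszm", GLSZM_SLOTS, n_voxels)


# ---------------------------------------------------------------------------
# GLDM


def oracle_gldm(levels, ng=64):
    shape = levels.shape
    n_voxels = int((levels > 0).sum())
    counts: dict[tuple[int, int], int] = {}
    for p in map(tuple, np.argwhere(levels > 0)):
        g = int(levels[p])
        dep = 0
        for d in OFFSETS_26:
            q = tuple(np.add(p, d))
            if _inside(shape, q) and levels[q] == g:
                dep += 1
        key = (g, dep + 1)  # dependence size includes the center voxel
        counts[key] = counts.get(key, 0) + 1
    return _rz_features(counts, "gldm", GLDM_SLOTS, n_voxels)


# ---------------------------------------------------------------------------
# NGTDM


def oracle_ngtdm(levels, ng=64):
    shape = levels.shape
    n_i = [0.0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    for p in map(tuple, np.argwhere(levels > 0)):
        g = int(levels[p])
        nbr = []
        for d in OFFSETS_26:
            q = tuple(np.add(p, d))
            if _inside(shape, q) and levels[q] > 0:
                nbr.append(int(levels[q]))
        if not nbr:
            continue
        n_i[g] += 1
        s_i[g] += abs(g - sum(nbr) / len(nbr))
    n_tot = sum(n_i)
    p_i = [v / n_tot for v in n_i]
    occ = [g for g in range(1, ng + 1) if n_i[g] > 0]
    ngp = len(occ)

    denom = sum(p_i[g] * s_i[g] for g in occ)
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p_i[a] * p_i[b] * (a - b) ** 2 for a in occ for b in occ)
            / (ngp * (ngp - 1))
            * sum(s_i[g] for g in occ)
            / n_tot
        )
        busy_den = sum(abs(a * p_i[a] - b * p_i[b]) for a in occ for b in occ)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
                for a in occ
                for b in occ
            )
            / n_tot
        )
        s_sum = sum(s_i[g] for g in occ)
        strength = (
            sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in occ for b in occ) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------
# first-order (histogram statistics computed directly)


def oracle_first_order(raw_values, level_histogram):
    x = sorted(float(v) for v in raw_values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    total = sum(level_histogram)
    probs = [c / total for c in level_histogram if c > 0]
    p10 = float(np.percentile(x, 10))
    p90 = float(np.percentile(x, 90))
    mid = [v for v in x if p10 <= v <= p90]
    mid_mean = sum(mid) / len(mid)
    out = {
        "F_Energy": sum(v * v for v in x),
        "F_Entropy": -sum(p * _log2(p) for p in probs),
        "F_Min": x[0],
        "F_P10": p10,
        "F_P90": p90,
        "F_Max": x[-1],
        "F_Mean": mean,
        "F_Median": float(np.median(x)),
        "F_IQR": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "F_Range": x[-1] - x[0],
        "F_MAD": sum(abs(v - mean) for v in x) / n,
        "F_rMAD": sum(abs(v - mid_mean) for v in mid) / len(mid),
        "F_RMS": math.sqrt(sum(v * v for v in x) / n),
        "F_Skew": sum((v - mean) ** 3 for v in x) / n / sd**3 if sd > 0 else 0.0,
        "F_Kurt": sum((v - mean) ** 4 for v in x) / n / sd**4 if sd > 0 else 0.0,
        "F_Variance": var,
        "F_Uniformity": sum(p * p for p in probs),
        "F_SD": sd,
    }
    return out


ORACLES = {
    "glcm": oracle_glcm,
    "glrlm": oracle_glrlm,
    "glszm": oracle_glszm,
    "gldm": oracle_gldm,
    "ngtdm": oracle_ngtdm,
}


# ---------------------------------------------------------------------------
# misc small oracles


def oracle_dice(a, b):
    inter = int((a & b).sum())
    return 2.0 * inter / (int(a.sum()) + int(b.sum()))


def oracle_auc_pairs(pos, neg):
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_bh(p_values):
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def oracle_icc_anova(data):
    """Spreadsheet-style ICC(A,1) from two-way ANOVA mean squares."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def oracle_greedy_prune(df, threshold=0.80):
    """Independent re-implementation of the pairwise-correlation pruning rule."""
    keys = [k for k in df.columns if df[k].std() > 0]
    while len(keys) >= 2:
        corr = df[keys].corr().abs()
        best = None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                r = corr.iloc[a, b]
                if best is None or r > best[0]:
                    best = (r, keys[a], keys[b])
        r, ka, kb = best
        if r < threshold:
            break
        mean_a = (corr[ka].sum() - 1.0) / (len(keys) - 1)
        mean_b = (corr[kb].sum() - 1.0) / (len(keys) - 1)
        if mean_a > mean_b:
            keys.remove(ka)
        elif mean_b > mean_a:
            keys.remove(kb)
        else:
            keys.remove(max(ka, kb))
    return keys


def oracle_autocorr_length(values, mask, spacing):
    """ROI-restricted empirical autocorrelation length via direct FFT autocorrelation.

    Returns the distance (mm) at which the radially-averaged normalized
    autocorrelation of the masked, demeaned field first drops below 1/e.
    """
    x = np.where(mask, values - values[mask].mean(), 0.0)
    w = mask.astype(float)
    n = np.asarray(x.shape)
    pad = [(0, s) for s in x.shape]
    axes = (0, 1, 2)
    xf = np.fft.rfftn(np.pad(x, pad), axes=axes)
    wf = np.fft.rfftn(np.pad(w, pad), axes=axes)
    num = np.fft.irfftn(xf * np.conj(xf), s=tuple(2 * n), axes=axes)
    den = np.fft.irfftn(wf * np.conj(wf), s=tuple(2 * n), axes=axes)
    lags = []
    for shift in range(0, min(x.shape) // 2):
        pts = []
        for axis in range(3):
            idx = [0, 0, 0]
            idx[axis] = shift
            if den[tuple(idx)] > 10:
                pts.append((num[tuple(idx)] / den[tuple(idx)], shift * spacing[axis]))
        lags.extend(pts)
    lags.sort(key=lambda t: t[1])
    c0 = lags[0][0]
    for c, dist in lags[1:]:
        if c / c0 < math.exp(-1):
            return dist
    return lags[-1][1]
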