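"""Second-order texture features from explicit gray-level matrices.

All families operate on a discretized gray-level array (levels >= 1 inside
the region, arbitrary outside) plus a boolean mask.  Neighborhoods are
3-D, 26-connected; GLCM and GLRLM use the 13 unique direction offsets at
Chebyshev distance 1 and *merge* counts over directions into a single
matrix before computing features (co-occurrences symmetrized).  Feature
formulas follow the IBSI definitions, with gray-level terms using the
actual discretized level values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: 13 unique 3-D direction offsets (the lexicographically positive half of
#: the 26-neighborhood)
UNIQUE_OFFSETS_3D: list[tuple[int, int, int]] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and (dy, dz) > (0, 0)) or (dx == 0 and dy == 0 and dz > 0)
]

TEXTURE_FAMILY_SIZES = {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}


def _offset_slices(shape, off):
    """Pairs of slices (src, dst) such that dst = src + off, both in bounds."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _present_levels(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not np.any(mask):
        raise ValueError("empty ROI")
    return np.unique(levels[mask])


# ----------------------------------------------------------------- GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray):
    """Symmetric co-occurrence counts merged over the 13 offsets.

    Returns ``(gray_values, counts)`` where counts[a, b] is the number of
    ordered in-mask voxel pairs at Chebyshev distance 1 with levels
    (gray_values[a], gray_values[b]); each unordered pair contributes to
    both orders.
    """
    gv = _present_levels(levels, mask)
    lut = np.zeros(int(gv.max()) + 1, dtype=np.int64)
    lut[gv] = np.arange(len(gv))
    C = np.zeros((len(gv), len(gv)), dtype=np.float64)
    for off in UNIQUE_OFFSETS_3D:
        s, d = _offset_slices(levels.shape, off)
        ok = mask[s] & mask[d]
        a = lut[levels[s][ok]]
        b = lut[levels[d][ok]]
        np.add.at(C, (a, b), 1.0)
    return gv, C + C.T


def glcm_features(gv: np.ndarray, C: np.ndarray) -> dict[str, float]:
    eps = np.finfo(float).eps
    total = C.sum()
    if total == 0:
        # single isolated voxel: no pairs — all features degenerate to 0/1
        P = np.zeros_like(C)
    else:
        P = C / total
    i = gv.astype(float)[:, None]
    j = gv.astype(float)[None, :]
    Ng = len(gv)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(px * gv))
    mu_y = float(np.sum(py * gv))
    sig_x = float(np.sqrt(np.sum(px * (gv - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (gv - mu_y) ** 2)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    diffs = np.abs(gv[:, None] - gv[None, :])
    sums = gv[:, None] + gv[None, :]
    kd = np.unique(diffs)
    p_dm = np.array([P[diffs == k].sum() for k in kd])
    ks = np.unique(sums)
    p_sm = np.array([P[sums == k].sum() for k in ks])

    out: dict[str, float] = {}
    out["Autocorrelation"] = float(np.sum(P * i * j))
    out["JointAverage"] = mu_x
    ipj = i + j - mu_x - mu_y
    out["ClusterProminence"] = float(np.sum(P * ipj**4))
    out["ClusterShade"] = float(np.sum(P * ipj**3))
    out["ClusterTendency"] = float(np.sum(P * ipj**2))
    out["Contrast"] = float(np.sum(P * (i - j) ** 2))
    if sig_x * sig_y > eps:
        out["Correlation"] = float(
            (np.sum(P * i * j) - mu_x * mu_y) / (sig_x * sig_y)
        )
    else:
        out["Correlation"] = 1.0
    da = float(np.sum(p_dm * kd))
    out["DifferenceAverage"] = da
    nz = p_dm > 0
    out["DifferenceEntropy"] = float(-np.sum(p_dm[nz] * np.log2(p_dm[nz])))
    out["DifferenceVariance"] = float(np.sum(p_dm * (kd - da) ** 2))
    out["JointEnergy"] = float(np.sum(P**2))
    nzP = P > 0
    hxy = float(-np.sum(P[nzP] * np.log2(P[nzP])))
    out["JointEntropy"] = hxy

    pxpy = px[:, None] * py[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.sum(P[nzP] * np.log2(pxpy[nzP] + eps)))
        nz2 = pxpy > 0
        hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    div = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / div) if div > eps else 0.0
    arg = -2.0 * (hxy2 - hxy)
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(arg)))) if hxy2 >= hxy else 0.0

    out["Idm"] = float(np.sum(P / (1.0 + (i - j) ** 2)))
    out["Idmn"] = float(np.sum(P / (1.0 + ((i - j) / Ng) ** 2)))
    out["Id"] = float(np.sum(P / (1.0 + np.abs(i - j))))
    out["Idn"] = float(np.sum(P / (1.0 + np.abs(i - j) / Ng)))
    offdiag = np.abs(i - j) > 0
    with np.errstate(divide="ignore"):
        iv = np.where(offdiag, P / np.where(offdiag, (i - j) ** 2, 1.0), 0.0)
    out["InverseVariance"] = float(iv.sum())
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float(np.sum(p_sm * ks))
    nzs = p_sm > 0
    out["SumEntropy"] = float(-np.sum(p_sm[nzs] * np.log2(p_sm[nzs])))
    out["SumSquares"] = float(np.sum(P * (i - mu_x) ** 2))

    # MCC: second largest eigenvalue magnitude of Q
    if Ng > 1 and total > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = px[:, None] * py[None, :]
            Q = np.zeros_like(P)
            valid = denom > 0
            # Q[a,b] = sum_k P[a,k] P[b,k] / (px[a] py[k])
            pk = np.where(py > 0, py, 1.0)
            Q = (P / np.where(px[:, None] > 0, px[:, None], 1.0)) @ (P / pk[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        out["MCC"] = float(np.sqrt(max(0.0, ev[-2].real)))
    else:
        out["MCC"] = 1.0
    return out


# ---------------------------------------------------------------- GLRLM


def _shift2d(arr: np.ndarray, s0: int, s1: int) -> np.ndarray:
    """Shift a 2-D array so out[p] = arr[p + (s0, s1)], zero fill."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for n, s in zip(arr.shape, (s0, s1)):
        if s >= 0:
            src.append(slice(s, n))
            dst.append(slice(0, n - s))
        else:
            src.append(slice(0, n + s))
            dst.append(slice(-s, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift3d(arr: np.ndarray, off) -> np.ndarray:
    """out[v] = arr[v - off] (push array content along +off), zero fill."""
    out = np.zeros_like(arr)
    src, dst = _offset_slices(arr.shape, off)
    out[dst] = arr[src]
    return out


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray):
    """Run-length counts merged over the 13 directions.

    Returns ``(gray_values, run_lengths, counts)`` with counts[a, l-1] the
    number of maximal runs of gray_values[a] of length l over all
    directions.
    """
    gv = _present_levels(levels, mask)
    lut = np.zeros(int(gv.max()) + 1, dtype=np.int64)
    lut[gv] = np.arange(len(gv))
    L = np.where(mask, levels, -1)
    maxlen = int(np.ceil(np.linalg.norm(levels.shape)))
    M = np.zeros((len(gv), maxlen), dtype=np.float64)

    for off in UNIQUE_OFFSETS_3D:
        # same[v] <=> v and v+off both in mask with equal level
        same = np.zeros(levels.shape, dtype=bool)
        s, d = _offset_slices(levels.shape, off)
        same[s] = (L[s] == L[d]) & mask[s] & mask[d]

        # run_len[v] = length of the run starting at v along +off
        run_len = np.zeros(levels.shape, dtype=np.int64)
        axis = next(a for a in range(3) if off[a] != 0)
        step = off[axis]
        other = [a for a in range(3) if a != axis]
        o0, o1 = off[other[0]], off[other[1]]
        n_ax = levels.shape[axis]
        order = range(n_ax - 1, -1, -1) if step > 0 else range(n_ax)
        for a in order:
            idx = [slice(None)] * 3
            idx[axis] = a
            nxt_a = a + step
            if 0 <= nxt_a < n_ax:
                idx_n = [slice(None)] * 3
                idx_n[axis] = nxt_a
                nxt = _shift2d(run_len[tuple(idx_n)], o0, o1)
            else:
                nxt = 0
            sl = tuple(idx)
            run_len[sl] = np.where(
                same[sl], 1 + nxt, np.where(mask[sl], 1, 0)
            )

        # starts: in-mask voxels whose predecessor along -off is not same
        pred_same = _shift3d(same, off)
        starts = mask & ~pred_same
        lens = run_len[starts]
        grays = lut[levels[starts]]
        np.add.at(M, (grays, lens - 1), 1.0)

    used = np.nonzero(M.sum(axis=0))[0]
    last = used[-1] + 1 if len(used) else 1
    return gv, np.arange(1, last + 1), M[:, :last]


def glrlm_features(gv, lengths, M, n_voxels: int) -> dict[str, float]:
    Nr = M.sum()
    if Nr == 0:
        raise ValueError("no runs")
    i = gv.astype(float)[:, None]
    j = lengths.astype(float)[None, :]
    P = M / Nr
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    mu_i = float(np.sum(pg * gv))
    mu_j = float(np.sum(pr * lengths))
    out = {}
    out["ShortRunEmphasis"] = float(np.sum(M / j**2) / Nr)
    out["LongRunEmphasis"] = float(np.sum(M * j**2) / Nr)
    out["GrayLevelNonUniformity"] = float(np.sum(M.sum(axis=1) ** 2) / Nr)
    out["GrayLevelNonUniformityNormalized"] = float(
        np.sum(M.sum(axis=1) ** 2) / Nr**2
    )
    out["RunLengthNonUniformity"] = float(np.sum(M.sum(axis=0) ** 2) / Nr)
    out["RunLengthNonUniformityNormalized"] = float(
        np.sum(M.sum(axis=0) ** 2) / Nr**2
    )
    out["RunPercentage"] = float(Nr / (n_voxels * len(UNIQUE_OFFSETS_3D)))
    out["GrayLevelVariance"] = float(np.sum(pg * (gv - mu_i) ** 2))
    out["RunVariance"] = float(np.sum(pr * (lengths - mu_j) ** 2))
    nz = P > 0
    out["RunEntropy"] = float(-np.sum(P[nz] * np.log2(P[nz])))
    out["LowGrayLevelRunEmphasis"] = float(np.sum(M / i**2) / Nr)
    out["HighGrayLevelRunEmphasis"] = float(np.sum(M * i**2) / Nr)
    out["ShortRunLowGrayLevelEmphasis"] = float(np.sum(M / (i**2 * j**2)) / Nr)
    out["ShortRunHighGrayLevelEmphasis"] = float(np.sum(M * i**2 / j**2) / Nr)
    out["LongRunLowGrayLevelEmphasis"] = float(np.sum(M * j**2 / i**2) / Nr)
    out["LongRunHighGrayLevelEmphasis"] = float(np.sum(M * i**2 * j**2) / Nr)
    return out


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(levels: np.ndarray, mask: np.ndarray):
    """Zone counts: 26-connected components of constant gray level."""
    gv = _present_levels(levels, mask)
    zones: dict[int, list[int]] = {}
    max_size = 1
    for g in gv:
        lab, n = ndimage.label((levels == g) & mask, structure=STRUCT_26)
        if n == 0:
            zones[int(g)] = []
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones[int(g)] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    M = np.zeros((len(gv), max_size), dtype=np.float64)
    for a, g in enumerate(gv):
        for s in zones[int(g)]:
            M[a, s - 1] += 1.0
    return gv, np.arange(1, max_size + 1), M


def glszm_features(gv, sizes, M, n_voxels: int) -> dict[str, float]:
    Nz = M.sum()
    if Nz == 0:
        raise ValueError("no zones")
    i = gv.astype(float)[:, None]
    s = sizes.astype(float)[None, :]
    P = M / Nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float(np.sum(pg * gv))
    mu_s = float(np.sum(ps * sizes))
    out = {}
    out["SmallAreaEmphasis"] = float(np.sum(M / s**2) / Nz)
    out["LargeAreaEmphasis"] = float(np.sum(M * s**2) / Nz)
    out["GrayLevelNonUniformity"] = float(np.sum(M.sum(axis=1) ** 2) / Nz)
    out["GrayLevelNonUniformityNormalized"] = float(
        np.sum(M.sum(axis=1) ** 2) / Nz**2
    )
    out["SizeZoneNonUniformity"] = float(np.sum(M.sum(axis=0) ** 2) / Nz)
    out["SizeZoneNonUniformityNormalized"] = float(
        np.sum(M.sum(axis=0) ** 2) / Nz**2
    )
    out["ZonePercentage"] = float(Nz / n_voxels)
    out["GrayLevelVariance"] = float(np.sum(pg * (gv - mu_i) ** 2))
    out["ZoneVariance"] = float(np.sum(ps * (sizes - mu_s) ** 2))
    nz = P > 0
    out["ZoneEntropy"] = float(-np.sum(P[nz] * np.log2(P[nz])))
    out["LowGrayLevelZoneEmphasis"] = float(np.sum(M / i**2) / Nz)
    out["HighGrayLevelZoneEmphasis"] = float(np.sum(M * i**2) / Nz)
    out["SmallAreaLowGrayLevelEmphasis"] = float(np.sum(M / (i**2 * s**2)) / Nz)
    out["SmallAreaHighGrayLevelEmphasis"] = float(np.sum(M * i**2 / s**2) / Nz)
    out["LargeAreaLowGrayLevelEmphasis"] = float(np.sum(M * s**2 / i**2) / Nz)
    out["LargeAreaHighGrayLevelEmphasis"] = float(np.sum(M * i**2 * s**2) / Nz)
    return out


# ----------------------------------------------------------------- GLDM


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0):
    """Dependence counts: P[a, j-1] = voxels of level gv[a] with j-1
    dependent 26-neighbors (|level difference| <= alpha); the center voxel
    itself counts as dependence 1."""
    gv = _present_levels(levels, mask)
    lut = np.zeros(int(gv.max()) + 1, dtype=np.int64)
    lut[gv] = np.arange(len(gv))
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in UNIQUE_OFFSETS_3D:
        s, d = _offset_slices(levels.shape, off)
        ok = mask[s] & mask[d] & (np.abs(levels[s] - levels[d]) <= alpha)
        inc_s = np.zeros(levels.shape, dtype=np.int64)
        inc_s[s] = ok
        inc_d = np.zeros(levels.shape, dtype=np.int64)
        inc_d[d] = ok
        dep += inc_s + inc_d
    j = dep[mask] + 1
    M = np.zeros((len(gv), 27), dtype=np.float64)
    np.add.at(M, (lut[levels[mask]], j - 1), 1.0)
    used = np.nonzero(M.sum(axis=0))[0]
    last = used[-1] + 1
    return gv, np.arange(1, last + 1), M[:, :last]


def gldm_features(gv, deps, M) -> dict[str, float]:
    Nz = M.sum()
    i = gv.astype(float)[:, None]
    j = deps.astype(float)[None, :]
    P = M / Nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_i = float(np.sum(pg * gv))
    mu_j = float(np.sum(pd * deps))
    out = {}
    out["SmallDependenceEmphasis"] = float(np.sum(M / j**2) / Nz)
    out["LargeDependenceEmphasis"] = float(np.sum(M * j**2) / Nz)
    out["GrayLevelNonUniformity"] = float(np.sum(M.sum(axis=1) ** 2) / Nz)
    out["DependenceNonUniformity"] = float(np.sum(M.sum(axis=0) ** 2) / Nz)
    out["DependenceNonUniformityNormalized"] = float(
        np.sum(M.sum(axis=0) ** 2) / Nz**2
    )
    out["GrayLevelVariance"] = float(np.sum(pg * (gv - mu_i) ** 2))
    out["DependenceVariance"] = float(np.sum(pd * (deps - mu_j) ** 2))
    nz = P > 0
    out["DependenceEntropy"] = float(-np.sum(P[nz] * np.log2(P[nz])))
    out["LowGrayLevelEmphasis"] = float(np.sum(M / i**2) / Nz)
    out["HighGrayLevelEmphasis"] = float(np.sum(M * i**2) / Nz)
    out["SmallDependenceLowGrayLevelEmphasis"] = float(
        np.sum(M / (i**2 * j**2)) / Nz
    )
    out["SmallDependenceHighGrayLevelEmphasis"] = float(
        np.sum(M * i**2 / j**2) / Nz
    )
    out["LargeDependenceLowGrayLevelEmphasis"] = float(
        np.sum(M * j**2 / i**2) / Nz
    )
    out["LargeDependenceHighGrayLevelEmphasis"] = float(
        np.sum(M * i**2 * j**2) / Nz
    )
    return out


# ---------------------------------------------------------------- NGTDM

COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray, mask: np.ndarray):
    """Per-level (n_i, p_i, s_i): counts, probabilities, and summed
    absolute differences from the 26-neighborhood average."""
    gv = _present_levels(levels, mask)
    Lm = np.where(mask, levels, 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.correlate(Lm, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(
        mask.astype(np.float64), kernel, mode="constant", cval=0.0
    )
    valid = mask & (nbr_cnt > 0)
    A = np.zeros(levels.shape)
    A[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(levels - A)
    Nvp = int(valid.sum())
    n = np.array([(valid & (levels == g)).sum() for g in gv], dtype=float)
    s = np.array([diff[valid & (levels == g)].sum() for g in gv], dtype=float)
    p = n / Nvp
    return gv, n, p, s, Nvp


def ngtdm_features(gv, n, p, s, Nvp) -> dict[str, float]:
    out = {}
    gvf = gv.astype(float)
    denom = float(np.sum(p * s))
    out["Coarseness"] = float(1.0 / denom) if denom > 0 else COARSENESS_CAP
    Ngp = int((p > 0).sum())
    ii = gvf[:, None]
    jj = gvf[None, :]
    pi = p[:, None]
    pj = p[None, :]
    if Ngp > 1:
        term1 = np.sum(pi * pj * (ii - jj) ** 2) / (Ngp * (Ngp - 1))
        term2 = s.sum() / Nvp
        out["Contrast"] = float(term1 * term2)
    else:
        out["Contrast"] = 0.0
    absdiff = np.abs(ii * pi - jj * pj)
    both = (pi > 0) & (pj > 0)
    denom_b = float(absdiff[both].sum())
    out["Busyness"] = float(denom / denom_b) if denom_b > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cplx = np.where(
            both,
            np.abs(ii - jj) * (pi * s[:, None] + pj * s[None, :]) / (pi + pj),
            0.0,
        )
    out["Complexity"] = float(cplx.sum() / Nvp)
    s_sum = float(s.sum())
    if s_sum > 0:
        strength = np.where(both, (pi + pj) * (ii - jj) ** 2, 0.0).sum()
        out["Strength"] = float(strength / s_sum)
    else:
        out["Strength"] = 0.0
    return out


# ------------------------------------------------------------- together


def texture_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 75 texture features, keys ``<family>_<Name>``."""
    if not np.any(mask):
        raise ValueError("empty ROI")
    n_vox = int(mask.sum())
    out: dict[str, float] = {}
    gv, C = glcm_matrix(levels, mask)
    for k, v in glcm_features(gv, C).items():
        out[f"glcm_{k}"] = v
    gv, ln, M = glrlm_matrix(levels, mask)
    for k, v in glrlm_features(gv, ln, M, n_vox).items():
        out[f"glrlm_{k}"] = v
    gv, sz, M = glszm_matrix(levels, mask)
    for k, v in glszm_features(gv, sz, M, n_vox).items():
        out[f"glszm_{k}"] = v
    gv, dp, M = gldm_matrix(levels, mask)
    for k, v in gldm_features(gv, dp, M).items():
        out[f"gldm_{k}"] = v
    for k, v in ngtdm_features(*ngtdm_table(levels, mask)).items():
        out[f"ngtdm_{k}"] = v
    assert len(out) == 75
    return out
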