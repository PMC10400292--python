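"""Feature-engine tests: hand-computed values and naive enumeration oracles.

The oracles below re-count pairs/runs/zones/dependences with plain Python
loops, independently of the vectorized implementation.
"""

import itertools

import numpy as np
import pytest

from radgen.features.firstorder import (
    FIRST_ORDER_NAMES,
    discretize,
    first_order_features,
)
from radgen.features.texture import (
    TEXTURE_FAMILY_SIZES,
    UNIQUE_OFFSETS_3D,
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
    texture_features,
)

# ------------------------------------------------------------ naive oracles


def naive_glcm(levels, mask):
    gv = sorted(set(levels[mask].tolist()))
    idx = {g: i for i, g in enumerate(gv)}
    C = np.zeros((len(gv), len(gv)))
    shape = levels.shape
    for p in itertools.product(*map(range, shape)):
        if not mask[p]:
            continue
        for off in UNIQUE_OFFSETS_3D:
            q = tuple(p[i] + off[i] for i in range(3))
            if all(0 <= q[i] < shape[i] for i in range(3)) and mask[q]:
                C[idx[levels[p]], idx[levels[q]]] += 1
                C[idx[levels[q]], idx[levels[p]]] += 1
    return np.array(gv), C


def naive_glrlm(levels, mask):
    gv = sorted(set(levels[mask].tolist()))
    idx = {g: i for i, g in enumerate(gv)}
    shape = levels.shape
    runs = {}
    for off in UNIQUE_OFFSETS_3D:
        for p in itertools.product(*map(range, shape)):
            if not mask[p]:
                continue
            prev = tuple(p[i] - off[i] for i in range(3))
            if (
                all(0 <= prev[i] < shape[i] for i in range(3))
                and mask[prev]
                and levels[prev] == levels[p]
            ):
                continue  # not a run start
            length = 1
            q = tuple(p[i] + off[i] for i in range(3))
            while (
                all(0 <= q[i] < shape[i] for i in range(3))
                and mask[q]
                and levels[q] == levels[p]
            ):
                length += 1
                q = tuple(q[i] + off[i] for i in range(3))
            runs[(levels[p], length)] = runs.get((levels[p], length), 0) + 1
    maxlen = max(l for _, l in runs)
    M = np.zeros((len(gv), maxlen))
    for (g, l), c in runs.items():
        M[idx[g], l - 1] = c
    return np.array(gv), np.arange(1, maxlen + 1), M


def _neighbors26(p, shape):
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        q = tuple(p[i] + d[i] for i in range(3))
        if all(0 <= q[i] < shape[i] for i in range(3)):
            yield q


def naive_glszm(levels, mask):
    gv = sorted(set(levels[mask].tolist()))
    idx = {g: i for i, g in enumerate(gv)}
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in itertools.product(*map(range, shape)):
        if not mask[p] or seen[p]:
            continue
        stack, size, g = [p], 0, levels[p]
        seen[p] = True
        while stack:
            q = stack.pop()
            size += 1
            for r in _neighbors26(q, shape):
                if mask[r] and not seen[r] and levels[r] == g:
                    seen[r] = True
                    stack.append(r)
        zones.append((g, size))
    maxsize = max(s for _, s in zones)
    M = np.zeros((len(gv), maxsize))
    for g, s in zones:
        M[idx[g], s - 1] += 1
    return np.array(gv), np.arange(1, maxsize + 1), M


def naive_gldm(levels, mask, alpha=0):
    gv = sorted(set(levels[mask].tolist()))
    idx = {g: i for i, g in enumerate(gv)}
    shape = levels.shape
    counts = {}
    for p in itertools.product(*map(range, shape)):
        if not mask[p]:
            continue
        dep = 1
        for q in _neighbors26(p, shape):
            if mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        counts[(levels[p], dep)] = counts.get((levels[p], dep), 0) + 1
    maxdep = max(d for _, d in counts)
    M = np.zeros((len(gv), maxdep))
    for (g, d), c in counts.items():
        M[idx[g], d - 1] = c
    return np.array(gv), np.arange(1, maxdep + 1), M


def naive_ngtdm(levels, mask):
    gv = sorted(set(levels[mask].tolist()))
    shape = levels.shape
    n = {g: 0 for g in gv}
    s = {g: 0.0 for g in gv}
    nvp = 0
    for p in itertools.product(*map(range, shape)):
        if not mask[p]:
            continue
        nbr = [levels[q] for q in _neighbors26(p, shape) if mask[q]]
        if not nbr:
            continue
        nvp += 1
        g = levels[p]
        n[g] += 1
        s[g] += abs(g - np.mean(nbr))
    return (
        np.array(gv),
        np.array([n[g] for g in gv], float),
        np.array([n[g] / nvp for g in gv]),
        np.array([s[g] for g in gv]),
        nvp,
    )


def _random_patches(n=6):
    rng = np.random.default_rng(12345)
    out = []
    for _ in range(n):
        shape = tuple(rng.integers(2, 5, size=2)) + (2,)
        levels = rng.integers(1, 4, size=shape).astype(np.int64)
        mask = rng.random(shape) < 0.8
        if mask.sum() < 2:
            mask[0, 0, 0] = mask[-1, -1, -1] = True
        out.append((levels, mask))
    return out


# --------------------------------------------------------- oracle equality


@pytest.mark.parametrize("patch_id", range(6))
def test_glcm_matrix_matches_pair_enumeration(patch_id):
    levels, mask = _random_patches()[patch_id]
    gv, C = glcm_matrix(levels, mask)
    gv_o, C_o = naive_glcm(levels, mask)
    assert np.array_equal(gv, gv_o)
    assert np.array_equal(C, C_o)


@pytest.mark.parametrize("patch_id", range(6))
def test_glrlm_matrix_matches_run_enumeration(patch_id):
    levels, mask = _random_patches()[patch_id]
    gv, ln, M = glrlm_matrix(levels, mask)
    gv_o, ln_o, M_o = naive_glrlm(levels, mask)
    assert np.array_equal(gv, gv_o)
    assert np.array_equal(M[:, : M_o.shape[1]], M_o)
    assert M[:, M_o.shape[1]:].sum() == 0


@pytest.mark.parametrize("patch_id", range(6))
def test_glszm_matrix_matches_zone_enumeration(patch_id):
    levels, mask = _random_patches()[patch_id]
    gv, sz, M = glszm_matrix(levels, mask)
    gv_o, sz_o, M_o = naive_glszm(levels, mask)
    assert np.array_equal(gv, gv_o)
    assert np.array_equal(M[:, : M_o.shape[1]], M_o)


@pytest.mark.parametrize("patch_id", range(6))
def test_gldm_matrix_matches_dependence_enumeration(patch_id):
    levels, mask = _random_patches()[patch_id]
    gv, dp, M = gldm_matrix(levels, mask)
    gv_o, dp_o, M_o = naive_gldm(levels, mask)
    assert np.array_equal(gv, gv_o)
    assert np.array_equal(M[:, : M_o.shape[1]], M_o)


@pytest.mark.parametrize("patch_id", range(6))
def test_ngtdm_table_matches_enumeration(patch_id):
    levels, mask = _random_patches()[patch_id]
    gv, n, p, s, nvp = ngtdm_table(levels, mask)
    gv_o, n_o, p_o, s_o, nvp_o = naive_ngtdm(levels, mask)
    assert np.array_equal(gv, gv_o)
    assert nvp == nvp_o
    assert np.array_equal(n, n_o)
    assert np.allclose(s, s_o, atol=1e-10)


def test_small_patch_glcm_features_by_hand():
    """2x2x1 patch [[1,1],[2,2]]: exhaustive pair counting gives the joint
    maximum and contrast exactly."""
    levels = np.array([[[1], [1]], [[2], [2]]], dtype=np.int64)
    mask = np.ones_like(levels, dtype=bool)
    gv, C = glcm_matrix(levels, mask)
    P = C / C.sum()
    # pairs: horizontal same-level 1-1 and 2-2 (x axis? here y axis), plus
    # cross pairs along x and diagonals; enumeration by hand:
    gv_o, C_o = naive_glcm(levels, mask)
    assert np.array_equal(C, C_o)
    contrast = sum(
        P[i, j] * (gv[i] - gv[j]) ** 2
        for i in range(len(gv))
        for j in range(len(gv))
    )
    from radgen.features.texture import glcm_features

    feats = glcm_features(gv, C)
    assert feats["Contrast"] == pytest.approx(contrast)
    assert feats["MaximumProbability"] == pytest.approx(P.max())


# ---------------------------------------------------------- discretization


def test_discretize_hand_example():
    vals = np.array([0.0, 24.9, 25.0, 50.0])
    assert discretize(vals, 25.0).tolist() == [1, 1, 2, 3]


def test_discretize_constant_roi_single_level():
    vals = np.full(10, 7.3)
    lv = discretize(vals, 25.0)
    assert set(lv.tolist()) == {1}


def test_discretize_shift_invariant():
    rng = np.random.default_rng(1)
    vals = rng.normal(0, 50, 100)
    assert np.array_equal(discretize(vals, 10.0), discretize(vals + 137.0, 10.0))


# ------------------------------------------------------------- first order


def test_first_order_hand_values():
    feats = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
    assert feats["Mean"] == pytest.approx(2.5)
    assert feats["Range"] == pytest.approx(3.0)
    assert feats["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
    assert feats["Variance"] == pytest.approx(1.25)  # population
    assert feats["Energy"] == pytest.approx(30.0)


def test_first_order_constant_roi_degenerate():
    feats = first_order_features(np.full(64, 42.0), 1.0)
    assert feats["Entropy"] == 0.0
    assert feats["Uniformity"] == 1.0
    assert feats["Variance"] == 0.0


def test_first_order_names_and_count():
    feats = first_order_features(np.arange(10.0), 2.0)
    assert list(feats) == FIRST_ORDER_NAMES
    assert len(feats) == 19
    assert feats["TotalEnergy"] == pytest.approx(2.0 * feats["Energy"])


def test_single_voxel_dispersion_undefined():
    feats = first_order_features(np.array([5.0]), 1.0)
    assert np.isnan(feats["Variance"])
    assert np.isfinite(feats["Mean"])


def test_first_order_invariant_to_voxel_shuffling_but_texture_not():
    rng = np.random.default_rng(3)
    levels = rng.integers(1, 5, size=(4, 4, 3)).astype(np.int64)
    mask = np.ones(levels.shape, dtype=bool)
    shuffled = levels.ravel().copy()
    rng.shuffle(shuffled)
    shuffled = shuffled.reshape(levels.shape)
    fo1 = first_order_features(levels[mask].astype(float), 1.0)
    fo2 = first_order_features(shuffled[mask].astype(float), 1.0)
    for k in fo1:
        assert fo1[k] == pytest.approx(fo2[k])
    t1 = texture_features(levels, mask)
    t2 = texture_features(shuffled, mask)
    assert t1["glcm_Contrast"] != pytest.approx(t2["glcm_Contrast"])


# ------------------------------------------------------- family counts etc.


def test_texture_feature_count_is_75_with_family_sizes():
    rng = np.random.default_rng(4)
    levels = rng.integers(1, 6, size=(5, 5, 4)).astype(np.int64)
    mask = np.ones(levels.shape, dtype=bool)
    feats = texture_features(levels, mask)
    assert len(feats) == 75
    for fam, size in TEXTURE_FAMILY_SIZES.items():
        assert sum(k.startswith(fam + "_") for k in feats) == size
    assert sum(TEXTURE_FAMILY_SIZES.values()) == 75


def test_constant_roi_texture_degeneracies():
    levels = np.ones((4, 4, 3), dtype=np.int64)
    mask = np.ones(levels.shape, dtype=bool)
    feats = texture_features(levels, mask)
    assert feats["glcm_Contrast"] == 0.0
    from radgen.features.texture import COARSENESS_CAP

    assert feats["ngtdm_Coarseness"] == COARSENESS_CAP
    # single zone covering the whole ROI
    gv, sz, M = glszm_matrix(levels, mask)
    assert M.sum() == 1 and M[0, -1] == 1
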