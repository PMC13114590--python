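"""Texture-feature extraction against independent brute-force oracles.

Every matrix family (GLCM, GLRLM, GLSZM, GLDM, NGTDM) is rebuilt here with
naive nested loops on tiny fixtures and compared with the vectorized
implementation; representative features are recomputed with literal
formula arithmetic on the brute-force matrices.
"""

import numpy as np
import pytest

from habitatvpi.preprocess import CTVolume
from habitatvpi.radiomics import (
    catalog_names,
    extract_per_habitat,
    extract_whole,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    habitat_catalog_names,
    ngtdm_features,
    ngtdm_table,
    zscore_features,
)

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def bf_glcm(levels, mask, n_levels):
    """Naive symmetric co-occurrence matrices, one per direction."""
    mats = np.zeros((13, n_levels, n_levels))
    nx, ny, nz = mask.shape
    for k, (dx, dy, dz) in enumerate(OFFSETS_13):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    a, b, c = x + dx, y + dy, z + dz
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and mask[a, b, c]:
                        i, j = levels[x, y, z] - 1, levels[a, b, c] - 1
                        mats[k, i, j] += 1
                        mats[k, j, i] += 1
    return mats


def bf_gldm(levels, mask, n_levels, alpha=0):
    """Naive dependence matrix (26-connectivity)."""
    nx, ny, nz = mask.shape
    P = np.zeros((n_levels, 27))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                dep = 0
                for dx, dy, dz in OFFSETS_26:
                    a, b, c = x + dx, y + dy, z + dz
                    if (
                        0 <= a < nx and 0 <= b < ny and 0 <= c < nz
                        and mask[a, b, c]
                        and abs(int(levels[x, y, z]) - int(levels[a, b, c])) <= alpha
                    ):
                        dep += 1
                P[levels[x, y, z] - 1, dep] += 1
    return P


def bf_runs(levels, mask, n_levels):
    """Naive run-length matrices by walking every line of every direction."""
    nx, ny, nz = mask.shape
    lmax = max(mask.shape)
    mats = np.zeros((13, n_levels, lmax))
    for k, d in enumerate(OFFSETS_13):
        seen = set()
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    prev = (x - d[0], y - d[1], z - d[2])
                    inside = all(0 <= p < s for p, s in zip(prev, mask.shape))
                    if inside:
                        continue  # not a line start
                    # walk the line, breaking runs at mask/level changes
                    run_level, run_len = None, 0
                    cx, cy, cz = x, y, z
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
                        key = (cx, cy, cz)
                        assert key not in seen
                        seen.add(key)
                        if mask[cx, cy, cz]:
                            lv = levels[cx, cy, cz]
                            if lv == run_level:
                                run_len += 1
                            else:
                                if run_level is not None:
                                    mats[k, run_level - 1, run_len - 1] += 1
                                run_level, run_len = lv, 1
                        else:
                            if run_level is not None:
                                mats[k, run_level - 1, run_len - 1] += 1
                            run_level, run_len = None, 0
                        cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                    if run_level is not None:
                        mats[k, run_level - 1, run_len - 1] += 1
    return mats


def bf_zones(levels, mask, n_levels):
    """Naive size-zone matrix via flood fill (26-connectivity)."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or visited[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                visited[x, y, z] = True
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        a, b, c = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= a < nx and 0 <= b < ny and 0 <= c < nz
                            and mask[a, b, c] and not visited[a, b, c]
                            and levels[a, b, c] == lv
                        ):
                            visited[a, b, c] = True
                            stack.append((a, b, c))
                zones.append((lv, size))
    smax = max(s for _, s in zones)
    P = np.zeros((n_levels, smax))
    for lv, s in zones:
        P[lv - 1, s - 1] += 1
    return P


def bf_ngtdm(levels, mask, n_levels):
    """Naive NGTD table: n_i and s_i from explicit neighbour means."""
    nx, ny, nz = mask.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nbs = []
                for dx, dy, dz in OFFSETS_26:
                    a, b, c = x + dx, y + dy, z + dz
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and mask[a, b, c]:
                        nbs.append(levels[a, b, c])
                if not nbs:
                    continue
                lv = levels[x, y, z]
                n_i[lv - 1] += 1
                s_i[lv - 1] += abs(lv - np.mean(nbs))
    return n_i, s_i


@pytest.fixture
def printed_fixture():
    """3x3x1 gray-level fixture {1,1,2; 2,2,3; 3,3,3}."""
    levels = np.array([[1, 1, 2], [2, 2, 3], [3, 3, 3]], dtype=np.int64)[..., None]
    mask = np.ones_like(levels, dtype=bool)
    return levels, mask


@pytest.fixture
def random_fixture():
    rng = np.random.default_rng(5)
    levels = rng.integers(1, 5, size=(4, 4, 2))
    mask = rng.random((4, 4, 2)) > 0.2
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask


class TestMatrixOracles:
    @pytest.mark.parametrize("fix", ["printed_fixture", "random_fixture"])
    def test_glcm_matrix_equals_bruteforce(self, fix, request):
        levels, mask = request.getfixturevalue(fix)
        ng = int(levels.max())
        np.testing.assert_array_equal(
            glcm_matrix(levels, mask, ng), bf_glcm(levels, mask, ng)
        )

    @pytest.mark.parametrize("fix", ["printed_fixture", "random_fixture"])
    def test_gldm_matrix_equals_bruteforce(self, fix, request):
        levels, mask = request.getfixturevalue(fix)
        ng = int(levels.max())
        np.testing.assert_array_equal(
            gldm_matrix(levels, mask, ng), bf_gldm(levels, mask, ng)
        )

    @pytest.mark.parametrize("fix", ["printed_fixture", "random_fixture"])
    def test_glrlm_matrix_equals_bruteforce(self, fix, request):
        levels, mask = request.getfixturevalue(fix)
        ng = int(levels.max())
        got = glrlm_matrix(levels, mask, ng)
        want = bf_runs(levels, mask, ng)
        lm = min(got.shape[2], want.shape[2])
        assert got[:, :, lm:].sum() == 0 and want[:, :, lm:].sum() == 0
        np.testing.assert_array_equal(got[:, :, :lm], want[:, :, :lm])

    @pytest.mark.parametrize("fix", ["printed_fixture", "random_fixture"])
    def test_glszm_matrix_equals_bruteforce(self, fix, request):
        levels, mask = request.getfixturevalue(fix)
        ng = int(levels.max())
        np.testing.assert_array_equal(
            glszm_matrix(levels, mask, ng), bf_zones(levels, mask, ng)
        )

    @pytest.mark.parametrize("fix", ["printed_fixture", "random_fixture"])
    def test_ngtdm_table_equals_bruteforce(self, fix, request):
        levels, mask = request.getfixturevalue(fix)
        ng = int(levels.max())
        n_got, s_got = ngtdm_table(levels, mask, ng)
        n_want, s_want = bf_ngtdm(levels, mask, ng)
        np.testing.assert_array_equal(n_got, n_want)
        np.testing.assert_allclose(s_got, s_want, atol=1e-10)


class TestFeatureArithmetic:
    def test_glcm_features_match_literal_formulas(self, printed_fixture):
        levels, mask = printed_fixture
        ng = int(levels.max())
        feats = glcm_features(levels, mask, ng)
        mats = bf_glcm(levels, mask, ng)
        shade, prom, contrast = [], [], []
        for P in mats:
            if P.sum() == 0:
                continue
            p = P / P.sum()
            mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
            mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
            shade.append(sum(
                (i + 1 + j + 1 - mu_i - mu_j) ** 3 * p[i, j]
                for i in range(ng) for j in range(ng)
            ))
            prom.append(sum(
                (i + 1 + j + 1 - mu_i - mu_j) ** 4 * p[i, j]
                for i in range(ng) for j in range(ng)
            ))
            contrast.append(sum(
                (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
            ))
        assert feats["ClusterShade"] == pytest.approx(np.mean(shade))
        assert feats["ClusterProminence"] == pytest.approx(np.mean(prom))
        assert feats["Contrast"] == pytest.approx(np.mean(contrast))

    def test_glcm_inversion_symmetry(self, random_fixture):
        levels, mask = random_fixture
        ng = int(levels.max())
        inv = np.where(mask, ng + 1 - levels, 0)
        f = glcm_features(levels, mask, ng)
        g = glcm_features(inv, mask, ng)
        assert g["ClusterShade"] == pytest.approx(-f["ClusterShade"], abs=1e-10)
        assert g["ClusterProminence"] == pytest.approx(f["ClusterProminence"])

    def test_gldm_features_match_literal_formulas(self, random_fixture):
        levels, mask = random_fixture
        ng = int(levels.max())
        feats = gldm_features(levels, mask, ng)
        P = bf_gldm(levels, mask, ng)
        nz = P.sum()
        lde = sum(P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(27)) / nz
        sde = sum(P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(27)) / nz
        ldlgle = sum(
            P[i, j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng) for j in range(27)
        ) / nz
        assert feats["LargeDependenceEmphasis"] == pytest.approx(lde)
        assert feats["SmallDependenceEmphasis"] == pytest.approx(sde)
        assert feats["LargeDependenceLowGrayLevelEmphasis"] == pytest.approx(ldlgle)
        assert feats["SmallDependenceEmphasis"] <= 1.0  # j >= 1 bound

    def test_uniform_cube_dependence_closed_form(self):
        # 3x3x3 constant cube: dependence+1 is 8 at corners, 12 on edges,
        # 18 on faces, 27 in the centre
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), dtype=bool)
        feats = gldm_features(levels, mask, 1)
        expected = (8 * 8**2 + 12 * 12**2 + 6 * 18**2 + 1 * 27**2) / 27
        assert feats["LargeDependenceEmphasis"] == pytest.approx(expected)

    def test_ngtdm_features_match_literal_formulas(self, random_fixture):
        levels, mask = random_fixture
        ng = int(levels.max())
        feats = ngtdm_features(levels, mask, ng)
        n_i, s_i = bf_ngtdm(levels, mask, ng)
        N = n_i.sum()
        p = n_i / N
        present = [i for i in range(ng) if p[i] > 0]
        ngp = len(present)
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * (s_i.sum() / N)
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = (p * s_i).sum() / busy_den
        assert feats["Contrast"] == pytest.approx(contrast)
        assert feats["Busyness"] == pytest.approx(busyness)

    def test_constant_voi_degenerate_conventions(self):
        vol = CTVolume(np.full((5, 5, 5), -300.0))
        mask = np.ones((5, 5, 5), dtype=bool)
        f = extract_whole(vol, mask)
        assert f["firstorder_Variance"] == 0
        assert f["GLCM_ClusterShade"] == 0
        assert f["NGTDM_Contrast"] == 0

    def test_blur_lowers_ngtdm_contrast(self):
        from scipy import ndimage

        rng = np.random.default_rng(11)
        data = rng.normal(0, 100, size=(12, 12, 12))
        mask = np.ones(data.shape, dtype=bool)
        from habitatvpi.preprocess import discretize_fixed_bins

        sharp = ngtdm_features(discretize_fixed_bins(data, mask, 8), mask, 8)
        blurred_data = ndimage.gaussian_filter(data, 1.5)
        blurred = ngtdm_features(
            discretize_fixed_bins(blurred_data, mask, 8), mask, 8
        )
        assert blurred["Contrast"] < sharp["Contrast"]


class TestFirstOrder:
    def test_hand_computed_values(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        levels = np.array([1, 2, 3, 4])
        f = firstorder_features(vals, levels, voxel_volume=1.0)
        assert f["Mean"] == 2.5
        assert f["Median"] == 2.5
        assert f["Variance"] == 1.25  # population convention
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_conventions(self):
        vals = np.full(4, 3.0)
        f = firstorder_features(vals, np.ones(4, dtype=int), 1.0)
        assert f["Variance"] == 0
        assert f["Skewness"] == 0
        assert f["Kurtosis"] == 0
        assert f["Minimum"] == f["Maximum"] == f["Mean"]


class TestCatalogContracts:
    def test_whole_lesion_feature_count(self):
        assert len(catalog_names()) == 106

    def test_per_habitat_feature_count(self):
        assert len(habitat_catalog_names(1)) == 93

    def test_extract_whole_emits_catalog(self):
        rng = np.random.default_rng(4)
        vol = CTVolume(rng.normal(-400, 200, size=(12, 12, 12)))
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        f = extract_whole(vol, mask)
        assert sorted(f) == sorted(catalog_names())

    def test_per_habitat_counts_and_missing_block(self):
        rng = np.random.default_rng(6)
        vol = CTVolume(rng.normal(-300, 150, size=(10, 10, 10)))
        hmap = np.zeros((10, 10, 10), dtype=int)
        hmap[2:5, 2:8, 2:8] = 1
        hmap[5:8, 2:8, 2:8] = 3  # habitat 2 absent
        f = extract_per_habitat(vol, hmap, n_habitats=3)
        assert len(f) == 279
        block2 = [v for n, v in f.items() if n.startswith("Habitat2_")]
        assert len(block2) == 93 and all(np.isnan(v) for v in block2)
        others = [v for n, v in f.items() if not n.startswith("Habitat2_")]
        assert not any(np.isnan(v) for v in others)

    def test_habitat_volumes_conserve_lesion_volume(self):
        rng = np.random.default_rng(7)
        vol = CTVolume(rng.normal(-300, 150, size=(10, 10, 10)))
        hmap = np.zeros((10, 10, 10), dtype=int)
        hmap[2:8, 2:8, 2:8] = rng.integers(1, 4, size=(6, 6, 6))
        f = extract_per_habitat(vol, hmap, n_habitats=3)
        whole = extract_whole(vol, hmap > 0)
        total = sum(f[f"Habitat{k}_shape_VoxelVolume"] for k in (1, 2, 3))
        assert total == pytest.approx(whole["shape_VoxelVolume"])

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.normal(-400, 150, size=(8, 8, 8))
        vol1 = CTVolume(np.pad(data, ((0, 4), (0, 4), (0, 4)), constant_values=0))
        vol2 = CTVolume(np.pad(data, ((4, 0), (4, 0), (4, 0)), constant_values=0))
        m = np.zeros((12, 12, 12), dtype=bool)
        m1, m2 = m.copy(), m.copy()
        m1[1:7, 1:7, 1:7] = True
        m2[5:11, 5:11, 5:11] = True
        f1 = extract_whole(vol1, m1)
        f2 = extract_whole(vol2, m2)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name


class TestZScore:
    def test_hand_arithmetic(self):
        import pandas as pd

        t = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        z, stats = zscore_features(t)
        np.testing.assert_allclose(z["f"], [-1.22474487, 0, 1.22474487])

    def test_frozen_stats_reproduce_fit(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        t = pd.DataFrame(rng.normal(5, 2, size=(20, 3)), columns=list("abc"))
        z1, stats = zscore_features(t)
        z2, _ = zscore_features(t, stats)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy())

    def test_constant_column_dropped(self):
        import pandas as pd

        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            z, stats = zscore_features(t)
        assert list(z.columns) == ["a"]
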