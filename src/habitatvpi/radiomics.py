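"""IBSI-style radiomic feature extraction.

Implements the 106-feature whole-lesion catalog used throughout the pipeline:
14 shape, 18 first-order, 24 gray-level co-occurrence (GLCM), 16 run-length
(GLRLM), 16 size-zone (GLSZM), 14 dependence (GLDM) and 5 neighbouring
gray-tone difference (NGTDM) features, minus one excluded co-occurrence
feature (SumAverage, which duplicates 2*JointAverage under matrix symmetry)
so the whole-lesion total is exactly 106.

Per-habitat extraction drops the shape family except VoxelVolume, giving 93
features per habitat (279 for the default three habitats).

Texture matrices are built on the 25-bin fixed-bin-count discretization of
the masked intensities, with distance-1 neighbourhoods (26-connectivity,
13 unique 3D directions, features averaged over directions).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .preprocess import CTVolume, discretize_fixed_bins

EXCLUDED_FEATURE = "GLCM_SumAverage"

_FIRSTORDER = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
_SHAPE = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]
_GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]
_GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]
_GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]
_GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]
_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]


def catalog_names(excluded: str = EXCLUDED_FEATURE) -> list[str]:
    """Ordered names of the 106 whole-lesion features."""
    names = (
        [f"shape_{n}" for n in _SHAPE]
        + [f"firstorder_{n}" for n in _FIRSTORDER]
        + [f"GLCM_{n}" for n in _GLCM]
        + [f"GLRLM_{n}" for n in _GLRLM]
        + [f"GLSZM_{n}" for n in _GLSZM]
        + [f"GLDM_{n}" for n in _GLDM]
        + [f"NGTDM_{n}" for n in _NGTDM]
    )
    return [n for n in names if n != excluded]


def habitat_catalog_names(k: int, excluded: str = EXCLUDED_FEATURE) -> list[str]:
    """Ordered names of the 93 per-habitat features for habitat ``k``."""
    names = ["shape_VoxelVolume"] + [
        n for n in catalog_names(excluded) if not n.startswith("shape_")
    ]
    return [f"Habitat{k}_{n}" for n in names]


def feature_family(name: str) -> str:
    base = name.split("_", 1)[0]
    if base.startswith("Habitat"):
        base = name.split("_", 2)[1]
    return base


# ---------------------------------------------------------------------------
# neighbourhood machinery


def _offsets26() -> np.ndarray:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    return np.array(offs, dtype=int)


def _offsets13() -> np.ndarray:
    """The 13 unique direction offsets (half of the 26-neighbourhood)."""
    return np.array([o for o in _offsets26().tolist() if tuple(o) > (0, 0, 0)])


def _shift_view(arr: np.ndarray, off: tuple[int, int, int]):
    """Return aligned views (a, b) with b displaced by ``off`` relative to a."""
    sl_a, sl_b = [], []
    for d, n in zip(off, arr.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# first order


def firstorder_features(
    values: np.ndarray, levels: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    """First-order statistics of the masked raw intensities.

    ``levels`` are the discretized gray levels of the same voxels (used for
    Entropy and Uniformity).  Degenerate (constant) inputs return 0 for
    skewness and kurtosis by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.mean()
    var = x.var()
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m = x - mean
        skew = (m**3).mean() / var**1.5
        kurt = (m**4).mean() / var**2
    else:
        skew = kurt = 0.0
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Mesh- and moment-based 3D shape descriptors of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    voxvol = float(n * spacing.prod())
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    coords = np.argwhere(mask) * spacing
    # surface voxels suffice for maximal diameters
    eroded = ndimage.binary_erosion(mask)
    surf_idx = np.argwhere(mask & ~eroded)

    def _max_diam(pts: np.ndarray) -> float:
        if len(pts) < 2:
            return 0.0
        if len(pts) > 80:
            try:
                from scipy.spatial import ConvexHull

                pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
            except Exception:
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def _max_diam_2d(drop_axis: int) -> float:
        keep = [a for a in range(3) if a != drop_axis]
        best = 0.0
        for v in np.unique(surf_idx[:, drop_axis]):
            pts = surf_idx[surf_idx[:, drop_axis] == v][:, keep] * spacing[keep]
            best = max(best, _max_diam(pts))
        return best

    centered = coords - coords.mean(0)
    if n > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    sphericity = (36 * np.pi * mesh_vol**2) ** (1 / 3) / area if area > 0 else 0.0
    return {
        "MeshVolume": mesh_vol,
        "VoxelVolume": voxvol,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_vol if mesh_vol > 0 else np.inf,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_diam(surf_idx * spacing),
        "Maximum2DDiameterSlice": _max_diam_2d(2),
        "Maximum2DDiameterColumn": _max_diam_2d(1),
        "Maximum2DDiameterRow": _max_diam_2d(0),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrices, one per direction: (13, Ng, Ng) counts."""
    mask = np.asarray(mask, dtype=bool)
    mats = np.zeros((13, n_levels, n_levels))
    for k, off in enumerate(_offsets13()):
        la, lb = _shift_view(levels, tuple(off))
        ma, mb = _shift_view(mask, tuple(off))
        valid = ma & mb
        a = la[valid] - 1
        b = lb[valid] - 1
        m = np.bincount(a * n_levels + b, minlength=n_levels**2).reshape(
            n_levels, n_levels
        ).astype(float)
        mats[k] = m + m.T
    return mats


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    s = P.sum()
    p = P / s
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(1)
    mu_x = (i * px).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    # symmetric matrix: marginals coincide
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(),
                        minlength=2 * Ng + 1)[2:]
    k_diff = np.arange(0, Ng)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(),
                         minlength=Ng)
    nz = p > 0
    HXY = -(p[nz] * np.log2(p[nz])).sum()
    pxpy = np.outer(px, px)
    m = nz & (pxpy > 0)
    HXY1 = -(p[m] * np.log2(pxpy[m])).sum()
    m2 = pxpy > 0
    HXY2 = -(pxpy[m2] * np.log2(pxpy[m2])).sum()
    HX = -(px[px > 0] * np.log2(px[px > 0])).sum()
    imc1 = (HXY - HXY1) / HX if HX > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY))))
    # MCC on gray levels actually present
    present = px > 0
    if present.sum() > 1:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2].real)))
    else:
        mcc = 1.0
    da = (k_diff * p_diff).sum()
    corr_den = sig_x * sig_x
    feats = {
        "Autocorrelation": (ii * jj * p).sum(),
        "ClusterProminence": (((ii + jj - 2 * mu_x) ** 4) * p).sum(),
        "ClusterShade": (((ii + jj - 2 * mu_x) ** 3) * p).sum(),
        "ClusterTendency": (((ii + jj - 2 * mu_x) ** 2) * p).sum(),
        "Contrast": (((ii - jj) ** 2) * p).sum(),
        "Correlation": ((ii * jj * p).sum() - mu_x**2) / corr_den if corr_den > 0 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum(),
        "DifferenceVariance": (((k_diff - da) ** 2) * p_diff).sum(),
        "Id": (p / (1 + np.abs(ii - jj))).sum(),
        "Idm": (p / (1 + (ii - jj) ** 2)).sum(),
        "Idmn": (p / (1 + ((ii - jj) ** 2) / Ng**2)).sum(),
        "Idn": (p / (1 + np.abs(ii - jj) / Ng)).sum(),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": (p[ii != jj] / ((ii - jj)[ii != jj] ** 2)).sum(),
        "JointAverage": mu_x,
        "JointEnergy": (p**2).sum(),
        "JointEntropy": HXY,
        "MCC": mcc,
        "MaximumProbability": p.max(),
        "SumAverage": (k_sum * p_sum).sum(),
        "SumEntropy": -(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum(),
        "SumSquares": (((ii - mu_x) ** 2) * p).sum(),
    }
    return {k: float(v) for k, v in feats.items()}


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLCM features averaged over the 13 unique directions."""
    mats = glcm_matrix(levels, mask, n_levels)
    per_dir = [_glcm_features_single(P) for P in mats if P.sum() > 0]
    if not per_dir:  # single isolated voxel: no pairs at all
        return {k: 0.0 for k in _GLCM}
    return {k: float(np.mean([d[k] for d in per_dir])) for k in _GLCM}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrices per direction: (13, Ng, Lmax) counts."""
    mask = np.asarray(mask, dtype=bool)
    idx = np.argwhere(mask)
    lv = levels[mask]
    lmax = max(mask.shape)
    mats = np.zeros((13, n_levels, lmax))
    for k, off in enumerate(_offsets13()):
        d = np.asarray(off)
        dd = int(d @ d)  # projection increment per step along the direction
        t = idx @ d
        base = idx * dd - t[:, None] * d[None, :]  # integer line invariant
        order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
        bs, ts, ls = base[order], t[order], lv[order]
        new_run = np.ones(len(ts), dtype=bool)
        if len(ts) > 1:
            same_line = (bs[1:] == bs[:-1]).all(1) & (ts[1:] == ts[:-1] + dd)
            new_run[1:] = ~(same_line & (ls[1:] == ls[:-1]))
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(ts)))
        run_levels = ls[starts]
        np.add.at(mats[k], (run_levels - 1, lengths - 1), 1.0)
    return mats


def _srm_features(P: np.ndarray, n_voxels: int, run: bool) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on one matrix."""
    Ns = P.sum()
    p = P / Ns
    Ng, Lm = P.shape
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Lm + 1)[None, :]
    pg = P.sum(1)
    pr = P.sum(0)
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    nz = p > 0
    names = (
        ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
         "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
         "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
         "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
         "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
         "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
         "ShortRunLowGrayLevelEmphasis"]
        if run
        else ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
              "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
              "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
              "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
              "SizeZoneNonUniformityNormalized", "ZonePercentage", "ZoneVariance",
              "ZoneEntropy", "SmallAreaEmphasis", "SmallAreaHighGrayLevelEmphasis",
              "SmallAreaLowGrayLevelEmphasis"]
    )
    vals = {
        "GLN": (pg**2).sum() / Ns,
        "GLNN": (pg**2).sum() / Ns**2,
        "GLV": (((i - mu_i) ** 2) * p).sum(),
        "HGLE": ((i**2) * p).sum(),
        "LE": ((j**2) * p).sum(),
        "LHGLE": ((i**2) * (j**2) * p).sum(),
        "LLGLE": (((j**2) / (i**2)) * p).sum(),
        "LGLE": ((1.0 / i**2) * p).sum(),
        "Entropy": -(p[nz] * np.log2(p[nz])).sum(),
        "SN": (pr**2).sum() / Ns,
        "SNN": (pr**2).sum() / Ns**2,
        "Pct": Ns / n_voxels,
        "SV": (((j - mu_j) ** 2) * p).sum(),
        "SE": ((1.0 / j**2) * p).sum(),
        "SHGLE": (((i**2) / (j**2)) * p).sum(),
        "SLGLE": ((1.0 / (i**2 * j**2)) * p).sum(),
    }
    if run:
        order = ["GLN", "GLNN", "GLV", "HGLE", "LE", "LHGLE", "LLGLE", "LGLE",
                 "Entropy", "SN", "SNN", "Pct", "SV", "SE", "SHGLE", "SLGLE"]
    else:
        order = ["GLN", "GLNN", "GLV", "HGLE", "LE", "LHGLE", "LLGLE", "LGLE",
                 "SN", "SNN", "Pct", "SV", "Entropy", "SE", "SHGLE", "SLGLE"]
    return {name: float(vals[key]) for name, key in zip(names, order)}


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 unique directions."""
    mats = glrlm_matrix(levels, mask, n_levels)
    n_vox = int(np.asarray(mask, bool).sum())
    per_dir = [_srm_features(P, n_vox, run=True) for P in mats if P.sum() > 0]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in _GLRLM}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix (Ng, Smax): 26-connected constant-level zones."""
    mask = np.asarray(mask, dtype=bool)
    struct = np.ones((3, 3, 3), dtype=int)
    zones = []  # (level, size)
    for g in range(1, n_levels + 1):
        comp, ncomp = ndimage.label((levels == g) & mask, structure=struct)
        if ncomp:
            sizes = np.bincount(comp.ravel())[1:]
            zones.extend((g, s) for s in sizes)
    smax = max(s for _, s in zones)
    P = np.zeros((n_levels, smax))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    P = glszm_matrix(levels, mask, n_levels)
    n_vox = int(np.asarray(mask, bool).sum())
    feats = _srm_features(P, n_vox, run=False)
    return {k: feats[k] for k in _GLSZM}


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix (Ng, 27): 26-connectivity, |level diff| <= alpha."""
    mask = np.asarray(mask, dtype=bool)
    dep = np.zeros(mask.shape, dtype=np.int64)
    for off in _offsets26():
        la, lb = _shift_view(levels, tuple(off))
        ma, mb = _shift_view(mask, tuple(off))
        ok = ma & mb & (np.abs(la - lb) <= alpha)
        # accumulate onto the 'a' side of the shifted view
        sl = tuple(
            slice(0, n - d) if d >= 0 else slice(-d, n)
            for d, n in zip(off, mask.shape)
        )
        dep[sl] += ok
    j = dep[mask] + 1  # dependence includes the center voxel
    lv = levels[mask]
    P = np.zeros((n_levels, 27))
    np.add.at(P, (lv - 1, j - 1), 1.0)
    return P


def gldm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    P = gldm_matrix(levels, mask, n_levels)
    Nz = P.sum()
    p = P / Nz
    Ng, Dm = P.shape
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Dm + 1)[None, :]
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    nz = p > 0
    feats = {
        "DependenceEntropy": -(p[nz] * np.log2(p[nz])).sum(),
        "DependenceNonUniformity": (P.sum(0) ** 2).sum() / Nz,
        "DependenceNonUniformityNormalized": (P.sum(0) ** 2).sum() / Nz**2,
        "DependenceVariance": (((j - mu_j) ** 2) * p).sum(),
        "GrayLevelNonUniformity": (P.sum(1) ** 2).sum() / Nz,
        "GrayLevelVariance": (((i - mu_i) ** 2) * p).sum(),
        "HighGrayLevelEmphasis": ((i**2) * p).sum(),
        "LargeDependenceEmphasis": ((j**2) * p).sum(),
        "LargeDependenceHighGrayLevelEmphasis": ((i**2) * (j**2) * p).sum(),
        "LargeDependenceLowGrayLevelEmphasis": (((j**2) / (i**2)) * p).sum(),
        "LowGrayLevelEmphasis": ((1.0 / i**2) * p).sum(),
        "SmallDependenceEmphasis": ((1.0 / j**2) * p).sum(),
        "SmallDependenceHighGrayLevelEmphasis": (((i**2) / (j**2)) * p).sum(),
        "SmallDependenceLowGrayLevelEmphasis": ((1.0 / (i**2 * j**2)) * p).sum(),
    }
    return {k: float(v) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level counts n_i and coarseness sums s_i of the NGTD matrix."""
    mask = np.asarray(mask, dtype=bool)
    nb_sum = np.zeros(mask.shape)
    nb_cnt = np.zeros(mask.shape)
    for off in _offsets26():
        sl = tuple(
            slice(0, n - d) if d >= 0 else slice(-d, n)
            for d, n in zip(off, mask.shape)
        )
        la, lb = _shift_view(levels.astype(float), tuple(off))
        ma, mb = _shift_view(mask, tuple(off))
        nb_sum[sl] += np.where(mb, lb, 0.0) * ma
        nb_cnt[sl] += (ma & mb)
    valid = mask & (nb_cnt > 0)
    abar = np.zeros(mask.shape)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    lv = levels[valid]
    diff = np.abs(lv - abar[valid])
    n_i = np.bincount(lv - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(lv - 1, weights=diff, minlength=n_levels)
    return n_i, s_i


def ngtdm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    n_i, s_i = ngtdm_table(levels, mask, n_levels)
    N = n_i.sum()
    p_i = n_i / N if N > 0 else n_i
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p_i > 0
    Ngp = int(present.sum())
    ip, pp, sp = i[present], p_i[present], s_i[present]
    sum_ps = (pp * sp).sum()
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if Ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = (pij * di**2).sum() / (Ngp * (Ngp - 1)) * (sp.sum() / N)
        busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        psum = pp[:, None] + pp[None, :]
        complexity = (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum() / N
        strength = (psum * di**2).sum() / sp.sum() if sp.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# z-score normalization with frozen training statistics


def zscore_features(table, stats: dict[str, tuple[float, float]] | None = None):
    """Z-score feature columns; training stats are frozen for later splits.

    When ``stats`` is None the statistics are estimated from ``table`` (the
    training split) and returned; zero-sd columns are dropped with a warning.
    When ``stats`` is given, only the listed columns are transformed with the
    stored means/sds.

    Returns (transformed table, stats dict name -> (mean, sd)).
    """
    import warnings

    import pandas as pd

    table = pd.DataFrame(table)
    if stats is None:
        mu = table.mean()
        sd = table.std(ddof=0)
        dead = list(table.columns[sd == 0])
        if dead:
            warnings.warn(f"dropping {len(dead)} constant feature(s)", stacklevel=2)
        keep = [c for c in table.columns if c not in dead]
        stats = {c: (float(mu[c]), float(sd[c])) for c in keep}
    out = table[list(stats)].copy()
    for c, (m, s) in stats.items():
        out[c] = (out[c] - m) / s
    return out, stats


# ---------------------------------------------------------------------------
# public extraction surface


def extract_whole(
    vol: CTVolume,
    mask: np.ndarray,
    n_bins: int = 25,
    excluded: str = EXCLUDED_FEATURE,
) -> dict[str, float]:
    """Extract the 106 whole-lesion features from a preprocessed volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("lesion mask must contain at least 2 voxels")
    levels = discretize_fixed_bins(vol, mask, n_bins)
    voxvol = float(np.prod(vol.spacing))
    out: dict[str, float] = {}
    out.update({f"shape_{k}": v for k, v in shape_features(mask, vol.spacing).items()})
    out.update({
        f"firstorder_{k}": v
        for k, v in firstorder_features(vol.data[mask], levels[mask], voxvol).items()
    })
    out.update({f"GLCM_{k}": v for k, v in glcm_features(levels, mask, n_bins).items()})
    out.update({f"GLRLM_{k}": v for k, v in glrlm_features(levels, mask, n_bins).items()})
    out.update({f"GLSZM_{k}": v for k, v in glszm_features(levels, mask, n_bins).items()})
    out.update({f"GLDM_{k}": v for k, v in gldm_features(levels, mask, n_bins).items()})
    out.update({f"NGTDM_{k}": v for k, v in ngtdm_features(levels, mask, n_bins).items()})
    out.pop(excluded, None)
    return out


def extract_per_habitat(
    vol: CTVolume,
    habitat_map: np.ndarray,
    n_habitats: int = 3,
    n_bins: int = 25,
    excluded: str = EXCLUDED_FEATURE,
) -> dict[str, float]:
    """Extract 93 features per habitat (NaN-filled block for absent habitats).

    Each habitat is re-discretized within its own mask; absent habitats yield
    a fully missing 93-feature block that downstream imputation fills.
    """
    habitat_map = np.asarray(habitat_map)
    if not (habitat_map > 0).any():
        raise ValueError("empty lesion: habitat map has no labelled voxels")
    out: dict[str, float] = {}
    for k in range(1, n_habitats + 1):
        hmask = habitat_map == k
        names = habitat_catalog_names(k, excluded)
        if hmask.sum() < 2:
            out.update({n: np.nan for n in names})
            continue
        levels = discretize_fixed_bins(vol, hmask, n_bins)
        voxvol = float(np.prod(vol.spacing))
        block: dict[str, float] = {
            "shape_VoxelVolume": float(hmask.sum() * voxvol)
        }
        block.update({
            f"firstorder_{kk}": v
            for kk, v in firstorder_features(vol.data[hmask], levels[hmask], voxvol).items()
        })
        block.update({f"GLCM_{kk}": v for kk, v in glcm_features(levels, hmask, n_bins).items()})
        block.update({f"GLRLM_{kk}": v for kk, v in glrlm_features(levels, hmask, n_bins).items()})
        block.update({f"GLSZM_{kk}": v for kk, v in glszm_features(levels, hmask, n_bins).items()})
        block.update({f"GLDM_{kk}": v for kk, v in gldm_features(levels, hmask, n_bins).items()})
        block.update({f"NGTDM_{kk}": v for kk, v in ngtdm_features(levels, hmask, n_bins).items()})
        block.pop(excluded, None)
        out.update({f"Habitat{k}_{kk}": v for kk, v in block.items()})
    return out
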