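"""Habitat partitioning of lesions.

Each z-normalized lesion is over-segmented into ~50 SLIC superpixels; ten
first-order statistics summarise every superpixel; superpixels pooled over
the training lesions are clustered with K-means (the fitted model is frozen
and applied unchanged to validation/test lesions); the cluster count is
chosen by the Davies-Bouldin index.  Voxels inherit their superpixel's
habitat, so habitats exactly partition the lesion mask.

Lesions in which some habitat is absent produce fully missing feature blocks
downstream; those are imputed with an iterative random-forest scheme
(missForest-style: per-feature RF regressions repeated until the relative
change in the imputed values increases, seeded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import slic as _skimage_slic
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .preprocess import CTVolume

SUPERPIXEL_FEATURE_NAMES = [
    "mean", "median", "variance", "skewness", "kurtosis",
    "minimum", "maximum", "p10", "p90", "entropy",
]


@dataclass
class SuperpixelMap:
    labels: np.ndarray  # 0 background, 1..S superpixels
    counts: np.ndarray  # voxel count per superpixel (index 0 unused)

    @property
    def n_superpixels(self) -> int:
        return int(self.labels.max())


def slic3d(
    vol_norm: CTVolume,
    mask: np.ndarray,
    n_superpixels: int = 50,
    compactness: float = 0.1,
) -> SuperpixelMap:
    """Partition a lesion into spatially compact superpixels.

    Runs spacing-aware SLIC on the z-normalized intensities restricted to the
    lesion mask.  Lesions smaller than ``n_superpixels`` voxels degrade to
    one superpixel per voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty lesion mask")
    if n_vox <= n_superpixels:
        warnings.warn(
            f"lesion has only {n_vox} voxels; using one superpixel per voxel",
            stacklevel=2,
        )
        labels = np.zeros(mask.shape, dtype=np.int32)
        labels[mask] = np.arange(1, n_vox + 1)
        return SuperpixelMap(labels, np.bincount(labels.ravel())[:])
    # crop to the mask bounding box for speed; SLIC is local anyway
    idx = np.argwhere(mask)
    lo = idx.min(0)
    hi = idx.max(0) + 1
    sub_img = vol_norm.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    seg = _skimage_slic(
        sub_img.astype(float),
        n_segments=n_superpixels,
        compactness=compactness,
        mask=sub_mask,
        channel_axis=None,
        spacing=tuple(vol_norm.spacing),
        start_label=1,
        enforce_connectivity=True,
    )
    # relabel consecutively 1..S
    labels = np.zeros(mask.shape, dtype=np.int32)
    uniq = np.unique(seg[seg > 0])
    remap = np.zeros(seg.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = remap[seg]
    counts = np.bincount(labels.ravel())
    return SuperpixelMap(labels, counts)


def _first_order_stats(x: np.ndarray, n_bins: int = 25) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    var = x.var()
    if var > 0:
        m = x - mean
        skew = (m**3).mean() / var**1.5
        kurt = (m**4).mean() / var**2
    else:
        skew = kurt = 0.0  # convention for constant / single-voxel superpixels
    if x.size > 1 and x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins)
        p = hist[hist > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    p10, p90 = np.percentile(x, [10, 90])
    return np.array([
        mean, np.median(x), var, skew, kurt, x.min(), x.max(), p10, p90, entropy,
    ])


def superpixel_features(vol_norm: CTVolume, spmap: SuperpixelMap) -> pd.DataFrame:
    """10 first-order statistics of the gray-level distribution per superpixel."""
    rows = []
    for s in range(1, spmap.n_superpixels + 1):
        vals = vol_norm.data[spmap.labels == s]
        rows.append(_first_order_stats(vals))
    return pd.DataFrame(
        rows, columns=SUPERPIXEL_FEATURE_NAMES,
        index=pd.RangeIndex(1, spmap.n_superpixels + 1, name="superpixel"),
    )


@dataclass
class ClusterModel:
    """Frozen K-means habitat model (centroids in standardized feature space)."""

    k: int
    centroids: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    feature_names: list[str]
    seed: int
    db_curve: dict[int, float] = field(default_factory=dict)

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(dtype=float)
        return (x - self.feature_mean) / self.feature_sd

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Nearest-centroid habitat assignment (1-based), no re-fitting."""
        z = self.standardize(features)
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(-1)
        return d2.argmin(1) + 1

    def to_json(self, path) -> None:
        payload = {
            "format": "habitatvpi.cluster_model.v1",
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "feature_names": self.feature_names,
            "seed": self.seed,
            "db_curve": {str(k): v for k, v in self.db_curve.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "habitatvpi.cluster_model.v1":
            raise ValueError(f"unrecognized cluster model file: {path}")
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"]),
            feature_mean=np.asarray(payload["feature_mean"]),
            feature_sd=np.asarray(payload["feature_sd"]),
            feature_names=payload["feature_names"],
            seed=payload["seed"],
            db_curve={int(k): v for k, v in payload["db_curve"].items()},
        )


def fit_habitat_model(
    features: pd.DataFrame, k: int, seed: int = 0, db_curve: dict[int, float] | None = None
) -> ClusterModel:
    """Fit K-means on pooled, z-scored superpixel features (k-means++, 10 restarts)."""
    if len(features) < k:
        raise ValueError(f"cannot fit {k} clusters on {len(features)} superpixels")
    x = features.to_numpy(dtype=float)
    mean = x.mean(0)
    sd = x.std(0)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    km = KMeans(n_clusters=k, n_init=10, init="k-means++", tol=1e-6, random_state=seed)
    km.fit(z)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        feature_mean=mean,
        feature_sd=sd,
        feature_names=list(features.columns),
        seed=seed,
        db_curve=db_curve or {},
    )


def davies_bouldin(features: np.ndarray, assignments: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of max_j (s_i + s_j) / d_ij.

    ``s_i`` is the mean Euclidean distance of cluster members to their
    centroid; ``d_ij`` the centroid-centroid distance.  Duplicate centroids
    make the ratio unbounded and raise.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    cents, scatters = [], []
    for u in uniq:
        pts = x[labels == u]
        if len(pts) == 0:
            raise ValueError(f"empty cluster {u}")
        c = pts.mean(0)
        cents.append(c)
        scatters.append(np.sqrt(((pts - c) ** 2).sum(1)).mean())
    cents = np.asarray(cents)
    s = np.asarray(scatters)
    k = len(uniq)
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.sqrt(((cents[i] - cents[j]) ** 2).sum())
            if d == 0:
                raise ValueError("duplicate centroids: Davies-Bouldin undefined")
            worst = max(worst, (s[i] + s[j]) / d)
        total += worst
    return total / k


def select_k(
    features: pd.DataFrame,
    k_range: range = range(2, 11),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose K minimizing the Davies-Bouldin index over ``k_range``.

    Ties go to the smallest K.  Returns (best K, the full DB curve).
    """
    x = features.to_numpy(dtype=float)
    mean, sd = x.mean(0), x.std(0)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    curve: dict[int, float] = {}
    for k in k_range:
        if len(z) < k:
            break
        km = KMeans(n_clusters=k, n_init=10, init="k-means++", tol=1e-6, random_state=seed)
        lab = km.fit_predict(z)
        curve[k] = davies_bouldin(z, lab)
    best = min(curve, key=lambda k: (curve[k], k))
    return best, curve


def assign_habitats(
    vol_norm: CTVolume, spmap: SuperpixelMap, model: ClusterModel
) -> np.ndarray:
    """Map every superpixel to its nearest habitat centroid (frozen model).

    Returns a voxel label volume (0 background, 1..K habitats) that exactly
    partitions the lesion mask.
    """
    feats = superpixel_features(vol_norm, spmap)
    hab_of_sp = model.predict(feats)
    lut = np.zeros(spmap.n_superpixels + 1, dtype=np.int32)
    lut[1:] = hab_of_sp
    return lut[spmap.labels]


def missing_habitats(habitat_map: np.ndarray, k: int) -> list[int]:
    present = set(np.unique(habitat_map[habitat_map > 0]).tolist())
    return [h for h in range(1, k + 1) if h not in present]


def impute_missing_habitats(
    table: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 5,
    n_estimators: int = 20,
) -> pd.DataFrame:
    """Iterative random-forest imputation of missing habitat feature blocks.

    missForest-style loop: initialize missing cells with column means, then
    repeatedly re-impute each incomplete column from all others with a random
    forest, stopping when the relative change in the imputed values increases
    or ``max_iter`` is reached.
    """
    df = table.copy()
    miss = df.isna()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"features missing in every case cannot be imputed: "
            f"{list(df.columns[all_missing])[:5]}"
        )
    if not miss.any().any():
        return df
    # group incomplete columns sharing a missingness pattern (one habitat
    # block missing per case yields identical patterns across its columns);
    # each group is re-imputed jointly with a multi-output forest
    incomplete = list(df.columns[miss.any(axis=0)])
    groups: dict[tuple, list[str]] = {}
    for col in incomplete:
        groups.setdefault(tuple(np.flatnonzero(miss[col].to_numpy())), []).append(col)
    order = sorted(groups, key=len)  # fewest missing cases first
    filled = df.fillna(df.mean())
    prev_delta = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        old = filled[incomplete].to_numpy(dtype=float).copy()
        for rows_key in order:
            cols = groups[rows_key]
            rows = np.asarray(rows_key)
            obs = np.setdiff1d(np.arange(len(df)), rows)
            predictors = [c for c in df.columns if c not in cols]
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",  # missForest's mtry = sqrt(p)
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(filled.iloc[obs][predictors], df.iloc[obs][cols])
            pred = rf.predict(filled.iloc[rows][predictors])
            filled.iloc[rows, [df.columns.get_loc(c) for c in cols]] = pred
        new = filled[incomplete].to_numpy(dtype=float)
        denom = (new**2).sum()
        delta = ((new - old) ** 2).sum() / denom if denom > 0 else 0.0
        if delta >= prev_delta:
            break
        prev_delta = delta
    return filled


def pca_projection(
    features: pd.DataFrame | np.ndarray, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of the (by default standardized) features.

    Returns (coordinates (n, <=2), explained variance ratios).  Rank-deficient
    inputs yield fewer components with a warning.  ``standardize=False`` runs
    PCA on the centered covariance instead (rotation-equivariant).
    """
    from sklearn.decomposition import PCA

    x = np.asarray(features, dtype=float)
    if len(x) < 3:
        raise ValueError("PCA projection needs at least 3 superpixels")
    if standardize:
        mean, sd = x.mean(0), x.std(0)
        sd[sd == 0] = 1.0
        z = (x - mean) / sd
    else:
        z = x - x.mean(0)
    rank = np.linalg.matrix_rank(z - z.mean(0))
    n_comp = min(2, rank)
    if n_comp < 2:
        warnings.warn("rank-deficient features: returning fewer than 2 components",
                      stacklevel=2)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(z)
    return coords, pca.explained_variance_ratio_
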