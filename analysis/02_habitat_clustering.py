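"""Cluster training-set superpixels into habitats.

Preprocesses every lesion (resample, lung-window clip, z-normalize), runs
3D SLIC (50 superpixels/lesion), pools the training superpixels, sweeps the
Davies-Bouldin curve over K=2..6, fits the frozen K=3 K-means model, and
writes results/db_curve.csv, results/cluster_model.json and the PCA
separability coordinates (results/pca_superpixels.csv).
"""

import warnings

import pandas as pd

import common
from habitatvpi import habitat as hb
from habitatvpi import pipeline as pl

warnings.simplefilter("ignore")

cases = common.cohort()
splits = common.splits(cases)

spfeats = {}
for case in cases:
    _, lesion, norm, *_ = pl.preprocess_case(case, common.PREPROC_SPEC)
    spmap = hb.slic3d(norm, lesion)
    spfeats[case.case_id] = hb.superpixel_features(norm, spmap)

pool = pd.concat([spfeats[cid] for cid in splits["train"]], ignore_index=True)
print(f"pooled {len(pool)} training superpixels from {len(splits['train'])} lesions")

best_k, curve = hb.select_k(pool, range(2, 7), seed=common.SEED)
pd.Series(curve, name="davies_bouldin").rename_axis("k").to_csv(
    common.RESULTS / "db_curve.csv"
)
print("DB curve:", {k: round(v, 3) for k, v in curve.items()},
      f"-> argmin K={best_k}")

# the study design fixes K=3 habitats (rim / transition / core phenotypes)
model = hb.fit_habitat_model(pool, k=3, seed=common.SEED, db_curve=curve)
model.to_json(common.RESULTS / "cluster_model.json")

coords, ev = hb.pca_projection(pool)
pca = pd.DataFrame(coords, columns=["pc1", "pc2"])
pca["habitat"] = model.predict(pool)
pca.to_csv(common.RESULTS / "pca_superpixels.csv", index=False)
print(f"PCA explained variance: {ev.round(3).tolist()}; "
      f"habitat sizes: {pca.habitat.value_counts().sort_index().to_dict()}")
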