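"""Extract radiological, whole-lesion and per-habitat feature tables.

Assigns habitats with the frozen cluster model from step 02, extracts the
106 whole-lesion and 279 per-habitat features (25-bin discretization),
imputes missing habitat blocks per split (missForest-style), and writes
results/features_{radiological,whole,habitat}.csv.
"""

import warnings

import pandas as pd

import common
from habitatvpi import habitat as hb
from habitatvpi import phantom as ph
from habitatvpi import pipeline as pl
from habitatvpi import radiomics as rx

warnings.simplefilter("ignore")

cases = common.cohort()
splits = common.splits(cases)
model = hb.ClusterModel.from_json(common.RESULTS / "cluster_model.json")

radiological, whole, habitat = {}, {}, {}
n_missing = 0
for case in cases:
    vol, lesion, norm, *_ = pl.preprocess_case(case, common.PREPROC_SPEC)
    spmap = hb.slic3d(norm, lesion)
    hmap = hb.assign_habitats(norm, spmap, model)
    n_missing += len(hb.missing_habitats(hmap, model.k))
    meas = ph.measure_radiological(case)
    radiological[case.case_id] = {k: meas[k] for k in pl.RADIOLOGICAL_FEATURES}
    whole[case.case_id] = rx.extract_whole(vol, lesion)
    habitat[case.case_id] = rx.extract_per_habitat(vol, hmap, model.k)

tables = {
    "radiological": pd.DataFrame.from_dict(radiological, orient="index").sort_index(),
    "whole": pd.DataFrame.from_dict(whole, orient="index").sort_index(),
    "habitat": pd.DataFrame.from_dict(habitat, orient="index").sort_index(),
}
print(f"{n_missing} missing habitat blocks across {len(cases)} cases "
      f"({100 * n_missing / (model.k * len(cases)):.1f}% of blocks); imputing per split")
filled = []
for s, ids in splits.items():
    part = tables["habitat"].loc[sorted(ids)]
    filled.append(hb.impute_missing_habitats(part, seed=common.SEED)
                  if part.isna().any().any() else part)
tables["habitat"] = pd.concat(filled).sort_index()

for name, tbl in tables.items():
    tbl.to_csv(common.RESULTS / f"features_{name}.csv", float_format="%.6g")
    print(f"features_{name}.csv: {tbl.shape[0]} cases x {tbl.shape[1]} features")
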