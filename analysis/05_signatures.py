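"""Select features and fit the three logistic signatures.

Runs the four-step selection chain (Spearman prune, Mann-Whitney screen,
mRMR top-10, LASSO) on the harmonized, z-scored training split for the
whole-lesion and habitat tables, then backward-eliminated logistic fits
with Youden cutoffs; the radiological signature is fitted on the raw
geometric measurements.  Writes results/{name}_signature.json,
selection traces, and a VIF multicollinearity report.
"""

import warnings

import pandas as pd

import common
from habitatvpi import modeling as md
from habitatvpi import radiomics as rx

warnings.simplefilter("ignore")

meta = pd.read_csv(common.RESULTS / "cohort.csv", index_col="case_id")
cases = common.cohort()
splits = common.splits(cases)
train_ids = sorted(splits["train"])
y_train = meta.loc[train_ids, "vpi"].to_numpy()

vif_rows = []
for name, path in [("radiomic", "features_whole_combat.csv"),
                   ("habitat", "features_habitat_combat.csv")]:
    tbl = pd.read_csv(common.RESULTS / path, index_col=0)
    ztrain, stats_ = rx.zscore_features(tbl.loc[train_ids])
    trace = md.select_features(ztrain, y_train, seed=common.SEED)
    trace.to_json(common.RESULTS / f"{name}_selection_trace.json")
    selected = trace.final or trace.steps[-2][1][:10]
    sig = md.backward_logistic(ztrain[selected], y_train, name=name,
                               min_features=1)
    sig.feature_stats = {c: stats_[c] for c in sig.coefficients}
    sig.to_json(common.RESULTS / f"{name}_signature.json")
    print(f"{name}: {' -> '.join(f'{s}:{len(v)}' for s, v in trace.steps)}")
    print(f"  signature: intercept {sig.intercept:+.3f}; " + "; ".join(
        f"{c} {b:+.3f} (OR {o:.3f})"
        for (c, b), o in zip(sig.coefficients.items(),
                             sig.odds_ratios().values())))
    print(f"  cutoff {sig.cutoff:.3f}")
    if len(sig.coefficients) >= 2:
        v = md.vif(ztrain[list(sig.coefficients)])
        vif_rows.append(v.rename(name))
        print(f"  VIF max {v.max():.2f}")

radiological = pd.read_csv(common.RESULTS / "features_radiological.csv",
                           index_col=0)
sig = md.backward_logistic(radiological.loc[train_ids], y_train,
                           name="radiological", min_features=1)
sig.to_json(common.RESULTS / "radiological_signature.json")
print("radiological:", {c: round(b, 3) for c, b in sig.coefficients.items()},
      f"cutoff {sig.cutoff:.3f}")

if vif_rows:
    pd.concat(vif_rows, axis=1).to_csv(common.RESULTS / "vif.csv")
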