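"""Evaluate the three signatures: discrimination, comparison, calibration,
and clinical utility.

Computes per-split AUC with DeLong CIs, confusion metrics at the signature
cutoffs, Brier scores, pairwise DeLong tests, calibration curves and
decision curves.  Writes results/performance.csv, results/delong.csv,
results/decision_curves.csv and ROC/calibration/DCA figures.
"""

import warnings

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import common
from habitatvpi import evaluate as ev
from habitatvpi import modeling as md

warnings.simplefilter("ignore")

meta = pd.read_csv(common.RESULTS / "cohort.csv", index_col="case_id")
cases = common.cohort()
splits = common.splits(cases)

tables = {
    "radiological": pd.read_csv(common.RESULTS / "features_radiological.csv",
                                index_col=0),
    "radiomic": pd.read_csv(common.RESULTS / "features_whole_combat.csv",
                            index_col=0),
    "habitat": pd.read_csv(common.RESULTS / "features_habitat_combat.csv",
                           index_col=0),
}
sigs = {name: md.SignatureModel.from_json(common.RESULTS / f"{name}_signature.json")
        for name in tables}

rows, delong_rows, dca_rows = [], [], []
fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
for si, (split, ids) in enumerate(splits.items()):
    ids = sorted(ids)
    y = meta.loc[ids, "vpi"].to_numpy()
    probs = {}
    for name, sig in sigs.items():
        p, cls = md.predict_signature(sig, tables[name].loc[ids])
        probs[name] = p
        roc = ev.roc_auc(p, y)
        conf = ev.confusion_metrics(cls, y)
        rows.append({
            "split": split, "model": name, "n": len(ids),
            "auc": roc.auc, "ci": f"{roc.ci_low:.3f}-{roc.ci_high:.3f}",
            "brier": ev.brier(p, y), **conf.as_strings(),
        })
        axes[si].plot(roc.fpr, roc.tpr, label=f"{name} ({roc.auc:.3f})")
        dca = ev.decision_curve(p, y)
        dca.insert(0, "model", name)
        dca.insert(0, "split", split)
        dca_rows.append(dca)
    for a, b in [("habitat", "radiomic"), ("habitat", "radiological"),
                 ("radiomic", "radiological")]:
        cmp_ = ev.delong_test(probs[a], probs[b], y)
        delong_rows.append({"split": split, "comparison": f"{a} vs {b}",
                            "z": cmp_.z, "p": cmp_.p})
    axes[si].plot([0, 1], [0, 1], "k:", lw=0.8)
    axes[si].set_title(split)
    axes[si].legend(fontsize=7)

perf = pd.DataFrame(rows)
perf.to_csv(common.RESULTS / "performance.csv", index=False)
pd.DataFrame(delong_rows).to_csv(common.RESULTS / "delong.csv", index=False)
pd.concat(dca_rows).to_csv(common.RESULTS / "decision_curves.csv", index=False)
fig.tight_layout()
fig.savefig(common.RESULTS / "roc_curves.png", dpi=120)

print(perf[["split", "model", "auc", "brier", "sensitivity",
            "specificity"]].to_string(index=False))
print()
print(pd.DataFrame(delong_rows).to_string(index=False))
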