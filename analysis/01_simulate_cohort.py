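"""Generate the synthetic subpleural-nodule cohort and summarise it.

Writes results/cohort.csv (per-case metadata: batch, VPI label, geometry)
and prints the group contrasts the generator is designed to produce:
VPI-positive nodules have larger solid components and longer solid-pleural
contact, while rim texture and core attenuation carry subregion-local
signal.
"""

import numpy as np
import pandas as pd
from scipy import stats

import common

cases = common.cohort()
rows = []
for c in cases:
    g = c.geometry
    rows.append({
        "case_id": c.case_id, "batch_id": c.batch_id, "vpi": c.vpi_label,
        "nodule_type": g.nodule_type, "max_diameter": g.max_diameter,
        "solid_diameter": g.solid_diameter, "ctr": 100 * g.solid_diameter / g.max_diameter,
        "dlp": g.dlp, "pl": g.pl, "spl": g.spl,
        "rim_texture": c.latents["rim_texture"],
        "core_intensity": c.latents["core_intensity"],
    })
meta = pd.DataFrame(rows)
common.RESULTS.mkdir(exist_ok=True)
meta.to_csv(common.RESULTS / "cohort.csv", index=False)

print(f"cohort: {len(meta)} cases, prevalence {meta.vpi.mean():.2f}, "
      f"{meta.nodule_type.value_counts().to_dict()}")
print(f"batches: {meta.batch_id.value_counts().to_dict()}")
for col in ("solid_diameter", "spl", "rim_texture", "core_intensity"):
    neg = meta.loc[meta.vpi == 0, col]
    pos = meta.loc[meta.vpi == 1, col]
    p = stats.mannwhitneyu(neg, pos, alternative="two-sided").pvalue
    print(f"{col:16s} VPI- median {np.median(neg):7.2f}  "
          f"VPI+ median {np.median(pos):7.2f}  p={p:.2e}")
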