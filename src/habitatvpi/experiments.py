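"""Reproducible desk-scale experiments over the pipeline.

These functions recompute, from scratch and under a single seed, the
summary quantities the package is checked against: feature-count contracts,
odds ratios implied by the published signature equations, confusion
percentages from published count fractions, harmonization effectiveness on
default phantom cohorts, DeLong type-I calibration, pipeline determinism,
and the directional habitat-vs-whole-lesion model ordering.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import evaluate as ev
from . import harmonize as hz
from . import phantom as ph
from . import pipeline as pl
from . import preprocess as pp
from . import radiomics as rx

#: Published per-split confusion counts (TP, FN, FP, TN) of the three
#: signature models; the bracketed Table percentages regenerate from these.
PUBLISHED_CONFUSION = {
    ("training", "habitat"): (64, 9, 12, 107),
    ("training", "radiomic"): (61, 12, 19, 100),
    ("training", "radiological"): (58, 15, 29, 90),
    ("validation", "habitat"): (29, 5, 6, 42),
    ("validation", "radiomic"): (26, 8, 8, 40),
    ("validation", "radiological"): (24, 10, 13, 35),
    ("external_test", "habitat"): (13, 2, 4, 20),
    ("external_test", "radiomic"): (11, 4, 5, 19),
    ("external_test", "radiological"): (10, 5, 7, 17),
}


def feature_count_contract(seed: int = 0) -> dict[str, int]:
    """Extract features from one synthetic VOI and count them."""
    cohort = ph.generate_cohort(
        ph.CohortConfig(n_cases=10, vpi_prevalence=0.4, seed=seed)
    )
    case = cohort[0]
    vol, lesion, _norm, _solid, sub = pl.preprocess_case(case, pp.PreprocSpec())
    whole = rx.extract_whole(vol, lesion)
    # a synthetic 3-habitat map from the constructed subregions
    hab = rx.extract_per_habitat(vol, np.where(lesion, sub, 0), n_habitats=3)
    per_habitat = sum(1 for k in hab if k.startswith("Habitat1_"))
    return {
        "whole_lesion": len(whole),
        "per_habitat": per_habitat,
        "habitat_total": len(hab),
    }


def reference_odds_ratios() -> dict[str, float]:
    """Odds ratios implied by the published signature coefficients."""
    sigs = pl.load_reference_signatures()
    return {
        "SPL": sigs["radiological"].odds_ratios()["SPL"],
        "GLCM_ClusterShade": sigs["radiomic"].odds_ratios()["GLCM_ClusterShade"],
        "GLDM_LargeDependenceLowGrayLevelEmphasis":
            sigs["radiomic"].odds_ratios()[
                "GLDM_LargeDependenceLowGrayLevelEmphasis"],
        "Habitat1_firstorder_Skewness":
            sigs["habitat"].odds_ratios()["Habitat1_firstorder_Skewness"],
        "Habitat2_NGTDM_Busyness":
            sigs["habitat"].odds_ratios()["Habitat2_NGTDM_Busyness"],
    }


def published_confusion_percentages() -> dict[str, dict[str, str]]:
    """Regenerate the bracketed percentages from the published count fractions."""
    out = {}
    for (split, model), (tp, fn, fp, tn) in PUBLISHED_CONFUSION.items():
        y = np.array([1] * (tp + fn) + [0] * (fp + tn))
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        out[f"{split}_{model}"] = ev.confusion_metrics(pred, y).as_strings()
    return out


def harmonization_effectiveness(seed: int = 0, n_cases: int = 60) -> hz.BatchAudit:
    """Batch-R² audit of ComBat on a default 5-batch phantom cohort."""
    cohort = ph.generate_cohort(
        ph.CohortConfig(n_cases=n_cases, vpi_prevalence=0.4, seed=seed)
    )
    import pandas as pd

    rows, batch = {}, {}
    for case in cohort:
        vol, lesion, *_ = pl.preprocess_case(case, pp.PreprocSpec())
        rows[case.case_id] = rx.extract_whole(vol, lesion)
        batch[case.case_id] = case.batch_id
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    batch = pd.Series(batch).loc[table.index]
    adj = hz.apply_combat(hz.fit_combat(table, batch), table, batch)
    return hz.audit_harmonization(table, adj, batch)


def delong_type1_rate(seed: int = 0, reps: int = 2000, n: int = 150,
                      alpha: float = 0.05) -> float:
    """Null rejection rate of the paired DeLong test.

    Two noisy copies of the same latent score predict the same labels; the
    AUC difference is null by construction.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        latent = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-latent))).astype(int)
        if y.min() == y.max():
            continue
        a = latent + rng.normal(0, 1.0, n)
        b = latent + rng.normal(0, 1.0, n)
        try:
            cmp_ = ev.delong_test(a, b, y)
        except ValueError:
            continue
        rejections += cmp_.p < alpha
    return rejections / reps


def pipeline_determinism(seed: int = 0, n_cases: int = 60):
    """Run the full pipeline twice under one seed; compare the manifests."""
    def _run():
        cfg = pl.RunConfig(
            cohort=ph.CohortConfig(n_cases=n_cases, vpi_prevalence=0.4,
                                   seed=seed),
            seed=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pl.run_pipeline(cfg)

    r1, r2 = _run(), _run()
    m1 = {k: v for k, v in r1.manifest.items() if k != "wall_clock_s"}
    m2 = {k: v for k, v in r2.manifest.items() if k != "wall_clock_s"}
    return m1 == m2, r1, r2


def habitat_model_ordering(seed: int = 0, n_seeds: int = 20,
                           n_cases: int = 150) -> dict:
    """Training-AUC ordering of habitat vs whole-lesion signatures.

    Runs ``n_seeds`` independently generated cohorts and counts how often
    the habitat signature's training AUC is at least the whole-lesion
    radiomic signature's.
    """
    wins = 0
    habitat_aucs, radiomic_aucs, radiological_aucs = [], [], []
    for i in range(n_seeds):
        cfg = pl.RunConfig(
            cohort=ph.CohortConfig(n_cases=n_cases, vpi_prevalence=0.4,
                                   seed=seed * 1009 + i),
            seed=seed + i, val_frac=0.2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pl.run_pipeline(cfg)
        tr = res.report[res.report["split"] == "train"].set_index("model")["auc"]
        wins += tr["habitat"] >= tr["radiomic"]
        habitat_aucs.append(tr["habitat"])
        radiomic_aucs.append(tr["radiomic"])
        radiological_aucs.append(tr["radiological"])
    return {
        "win_fraction": wins / n_seeds,
        "mean_auc_habitat": float(np.mean(habitat_aucs)),
        "mean_auc_radiomic": float(np.mean(radiomic_aucs)),
        "mean_auc_radiological": float(np.mean(radiological_aucs)),
        "n_seeds": n_seeds,
        "n_cases": n_cases,
    }
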