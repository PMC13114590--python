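"""End-to-end orchestration, cohort I/O and model serialization.

``run_pipeline`` executes the full analysis on a (synthetic or loaded)
cohort: preprocessing, habitat clustering frozen on the training split,
whole-lesion and per-habitat feature extraction, missing-habitat imputation,
ComBat harmonization (fitted on training, applied frozen), the four-step
feature selection, the three logistic signatures, and the evaluation
report.  A manifest of content hashes makes determinism checkable: two runs
with the same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import habitat as hb
from . import harmonize as hz
from . import modeling as md
from . import phantom as ph
from . import preprocess as pp
from . import radiomics as rx

RADIOLOGICAL_FEATURES = ["max_diameter", "solid_diameter", "ctr", "dlp", "pl", "spl"]


@dataclass
class RunConfig:
    """Pipeline parameters; every stochastic stage derives its seed from ``seed``."""

    cohort: ph.CohortConfig = field(default_factory=ph.CohortConfig)
    val_frac: float = 0.3
    test_frac: float = 0.0
    k_habitats: int | None = 3   # None: choose by Davies-Bouldin argmin
    k_range: tuple[int, int] = (2, 6)
    n_superpixels: int = 50
    compactness: float = 0.1
    n_bins: int = 25
    harmonize: bool = True
    mrmr_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_frac < 1 or not 0 <= self.test_frac < 1:
            raise ValueError("invalid split fractions")
        if self.val_frac + self.test_frac >= 1:
            raise ValueError("split fractions must leave a training set")


@dataclass
class PipelineResult:
    manifest: dict[str, str]
    splits: dict[str, list[str]]
    cluster_model: hb.ClusterModel
    signatures: dict[str, md.SignatureModel]
    combat_models: dict[str, hz.CombatModel]
    feature_tables: dict[str, pd.DataFrame]
    predictions: pd.DataFrame
    report: pd.DataFrame
    delong: pd.DataFrame
    imputed_blocks: dict[str, int]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, df.columns)).encode())
    h.update(",".join(map(str, df.index)).encode())
    h.update(np.ascontiguousarray(df.to_numpy(float)).tobytes())
    return h.hexdigest()


def split_cohort(
    case_ids: list[str], val_frac: float, test_frac: float
) -> dict[str, list[str]]:
    """Deterministic case-id-sorted split (emulates a scan-date ordering)."""
    ids = sorted(case_ids)
    n = len(ids)
    n_test = int(round(test_frac * n))
    n_val = int(round(val_frac * n))
    n_train = n - n_val - n_test
    out = {"train": ids[:n_train], "validation": ids[n_train:n_train + n_val]}
    if n_test:
        out["test"] = ids[n_train + n_val:]
    return out


def preprocess_case(case: ph.PhantomCase, spec: pp.PreprocSpec):
    """Resample to the common grid and build both intensity paths.

    Returns (resampled HU volume, lesion mask, habitat-path normalized
    volume, solid mask, subregion truth) all on the target grid.
    """
    vol = pp.resample_isotropic(case.volume, spec)
    lesion = pp.resample_isotropic(
        pp.CTVolume(case.lesion_mask.astype(float), case.volume.spacing,
                    case.volume.origin), spec, is_mask=True
    ).data.astype(bool)
    solid = pp.resample_isotropic(
        pp.CTVolume(case.solid_mask.astype(float), case.volume.spacing,
                    case.volume.origin), spec, is_mask=True
    ).data.astype(bool)
    sub = pp.resample_isotropic(
        pp.CTVolume(case.subregion_truth.astype(float), case.volume.spacing,
                    case.volume.origin), spec, is_mask=True
    ).data.astype(np.int8)
    norm = pp.znormalize(pp.clip_window(vol, spec), lesion)
    return vol, lesion, norm, solid, sub


def run_pipeline(config: RunConfig) -> PipelineResult:
    t0 = time.time()
    manifest: dict[str, str] = {}
    spec = pp.PreprocSpec(n_bins=config.n_bins)
    cohort = ph.generate_cohort(config.cohort)
    manifest["simulate"] = _hash_array(
        np.concatenate([c.volume.data.ravel()[:1000] for c in cohort])
    )

    splits = split_cohort([c.case_id for c in cohort], config.val_frac,
                          config.test_frac)
    by_id = {c.case_id: c for c in cohort}

    # --- preprocessing + habitat clustering (frozen on train) ---------------
    pre: dict[str, tuple] = {}
    spmaps: dict[str, hb.SuperpixelMap] = {}
    spfeats: dict[str, pd.DataFrame] = {}
    for cid, case in by_id.items():
        vol, lesion, norm, solid, sub = preprocess_case(case, spec)
        pre[cid] = (vol, lesion, norm, solid, sub)
        spmap = hb.slic3d(norm, lesion, config.n_superpixels, config.compactness)
        spmaps[cid] = spmap
        spfeats[cid] = hb.superpixel_features(norm, spmap)

    train_pool = pd.concat([spfeats[cid] for cid in splits["train"]],
                           ignore_index=True)
    if config.k_habitats is None:
        k, curve = hb.select_k(train_pool, range(*config.k_range), seed=config.seed)
    else:
        k, curve = config.k_habitats, {}
    cluster_model = hb.fit_habitat_model(train_pool, k, seed=config.seed,
                                         db_curve=curve)
    manifest["habitat_model"] = _hash_array(cluster_model.centroids)

    # --- feature extraction -------------------------------------------------
    radiological_rows, whole_rows, habitat_rows = {}, {}, {}
    for cid, case in by_id.items():
        vol, lesion, norm, solid, sub = pre[cid]
        hmap = hb.assign_habitats(norm, spmaps[cid], cluster_model)
        meas = ph.measure_radiological(case)
        radiological_rows[cid] = {f: meas[f] for f in RADIOLOGICAL_FEATURES}
        whole_rows[cid] = rx.extract_whole(vol, lesion, config.n_bins)
        habitat_rows[cid] = rx.extract_per_habitat(vol, hmap, k, config.n_bins)

    ids_order = sorted(by_id)
    radiological = pd.DataFrame.from_dict(radiological_rows, orient="index").loc[ids_order]
    whole = pd.DataFrame.from_dict(whole_rows, orient="index").loc[ids_order]
    habitat_tbl = pd.DataFrame.from_dict(habitat_rows, orient="index").loc[ids_order]
    manifest["features_whole"] = _hash_df(whole)
    manifest["features_habitat_raw"] = _hash_df(habitat_tbl.fillna(-9e9))

    # --- missing-habitat imputation (per split, missForest-style) ----------
    imputed_blocks: dict[str, int] = {}
    filled_parts = []
    for s, ids in splits.items():
        part = habitat_tbl.loc[ids]
        n_blocks = sum(
            part.loc[cid, [c for c in part.columns if c.startswith(f"Habitat{h}_")]]
            .isna().all()
            for cid in ids for h in range(1, k + 1)
        )
        imputed_blocks[s] = int(n_blocks)
        filled_parts.append(
            hb.impute_missing_habitats(part, seed=config.seed) if part.isna().any().any()
            else part
        )
    habitat_tbl = pd.concat(filled_parts).loc[ids_order]
    manifest["features_habitat"] = _hash_df(habitat_tbl)

    # --- harmonization (fit on train, frozen elsewhere) ---------------------
    batch = pd.Series({cid: by_id[cid].batch_id for cid in ids_order}).loc[ids_order]
    combat_models: dict[str, hz.CombatModel] = {}
    if config.harmonize:
        for label, tbl in [("whole", whole), ("habitat", habitat_tbl)]:
            model = hz.fit_combat(tbl.loc[splits["train"]],
                                  batch.loc[splits["train"]])
            combat_models[label] = model
            adj = hz.apply_combat(model, tbl, batch)
            if label == "whole":
                whole = adj
            else:
                habitat_tbl = adj
        manifest["harmonize"] = _hash_df(whole)

    # --- z-scoring with train stats + selection + signatures ----------------
    y = pd.Series({cid: by_id[cid].vpi_label for cid in ids_order}).loc[ids_order]
    y_train = y.loc[splits["train"]].to_numpy()

    signatures: dict[str, md.SignatureModel] = {}
    tables = {"radiological": radiological, "radiomic": whole, "habitat": habitat_tbl}
    for label in ("radiomic", "habitat"):
        tbl = tables[label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ztrain, stats_ = rx.zscore_features(tbl.loc[splits["train"]])
            zfull, _ = rx.zscore_features(tbl, stats_)
        trace = md.select_features(ztrain, y_train, seed=config.seed,
                                   mrmr_k=config.mrmr_k)
        selected = trace.final
        if not selected:  # fall back to the last non-empty selection stage
            selected = next(
                (s for _, s in reversed(trace.steps) if s), list(ztrain.columns)
            )[: config.mrmr_k]
        sig = md.backward_logistic(zfull.loc[splits["train"], selected],
                                   y_train, name=label, min_features=1)
        sig.feature_stats = {c: stats_[c] for c in sig.coefficients}
        signatures[label] = sig
        tables[label] = tbl

    signatures["radiological"] = md.backward_logistic(
        radiological.loc[splits["train"]], y_train, name="radiological",
        min_features=1,
    )

    # --- evaluation ----------------------------------------------------------
    pred_rows = []
    report_rows = []
    delong_rows = []
    probs_by_split: dict[str, dict[str, np.ndarray]] = {}
    for s, ids in splits.items():
        probs_by_split[s] = {}
        ys = y.loc[ids].to_numpy()
        for label, sig in signatures.items():
            p, cls = md.predict_signature(sig, tables[label].loc[ids])
            probs_by_split[s][label] = p
            roc = ev.roc_auc(p, ys)
            conf = ev.confusion_metrics(cls, ys)
            report_rows.append({
                "split": s, "model": label, "n": len(ids),
                "auc": roc.auc, "auc_ci_low": roc.ci_low, "auc_ci_high": roc.ci_high,
                "brier": ev.brier(p, ys), "cutoff": sig.cutoff,
                **conf.as_strings(),
            })
            for cid, pi, ci_ in zip(ids, p, cls):
                pred_rows.append({"case_id": cid, "split": s, "model": label,
                                  "prob": pi, "class": int(ci_),
                                  "vpi": int(y.loc[cid])})
        for a, b in [("habitat", "radiomic"), ("habitat", "radiological"),
                     ("radiomic", "radiological")]:
            cmp_ = ev.delong_test(probs_by_split[s][a], probs_by_split[s][b], ys)
            delong_rows.append({"split": s, "model_a": a, "model_b": b,
                                "auc_a": cmp_.auc_a, "auc_b": cmp_.auc_b,
                                "z": cmp_.z, "p": cmp_.p})

    predictions = pd.DataFrame(pred_rows)
    report = pd.DataFrame(report_rows)
    delong = pd.DataFrame(delong_rows)
    manifest["predictions"] = _hash_df(
        predictions.set_index(["case_id", "model", "split"])[["prob"]]
    )
    manifest["signatures"] = hashlib.sha256(json.dumps(
        {n: [s.intercept, s.coefficients, s.cutoff] for n, s in signatures.items()},
        sort_keys=True).encode()).hexdigest()
    manifest["wall_clock_s"] = f"{time.time() - t0:.1f}"
    return PipelineResult(
        manifest=manifest, splits=splits, cluster_model=cluster_model,
        signatures=signatures, combat_models=combat_models,
        feature_tables=tables, predictions=predictions, report=report,
        delong=delong, imputed_blocks=imputed_blocks,
    )


# ---------------------------------------------------------------------------
# NIfTI cohort I/O


def write_cohort(cases: list[ph.PhantomCase], outdir) -> Path:
    """Write volumes/masks as NIfTI (.nii.gz) plus a metadata CSV."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        affine = np.diag(list(case.volume.spacing) + [1.0])
        affine[:3, 3] = case.volume.origin
        nib.save(nib.Nifti1Image(case.volume.data.astype(np.float32), affine),
                 outdir / f"{case.case_id}_ct.nii.gz")
        for name, arr in [("lesion", case.lesion_mask), ("solid", case.solid_mask),
                          ("subregions", case.subregion_truth)]:
            nib.save(nib.Nifti1Image(arr.astype(np.uint8), affine),
                     outdir / f"{case.case_id}_{name}.nii.gz")
        g = case.geometry
        rows.append({
            "case_id": case.case_id, "batch_id": case.batch_id,
            "vpi": case.vpi_label, "max_diameter": g.max_diameter,
            "solid_diameter": g.solid_diameter, "dlp": g.dlp, "pl": g.pl,
            "spl": g.spl, "nodule_type": g.nodule_type,
            "pleura_plane_z": g.pleura_plane_z,
        })
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    return outdir


def read_cohort(path) -> list[ph.PhantomCase]:
    """Load a cohort written by :func:`write_cohort`; validates grids."""
    import nibabel as nib

    path = Path(path)
    meta = pd.read_csv(path / "cohort.csv")
    required = {"case_id", "batch_id", "vpi"}
    if not required <= set(meta.columns):
        raise ValueError(f"cohort.csv missing columns: {required - set(meta.columns)}")
    cases = []
    for _, row in meta.iterrows():
        cid = row["case_id"]
        img = nib.load(path / f"{cid}_ct.nii.gz")
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        vol = pp.CTVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)
        masks = {}
        for name in ("lesion", "solid", "subregions"):
            m = nib.load(path / f"{cid}_{name}.nii.gz")
            arr = np.asarray(m.dataobj)
            if arr.shape != vol.data.shape:
                raise ValueError(f"case {cid}: {name} mask grid differs from volume")
            masks[name] = arr
        geom = ph.NoduleGeometry(
            center=(0.0, 0.0, 0.0), max_diameter=row["max_diameter"],
            solid_diameter=row["solid_diameter"],
            pleura_plane_z=row.get("pleura_plane_z", 0.0), dlp=row["dlp"],
            pl=row["pl"], spl=row["spl"], nodule_type=row["nodule_type"],
        )
        cases.append(ph.PhantomCase(
            case_id=cid, volume=vol, lesion_mask=masks["lesion"].astype(bool),
            solid_mask=masks["solid"].astype(bool),
            subregion_truth=masks["subregions"].astype(np.int8), geometry=geom,
            batch_id=row["batch_id"], vpi_label=int(row["vpi"]),
        ))
    return cases


# ---------------------------------------------------------------------------
# model serialization


def serialize_models(cluster_model: hb.ClusterModel,
                     signatures: dict[str, md.SignatureModel], path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cluster_model.to_json(path / "cluster_model.json")
    for name, sig in signatures.items():
        sig.to_json(path / f"{name}_signature.json")
    return path


def load_models(path) -> tuple[hb.ClusterModel, dict[str, md.SignatureModel]]:
    path = Path(path)
    cluster = hb.ClusterModel.from_json(path / "cluster_model.json")
    sigs = {}
    for f in sorted(path.glob("*_signature.json")):
        sig = md.SignatureModel.from_json(f)
        sigs[sig.name] = sig
    return cluster, sigs


def load_reference_signatures() -> dict[str, md.SignatureModel]:
    """The three published signature equations shipped with the package."""
    out = {}
    base = resources.files("habitatvpi") / "reference"
    for name in ("radiological", "radiomic", "habitat"):
        with resources.as_file(base / f"{name}_signature.json") as f:
            out[name] = md.SignatureModel.from_json(f)
    return out
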