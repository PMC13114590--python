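"""Synthetic subpleural-nodule cohort generator.

Real multicenter LDCT data for this problem are not publicly deposited, so
every downstream stage is exercised on digital phantoms that carry the same
signal structure the analysis assumes:

* a subpleural nodule (sphere with perturbed concentric subregions) abutting
  or near an axis-aligned pleural plane at z = 0 (lung at z > 0);
* three latent intensity subregions — peripheral rim, transition zone and
  dense core — with increasing mean attenuation, plus a brighter solid
  component (part-solid vs solid composition);
* per-scanner batch effects (multiplicative scale then additive HU shift,
  then extra noise) over five center–scanner batches;
* a visceral-pleural-invasion (VPI) label drawn from a logistic model on
  standardized covariates: solid-component diameter, solid–pleural contact
  length (SPL), a rim-texture latent (spatial correlation length of the rim
  noise) and a core-attenuation latent — so most of the label signal is
  subregion-local, while label-independent nuisance heterogeneity in the
  transition zone confounds whole-lesion summaries of it;
* per-case subregion composition: the normalized radii of the core and
  transition boundaries are drawn per nodule, so lesions differ in how much
  rim/transition/core they contain.

Every random quantity flows from a single seed; regeneration with the same
config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .preprocess import CTVolume

RIM, TRANSITION, CORE = 1, 2, 3

HU_MIN, HU_MAX = -1024.0, 400.0


@dataclass
class NoduleGeometry:
    """Ground-truth geometric measurements of one nodule (all mm)."""

    center: tuple[float, float, float]
    max_diameter: float
    solid_diameter: float
    pleura_plane_z: float
    dlp: float  # shortest lesion-to-pleura distance (>= 0)
    pl: float   # lesion-pleura contact length
    spl: float  # solid-component-pleura contact length
    nodule_type: str  # "part_solid" | "solid"

    def __post_init__(self) -> None:
        if self.solid_diameter > self.max_diameter + 1e-9:
            raise ValueError("solid_diameter must be <= max_diameter")
        if self.spl > self.pl + 1e-9:
            raise ValueError("spl must be <= pl")
        if self.max_diameter >= 30.0:
            raise ValueError("nodules with diameter >= 30 mm are excluded")
        if self.dlp > 0 and (self.pl > 0 or self.spl > 0):
            raise ValueError("a detached lesion (dlp > 0) cannot have pleural contact")


@dataclass
class BatchSpec:
    """Per-scanner intensity distortion: HU' = HU*scale + shift + N(0, sd)."""

    shift: float = 0.0
    scale: float = 1.0
    noise_sd: float = 0.0


DEFAULT_BATCHES: dict[str, BatchSpec] = {
    "C1-S1": BatchSpec(0.0, 1.00, 0.0),
    "C1-S2": BatchSpec(15.0, 1.05, 8.0),
    "C2-S1": BatchSpec(-12.0, 0.97, 5.0),
    "C2-S2": BatchSpec(8.0, 1.02, 10.0),
    "C3-S1": BatchSpec(-20.0, 0.94, 6.0),
}

DEFAULT_EFFECTS: dict[str, float] = {
    "solid_diameter": 0.5,
    "spl": 0.4,
    "rim_texture": 1.5,
    "core_intensity": 1.2,
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 192
    vpi_prevalence: float = 0.38
    batch_specs: dict[str, BatchSpec] = field(
        default_factory=lambda: dict(DEFAULT_BATCHES)
    )
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    seed: int = 0
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.0)
    margin_mm: float = 4.0
    # subregion mean attenuation (HU), part-solid composition
    rim_hu: float = -600.0
    transition_hu: float = -300.0
    core_hu: float = 20.0
    solid_boost_hu: float = 280.0
    base_noise_sd: float = 45.0
    rim_texture_scale: float = 0.5  # texture correlation length = 0.8*exp(scale*latent)
    core_shift_hu: float = 60.0     # core mean offset per unit of the core latent
    # per-case subregion composition (normalized radius thresholds): tumors
    # differ in how much rim/transition/core they contain, which dilutes
    # whole-lesion summaries of subregion-local properties
    core_radius_range: tuple[float, float] = (0.40, 0.60)
    transition_radius_range: tuple[float, float] = (0.70, 0.88)
    part_solid_fraction: float = 0.6
    contact_fraction: float = 0.65

    def __post_init__(self) -> None:
        if not (0.0 < self.vpi_prevalence < 1.0):
            raise ValueError("vpi_prevalence must lie in (0, 1)")
        if self.n_cases < 2 * len(self.batch_specs):
            raise ValueError("need at least 2 cases per batch")


@dataclass
class PhantomCase:
    case_id: str
    volume: CTVolume
    lesion_mask: np.ndarray
    solid_mask: np.ndarray
    subregion_truth: np.ndarray
    geometry: NoduleGeometry
    batch_id: str
    vpi_label: int
    latents: dict[str, float] = field(default_factory=dict)


def _smooth_noise(shape, rng: np.random.Generator, sigma: float = 2.0) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _simulate_case(
    cfg: CohortConfig, rng: np.random.Generator, case_id: str, batch_id: str
) -> PhantomCase:
    sp = np.asarray(cfg.spacing)
    r = rng.uniform(5.0, 14.0)  # nodule radius, mm (diameter 10-28 < 30)
    part_solid = rng.random() < cfg.part_solid_fraction
    solid_frac = rng.uniform(0.3, 0.85) if part_solid else rng.uniform(0.85, 1.0)
    rs = solid_frac * r
    contact = rng.random() < cfg.contact_fraction
    if contact:
        zc = rng.uniform(0.4 * r, 0.95 * r)  # center height above pleura: plane cuts sphere
        dlp = 0.0
    else:
        dlp = rng.uniform(0.5, 6.0)
        zc = r + dlp

    ext_xy = 2 * r + 2 * cfg.margin_mm
    ext_z = zc + r + 2 * cfg.margin_mm
    shape = (
        int(np.ceil(ext_xy / sp[0])),
        int(np.ceil(ext_xy / sp[1])),
        int(np.ceil(ext_z / sp[2])),
    )
    origin = (-ext_xy / 2, -ext_xy / 2, -cfg.margin_mm)
    xs = origin[0] + np.arange(shape[0]) * sp[0]
    ys = origin[1] + np.arange(shape[1]) * sp[1]
    zs_ = origin[2] + np.arange(shape[2]) * sp[2]
    X, Y, Z = np.meshgrid(xs, ys, zs_, indexing="ij")

    center = (0.0, 0.0, float(zc))
    dist = np.sqrt(X**2 + Y**2 + (Z - zc) ** 2)
    lung = Z >= 0  # pleural plane at z = 0
    lesion = (dist <= r) & lung
    solid = (dist <= rs) & lung

    # concentric subregions with stochastic boundary perturbation and
    # per-case composition (threshold radii drawn per nodule)
    rho = dist / r
    rho = rho * (1.0 + 0.05 * _smooth_noise(shape, rng))
    r_core = rng.uniform(*cfg.core_radius_range)
    r_trans = rng.uniform(*cfg.transition_radius_range)
    sub = np.zeros(shape, dtype=np.int8)
    sub[lesion] = RIM
    sub[lesion & (rho < r_trans)] = TRANSITION
    sub[lesion & (rho < r_core)] = CORE

    # latents driving the label signal: rim-texture roughness and a
    # core-attenuation offset, each local to one subregion; plus
    # label-independent nuisance heterogeneity in the transition zone that
    # confounds whole-lesion summaries of those signals
    z_tex = float(rng.standard_normal())
    z_core = float(rng.standard_normal())
    z_nuis_tex = float(rng.standard_normal())
    z_nuis_mean = float(rng.standard_normal())
    # texture latents set the spatial correlation length of the noise in
    # their subregion (coarse vs fine texture at fixed amplitude), which
    # survives the fixed-bin-count discretization of texture extraction
    rim_sigma = 0.8 * np.exp(cfg.rim_texture_scale * z_tex)
    trans_sigma = 0.8 * np.exp(cfg.rim_texture_scale * z_nuis_tex)

    hu = np.where(Z >= 0, -850.0, 40.0)  # lung parenchyma above, chest wall below
    means = {RIM: cfg.rim_hu, TRANSITION: cfg.transition_hu, CORE: cfg.core_hu}
    if not part_solid:
        means = {RIM: -280.0, TRANSITION: -80.0, CORE: 100.0}
    means[CORE] = means[CORE] + cfg.core_shift_hu * z_core
    means[TRANSITION] = means[TRANSITION] + cfg.core_shift_hu * z_nuis_mean
    for lab, mu in means.items():
        hu[sub == lab] = mu
    hu[solid & lesion] += cfg.solid_boost_hu if part_solid else 80.0

    noise = rng.standard_normal(shape) * 40.0
    noise[lesion] = rng.standard_normal(int(lesion.sum())) * cfg.base_noise_sd
    rim_vox = sub == RIM
    rim_field = _smooth_noise(shape, rng, sigma=rim_sigma)
    noise[rim_vox] = rim_field[rim_vox] * cfg.base_noise_sd
    trans_vox = sub == TRANSITION
    trans_field = _smooth_noise(shape, rng, sigma=trans_sigma)
    noise[trans_vox] = trans_field[trans_vox] * cfg.base_noise_sd
    hu = hu + noise

    # analytic contact lengths (chord of sphere cut by the pleural plane)
    pl = 2.0 * np.sqrt(max(r**2 - zc**2, 0.0)) if zc < r else 0.0
    spl = 2.0 * np.sqrt(max(rs**2 - zc**2, 0.0)) if zc < rs else 0.0

    geom = NoduleGeometry(
        center=center,
        max_diameter=2 * r,
        solid_diameter=2 * rs,
        pleura_plane_z=0.0,
        dlp=dlp,
        pl=pl,
        spl=spl,
        nodule_type="part_solid" if part_solid else "solid",
    )
    vol = CTVolume(hu, tuple(sp), origin)
    return PhantomCase(
        case_id=case_id,
        volume=vol,
        lesion_mask=lesion,
        solid_mask=solid & lesion,
        subregion_truth=sub,
        geometry=geom,
        batch_id=batch_id,
        vpi_label=0,  # assigned at cohort level
        latents={"rim_texture": z_tex, "rim_noise_sigma": float(rim_sigma),
                 "core_intensity": z_core,
                 "transition_texture_nuisance": z_nuis_tex,
                 "transition_mean_nuisance": z_nuis_mean},
    )


def _solve_intercept(logits: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept making mean sigmoid(b0 + logits) = prevalence."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(mid + logits)))).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: CohortConfig) -> list[PhantomCase]:
    """Generate a reproducible synthetic cohort.

    The VPI label is drawn from a logistic model on the configured covariates,
    standardized within the cohort so the effect sizes are scale-free; the
    intercept is solved so the expected prevalence matches the config.  Batch
    effects are applied to the HU volumes after label assignment (the label
    depends on anatomy, not on the scanner).
    """
    rng = np.random.default_rng(config.seed)
    batches = list(config.batch_specs)
    batch_ids = [batches[i % len(batches)] for i in range(config.n_cases)]
    rng.shuffle(batch_ids)
    cases = [
        _simulate_case(config, rng, f"case{i:04d}", batch_ids[i])
        for i in range(config.n_cases)
    ]

    cov_map = {
        "solid_diameter": np.array([c.geometry.solid_diameter for c in cases]),
        "spl": np.array([c.geometry.spl for c in cases]),
        "rim_texture": np.array([c.latents["rim_texture"] for c in cases]),
        "core_intensity": np.array([c.latents["core_intensity"] for c in cases]),
    }
    logits = np.zeros(config.n_cases)
    for name, beta in config.effect_sizes.items():
        x = cov_map[name]
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        logits = logits + beta * z
    b0 = _solve_intercept(logits, config.vpi_prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + logits)))
    labels = (rng.random(config.n_cases) < p).astype(int)

    for i, (case, y) in enumerate(zip(cases, labels)):
        case.vpi_label = int(y)
        spec = config.batch_specs[case.batch_id]
        hu = case.volume.data * spec.scale + spec.shift
        if spec.noise_sd > 0:
            hu = hu + rng.standard_normal(hu.shape) * spec.noise_sd
        case.volume.data = np.clip(hu, HU_MIN, HU_MAX)
        case.latents["vpi_prob"] = float(p[i])
    return cases


# ---------------------------------------------------------------------------
# radiological measurement on the voxel grid


def _max_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    if len(pts) > 300 and pts.shape[1] >= 2:
        try:
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _world_coords(mask: np.ndarray, vol: CTVolume) -> np.ndarray:
    idx = np.argwhere(mask).astype(float)
    return idx * np.asarray(vol.spacing) + np.asarray(vol.origin)


def measure_radiological(case: PhantomCase) -> dict[str, float]:
    """Measure the radiological metrics from the voxel masks (mm / percent).

    Diameters are maximal pairwise distances over mask voxels; the
    lesion-to-pleura distance and contact lengths are taken against the
    axis-aligned pleural plane (contact = maximal in-plane chord of the mask
    restricted to the plane-adjacent voxel layer).
    """
    if not case.lesion_mask.any():
        raise ValueError("empty lesion mask")
    vol = case.volume
    plane_z = case.geometry.pleura_plane_z
    lesion_xyz = _world_coords(case.lesion_mask, vol)
    max_d = _max_pairwise(lesion_xyz)
    solid_xyz = _world_coords(case.solid_mask, vol)
    solid_d = _max_pairwise(solid_xyz) if len(solid_xyz) else 0.0

    dz = np.asarray(vol.spacing)[2]
    dlp = max(0.0, float(lesion_xyz[:, 2].min() - plane_z))
    if dlp < dz:  # touching within one voxel layer
        dlp_measured = 0.0 if dlp < dz / 2 else dlp
    else:
        dlp_measured = dlp

    def _contact(xyz: np.ndarray) -> float:
        if len(xyz) == 0:
            return 0.0
        layer = xyz[np.abs(xyz[:, 2] - plane_z) < dz]
        if len(layer) < 2:
            return 0.0
        return _max_pairwise(layer[:, :2])

    pl = _contact(lesion_xyz) if dlp_measured == 0 else 0.0
    spl = _contact(solid_xyz) if dlp_measured == 0 else 0.0
    ctr = 100.0 * solid_d / max_d if max_d > 0 else 0.0
    return {
        "max_diameter": max_d,
        "solid_diameter": solid_d,
        "dlp": dlp_measured,
        "pl": pl,
        "spl": min(spl, pl),
        "ctr": ctr,
    }


def ctr_percent(solid_diameter: float, max_diameter: float) -> float:
    """Consolidation-to-tumor ratio: (solid diameter / maximal diameter) x 100%."""
    if max_diameter <= 0:
        raise ValueError("max_diameter must be positive")
    return 100.0 * solid_diameter / max_diameter


def rater_noise(
    measurements: np.ndarray, sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent rater replicates: truth + N(0, sd^2) jitter each."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    m = np.asarray(measurements, dtype=float)
    return m + rng.standard_normal(m.shape) * sd, m + rng.standard_normal(m.shape) * sd
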