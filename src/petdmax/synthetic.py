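"""Synthetic phantom cohorts with ground truth.

Each phantom patient is a whole-body SUV grid: a low-SUV noisy background
(well below the segmentation threshold) carrying hyper-metabolic lesions
modelled as solid uniform-plateau balls — one primary tumor in a chest
sub-box, metastatic lymph nodes near it, and distant metastases anywhere in
the body box.  Survival outcomes follow a proportional-hazards model whose
linear predictor is driven by the true dissemination distance (Dmax, cm)
and log total metabolic tumor volume, so that every downstream stage of the
analysis has an exact oracle.

Uniform plateaus (rather than realistic textures) keep every feature
formula exactly recoverable: the threshold geometry the analysis depends on
is exercised while SUVmean == SUVmax == the sampled plateau.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PatientFeatures, aggregate_patient
from .io import SUVVolume, write_suv_volume
from .segmentation import Lesion, LesionSet, SegmentationConfig, _centroid_mm

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "SurvivalDraw",
    "generate_patient",
    "generate_survival",
    "generate_cohort",
    "sample_feature_table",
]

#: Clinical covariate frequencies emulating an advanced-NSCLC cohort
#: (majority male, adenocarcinoma the most common histology, stage IVB the
#: most represented).  These covariates carry no effect in the hazard model.
HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous", "large_cell", "nos")
HISTOLOGY_PROBS = (41 / 78, 17 / 78, 3 / 78, 17 / 78)
STAGE_LEVELS = ("IIIA", "IIIB", "IIIC", "IVA", "IVB")
STAGE_PROBS = (2 / 78, 9 / 78, 5 / 78, 19 / 78, 43 / 78)
MALE_PROB = 55 / 78


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the phantom cohort.

    Geometry is a nested-boxes abstraction of a whole body: the primary
    lesion is placed in a central "chest" sub-box, nodes within
    ``node_distance_mm`` of the primary, distant lesions anywhere inside the
    body box.  Lesion centres are kept far enough apart that distinct truth
    lesions never merge under segmentation, unless ``coalescent_pair`` asks
    for one deliberately overlapping nodal conglomerate (which is then a
    single truth lesion).
    """

    n_patients: int = 78
    shape: tuple[int, int, int] = (48, 48, 168)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    axial_axis: int = 2
    background_mean: float = 0.8
    background_sd: float = 0.2
    n_nodes_mean: float = 2.2
    n_distant_mean: float = 2.4
    max_lesions: int = 12
    radius_range_mm: tuple[float, float] = (6.0, 20.0)
    peak_suv_range: tuple[float, float] = (4.0, 15.0)
    node_distance_mm: float = 90.0
    chest_fraction: tuple[float, float] = (0.55, 0.85)  # axial band for the primary
    coalescent_pair: bool = False
    suv_threshold: float = 2.5
    recoverable_margin: float = 1.0
    # proportional-hazards outcome model (time unit: months)
    baseline_rate: float = 7e-4
    beta_dmax: float = 0.1        # per cm of dissemination
    beta_logmtv: float = 0.3      # per log-mL of total tumor volume
    pfs_rate_multiplier: float = 1.5
    horizon_months: float = 43.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline hazard rate must be positive")
        if self.peak_suv_range[0] < self.suv_threshold + self.recoverable_margin:
            raise ValueError(
                "lesion plateau SUV must exceed the segmentation threshold "
                f"by at least {self.recoverable_margin} so truth lesions are "
                "recoverable")
        if self.horizon_months < 0:
            raise ValueError("censoring horizon must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Per-patient ground truth: lesion geometry and noiseless features.

    ``features`` is exactly what the features module computes on the
    noiseless label volume, so it is the oracle for end-to-end recovery.
    """

    patient_id: str
    lesion_set: LesionSet
    classes: dict
    features: PatientFeatures


@dataclass(frozen=True)
class SurvivalDraw:
    os_months: float
    os_event: int
    pfs_months: float
    pfs_event: int
    linear_predictor: float
    uncensored_event_months: float


def _rasterize_ball(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    """(n, 3) indices of voxels whose centres lie within the ball."""
    spacing = np.asarray(spacing, dtype=float)
    lo = np.maximum(np.floor((center_mm - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + radius_mm) / spacing).astype(int) + 1,
                    np.asarray(shape))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    inside = np.linalg.norm(idx * spacing - center_mm, axis=1) <= radius_mm
    return idx[inside]


def _sample_center(rng, shape, spacing, margin_mm, axial_axis,
                   axial_band=None) -> np.ndarray:
    extent = np.asarray(shape) * np.asarray(spacing)
    lo = np.full(3, margin_mm)
    hi = extent - margin_mm
    if axial_band is not None:
        lo[axial_axis] = max(lo[axial_axis], axial_band[0] * extent[axial_axis])
        hi[axial_axis] = min(hi[axial_axis], axial_band[1] * extent[axial_axis])
    if np.any(hi <= lo):
        raise ValueError("grid too small for the requested lesion placement")
    return rng.uniform(lo, hi)


def generate_patient(config: GeneratorConfig, seed: int,
                     patient_id: str | None = None
                     ) -> tuple[SUVVolume, np.ndarray, TruthRecord]:
    """Generate one phantom: SUV volume, truth label volume, truth record.

    Lesion counts: exactly one primary plus Poisson numbers of nodes and
    distant metastases, resampled so every patient carries >= 2 lesions
    (the eligibility condition of the analysis).  Raises if the grid cannot
    host the requested lesions within a bounded number of placement
    attempts.
    """
    rng = np.random.default_rng(seed)
    if patient_id is None:
        patient_id = f"phantom_{seed:06d}"
    shape, spacing = config.shape, np.asarray(config.spacing)
    r_lo, r_hi = config.radius_range_mm
    # centre separation that guarantees distinct truth lesions stay distinct
    # after voxelization: sum of radii bound plus one voxel diagonal
    min_sep = 2.0 * r_hi + float(np.linalg.norm(spacing))

    for _ in range(20):  # cohort-level resample guard (placement may fail)
        n_nodes = int(rng.poisson(config.n_nodes_mean))
        n_distant = int(rng.poisson(config.n_distant_mean))
        if 1 + n_nodes + n_distant <= config.max_lesions and n_nodes + n_distant >= 1:
            break
    else:
        raise ValueError("could not draw an admissible lesion count")
    if config.coalescent_pair and n_nodes < 2:
        n_nodes = 2

    centers: list[np.ndarray] = []
    radii: list[float] = []
    classes: list[str] = []

    def place(cls: str, near: np.ndarray | None = None,
              axial_band=None) -> np.ndarray:
        for _ in range(200):
            if near is not None:
                offset = rng.uniform(-config.node_distance_mm,
                                     config.node_distance_mm, size=3)
                cand = near + offset
                extent = np.asarray(shape) * spacing
                if np.any(cand < r_hi) or np.any(cand > extent - r_hi):
                    continue
            else:
                cand = _sample_center(rng, shape, spacing, r_hi,
                                      config.axial_axis, axial_band)
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                radii.append(float(rng.uniform(r_lo, r_hi)))
                classes.append(cls)
                return cand
        raise ValueError(
            f"grid too small to place a {cls} lesion for patient {patient_id} "
            "after 200 attempts")

    primary_center = place("primary", axial_band=config.chest_fraction)
    coalescent_partner: int | None = None
    for k in range(n_nodes):
        place("node", near=primary_center)
        if config.coalescent_pair and k == 0:
            # deliberately overlapping second ball: one nodal conglomerate
            base = centers[-1]
            r1 = radii[-1]
            r2 = float(rng.uniform(r_lo, r_hi))
            for _ in range(50):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                partner = base + direction * 0.6 * (r1 + r2)
                others = centers[:-1]
                if all(np.linalg.norm(partner - c) >= min_sep for c in others):
                    break
            else:
                raise ValueError("could not place a coalescent node pair")
            centers.append(partner)
            radii.append(r2)
            classes.append("node")
            coalescent_partner = len(centers) - 1
    for _ in range(n_distant):
        place("distant")

    background = rng.normal(config.background_mean, config.background_sd,
                            size=shape)
    values = np.clip(background, 0.0, None)
    labels = np.zeros(shape, dtype=np.int32)

    # merge the coalescent pair into a single truth lesion
    lesion_members: list[list[int]] = []
    for i in range(len(centers)):
        if coalescent_partner is not None and i == coalescent_partner:
            lesion_members[-1].append(i)
        else:
            lesion_members.append([i])

    truth_lesions: list[Lesion] = []
    class_map: dict[int, str] = {}
    for label, members in enumerate(lesion_members, start=1):
        plateau = float(rng.uniform(*config.peak_suv_range))
        vox_list = [_rasterize_ball(shape, spacing, centers[i], radii[i])
                    for i in members]
        vox = np.unique(np.concatenate(vox_list, axis=0), axis=0)
        if vox.shape[0] == 0:
            raise ValueError("degenerate lesion rasterized to zero voxels")
        values[vox[:, 0], vox[:, 1], vox[:, 2]] = plateau
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = label
        cls = classes[members[0]]
        truth_lesions.append(Lesion(label=label, voxels=vox, lesion_class=cls,
                                    centroid_mm=_centroid_mm(vox, config.spacing)))
        class_map[label] = cls

    volume = SUVVolume(values=values, spacing=tuple(config.spacing),
                       axial_axis=config.axial_axis, patient_id=patient_id)
    # order truth lesions exactly as segmentation would label them
    ordered = sorted(truth_lesions,
                     key=lambda l: (-l.n_voxels, tuple(l.voxels[0])))
    ordered = tuple(dataclasses.replace(l, label=i + 1)
                    for i, l in enumerate(ordered))
    class_map = {l.label: l.lesion_class for l in ordered}
    lesion_set = LesionSet(
        lesions=ordered, source_volume_id=patient_id,
        config=SegmentationConfig(suv_threshold=config.suv_threshold))
    truth_features = aggregate_patient(volume, lesion_set)
    return volume, labels, TruthRecord(patient_id=patient_id,
                                       lesion_set=lesion_set,
                                       classes=class_map,
                                       features=truth_features)


def generate_survival(dmax_cm: float, mtv_tot_ml: float,
                      config: GeneratorConfig,
                      rng: np.random.Generator) -> SurvivalDraw:
    """Draw proportional-hazards outcomes for one patient.

    Event time ~ Exponential with rate
    ``baseline_rate * exp(beta_dmax * dmax_cm + beta_logmtv * log(mtv_tot_ml))``,
    administratively censored at the horizon.  Progression time is an
    independent Exponential with a proportionally larger rate; PFS is the
    earlier of progression and death.
    """
    lp = config.beta_dmax * dmax_cm + config.beta_logmtv * np.log(mtv_tot_ml)
    rate = config.baseline_rate * np.exp(lp)
    t_death = rng.exponential(1.0 / rate)
    t_prog = rng.exponential(1.0 / (rate * config.pfs_rate_multiplier))
    horizon = config.horizon_months
    os_event = int(t_death <= horizon and horizon > 0)
    pfs_time = min(t_prog, t_death)
    pfs_event = int(pfs_time <= horizon and horizon > 0)
    return SurvivalDraw(
        os_months=float(min(t_death, horizon)),
        os_event=os_event,
        pfs_months=float(min(pfs_time, horizon)),
        pfs_event=pfs_event,
        linear_predictor=float(lp),
        uncensored_event_months=float(t_death),
    )


def _draw_covariates(rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(64.0, 12.0), 38.0, 84.0))
    gender = int(rng.random() < MALE_PROB)  # 1 = male
    histology = HISTOLOGY_LEVELS[rng.choice(len(HISTOLOGY_LEVELS),
                                            p=HISTOLOGY_PROBS)]
    stage = STAGE_LEVELS[rng.choice(len(STAGE_LEVELS), p=STAGE_PROBS)]
    return {
        "age": age,
        "gender": gender,
        "histology": histology,
        "histology_adeno": int(histology == "adenocarcinoma"),
        "stage": stage,
        "stage_ordinal": STAGE_LEVELS.index(stage) + 1,
    }


def _features_row(truth: TruthRecord) -> dict:
    f = truth.features
    pm = f.primary_metrics
    tm = f.targeted_metrics
    return {
        "patient_id": f.patient_id,
        "n_lesions": f.n_lesions,
        "suv_max_primary": pm.suv_max if pm else np.nan,
        "suv_mean_primary": pm.suv_mean if pm else np.nan,
        "mtv_primary_ml": pm.mtv_ml if pm else np.nan,
        "tlg_primary_g": pm.tlg_g if pm else np.nan,
        "suv_max_targeted": tm.suv_max,
        "suv_mean_targeted": tm.suv_mean,
        "mtv_tot_ml": f.mtv_tot_ml,
        "tlg_wb_g": f.tlg_wb_g,
        "dmax_cm": f.dmax_cm,
        "dmax_pair_type": f.dmax_pair_type,
    }


def generate_cohort(config: GeneratorConfig, out_dir: str | None = None
                    ) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Generate a full phantom cohort.

    Returns the cohort table (features + covariates + outcomes) and the
    per-patient truth records; when ``out_dir`` is given, also writes one
    NIfTI volume per patient plus ``cohort.csv`` and ``truth.csv`` (the
    seed is recorded in the CSVs).  Fully reproducible from (config, seed).
    """
    ss = np.random.SeedSequence(config.seed)
    patient_seeds = [int(s) for s in ss.generate_state(config.n_patients) >> 1]
    outcome_rng = np.random.default_rng(ss.spawn(1)[0])
    rows, truths = [], []
    for i, pseed in enumerate(patient_seeds):
        pid = f"P{i + 1:04d}"
        volume, labels, truth = generate_patient(config, pseed, patient_id=pid)
        truths.append(truth)
        row = _features_row(truth)
        row.update(_draw_covariates(outcome_rng))
        draw = generate_survival(truth.features.dmax_cm,
                                 truth.features.mtv_tot_ml, config, outcome_rng)
        row.update(os_months=draw.os_months, os_event=draw.os_event,
                   pfs_months=draw.pfs_months, pfs_event=draw.pfs_event)
        row["seed"] = pseed
        rows.append(row)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_suv_volume(volume, os.path.join(out_dir, f"{pid}.nii.gz"))
    cohort = pd.DataFrame(rows)
    truth_df = pd.DataFrame([
        {**_features_row(t), "seed": s, "linear_predictor":
            config.beta_dmax * t.features.dmax_cm
            + config.beta_logmtv * np.log(t.features.mtv_tot_ml)}
        for t, s in zip(truths, patient_seeds)])
    if out_dir is not None:
        cohort.to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
        truth_df.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return cohort, truths


def sample_feature_table(n: int, config: GeneratorConfig,
                         seed: int) -> pd.DataFrame:
    """Tabular cohort draws without image phantoms.

    Dissemination and total-volume are sampled from log-normal
    distributions matching the study-scale moments (Dmax mean ~30 cm,
    SD ~21 cm; MTV_TOT mean ~156 mL, SD ~177 mL); outcomes then follow the
    same proportional-hazards model as the image phantoms.  Intended for
    large simulation studies (estimator calibration, stepwise-selection
    behaviour) where rasterizing thousands of volumes is pointless.
    """

    def lognorm_params(mean, sd):
        sigma2 = np.log(1.0 + (sd / mean) ** 2)
        return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)

    rng = np.random.default_rng(seed)
    mu_d, sg_d = lognorm_params(29.98, 20.98)
    mu_m, sg_m = lognorm_params(155.90, 176.94)
    # primary/targeted markers are pure-noise covariates on study-scale moments
    noise_markers = {
        "suv_max_primary": lognorm_params(11.80, 5.73),
        "suv_mean_primary": lognorm_params(5.37, 2.09),
        "mtv_primary_ml": lognorm_params(60.61, 102.57),
        "tlg_primary_g": lognorm_params(340.36, 558.40),
        "suv_max_targeted": lognorm_params(14.74, 7.22),
        "suv_mean_targeted": lognorm_params(5.71, 1.76),
    }
    rows = []
    for i in range(n):
        dmax = float(rng.lognormal(mu_d, sg_d))
        mtv = float(rng.lognormal(mu_m, sg_m))
        row = {"patient_id": f"S{i + 1:05d}", "n_lesions": 2,
               "dmax_cm": dmax, "mtv_tot_ml": mtv,
               "log_mtv_tot": float(np.log(mtv)),
               "tlg_wb_g": mtv * float(rng.lognormal(*lognorm_params(5.5, 1.7)))}
        for name, (mu, sg) in noise_markers.items():
            row[name] = float(rng.lognormal(mu, sg))
        row.update(_draw_covariates(rng))
        draw = generate_survival(dmax, mtv, config, rng)
        row.update(os_months=draw.os_months, os_event=draw.os_event,
                   pfs_months=draw.pfs_months, pfs_event=draw.pfs_event)
        rows.append(row)
    return pd.DataFrame(rows)
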