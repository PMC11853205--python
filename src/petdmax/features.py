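"""Per-lesion metabolic metrics and patient-level aggregates.

Per lesion: SUVmax, SUVmean (over the segmented voxels only), metabolic
tumor volume MTV (mL) and total lesion glycolysis TLG = MTV x SUVmean (g).
Per patient: MTV_TOT and TLG_WB (sums over all lesions), the targeted
lesion (highest SUVmax), and the tumor-dissemination statistic Dmax — the
largest physical distance between any two lesions, reported in cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import SUVVolume
from .segmentation import Lesion, LesionSet

__all__ = [
    "LesionMetrics",
    "PatientFeatures",
    "lesion_metrics",
    "select_targeted_lesion",
    "compute_dmax",
    "aggregate_patient",
    "pair_type",
]

#: Dissemination pair-type taxonomy (which lesion classes realise Dmax).
PAIR_TYPES = ("primary-node", "primary-distant", "node-node",
              "node-distant", "distant-distant", "unknown")


@dataclass(frozen=True)
class LesionMetrics:
    label: int
    lesion_class: str
    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg_g: float
    n_voxels: int


@dataclass(frozen=True)
class PatientFeatures:
    """Patient-level quantification summary.

    ``dmax_cm`` and its pair fields are ``None`` when the patient has fewer
    than two lesions (dissemination is undefined); ``primary_metrics`` is
    present iff exactly one lesion is classed "primary".
    """

    patient_id: str
    n_lesions: int
    mtv_tot_ml: float
    tlg_wb_g: float
    dmax_cm: float | None
    dmax_pair: tuple[int, int] | None
    dmax_pair_type: str | None
    primary_metrics: LesionMetrics | None
    targeted_metrics: LesionMetrics
    lesion_metrics: tuple[LesionMetrics, ...]


def lesion_metrics(volume: SUVVolume, lesion: Lesion) -> LesionMetrics:
    """Compute SUVmax / SUVmean / MTV / TLG over exactly the lesion's voxels.

    MTV = n_voxels x voxel volume (mL); TLG = MTV x SUVmean (g).
    """
    vox = lesion.voxels
    shape = volume.values.shape
    if vox.min() < 0 or np.any(vox >= np.asarray(shape)):
        raise IndexError(
            f"lesion {lesion.label} has voxel indices outside the {shape} grid")
    suv = volume.values[vox[:, 0], vox[:, 1], vox[:, 2]]
    suv_mean = float(suv.mean())
    mtv_ml = lesion.n_voxels * volume.voxel_volume_ml
    return LesionMetrics(
        label=lesion.label,
        lesion_class=lesion.lesion_class,
        suv_max=float(suv.max()),
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg_g=mtv_ml * suv_mean,
        n_voxels=lesion.n_voxels,
    )


def select_targeted_lesion(metrics: Sequence[LesionMetrics]) -> LesionMetrics:
    """The targeted lesion: highest SUVmax; ties broken by larger MTV, then
    smaller label."""
    if not metrics:
        raise ValueError("cannot select a targeted lesion from an empty list")
    return max(metrics, key=lambda m: (m.suv_max, m.mtv_ml, -m.label))


def pair_type(class_a: str, class_b: str) -> str:
    """Map two lesion classes to the dissemination pair-type taxonomy.

    Any "unknown" class makes the pair type "unknown"; never guessed.
    """
    if "unknown" in (class_a, class_b):
        return "unknown"
    order = {"primary": 0, "node": 1, "distant": 2}
    a, b = sorted((class_a, class_b), key=order.__getitem__)
    return f"{a}-{b}"


def compute_dmax(lesion_set: LesionSet, volume: SUVVolume,
                 mode: str = "centroid") -> tuple[float, tuple[int, int], str]:
    """Largest Euclidean distance between two lesions, in cm.

    mode="centroid" (default): centroid-to-centroid, the convention of the
    lymphoma dissemination literature.  mode="voxel_extremes": maximal
    voxel-centre to voxel-centre distance between the two lesions.
    Returns (dmax_cm, (label_a, label_b), pair_type); exact distance ties
    are broken toward the smallest (label_a, label_b) pair.
    """
    if mode not in ("centroid", "voxel_extremes"):
        raise ValueError(f"unknown Dmax mode {mode!r}")
    lesions = list(lesion_set)
    if len(lesions) < 2:
        raise ValueError(
            "Dmax undefined: at least two segmented lesions are required "
            f"(patient has {len(lesions)})")
    spacing = np.asarray(volume.spacing, dtype=np.float64)
    best: tuple[float, tuple[int, int]] | None = None
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            a, b = lesions[i], lesions[j]
            if mode == "centroid":
                d = float(np.linalg.norm(np.asarray(a.centroid_mm)
                                         - np.asarray(b.centroid_mm)))
            else:
                d = float(cdist(a.voxels * spacing, b.voxels * spacing).max())
            key = tuple(sorted((a.label, b.label)))
            if best is None or d > best[0] or (d == best[0] and key < best[1]):
                best = (d, key)
    d_mm, (la, lb) = best
    ptype = pair_type(lesion_set.get(la).lesion_class, lesion_set.get(lb).lesion_class)
    return d_mm / 10.0, (la, lb), ptype


def aggregate_patient(volume: SUVVolume, lesion_set: LesionSet,
                      dmax_mode: str = "centroid") -> PatientFeatures:
    """Aggregate a patient's lesions into whole-body features.

    MTV_TOT and TLG_WB are exact sums over lesions; Dmax fields are
    populated only when >= 2 lesions exist.
    """
    if len(lesion_set) == 0:
        raise ValueError("cannot aggregate an empty lesion set")
    per_lesion = tuple(lesion_metrics(volume, lesion) for lesion in lesion_set)
    primaries = [m for m in per_lesion if m.lesion_class == "primary"]
    if len(lesion_set) >= 2:
        dmax_cm, dmax_pair, dmax_ptype = compute_dmax(lesion_set, volume, dmax_mode)
    else:
        dmax_cm = dmax_pair = dmax_ptype = None
    return PatientFeatures(
        patient_id=volume.patient_id or lesion_set.source_volume_id,
        n_lesions=len(lesion_set),
        mtv_tot_ml=float(sum(m.mtv_ml for m in per_lesion)),
        tlg_wb_g=float(sum(m.tlg_g for m in per_lesion)),
        dmax_cm=dmax_cm,
        dmax_pair=dmax_pair,
        dmax_pair_type=dmax_ptype,
        primary_metrics=primaries[0] if len(primaries) == 1 else None,
        targeted_metrics=select_targeted_lesion(per_lesion),
        lesion_metrics=per_lesion,
    )
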