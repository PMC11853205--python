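"""Absolute-SUV-threshold lesion segmentation.

FDG-avid lesions are the maximal connected components of the set of voxels
with SUV strictly above an absolute threshold (default 2.5), outside all
physiological-uptake exclusion masks, that span at least a configurable
number of contiguous axial slices (default 2).  Coalescent lesions — e.g.
nodal conglomerates physically merged above the threshold — form a single
connected component and are therefore a single lesion by construction.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io import ExclusionMask, SUVVolume

__all__ = [
    "SegmentationConfig",
    "Lesion",
    "LesionSet",
    "segment_lesions",
    "classify_lesions",
    "lesions_to_label_volume",
    "write_lesion_set",
]

#: Lesion anatomical classes used in the dissemination pair-type taxonomy.
LESION_CLASSES = ("primary", "node", "distant", "unknown")


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold, connectivity and axial-extent rules for segmentation.

    suv_threshold
        Absolute SUV cut; voxels are lesion candidates iff SUV is *strictly*
        greater than this value.  Default 2.5.
    connectivity
        3-D voxel neighbourhood: 6 (faces), 18 (faces+edges) or 26 (full).
        Default 26, the common hot-spot convention; it also merges
        coalescent nodes without any extra heuristic.
    min_axial_slices
        A component must occupy at least one contiguous run of this many
        distinct axial slice indices to count as a lesion.  Default 2.
    """

    suv_threshold: float = 2.5
    connectivity: int = 26
    min_axial_slices: int = 2

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0:
            raise ValueError(f"suv_threshold must be positive, got {self.suv_threshold}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_axial_slices < 1:
            raise ValueError("min_axial_slices must be >= 1")


@dataclass(frozen=True)
class Lesion:
    """A single segmented lesion.

    ``voxels`` is an (n, 3) integer array of grid indices, sorted
    lexicographically; ``centroid_mm`` is the unweighted mean of the voxel
    centre physical coordinates (index * spacing).
    """

    label: int
    voxels: np.ndarray
    lesion_class: str = "unknown"
    centroid_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=np.intp)
        if voxels.ndim != 2 or voxels.shape[1] != 3 or voxels.shape[0] == 0:
            raise ValueError("voxels must be a non-empty (n, 3) index array")
        order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
        object.__setattr__(self, "voxels", voxels[order])
        if self.label < 1:
            raise ValueError("lesion label must be >= 1")
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        object.__setattr__(self, "centroid_mm", tuple(float(c) for c in self.centroid_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass(frozen=True)
class LesionSet:
    """Segmentation result: disjoint labelled lesions from one volume."""

    lesions: tuple[Lesion, ...]
    source_volume_id: str = ""
    config: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def __getitem__(self, i: int) -> Lesion:
        return self.lesions[i]

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(l.label for l in self.lesions)

    def get(self, label: int) -> Lesion:
        for lesion in self.lesions:
            if lesion.label == label:
                return lesion
        raise KeyError(f"no lesion with label {label}")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _has_contiguous_run(slice_indices: np.ndarray, min_len: int) -> bool:
    """True iff the sorted unique indices contain a run of >= min_len
    consecutive integers."""
    idx = np.unique(slice_indices)
    if min_len <= 1:
        return idx.size >= 1
    if idx.size < min_len:
        return False
    run = 1
    for a, b in zip(idx[:-1], idx[1:]):
        run = run + 1 if b == a + 1 else 1
        if run >= min_len:
            return True
    return False


def _centroid_mm(voxels: np.ndarray, spacing: Sequence[float]) -> tuple[float, float, float]:
    centre = voxels.mean(axis=0) * np.asarray(spacing, dtype=np.float64)
    return tuple(float(c) for c in centre)


def segment_lesions(volume: SUVVolume, config: SegmentationConfig | None = None,
                    masks: Iterable[ExclusionMask] = ()) -> LesionSet:
    """Segment FDG-avid lesions from an SUV volume.

    Pipeline order: apply exclusion masks, threshold strictly (SUV > cut),
    label connected components under the configured connectivity, then drop
    components failing the contiguous axial-slice rule.  Labels are assigned
    in decreasing component-size order; ties broken by the lexicographically
    smallest voxel index.

    An all-sub-threshold volume yields an empty LesionSet (the >=2-lesion
    eligibility rule is a cohort-level filter, not a segmentation error).
    """
    if config is None:
        config = SegmentationConfig()
    hot = volume.values > config.suv_threshold
    for mask in masks:
        if mask.values.shape != volume.values.shape:
            raise ValueError(
                f"exclusion mask {mask.label!r} shape {mask.values.shape} does not "
                f"match volume shape {volume.values.shape}")
        hot &= ~mask.values

    labelled, n_comp = ndimage.label(hot, structure=_STRUCTURES[config.connectivity])
    components: list[np.ndarray] = []
    if n_comp:
        all_idx = np.argwhere(labelled > 0)
        comp_of = labelled[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]]
        order = np.argsort(comp_of, kind="stable")
        all_idx, comp_of = all_idx[order], comp_of[order]
        starts = np.searchsorted(comp_of, np.arange(1, n_comp + 1), side="left")
        ends = np.searchsorted(comp_of, np.arange(1, n_comp + 1), side="right")
        components = [all_idx[s:e] for s, e in zip(starts, ends)]

    axial = volume.axial_axis
    kept = [vox for vox in components
            if _has_contiguous_run(vox[:, axial], config.min_axial_slices)]

    def sort_key(vox: np.ndarray):
        lex_min = min(map(tuple, vox))
        return (-vox.shape[0], lex_min)

    kept.sort(key=sort_key)
    lesions = tuple(
        Lesion(label=i + 1, voxels=vox, centroid_mm=_centroid_mm(vox, volume.spacing))
        for i, vox in enumerate(kept))
    return LesionSet(lesions=lesions, source_volume_id=volume.patient_id, config=config)


def classify_lesions(lesion_set: LesionSet,
                     class_map: Mapping[int, str]) -> LesionSet:
    """Attach anatomical classes (primary / node / distant) to lesions.

    Classes are supplied externally (ground truth or reader annotation);
    there is no automatic anatomy recognition.  Labels absent from the map
    become ``"unknown"``; a mapped label absent from the set is an error.
    """
    known = set(lesion_set.labels)
    stale = sorted(set(class_map) - known)
    if stale:
        raise KeyError(f"class map references non-existent lesion label(s) {stale}")
    lesions = tuple(
        dataclasses.replace(l, lesion_class=class_map.get(l.label, "unknown"))
        for l in lesion_set)
    return dataclasses.replace(lesion_set, lesions=lesions)


def lesions_to_label_volume(lesion_set: LesionSet, shape: tuple[int, int, int]) -> np.ndarray:
    """Render a LesionSet as an integer label volume (0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for lesion in lesion_set:
        out[lesion.voxels[:, 0], lesion.voxels[:, 1], lesion.voxels[:, 2]] = lesion.label
    return out


def write_lesion_set(lesion_set: LesionSet, volume: SUVVolume,
                     label_path: str, csv_path: str) -> None:
    """Serialize lesions as a NIfTI label volume plus a CSV sidecar."""
    import nibabel as nib

    from .io import _spacing_affine

    labels = lesions_to_label_volume(lesion_set, volume.values.shape)
    img = nib.Nifti1Image(labels, _spacing_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, label_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "class", "n_voxels",
                         "centroid_x_mm", "centroid_y_mm", "centroid_z_mm"])
        for lesion in lesion_set:
            writer.writerow([lesion.label, lesion.lesion_class, lesion.n_voxels,
                             *(f"{c:.6f}" for c in lesion.centroid_mm)])
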