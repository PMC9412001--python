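"""Triplanar inference: slice, ensemble, and merge orientation predictions.

A preprocessed volume pair is sliced along the sagittal, coronal, and
axial planes; every slice pair runs through each fold model and the
softmax outputs are averaged over folds, giving one 3D probability volume
per orientation. The three volumes are then merged into the final
new-lesion mask by one of four strategies:

softmax_average
    threshold the voxel-wise mean of the three probability volumes;
union / majority / unanimous
    lesion-wise voting — threshold each orientation into a hard mask,
    take connected components of their voxel-wise union as candidate
    lesions, count in how many orientations each candidate was detected,
    and keep candidates with at least 1 / 2 / 3 votes. A kept lesion's
    segmentation is the union of the positive voxels across orientations
    (exactly the candidate component).

Unanimous voting is the most precise and union the most sensitive; by
construction unanimous ⊆ majority ⊆ union.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .preprocessing import PreprocessConfig, preprocess_pair
from .training import FoldModels
from .unet import UNet2D, ORIENTATIONS
from .volume_io import BinaryMask3D, GeometryError, VolumePair

__all__ = ["OrientationPredictions", "MergeStrategy", "LesionSet",
           "predict_orientation", "predict_all_orientations",
           "label_lesions", "merge_orientations", "segment_pair"]

_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}
_MIN_VOTES = {"union": 1, "majority": 2, "unanimous": 3}


@dataclasses.dataclass
class OrientationPredictions:
    """Per-orientation fold-averaged probability volumes on one cube grid."""
    axial: np.ndarray
    coronal: np.ndarray
    sagittal: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.axial.shape, self.coronal.shape, self.sagittal.shape}
        if len(shapes) != 1:
            raise GeometryError(f"orientation volumes differ in shape: {shapes}")

    def get(self, orientation: str) -> np.ndarray:
        return getattr(self, orientation)


@dataclasses.dataclass(frozen=True)
class MergeStrategy:
    kind: str = "unanimous"
    threshold: float = 0.5
    connectivity: int = 26
    min_overlap_fraction: float = 0.0  # 0: any (>= 1 voxel) overlap votes

    def __post_init__(self) -> None:
        if self.kind not in ("softmax_average", "union", "majority",
                             "unanimous"):
            raise ValueError(f"unknown merge strategy {self.kind!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18, or 26")


@dataclasses.dataclass
class LesionSet:
    """Connected components of a binary mask, with per-lesion bookkeeping."""
    labels: np.ndarray                 # 0 = background, 1..n = lesions
    lesions: list[dict]                # id, n_voxels, volume_mm3, votes
    connectivity: int

    def __len__(self) -> int:
        return len(self.lesions)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def label_lesions(mask: BinaryMask3D, connectivity: int = 26) -> LesionSet:
    """Label connected components under 6/18/26-connectivity.

    Labels follow volume scan order, so they are deterministic
    (lexicographic by each component's first voxel index).
    """
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    voxel_mm3 = float(np.prod(mask.spacing))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    lesions = [{"id": i, "n_voxels": int(counts[i]),
                "volume_mm3": float(counts[i]) * voxel_mm3}
               for i in range(1, n + 1)]
    return LesionSet(labels=labels, lesions=lesions, connectivity=connectivity)


def predict_orientation(models: FoldModels | list[UNet2D], pair: VolumePair,
                        orientation: str, chunk: int = 32) -> np.ndarray:
    """Fold-ensemble probability volume for one slicing orientation."""
    nets = models.models if isinstance(models, FoldModels) else list(models)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    axis = _AXIS[orientation]
    n = pair.shape[axis]
    if pair.shape != (nets[0].config.slice_size,) * 3:
        raise ValueError(
            f"pair grid {pair.shape} does not match model slice size "
            f"{nets[0].config.slice_size}; preprocess to the cube first")
    base = np.moveaxis(pair.baseline.data, axis, 0)
    fup = np.moveaxis(pair.followup.data, axis, 0)
    x = np.stack([base, fup], axis=1)  # (n_slices, 2, N, N)
    acc = np.zeros((n,) + x.shape[2:], dtype=np.float64)
    for net in nets:
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            acc[sl] += net.forward(x[sl], train=False)[:, 1]
    acc /= len(nets)
    return np.moveaxis(acc, 0, axis)


def predict_all_orientations(models: FoldModels | list[UNet2D],
                             pair: VolumePair) -> OrientationPredictions:
    return OrientationPredictions(
        axial=predict_orientation(models, pair, "axial"),
        coronal=predict_orientation(models, pair, "coronal"),
        sagittal=predict_orientation(models, pair, "sagittal"))


def merge_orientations(preds: OrientationPredictions,
                       strategy: MergeStrategy = MergeStrategy(),
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       affine: np.ndarray | None = None
                       ) -> tuple[BinaryMask3D, LesionSet]:
    """Merge the three orientation predictions into the final mask."""
    affine = np.diag(list(spacing) + [1.0]) if affine is None else affine
    if strategy.kind == "softmax_average":
        mean = (preds.axial + preds.coronal + preds.sagittal) / 3.0
        mask = BinaryMask3D(mean > strategy.threshold, spacing, affine)
        return mask, label_lesions(mask, strategy.connectivity)

    hard = {o: preds.get(o) > strategy.threshold for o in ORIENTATIONS}
    union = hard["sagittal"] | hard["coronal"] | hard["axial"]
    labels, n = ndimage.label(union, structure=_structure(strategy.connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    votes = np.zeros(n + 1, dtype=int)
    for o in ORIENTATIONS:
        overlap = np.bincount(labels[hard[o]].ravel(), minlength=n + 1)
        if strategy.min_overlap_fraction > 0:
            votes += (overlap >= strategy.min_overlap_fraction
                      * np.maximum(counts, 1)).astype(int)
        else:
            votes += (overlap > 0).astype(int)
    votes[0] = 0
    keep = votes >= _MIN_VOTES[strategy.kind]
    final = keep[labels] & (labels > 0)
    mask = BinaryMask3D(final, spacing, affine)
    lesion_set = label_lesions(mask, strategy.connectivity)
    # carry the vote count of each kept lesion (match by any shared voxel)
    for les in lesion_set.lesions:
        src = labels[lesion_set.labels == les["id"]]
        les["votes"] = int(votes[src[0]])
    return mask, lesion_set


def segment_pair(models: FoldModels | list[UNet2D], pair: VolumePair,
                 strategy: MergeStrategy = MergeStrategy(),
                 preprocess_config: PreprocessConfig = PreprocessConfig(),
                 preprocessed: bool = False
                 ) -> tuple[BinaryMask3D, LesionSet]:
    """Full pipeline for one subject: preprocess, predict, merge, resample.

    The returned mask lives on the follow-up's native grid (nearest-
    neighbor label resampling); the lesion table is computed on the cube
    grid where the voting happened.
    """
    if preprocessed:
        cube_pair = pair
    else:
        cube_pair, _ = preprocess_pair(pair, [], preprocess_config)
    preds = predict_all_orientations(models, cube_pair)
    cube_mask, lesions = merge_orientations(
        preds, strategy, spacing=cube_pair.followup.spacing,
        affine=cube_pair.followup.affine)
    if preprocessed:
        return cube_mask, lesions
    # map native voxel indices into cube indices through the two affines
    t = np.linalg.inv(cube_mask.affine) @ pair.followup.affine
    native = ndimage.affine_transform(
        cube_mask.data, t[:3, :3], offset=t[:3, 3],
        output_shape=pair.followup.shape, order=0, mode="constant")
    out = BinaryMask3D(native, pair.followup.spacing,
                       pair.followup.affine.copy(),
                       id=pair.followup.id)
    return out, lesions
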