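"""Preprocessing: registration, brain cropping, cube resampling, z-scoring.

The chain mirrors a standard longitudinal pipeline: (1) optional affine
registration to a template, (2) crop of the field of view to a box around
the brain, (3) resampling to an isotropic N³ cube so that slices from all
three orientations share one size, (4) per-volume z-score normalization.
When no template is supplied the registration step degrades to the
identity — the input pair is assumed co-registered.

Training-time augmentation (flips, rotations, elastic deformation,
contrast, bias field) applies one shared spatial transform to both time
points and the ground truth; intensity transforms touch the images only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import BinaryMask3D, Volume, VolumePair

__all__ = [
    "PreprocessConfig", "AugmentConfig", "RegistrationError", "CropError",
    "estimate_affine", "crop_to_brain", "preprocess_pair", "augment",
    "zscore",
]


class RegistrationError(RuntimeError):
    pass


class CropError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    cube_size: int = 256
    template: Volume | None = None
    crop_margin: int = 2

    def __post_init__(self) -> None:
        if self.cube_size < 16:
            raise ValueError("cube_size must be >= 16")
        if self.crop_margin < 0:
            raise ValueError("crop_margin must be >= 0")


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes follow conventional lesion-segmentation augmentation
    ranges: rotations up to 10°, elastic field smoothed at σ = 4 voxels
    with ~2-voxel peak displacement, multiplicative gamma in [0.8, 1.2],
    and a bias field of up to 20% relative amplitude."""
    rotation_max_deg: float = 10.0
    flip_axes: tuple[str, ...] = ("sagittal", "coronal", "axial")
    elastic_sigma: float = 4.0
    elastic_alpha: float = 2.0
    contrast_range: tuple[float, float] = (0.8, 1.2)
    bias_field_strength: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_max_deg < 0 or self.elastic_sigma < 0 \
                or self.elastic_alpha < 0 or self.bias_field_strength < 0:
            raise ValueError("augmentation magnitudes must be >= 0")
        if min(self.contrast_range) <= 0:
            raise ValueError("contrast bounds must be positive")


_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def _to_sitk(volume: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        volume.data.transpose(2, 1, 0).astype(np.float64)))
    img.SetSpacing(tuple(volume.spacing))
    return img


def estimate_affine(moving: Volume, template: Volume) -> np.ndarray:
    """12-parameter affine aligning ``moving`` to ``template``.

    Optimizes a mean-squares intensity criterion with a multi-resolution
    gradient-descent scheme (both volumes are the same modality here).
    Returns the 4×4 voxel-space transform mapping template voxel indices
    to moving voxel indices.
    """
    for name, v in (("moving", moving), ("template", template)):
        if float(np.std(v.data)) == 0.0:
            raise RegistrationError(f"{name} volume has constant intensity")
    fixed = _to_sitk(template)
    mov = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    try:
        transform = reg.Execute(fixed, mov)
    except RuntimeError as exc:  # pragma: no cover - sitk failure paths
        raise RegistrationError(f"registration failed: {exc}") from exc
    affine = sitk.AffineTransform(transform)
    mat = np.eye(4)
    mat[:3, :3] = np.asarray(affine.GetMatrix()).reshape(3, 3)
    center = np.asarray(affine.GetCenter())
    mat[:3, 3] = (np.asarray(affine.GetTranslation()) + center
                  - mat[:3, :3] @ center)
    # physical-space transform → voxel-space (index) transform
    sp_t = np.diag(list(template.spacing) + [1.0])
    sp_m_inv = np.diag([1.0 / s for s in moving.spacing] + [1.0])
    return sp_m_inv @ mat @ sp_t


def apply_affine(volume: Volume, transform: np.ndarray,
                 reference: Volume, order: int = 1) -> Volume:
    """Resample ``volume`` onto ``reference``'s grid under a voxel affine."""
    mat = transform[:3, :3]
    off = transform[:3, 3]
    data = ndimage.affine_transform(volume.data, mat, offset=off,
                                    output_shape=reference.shape,
                                    order=order, mode="constant")
    return Volume(data, reference.spacing, reference.affine.copy(),
                  id=volume.id)


# --------------------------------------------------------------------------
# cropping and resampling
# --------------------------------------------------------------------------

def crop_to_brain(volume: Volume, margin: int = 0
                  ) -> tuple[Volume, tuple[slice, slice, slice]]:
    """Tight Otsu-foreground bounding box, expanded by ``margin`` voxels.

    Returns the cropped volume and the crop box so masks can be cropped
    identically.
    """
    data = volume.data
    if float(data.max()) == float(data.min()):
        raise CropError("cannot crop: volume is constant")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise CropError("cannot crop: no voxel above the Otsu threshold")
    box = []
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        lo = max(0, int(idx[0]) - margin)
        hi = min(data.shape[ax], int(idx[-1]) + 1 + margin)
        box.append(slice(lo, hi))
    box = tuple(box)
    cropped = data[box]
    new_affine = volume.affine.copy()
    new_affine[:3, 3] = (volume.affine @ np.array(
        [box[0].start, box[1].start, box[2].start, 1.0]))[:3]
    return Volume(cropped, volume.spacing, new_affine, id=volume.id), box


def _resample_cube(data: np.ndarray, cube: int, order: int) -> np.ndarray:
    grids = np.meshgrid(*[np.linspace(0, n - 1, cube) for n in data.shape],
                        indexing="ij")
    return ndimage.map_coordinates(data.astype(np.float32), grids,
                                   order=order, mode="nearest")


def zscore(data: np.ndarray) -> np.ndarray:
    sd = float(data.std())
    if sd == 0:
        raise ValueError("cannot z-score a constant volume")
    return (data - float(data.mean())) / sd


def preprocess_pair(pair: VolumePair,
                    masks: list[BinaryMask3D] | None = None,
                    config: PreprocessConfig = PreprocessConfig()
                    ) -> tuple[VolumePair, list[BinaryMask3D]]:
    """Run the full chain on one subject.

    The crop box is estimated on the follow-up volume and applied to the
    baseline and every mask, so all outputs land on one ``cube_size``³
    grid. Images are interpolated linearly and z-scored; masks use
    nearest-neighbor interpolation and stay binary.
    """
    masks = masks or []
    baseline, followup = pair.baseline, pair.followup
    if config.template is not None:
        t_b = estimate_affine(baseline, config.template)
        t_f = estimate_affine(followup, config.template)
        baseline = apply_affine(baseline, t_b, config.template, order=1)
        followup = apply_affine(followup, t_f, config.template, order=1)
        masks = [BinaryMask3D(
            ndimage.affine_transform(m.data.astype(np.float32), t_f[:3, :3],
                                     offset=t_f[:3, 3],
                                     output_shape=config.template.shape,
                                     order=0) > 0.5,
            config.template.spacing, config.template.affine.copy(), id=m.id)
            for m in masks]
    for m in masks:
        if tuple(m.shape) != tuple(followup.shape):
            raise CropError(f"mask {m.id!r} not on the follow-up grid")

    cropped_f, box = crop_to_brain(followup, config.crop_margin)
    box_shape = tuple(s.stop - s.start for s in box)
    cube = config.cube_size
    scale = [(bs - 1) / (cube - 1) if cube > 1 else 1.0 for bs in box_shape]
    new_affine = cropped_f.affine.copy()
    new_affine[:3, :3] = cropped_f.affine[:3, :3] @ np.diag(scale)
    new_spacing = tuple(sp * sc for sp, sc in zip(followup.spacing, scale))

    def do_volume(v: Volume) -> Volume:
        data = _resample_cube(v.data[box], cube, order=1)
        return Volume(zscore(data), new_spacing, new_affine, id=v.id)

    out_pair = VolumePair(do_volume(baseline), do_volume(followup))
    out_masks = [BinaryMask3D(_resample_cube(m.data[box], cube, order=0) > 0.5,
                              new_spacing, new_affine, id=m.id)
                 for m in masks]
    return out_pair, out_masks


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def _elastic_field(shape, sigma, alpha, rng):
    disp = [ndimage.gaussian_filter(rng.normal(size=shape), sigma)
            for _ in range(3)]
    peak = max(max(abs(d.max()), abs(d.min())) for d in disp)
    return [d * (alpha / max(peak, 1e-12)) for d in disp]


def augment(pair: VolumePair, gt: BinaryMask3D,
            config: AugmentConfig = AugmentConfig()
            ) -> tuple[VolumePair, BinaryMask3D]:
    """Apply one random augmentation draw to a preprocessed subject.

    Spatial transforms (flips, rotation, elastic) hit both images and the
    ground truth with identical parameters; intensity transforms (gamma
    contrast, bias field) hit the images only. With all magnitudes zero
    the input is returned unchanged. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    imgs = [pair.baseline.data.copy(), pair.followup.data.copy()]
    mask = gt.data.copy().astype(np.float32)

    for name in ("sagittal", "coronal", "axial"):
        if name in config.flip_axes and rng.random() < 0.5:
            ax = _AXIS[name]
            imgs = [np.flip(i, axis=ax) for i in imgs]
            mask = np.flip(mask, axis=ax)

    if config.rotation_max_deg > 0:
        angle = float(rng.uniform(-config.rotation_max_deg,
                                  config.rotation_max_deg))
        axes = tuple(sorted(rng.choice(3, size=2, replace=False).tolist()))
        imgs = [ndimage.rotate(i, angle, axes=axes, reshape=False, order=1,
                               mode="nearest") for i in imgs]
        mask = ndimage.rotate(mask, angle, axes=axes, reshape=False, order=0,
                              mode="constant")

    if config.elastic_alpha > 0 and config.elastic_sigma > 0:
        disp = _elastic_field(mask.shape, config.elastic_sigma,
                              config.elastic_alpha, rng)
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in mask.shape],
                            indexing="ij")
        coords = [g + d for g, d in zip(grids, disp)]
        imgs = [ndimage.map_coordinates(i, coords, order=1, mode="nearest")
                for i in imgs]
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant")

    lo, hi = config.contrast_range
    if not (lo == hi == 1.0):
        gamma = float(rng.uniform(lo, hi))
        out = []
        for i in imgs:
            mn, mx = float(i.min()), float(i.max())
            span = max(mx - mn, 1e-12)
            out.append(((i - mn) / span) ** gamma * span + mn)
        imgs = out

    if config.bias_field_strength > 0:
        coeff = rng.normal(size=(3, 3, 3))
        g = np.meshgrid(*[np.linspace(-1, 1, n) for n in mask.shape],
                        indexing="ij")
        field = np.zeros(mask.shape)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    field += coeff[i, j, k] * g[0] ** i * g[1] ** j * g[2] ** k
        field = 1.0 + config.bias_field_strength * field / max(
            np.abs(field).max(), 1e-12)
        out = []
        for i in imgs:
            mn = float(i.min())
            out.append((i - mn) * field + mn)
        imgs = out

    new_pair = VolumePair(
        Volume(np.ascontiguousarray(imgs[0]), pair.baseline.spacing,
               pair.baseline.affine.copy(), id=pair.baseline.id),
        Volume(np.ascontiguousarray(imgs[1]), pair.followup.spacing,
               pair.followup.affine.copy(), id=pair.followup.id))
    new_gt = BinaryMask3D(np.ascontiguousarray(mask) > 0.5, gt.spacing,
                          gt.affine.copy(), id=gt.id)
    return new_pair, new_gt
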