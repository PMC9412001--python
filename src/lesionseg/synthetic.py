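"""Synthetic longitudinal FLAIR-like phantoms with known new lesions.

The generator emulates the study conditions every other module is tested
under: a pair of co-registered 3D volumes of one subject where the
follow-up contains additional hyperintense "new" lesions that the baseline
lacks, plus simulated expert raters with controllable per-lesion
sensitivity, boundary jitter, and false-positive behavior.

The phantom is deliberately simple — an ellipsoidal two-tissue brain,
spherical lesions smoothed with a small Gaussian, additive noise and a
smooth multiplicative bias field. It provides the statistical structure the
algorithms need (new-lesion contrast, anisotropic spacing, multi-rater
disagreement) without attempting MR physics or realistic white-matter
geometry.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask3D, Volume, VolumePair

__all__ = ["PhantomParams", "RaterModel", "GenerationError",
           "generate_phantom_pair", "simulate_raters"]


class GenerationError(RuntimeError):
    """Lesion placement failed; retry with fewer or smaller lesions."""


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Defaults give a desk-scale 64³ isotropic phantom.

    Lesion radii are in mm; the minimum of 1.5 mm keeps every lesion at or
    above 3 mm diameter, the smallest lesion size annotated in the study
    regime this emulates. ``lesion_contrast`` multiplies the local tissue
    intensity, making new lesions strictly hyperintense.
    """
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes_fraction: tuple[float, float, float] = (0.42, 0.45, 0.40)
    tissue_intensity: float = 1.0
    shell_intensity: float = 0.85
    n_baseline_lesions: tuple[int, int] = (0, 2)
    n_new_lesions: tuple[int, int] = (1, 4)
    lesion_radius_mm: tuple[float, float] = (2.0, 4.0)
    lesion_contrast: float = 1.8
    noise_sd: float = 0.05
    bias_field_amplitude: float = 0.2
    smooth_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_radius_mm[0] < 1.5:
            raise ValueError("minimum lesion radius is 1.5 mm "
                             "(3 mm diameter regime)")


@dataclasses.dataclass(frozen=True)
class RaterModel:
    """A simulated expert annotator operating on the lesion level."""
    sensitivity: float = 0.9
    boundary_jitter_sd: float = 0.5   # voxels, rigid per-lesion shift
    dilation_bias: int = 0            # >0 dilate, <0 erode, iterations
    false_positive_rate: float = 0.0  # expected FP blobs per volume
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")


def _ellipsoid_radius(shape, axes_fraction):
    """Normalized ellipsoid radius field r (r < 1 inside the brain)."""
    coords = np.meshgrid(*[np.arange(n) - (n - 1) / 2.0 for n in shape],
                         indexing="ij")
    semi = [f * n / 2.0 for f, n in zip(axes_fraction, shape)]
    return np.sqrt(sum((c / s) ** 2 for c, s in zip(coords, semi)))


def _sphere_mask(shape, spacing, center, radius_mm):
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((c - ctr) * sp) ** 2
             for c, ctr, sp in zip(coords, center, spacing))
    return d2 <= radius_mm ** 2


def _bias_field(shape, amplitude, rng):
    """Smooth multiplicative field: 1 + amplitude * random quadratic."""
    coeff = rng.normal(size=(3, 3, 3))
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    field = np.zeros(shape)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                field += coeff[i, j, k] * grids[0] ** i * grids[1] ** j * grids[2] ** k
    field /= max(np.abs(field).max(), 1e-12)
    return 1.0 + amplitude * field


def generate_phantom_pair(params: PhantomParams = PhantomParams()
                          ) -> tuple[VolumePair, BinaryMask3D, list[dict]]:
    """Build one subject: baseline, follow-up, new-lesion truth, catalog.

    Baseline lesions appear identically in both time points; new lesions
    only in the follow-up. Lesions are placed inside the brain, pairwise
    disjoint, by rejection sampling with bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    r = _ellipsoid_radius(shape, params.brain_axes_fraction)
    tissue = np.where(r < 1.0,
                      np.where(r < 0.7, params.tissue_intensity,
                               params.shell_intensity), 0.0)

    n_base = int(rng.integers(params.n_baseline_lesions[0],
                              params.n_baseline_lesions[1] + 1))
    n_new = int(rng.integers(params.n_new_lesions[0],
                             params.n_new_lesions[1] + 1))
    placed: list[tuple[np.ndarray, float]] = []  # (center voxel, radius mm)

    def place_one() -> tuple[np.ndarray, float]:
        radius = float(rng.uniform(*params.lesion_radius_mm))
        semi = np.array([0.8 * f * n / 2.0
                         for f, n in zip(params.brain_axes_fraction, shape)])
        mid = np.array([(n - 1) / 2.0 for n in shape])
        for _ in range(500):
            u = rng.uniform(-1, 1, size=3)
            if (u ** 2).sum() > 1.0:  # rejection: uniform in the unit ball
                continue
            c = mid + u * semi  # inside the brain, away from the shell
            ok = True
            for c2, r2 in placed:
                sep = np.sqrt((((c - c2) * params.spacing) ** 2).sum())
                # gap > sqrt(3) voxels so lesions never touch, even
                # diagonally (26-connectivity)
                if sep < radius + r2 + 2.0 * max(params.spacing):
                    ok = False
                    break
            if ok:
                placed.append((c, radius))
                return c, radius
        raise GenerationError(
            "could not place a lesion after 500 tries; "
            "use fewer or smaller lesions")

    base_lesions = [place_one() for _ in range(n_base)]
    new_lesions = [place_one() for _ in range(n_new)]

    base_mask = np.zeros(shape, dtype=bool)
    for c, rad in base_lesions:
        base_mask |= _sphere_mask(shape, params.spacing, c, rad)
    new_mask = np.zeros(shape, dtype=bool)
    for c, rad in new_lesions:
        new_mask |= _sphere_mask(shape, params.spacing, c, rad)

    lesion_value = params.lesion_contrast * params.tissue_intensity

    def render(with_new: bool, noise_rng: np.random.Generator) -> np.ndarray:
        img = tissue.copy()
        img[base_mask] = lesion_value
        if with_new:
            img[new_mask] = lesion_value
        img = ndimage.gaussian_filter(img, params.smooth_sigma)
        img *= _bias_field(shape, params.bias_field_amplitude, noise_rng)
        img += noise_rng.normal(0.0, params.noise_sd, size=shape)
        return img.astype(np.float32)

    affine = np.diag(list(params.spacing) + [1.0])
    sid = f"phantom-{params.seed}"
    baseline = Volume(render(False, rng), params.spacing, affine,
                      id=f"{sid}-t0")
    followup = Volume(render(True, rng), params.spacing, affine,
                      id=f"{sid}-t1")
    gt = BinaryMask3D(new_mask, params.spacing, affine, id=f"{sid}-gt")

    voxel_mm3 = float(np.prod(params.spacing))
    catalog = []
    for i, (c, rad) in enumerate(new_lesions):
        vox = int(_sphere_mask(shape, params.spacing, c, rad).sum())
        catalog.append({"lesion": i, "center": tuple(np.round(c, 2).tolist()),
                        "radius_mm": rad, "n_voxels": vox,
                        "volume_mm3": vox * voxel_mm3})
    return VolumePair(baseline, followup), gt, catalog


def _shift_mask(mask: np.ndarray, shift: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        s = int(s)
        n = mask.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax] = slice(s, n)
            src[ax] = slice(0, n - s)
        else:
            dst[ax] = slice(0, n + s)
            src[ax] = slice(-s, n)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def simulate_raters(gt: BinaryMask3D, catalog: list[dict],
                    raters: list[RaterModel]) -> list[BinaryMask3D]:
    """Simulate expert annotations of the true new-lesion mask.

    Each rater independently misses whole lesions (1 − sensitivity),
    rigidly jitters surviving lesion boundaries, applies a systematic
    dilation/erosion bias, and may add small false-positive blobs.
    """
    labels, n_lesions = ndimage.label(gt.data,
                                      structure=np.ones((3, 3, 3), dtype=int))
    out = []
    for ri, rater in enumerate(raters):
        rng = np.random.default_rng(rater.seed)
        mask = np.zeros(gt.shape, dtype=bool)
        for lesion in range(1, n_lesions + 1):
            if rng.random() >= rater.sensitivity:
                continue
            blob = labels == lesion
            if rater.boundary_jitter_sd > 0:
                shift = np.round(rng.normal(0, rater.boundary_jitter_sd,
                                            size=3)).astype(int)
                blob = _shift_mask(blob, shift)
            if rater.dilation_bias > 0:
                blob = ndimage.binary_dilation(blob,
                                               iterations=rater.dilation_bias)
            elif rater.dilation_bias < 0:
                eroded = ndimage.binary_erosion(blob,
                                                iterations=-rater.dilation_bias)
                blob = eroded if eroded.any() else blob  # never erase a lesion
            mask |= blob
        n_fp = rng.poisson(rater.false_positive_rate)
        for _ in range(n_fp):
            center = np.array([rng.uniform(0.25 * n, 0.75 * n)
                               for n in gt.shape])
            radius = rng.uniform(1.5, 2.5)
            fp = _sphere_mask(gt.shape, gt.spacing, center, radius)
            if not (fp & (gt.data > 0)).any():
                mask |= fp
        out.append(BinaryMask3D(mask, gt.spacing, gt.affine.copy(),
                                id=f"rater{ri}"))
    return out
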