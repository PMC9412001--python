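"""Loss functions and 5-fold training of the triplanar U-Net.

The training objective is the sum of a soft Dice loss and a TopK loss.
Writing ``g_ic ∈ {0,1}`` for the one-hot ground truth and ``p_ic ∈ (0,1)``
for the softmax output at voxel ``i``, class ``c``:

    L_Dice = 1 - 2 Σ_ic g_ic p_ic / (Σ_ic g_ic² + Σ_ic p_ic²)
    L_TopK = mean of the k% largest per-voxel cross-entropies
             CE_i = -Σ_c g_ic log p_ic
    L_total = L_Dice + L_TopK

TopK is a hard-mining variant of cross-entropy: it keeps only the k%
hardest voxels (largest CE) and reduces to plain mean cross-entropy at
k = 100. Both sums run over *both* class channels.

Batches mix axial, coronal, and sagittal slices from different subjects;
a single network is trained on all three orientations. Cross-validated
training holds out a random 20% of subjects per fold and returns one model
per fold; the fold ensemble is what inference consumes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._nn import SGDMomentum
from .unet import UNet2D, UNetConfig, ORIENTATIONS
from .volume_io import BinaryMask3D, VolumePair

__all__ = [
    "LossConfig", "TrainConfig", "FoldModels",
    "dice_loss", "dice_loss_grad", "topk_loss", "topk_loss_grad",
    "total_loss", "total_loss_grad", "make_batches", "train_folds",
    "extract_slice",
]

_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class LossConfig:
    """k_percent: fraction (in %) of hardest voxels the TopK loss keeps."""
    k_percent: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.k_percent <= 100:
            raise ValueError("k_percent must be in (0, 100]")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 20
    lr_initial: float = 0.0001
    momentum: float = 0.9
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    early_stop_patience: int = 10
    max_epochs: int = 100
    n_folds: int = 5
    holdout_fraction: float = 0.2
    steps_per_epoch: int | None = None  # None: cover every slice once
    foreground_slice_fraction: float = 0.0  # fraction of batch slots forced
    # to sample a slice containing ground-truth foreground (0 = uniform)
    val_slices_per_subject: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


@dataclasses.dataclass
class FoldModels:
    """The trained fold ensemble M_0 .. M_{n_folds-1}."""
    models: list[UNet2D]
    fold_assignments: dict[int, list[str]]  # fold -> held-out subject ids
    history: list[dict]  # epoch, fold, train_loss, val_loss, lr


# --------------------------------------------------------------------------
# losses (operate on probability arrays; class axis configurable)
# --------------------------------------------------------------------------

def _check_shapes(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")


def dice_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Soft Dice loss; sums run over every entry (all voxels, all classes)."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _check_shapes(p, g)
    num = 2.0 * float((g * p).sum())
    den = float((g * g).sum() + (p * p).sum())
    return 1.0 - num / max(den, _EPS)


def dice_loss_grad(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`dice_loss` w.r.t. ``p``."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num = 2.0 * (g * p).sum()
    den = max(float((g * g).sum() + (p * p).sum()), _EPS)
    return (-2.0 * g * den + 2.0 * num * p) / (den * den)


def _per_voxel_ce(p: np.ndarray, g: np.ndarray, class_axis: int) -> np.ndarray:
    return -(g * np.log(np.clip(p, _EPS, None))).sum(axis=class_axis)


def _topk_count(n_voxels: int, k_percent: float) -> int:
    m = int(n_voxels * k_percent / 100.0)
    if m == 0:
        raise ValueError(
            f"k_percent={k_percent} selects zero of {n_voxels} voxels")
    return m


def topk_loss(p: np.ndarray, g: np.ndarray, k_percent: float = 10.0,
              class_axis: int = 0) -> float:
    """Mean cross-entropy over the k% voxels with the largest CE."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _check_shapes(p, g)
    ce = _per_voxel_ce(p, g, class_axis).ravel()
    m = _topk_count(ce.size, k_percent)
    hardest = np.partition(ce, ce.size - m)[ce.size - m:]
    return float(hardest.mean())


def topk_loss_grad(p: np.ndarray, g: np.ndarray, k_percent: float = 10.0,
                   class_axis: int = 0) -> np.ndarray:
    """Analytic gradient of :func:`topk_loss` w.r.t. ``p``.

    Voxels outside the selected hard set receive zero gradient (the
    selection is treated as constant, as in subgradient descent).
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    ce = _per_voxel_ce(p, g, class_axis)
    flat = ce.ravel()
    m = _topk_count(flat.size, k_percent)
    order = np.argsort(flat, kind="stable")
    selected = np.zeros(flat.size, dtype=bool)
    selected[order[flat.size - m:]] = True
    sel = selected.reshape(ce.shape)
    sel = np.expand_dims(sel, class_axis)
    return np.where(sel, -g / np.clip(p, _EPS, None), 0.0) / m


def total_loss(p: np.ndarray, g: np.ndarray,
               config: LossConfig = LossConfig(),
               class_axis: int = 0) -> float:
    """Sum of the Dice and TopK partial losses."""
    return dice_loss(p, g) + topk_loss(p, g, config.k_percent, class_axis)


def total_loss_grad(p: np.ndarray, g: np.ndarray,
                    config: LossConfig = LossConfig(),
                    class_axis: int = 0) -> np.ndarray:
    return (dice_loss_grad(p, g)
            + topk_loss_grad(p, g, config.k_percent, class_axis))


# --------------------------------------------------------------------------
# slicing and batching
# --------------------------------------------------------------------------

_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


def extract_slice(data: np.ndarray, orientation: str, index: int) -> np.ndarray:
    """2D slice of a 3D array along the named anatomical orientation."""
    axis = _AXIS[orientation]
    return np.take(data, index, axis=axis)


def make_batches(subjects: list[tuple[VolumePair, BinaryMask3D]],
                 config: TrainConfig, seed: int,
                 n_batches: int | None = None):
    """Yield (x, y) training batches of mixed-orientation slice pairs.

    ``x`` is (batch_size, 2, N, N): channel 0 baseline, channel 1 follow-up.
    ``y`` is (batch_size, N, N) binary ground truth. Slices are drawn
    uniformly over (subject, orientation, slice index); with few subjects,
    repeats within a batch are possible. Same seed, same sequence.

    ``config.foreground_slice_fraction`` of the batch slots instead draw
    from the lesion-containing slices of the chosen subject/orientation
    (when any exist), counteracting the extreme class imbalance of sparse
    lesions. No slice is ever excluded.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    n = subjects[0][0].shape[0]
    # per (subject, orientation): slice indices containing any foreground
    fg_index: list[list[np.ndarray]] = []
    for pair, gt in subjects:
        per_orient = []
        for o in ORIENTATIONS:
            ax = _AXIS[o]
            other = tuple(a for a in range(3) if a != ax)
            per_orient.append(np.nonzero(gt.data.any(axis=other))[0])
        fg_index.append(per_orient)
    if n_batches is None:
        if config.steps_per_epoch is not None:
            n_batches = config.steps_per_epoch
        else:
            n_batches = max(1, math.ceil(len(subjects) * 3 * n / config.batch_size))
    for _ in range(n_batches):
        x = np.empty((config.batch_size, 2, n, n), dtype=np.float32)
        y = np.empty((config.batch_size, n, n), dtype=np.float32)
        for b in range(config.batch_size):
            si = int(rng.integers(len(subjects)))
            pair, gt = subjects[si]
            oi = int(rng.integers(3))
            orient = ORIENTATIONS[oi]
            candidates = fg_index[si][oi]
            if (candidates.size and rng.random()
                    < config.foreground_slice_fraction):
                idx = int(candidates[rng.integers(candidates.size)])
            else:
                idx = int(rng.integers(pair.shape[_AXIS[orient]]))
            x[b, 0] = extract_slice(pair.baseline.data, orient, idx)
            x[b, 1] = extract_slice(pair.followup.data, orient, idx)
            y[b] = extract_slice(gt.data, orient, idx)
        yield x, y


def _one_hot(y: np.ndarray) -> np.ndarray:
    """(B, N, N) binary → (B, 2, N, N) one-hot."""
    return np.stack([1.0 - y, y], axis=1)


def _batch_loss_and_grad(model: UNet2D, x: np.ndarray, y: np.ndarray,
                         loss_config: LossConfig, train: bool):
    probs = model.forward(x, train=train)
    g = _one_hot(y)
    loss = total_loss(probs, g, loss_config, class_axis=1)
    if not train:
        return loss, None
    dprobs = total_loss_grad(probs, g, loss_config, class_axis=1)
    return loss, dprobs


def _validation_loss(model: UNet2D, val_subjects, config: TrainConfig,
                     loss_config: LossConfig, seed: int) -> float:
    """Mean slice-level loss over a fixed random sample of validation slices."""
    losses = []
    for x, y in make_batches(val_subjects, config, seed,
                             n_batches=max(1, len(val_subjects)
                                           * config.val_slices_per_subject
                                           // config.batch_size)):
        loss, _ = _batch_loss_and_grad(model, x, y, loss_config, train=False)
        losses.append(loss)
    return float(np.mean(losses))


def train_folds(subjects: list[tuple[VolumePair, BinaryMask3D]],
                train_config: TrainConfig = TrainConfig(),
                loss_config: LossConfig = LossConfig(),
                unet_config: UNetConfig = UNetConfig(),
                verbose: bool = False) -> FoldModels:
    """Train one model per fold on random 80-20 subject-level splits.

    The learning rate is halved when the validation loss plateaus and
    training stops early when it stops improving. Splits are subject-level
    so no subject contributes slices to both sides of its own fold.
    """
    if not subjects:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_config.seed)
    n_hold = max(1, round(train_config.holdout_fraction * len(subjects))) \
        if len(subjects) > 1 else 0
    models: list[UNet2D] = []
    assignments: dict[int, list[str]] = {}
    history: list[dict] = []
    for fold in range(train_config.n_folds):
        perm = rng.permutation(len(subjects))
        val_idx = sorted(perm[:n_hold].tolist())
        train_idx = sorted(perm[n_hold:].tolist())
        val_subjects = [subjects[i] for i in val_idx] or [subjects[i] for i in train_idx]
        train_subjects = [subjects[i] for i in train_idx]
        assignments[fold] = [subjects[i][0].followup.id for i in val_idx]

        model = UNet2D(unet_config, seed=int(rng.integers(2 ** 31)))
        opt = SGDMomentum(model.layers(), lr=train_config.lr_initial,
                          momentum=train_config.momentum)
        best_val = np.inf
        plateau = stall = 0
        for epoch in range(train_config.max_epochs):
            epoch_seed = int(rng.integers(2 ** 31))
            batch_losses = []
            for x, y in make_batches(train_subjects, train_config, epoch_seed):
                opt.zero_grad()
                loss, dprobs = _batch_loss_and_grad(model, x, y, loss_config,
                                                    train=True)
                model.backward(dprobs)
                opt.step()
                batch_losses.append(loss)
            val = _validation_loss(model, val_subjects, train_config,
                                   loss_config, seed=train_config.seed + 997)
            history.append({"fold": fold, "epoch": epoch,
                            "train_loss": float(np.mean(batch_losses)),
                            "val_loss": val, "lr": opt.lr})
            if verbose:
                print(f"fold {fold} epoch {epoch}: train "
                      f"{np.mean(batch_losses):.4f} val {val:.4f} lr {opt.lr:g}")
            if val < best_val - 1e-6:
                best_val = val
                plateau = stall = 0
            else:
                plateau += 1
                stall += 1
                if plateau >= train_config.plateau_patience:
                    opt.lr *= train_config.plateau_factor
                    plateau = 0
                if stall >= train_config.early_stop_patience:
                    break
        models.append(model)
    return FoldModels(models=models, fold_assignments=assignments,
                      history=history)
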