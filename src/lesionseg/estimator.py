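"""Scikit-learn style estimator wrapping the full segmentation pipeline."""

from __future__ import annotations

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocessing import PreprocessConfig, preprocess_pair
from .training import FoldModels, LossConfig, TrainConfig, train_folds
from .triplanar import LesionSet, MergeStrategy, segment_pair
from .unet import UNetConfig
from .volume_io import BinaryMask3D, VolumePair

__all__ = ["TriplanarLesionSegmenter"]


class TriplanarLesionSegmenter(BaseEstimator):
    """New-lesion segmenter for longitudinal volume pairs.

    ``fit`` takes a list of :class:`VolumePair` and a list of
    :class:`BinaryMask3D` ground-truth masks, preprocesses every subject
    to a ``cube_size``³ grid, and trains one 2D U-Net per cross-validation
    fold on mixed-orientation slices. ``predict`` runs the fold ensemble
    along the three orthogonal planes and merges the orientation
    predictions with the configured voting strategy.

    Parameters mirror the pipeline configuration; fitted state lives in
    ``models_`` (the fold ensemble) and ``history_`` (per-epoch losses).

    Examples
    --------
    >>> from lesionseg.synthetic import generate_phantom_pair, PhantomParams
    >>> pairs, gts = [], []
    >>> for seed in range(3):
    ...     pair, gt, _ = generate_phantom_pair(PhantomParams(seed=seed))
    ...     pairs.append(pair); gts.append(gt)
    >>> seg = TriplanarLesionSegmenter(cube_size=64, depth=3, base_channels=8,
    ...                                n_folds=1, max_epochs=1,
    ...                                steps_per_epoch=2)
    >>> masks = seg.fit(pairs, gts).predict(pairs[:1])
    """

    def __init__(self, cube_size: int = 256, crop_margin: int = 2,
                 base_channels: int = 32, depth: int = 5,
                 n_folds: int = 5, holdout_fraction: float = 0.2,
                 batch_size: int = 20, lr_initial: float = 0.0001,
                 momentum: float = 0.9, max_epochs: int = 100,
                 steps_per_epoch: int | None = None,
                 plateau_patience: int = 5, early_stop_patience: int = 10,
                 k_percent: float = 10.0,
                 merge: str = "unanimous", threshold: float = 0.5,
                 connectivity: int = 26, seed: int = 0):
        self.cube_size = cube_size
        self.crop_margin = crop_margin
        self.base_channels = base_channels
        self.depth = depth
        self.n_folds = n_folds
        self.holdout_fraction = holdout_fraction
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.steps_per_epoch = steps_per_epoch
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.k_percent = k_percent
        self.merge = merge
        self.threshold = threshold
        self.connectivity = connectivity
        self.seed = seed

    # -- config assembly -------------------------------------------------
    def _preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(cube_size=self.cube_size,
                                crop_margin=self.crop_margin)

    def _strategy(self) -> MergeStrategy:
        return MergeStrategy(kind=self.merge, threshold=self.threshold,
                             connectivity=self.connectivity)

    # -- sklearn API -----------------------------------------------------
    def fit(self, X: list[VolumePair], y: list[BinaryMask3D]
            ) -> "TriplanarLesionSegmenter":
        if len(X) != len(y):
            raise ValueError(f"got {len(X)} pairs but {len(y)} masks")
        if not X:
            raise ValueError("empty training set")
        pcfg = self._preprocess_config()
        subjects = []
        for pair, gt in zip(X, y):
            cube_pair, cube_masks = preprocess_pair(pair, [gt], pcfg)
            subjects.append((cube_pair, cube_masks[0]))
        fold_models = train_folds(
            subjects,
            TrainConfig(batch_size=self.batch_size,
                        lr_initial=self.lr_initial, momentum=self.momentum,
                        plateau_patience=self.plateau_patience,
                        early_stop_patience=self.early_stop_patience,
                        max_epochs=self.max_epochs, n_folds=self.n_folds,
                        holdout_fraction=self.holdout_fraction,
                        steps_per_epoch=self.steps_per_epoch,
                        seed=self.seed),
            LossConfig(k_percent=self.k_percent),
            UNetConfig(base_channels=self.base_channels, depth=self.depth,
                       slice_size=self.cube_size))
        self.models_: FoldModels = fold_models
        self.history_ = fold_models.history
        self.fold_assignments_ = fold_models.fold_assignments
        self.n_features_in_ = 2  # two time-point channels
        return self

    def predict(self, X: list[VolumePair]) -> list[BinaryMask3D]:
        check_is_fitted(self, "models_")
        return [segment_pair(self.models_, pair, self._strategy(),
                             self._preprocess_config())[0] for pair in X]

    def predict_lesions(self, X: list[VolumePair]) -> list[LesionSet]:
        check_is_fitted(self, "models_")
        return [segment_pair(self.models_, pair, self._strategy(),
                             self._preprocess_config())[1] for pair in X]

    def score(self, X: list[VolumePair], y: list[BinaryMask3D]) -> float:
        """Mean lesion-wise F1 across subjects (challenge-style scoring)."""
        from .metrics import evaluate_cohort
        preds = self.predict(X)
        _, mean = evaluate_cohort(list(zip(preds, y)))
        return mean["f1"]
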