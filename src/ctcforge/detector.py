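"""Scikit-learn style estimator facade over the detection model + trainer."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import DetectionDataset
from .evaluation import bootstrap_metrics, evaluate_images, map_at_50
from .model import CTCDetectionModel, get_config
from .training import (TrainConfig, init_adapters, predict_dataset, train)

__all__ = ["CTCDetector"]


class CTCDetector(BaseEstimator):
    """Transformer-based cell detector with copy-paste-aware training.

    Follows the scikit-learn estimator protocol: hyperparameters are
    constructor arguments, :meth:`fit` trains on a detection dataset
    (optionally mixing in a synthetic dataset with the sample-size-weighted
    loss), and fitted state lives in trailing-underscore attributes.

    Parameters
    ----------
    variant : "tiny-test" or "paper-base"
        Architecture preset. "tiny-test" is CPU-sized.
    epochs, batch_size, base_lr, t_max, weight_decay : training recipe.
    multi_scale : tuple of (H, W) sizes sampled per batch.
    lambda_consistency : weight of the augmentation-consistency regularizer
        (active only when synthetic data is present).
    score_threshold, nms_iou : inference-time filtering.
    """

    def __init__(self, variant: str = "tiny-test", epochs: int = 15,
                 batch_size: int = 8, base_lr: float = 0.001, t_max: int = 50,
                 weight_decay: float = 0.05, multi_scale: tuple = ((128, 128),),
                 lambda_consistency: float = 1.0, score_threshold: float = 0.3,
                 nms_iou: float = 0.5, seed: int = 0):
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.t_max = t_max
        self.weight_decay = weight_decay
        self.multi_scale = multi_scale
        self.lambda_consistency = lambda_consistency
        self.score_threshold = score_threshold
        self.nms_iou = nms_iou
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(base_lr=self.base_lr, t_max=self.t_max,
                           epochs=self.epochs, batch_size=self.batch_size,
                           weight_decay=self.weight_decay,
                           multi_scale=tuple(self.multi_scale),
                           lambda_consistency=self.lambda_consistency,
                           score_threshold=self.score_threshold,
                           seed=self.seed)

    def fit(self, X: DetectionDataset, y=None, synthetic: DetectionDataset | None = None):
        """Train on a real detection dataset, optionally mixed with synthetic."""
        from dataclasses import replace

        cfg = replace(get_config(self.variant),
                      n_classes=len(X.class_names))
        model = CTCDetectionModel(cfg, seed=self.seed)
        init_adapters(model, rng=np.random.default_rng(self.seed))
        self.model_, self.history_ = train(model, X, synthetic,
                                           self._train_config())
        self.classes_ = list(X.class_names)
        return self

    def predict(self, X) -> list:
        """Predict scored boxes for a DetectionDataset or an image stack."""
        self._check_fitted()
        if isinstance(X, DetectionDataset):
            return predict_dataset(self.model_, X,
                                   score_threshold=self.score_threshold,
                                   nms_iou=self.nms_iou)
        return self.model_.predict(np.asarray(X),
                                   score_threshold=self.score_threshold,
                                   nms_iou=self.nms_iou)

    def score(self, X: DetectionDataset, y=None) -> float:
        """mAP@0.5 on a held-out detection dataset."""
        records = self.evaluate(X)
        val, _ = map_at_50(records)
        return val

    def evaluate(self, X: DetectionDataset, n_neg: int = 20):
        self._check_fitted()
        preds = self.predict(X)
        return evaluate_images(preds, X, score_threshold=self.score_threshold,
                               n_neg=n_neg, seed=self.seed)

    def report(self, X: DetectionDataset, n_boot: int = 1000):
        """Point metrics plus bootstrap distributions on a test dataset."""
        return bootstrap_metrics(self.evaluate(X), n_boot=n_boot, seed=self.seed)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("CTCDetector is not fitted; call fit() first")
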