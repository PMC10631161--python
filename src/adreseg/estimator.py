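"""Scikit-learn-style estimator facade over the network and trainer.

:class:`TumorSegmenter` bundles architecture and optimization settings as
constructor parameters (so it composes with ``get_params``/``set_params``
and sklearn model selection), trains on a list of preprocessed
image/mask pairs with ``fit``, and segments whole volumes with
``predict``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .infer import binarize, predict_volume
from .metrics import evaluate_case
from .network import NetConfig, SegmentationNetwork
from .trainer import TrainConfig, TrainingCase, train

__all__ = ["TumorSegmenter"]


class TumorSegmenter(BaseEstimator):
    """Volumetric tumor segmentation estimator.

    Parameters mirror the architecture (stem width, transformer depth and
    heads, ablation switches) and the training protocol (Adam schedule
    endpoints, weight decay, slab depth, batch size, seed).  ``fit``
    expects cases whose images are already windowed/resampled/normalized;
    in-plane grid dims must be divisible by 16.

    Attributes set by :meth:`fit` (trailing underscore): ``model_``,
    ``net_config_``, ``train_config_``, ``history_``.
    """

    def __init__(
        self,
        stem_channels: int = 16,
        n_transformer_layers: int = 4,
        n_heads: int = 8,
        use_skip: bool = True,
        use_transformer: bool = True,
        ffn_ratio: int = 4,
        dropout: float = 0.1,
        epochs: int = 1000,
        batch_size: int = 2,
        lr_initial: float = 2e-4,
        lr_final: float = 4e-7,
        weight_decay: float = 1e-5,
        slab_depth: int = 32,
        seed: int = 1000,
        schedule: str = "log",
        warmup_epochs: int = 0,
        fg_slab_bias: float = 0.0,
        adam_beta2: float = 0.999,
        max_steps: int | None = None,
        stop_loss: float | None = None,
    ):
        self.stem_channels = stem_channels
        self.n_transformer_layers = n_transformer_layers
        self.n_heads = n_heads
        self.use_skip = use_skip
        self.use_transformer = use_transformer
        self.ffn_ratio = ffn_ratio
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.weight_decay = weight_decay
        self.slab_depth = slab_depth
        self.seed = seed
        self.schedule = schedule
        self.warmup_epochs = warmup_epochs
        self.fg_slab_bias = fg_slab_bias
        self.adam_beta2 = adam_beta2
        self.max_steps = max_steps
        self.stop_loss = stop_loss

    # ------------------------------------------------------------------
    def _as_cases(self, X, y=None) -> list[TrainingCase]:
        if y is not None:
            return [TrainingCase(np.asarray(img), np.asarray(msk)) for img, msk in zip(X, y)]
        return [c if isinstance(c, TrainingCase) else TrainingCase(*c) for c in X]

    def fit(self, X, y=None) -> "TumorSegmenter":
        """Fit on cases: ``X`` is a list of (image, mask) pairs or
        :class:`TrainingCase` objects (``y`` may carry the masks instead)."""
        cases = self._as_cases(X, y)
        if not cases:
            raise ValueError("no training cases")
        W, H = cases[0].image.shape[:2]
        self.net_config_ = NetConfig(
            input_size=(W, H, self.slab_depth),
            stem_channels=self.stem_channels,
            stage_channels=tuple(self.stem_channels * 2 ** i for i in range(1, 5)),
            n_transformer_layers=self.n_transformer_layers,
            n_heads=self.n_heads,
            use_skip=self.use_skip,
            use_transformer=self.use_transformer,
            ffn_ratio=self.ffn_ratio,
            dropout=self.dropout,
        )
        self.train_config_ = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_initial=self.lr_initial,
            lr_final=self.lr_final,
            weight_decay=self.weight_decay,
            slab_depth=self.slab_depth,
            seed=self.seed,
            schedule=self.schedule,
            warmup_epochs=self.warmup_epochs,
            fg_slab_bias=self.fg_slab_bias,
            adam_beta2=self.adam_beta2,
        )
        self.model_ = SegmentationNetwork(self.net_config_, seed=self.seed)
        self.history_ = train(
            self.model_,
            cases,
            self.train_config_,
            max_steps=self.max_steps,
            stop_loss=self.stop_loss,
        )
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-volume foreground probability maps."""
        self._check_fitted()
        return [predict_volume(self.model_, np.asarray(v), self.slab_depth) for v in X]

    def predict(self, X, threshold: float = 0.5) -> list[np.ndarray]:
        """Binary masks for a list of preprocessed volumes."""
        return [binarize(p, threshold) for p in self.predict_proba(X)]

    def score(self, X, y=None) -> float:
        """Mean Dice score over cases (sklearn greater-is-better contract)."""
        cases = self._as_cases(X, y)
        preds = self.predict([c.image for c in cases])
        return float(
            np.mean([evaluate_case(p, c.mask).dsc for p, c in zip(preds, cases)])
        )

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
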