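"""Scikit-learn style estimator facade over the MC-UNet pipeline.

`MCUNetSegmenter` follows the sklearn estimator contract — keyword-only
constructor mirroring `get_params`/`set_params`, `fit` returning self,
fitted attributes with a trailing underscore — so it composes with
sklearn model selection utilities.  Samples are whole images: ``X`` is
an (n, H, W, 3) uint8 array or a list of such images, ``y`` the matching
binary vessel masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .blocks import DropBlockConfig
from .data import SampleRecord
from .model import ModelConfig, build_model, count_parameters
from .train import TrainConfig, dice_coefficient, predict_image, train


class MCUNetSegmenter(BaseEstimator):
    """Retinal vessel segmenter with a fit/predict interface.

    Parameters
    ----------
    depth, base_channels : U-shape geometry (4 levels, width 16 by default).
    use_dac, use_mkp : enable the bottleneck context modules.
    dilation_rates, pooling_kernels : DAC rates and MKP window sizes.
    block_size, keep_prob : DropBlock regularisation.
    fusion_mode : 'concat' or 'sum' bottleneck fusion.
    epochs, batch_size, learning_rate, loss : training recipe.
    threshold : probability cutoff used by :meth:`predict`.
    random_state : seeds init, DropBlock and shuffling.

    Attributes
    ----------
    model_ : the fitted network.
    history_ : per-epoch training losses.
    n_parameters_ : learnable scalar count of ``model_``.
    """

    def __init__(self, *, depth=4, base_channels=16, use_dac=True,
                 use_mkp=True, dilation_rates=(1, 3, 5),
                 pooling_kernels=(2, 3, 5, 6), block_size=7, keep_prob=0.82,
                 fusion_mode="concat", epochs=20, batch_size=2,
                 learning_rate=1e-3, loss="bce", threshold=0.5,
                 random_state=0):
        self.depth = depth
        self.base_channels = base_channels
        self.use_dac = use_dac
        self.use_mkp = use_mkp
        self.dilation_rates = dilation_rates
        self.pooling_kernels = pooling_kernels
        self.block_size = block_size
        self.keep_prob = keep_prob
        self.fusion_mode = fusion_mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            depth=self.depth, base_channels=self.base_channels,
            use_dac=self.use_dac, use_mkp=self.use_mkp,
            dilation_rates=tuple(self.dilation_rates),
            pooling_kernels=tuple(self.pooling_kernels),
            dropblock=DropBlockConfig(self.block_size, self.keep_prob),
            fusion_mode=self.fusion_mode)

    @staticmethod
    def _as_images(X):
        if isinstance(X, np.ndarray) and X.ndim == 4:
            return [X[i] for i in range(X.shape[0])]
        return [np.asarray(x) for x in X]

    def fit(self, X, y, fov=None):
        """Train on images ``X`` with binary vessel masks ``y``."""
        images = self._as_images(X)
        masks = [np.asarray(m) for m in y]
        if len(images) != len(masks):
            raise ValueError("X and y must have the same length")
        records = []
        for i, (img, mask) in enumerate(zip(images, masks)):
            f = (np.asarray(fov[i]) if fov is not None
                 else np.ones(mask.shape, dtype=np.uint8))
            records.append(SampleRecord(id=f"sample_{i:04d}", image=img,
                                        vessel_mask=mask.astype(np.uint8),
                                        fov_mask=f.astype(np.uint8)))
        model = build_model(self._model_config(), seed=self.random_state)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          learning_rate=self.learning_rate, loss=self.loss,
                          seed=self.random_state)
        self.model_, history = train(model, records, cfg)
        self.history_ = [h["loss"] for h in history]
        self.n_parameters_ = count_parameters(self.model_)
        return self

    def predict_proba(self, X):
        """Per-pixel vessel probabilities, one (H, W) map per image."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return [predict_image(self.model_, img) for img in self._as_images(X)]

    def predict(self, X):
        """Binary vessel masks at the configured threshold."""
        return [(p >= self.threshold).astype(np.uint8)
                for p in self.predict_proba(X)]

    def score(self, X, y, fov=None):
        """Mean Dice overlap against the reference masks."""
        scores = []
        for prob, mask in zip(self.predict_proba(X), y):
            scores.append(dice_coefficient(prob, np.asarray(mask),
                                           self.threshold))
        return float(np.mean(scores))
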