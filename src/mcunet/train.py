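"""Seeded training and inference binding model, data and metrics.

The benchmark papers in this area rarely publish optimiser settings, so
the defaults here are the field's standard recipe: Adam at 1e-3 on
per-pixel binary cross-entropy over full (padded) images, optional soft
Dice or the sum of both.  Runs are fully reproducible given the config
seed: parameter init, DropBlock masks and batch shuffling all derive
from it.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import tensor as T
from .data import SampleRecord, crop_prediction, preprocess
from .metrics import aggregate, report_csv, report_text
from .model import MCUNet, ModelConfig, build_model

__all__ = ["TrainConfig", "Adam", "train", "predict_image", "evaluate",
           "save_checkpoint", "load_checkpoint", "parameter_checksum",
           "dice_coefficient"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 2
    learning_rate: float = 1e-3
    loss: str = "bce"              # {bce, dice, bce+dice}
    seed: int = 0
    checkpoint_dir: str | None = None
    device: str = "cpu"
    patience: int | None = None    # early stop after N epochs w/o improvement

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("bce", "dice", "bce+dice"):
            raise ValueError("loss must be one of bce, dice, bce+dice")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported by this build")


class Adam:
    """Adaptive-moment optimiser over a parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _soft_dice_loss(probs: T.Tensor, target: np.ndarray,
                    smooth: float = 1.0) -> T.Tensor:
    inter = T.tsum(T.mul(probs, target))
    denom = T.add(T.tsum(probs), float(target.sum()))
    dice = T.div(T.add(T.mul(inter, 2.0), smooth), T.add(denom, smooth))
    return T.add(1.0, T.mul(dice, -1.0))


def _loss_fn(model: MCUNet, batch_x: np.ndarray, batch_y: np.ndarray,
             kind: str) -> T.Tensor:
    logits = model.forward_logits(batch_x)
    if kind == "bce":
        return T.bce_with_logits(logits, batch_y)
    probs = T.sigmoid(logits)
    if kind == "dice":
        return _soft_dice_loss(probs, batch_y)
    return T.add(T.bce_with_logits(logits, batch_y),
                 _soft_dice_loss(probs, batch_y))


def _stack_records(records, depth):
    xs, ys = [], []
    for rec in records:
        chw, _ = preprocess(rec.image, depth=depth)
        xs.append(chw)
        mask, _ = preprocess(np.stack([rec.vessel_mask] * 3, -1) * 255,
                             depth=depth)
        ys.append(mask[:1])
    return np.stack(xs), np.stack(ys)


def train(model: MCUNet, records, cfg: TrainConfig):
    """Optimise ``model`` on the given records; returns (model, history).

    ``history`` is a list of per-epoch dicts with the mean training loss.
    The best-loss state is kept and restored at the end (and written to
    ``checkpoint_dir`` when set).  A NaN loss aborts with a diagnostic.
    """
    cfg.validate()
    records = [r for r in records]
    if not records:
        raise ValueError("training requires a nonempty set of records")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    X, Y = _stack_records(records, model.cfg.depth)
    n = len(records)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    best = (np.inf, None)
    since_best = 0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = _loss_fn(model, X[idx], Y[idx], cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={loss.data!r} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        history.append({"epoch": epoch, "loss": mean_loss})
        if mean_loss < best[0]:
            best = (mean_loss, model.state_dict())
            since_best = 0
        else:
            since_best += 1
        if cfg.patience is not None and since_best > cfg.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    if cfg.checkpoint_dir:
        os.makedirs(cfg.checkpoint_dir, exist_ok=True)
        save_checkpoint(model, os.path.join(cfg.checkpoint_dir, "best.npz"))
    return model, history


def predict_image(model: MCUNet, image: np.ndarray) -> np.ndarray:
    """Probability map for an arbitrary-size RGB image.

    Pads reflectively to the network's divisibility requirement, runs the
    model in inference mode, crops back.  Values lie strictly in (0, 1).
    """
    was_training = model.training
    model.eval()
    chw, pad = preprocess(image, depth=model.cfg.depth)
    probs = model(chw[None])
    if was_training:
        model.train()
    return crop_prediction(probs.data[0, 0], pad)


def evaluate(model: MCUNet, records, *, threshold: float = 0.5,
             use_fov: bool = True, mode: str = "pooled",
             dataset_name: str = "dataset", report_path: str | None = None):
    """Pooled ACC/SEN/SP/AUC/F1 over the records' FOV pixels.

    Returns the metric dict; optionally writes a CSV report.
    """
    items = [(predict_image(model, r.image), r.vessel_mask, r.fov_mask)
             for r in records]
    row = aggregate(items, mode=mode, threshold=threshold, use_fov=use_fov)
    results = {dataset_name: row}
    if report_path:
        report_csv(results, report_path)
    return row, report_text(results)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray,
                     threshold: float = 0.5) -> float:
    """Hard Dice overlap of a thresholded probability map vs a mask."""
    p = np.asarray(pred) >= threshold
    t = np.asarray(truth) > 0.5
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


# ---------------------------------------------------------------------------
# checkpoints / determinism helpers
# ---------------------------------------------------------------------------

def save_checkpoint(model: MCUNet, path):
    """Store the flat parameter enumeration plus the building config."""
    state = model.state_dict()
    np.savez(path, __config__=yaml.safe_dump(model.cfg.to_dict()), **state)


def load_checkpoint(path) -> MCUNet:
    with np.load(path, allow_pickle=False) as archive:
        cfg = ModelConfig.from_dict(yaml.safe_load(str(archive["__config__"])))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    model.eval()
    return model


def parameter_checksum(model: MCUNet) -> str:
    """SHA-256 over the ordered parameter bytes (training determinism)."""
    h = hashlib.sha256()
    for name, p in sorted(model.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
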