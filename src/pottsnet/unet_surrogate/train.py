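"""Training loop for the surrogate: composite BCE + 10x MSE loss, Adam, history.

The loss balances the two output channels the way the published setup does:
per-pixel binary cross-entropy on the vessel-mask channel plus mean-squared
error on the field channel scaled by 10.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np

from ..dataset_builder import PairDataset, TwoChannelFrame
from .model import SurrogateConfig, UNet, build_surrogate

__all__ = ["TrainingHistory", "composite_loss", "train"]

_EPS = 1e-7


@dataclass
class TrainingHistory:
    """Per-epoch losses and timing; ``epochs_run`` always equals the rows recorded."""

    train_loss: List[float] = dc_field(default_factory=list)
    test_loss: List[float] = dc_field(default_factory=list)
    train_bce: List[float] = dc_field(default_factory=list)
    train_mse: List[float] = dc_field(default_factory=list)
    epoch_wall_time: List[float] = dc_field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "test_loss": self.test_loss,
            "train_bce": self.train_bce,
            "train_mse": self.train_mse,
            "epoch_wall_time": self.epoch_wall_time,
        }


def composite_loss(
    prediction: TwoChannelFrame,
    target: TwoChannelFrame,
    mask_weight: float = 1.0,
    field_weight: float = 10.0,
) -> float:
    """BCE(mask probabilities, binary target) + 10 x MSE(field, target field).

    The prediction's mask channel must hold probabilities; the target's must
    be strictly binary.
    """
    mask_p = np.asarray(prediction.mask, dtype=np.float64)
    mask_t = np.asarray(target.mask, dtype=np.float64)
    if mask_p.shape != mask_t.shape or prediction.field.shape != target.field.shape:
        raise ValueError("prediction and target shapes differ")
    if not np.isin(np.unique(mask_t), (0.0, 1.0)).all():
        raise ValueError("target mask must be binary")
    p = np.clip(mask_p, _EPS, 1.0 - _EPS)
    bce = float(-np.mean(mask_t * np.log(p) + (1.0 - mask_t) * np.log(1.0 - p)))
    mse = float(np.mean((np.asarray(prediction.field, dtype=np.float64) - target.field) ** 2))
    return mask_weight * bce + field_weight * mse


def _loss_and_grads(
    model: UNet, x: np.ndarray, y: np.ndarray, mask_w: float, field_w: float
) -> Tuple[float, float, float]:
    """Forward + backward on one batch; returns (loss, bce, mse).

    Uses the numerically stable logits form of BCE; gradients of the batch
    mean flow into ``model.backward``.
    """
    logits, fld = model.forward(x)
    y_mask = y[:, :1]
    y_field = y[:, 1:]
    z = logits
    # log(1 + e^-|z|) + max(z, 0) - z*y  == -log sigmoid(z)*y - log(1-sigmoid)*(1-y)
    bce_map = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y_mask
    bce = float(bce_map.mean())
    diff = fld - y_field
    mse = float(np.mean(diff ** 2))
    n = z.size
    d_logits = mask_w * (1.0 / (1.0 + np.exp(-z)) - y_mask) / n
    d_field = field_w * 2.0 * diff / diff.size
    model.backward(d_logits.astype(np.float32), d_field.astype(np.float32))
    return mask_w * bce + field_w * mse, bce, mse


def _batch_arrays(dataset: PairDataset, rows: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for j in rows:
        i_in, i_tgt = dataset.pair_indices[j]
        xs.append(np.stack([dataset.masks[i_in].astype(np.float32),
                            dataset.fields[i_in]]))
        ys.append(np.stack([dataset.masks[i_tgt].astype(np.float32),
                            dataset.fields[i_tgt]]))
    return np.stack(xs), np.stack(ys)


def _eval_loss(model: UNet, dataset: PairDataset, rows: np.ndarray,
               mask_w: float, field_w: float, batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(rows), batch_size):
        x, y = _batch_arrays(dataset, rows[start:start + batch_size])
        logits, fld = model.forward(x)
        z = logits
        y_mask, y_field = y[:, :1], y[:, 1:]
        bce = float((np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y_mask).mean())
        mse = float(np.mean((fld - y_field) ** 2))
        total += (mask_w * bce + field_w * mse) * len(x)
        count += len(x)
    return total / max(count, 1)


def train(
    dataset: PairDataset,
    config: SurrogateConfig,
    test_dataset: Optional[PairDataset] = None,
    model: Optional[UNet] = None,
    log: Optional[callable] = None,
) -> Tuple[UNet, TrainingHistory]:
    """Train the surrogate on (frame, frame+horizon) pairs.

    Seeded end to end: weight initialization and epoch shuffling both derive
    from ``config.seed``, so histories reproduce to float tolerance.  A
    non-finite loss aborts with diagnostics rather than training on.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset has no pairs")
    if model is None:
        model = build_surrogate(config)
    opt = model.make_optimizer()
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    mask_w, field_w = config.loss_mask_weight, config.loss_field_weight
    n = len(dataset)
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        ep_loss = ep_bce = ep_mse = 0.0
        for start in range(0, n, config.batch_size):
            rows = order[start:start + config.batch_size]
            x, y = _batch_arrays(dataset, rows)
            opt.zero_grad()
            loss, bce, mse = _loss_and_grads(model, x, y, mask_w, field_w)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting at {start} (bce={bce}, mse={mse})"
                )
            opt.step()
            ep_loss += loss * len(rows)
            ep_bce += bce * len(rows)
            ep_mse += mse * len(rows)
        history.train_loss.append(ep_loss / n)
        history.train_bce.append(ep_bce / n)
        history.train_mse.append(ep_mse / n)
        if test_dataset is not None and len(test_dataset) > 0:
            history.test_loss.append(
                _eval_loss(model, test_dataset, np.arange(len(test_dataset)),
                           mask_w, field_w, config.batch_size)
            )
        else:
            history.test_loss.append(float("nan"))
        history.epoch_wall_time.append(time.time() - t0)
        if log is not None:
            log(epoch, history)
    return model, history
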