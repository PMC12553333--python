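"""Task-conditioned losses, seeded mini-batch training, and prediction.

The loss is a pure function of the task declaration:

* single/pair regression      -> mean squared error
* single classification       -> softmax + cross-entropy (also for binary)
* pair binary classification  -> sigmoid + binary cross-entropy
* residue classification      -> per-token softmax cross-entropy, averaged
  over the true (non-pad) length T of each sequence, then over the batch

The single-vs-pair binary asymmetry (softmax+CE vs sigmoid+BCE) is kept
deliberately.  Training runs seeded shuffled mini-batches under Adam and is
bit-deterministic given (data, config, seed); the final-epoch model is
returned together with the full per-epoch history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DatasetSplit, Record, TaskSpec, TrainConfig
from .errors import IncompatibleTask, NonFiniteLoss
from .nn import Adam
from .nn import tensor as T
from .nn.tensor import Tensor
from .zoo.base import PredictorModel
from .zoo.batches import ModelBatch


@dataclass(frozen=True)
class LossSpec:
    """Which loss a task uses; reduction is always a batch mean (and a mean
    over the T real residues first, for residue-level tasks)."""

    kind: str  # mse | cross_entropy | binary_cross_entropy | residue_cross_entropy


def loss_for_task(task_spec: TaskSpec) -> LossSpec:
    if task_spec.level == "residue":
        return LossSpec("residue_cross_entropy")
    if task_spec.objective == "regression":
        return LossSpec("mse")
    if task_spec.arity == "pair" and task_spec.objective == "binary":
        return LossSpec("binary_cross_entropy")
    return LossSpec("cross_entropy")


# -- loss kernels (autodiff Tensors) --------------------------------------

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    d = pred - Tensor(np.asarray(target, dtype=pred.dtype))
    return T.tmean(d * d)


def cross_entropy_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Softmax cross-entropy; ``target`` holds class indices."""
    lp = T.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(len(target)), np.asarray(target, dtype=int)] = 1.0
    return -T.tmean(T.tsum(lp * Tensor(onehot), axis=-1))


def binary_cross_entropy_loss(logit: Tensor, target: np.ndarray) -> Tensor:
    """Sigmoid + BCE from raw logits, numerically stable:
    max(z,0) - z*y + log(1 + exp(-|z|))."""
    y = Tensor(np.asarray(target, dtype=logit.dtype))
    return T.tmean(T.relu(logit) - logit * y +
                   T.log(1.0 + T.exp(-T.tabs(logit))))


def residue_cross_entropy_loss(logits: Tensor, target: np.ndarray,
                               mask: np.ndarray) -> Tensor:
    """Per-token CE averaged over each sequence's real length, then the batch."""
    B, L, C = logits.shape
    lp = T.log_softmax(logits, axis=-1)
    onehot = np.zeros((B, L, C), dtype=logits.dtype)
    b, l = np.nonzero(mask > 0)
    onehot[b, l, np.asarray(target)[b, l]] = 1.0
    tok_ll = T.tsum(lp * Tensor(onehot), axis=-1)          # (B, L)
    lengths = np.maximum(mask.sum(axis=1), 1.0).astype(logits.dtype)
    per_seq = T.tsum(tok_ll * Tensor(mask.astype(logits.dtype)), axis=1) \
        * Tensor(1.0 / lengths)
    return -T.tmean(per_seq)


def compute_loss(loss_spec: LossSpec, pred: Tensor, batch: ModelBatch) -> Tensor:
    if loss_spec.kind == "mse":
        return mse_loss(pred, batch.labels)
    if loss_spec.kind == "cross_entropy":
        return cross_entropy_loss(pred, batch.labels)
    if loss_spec.kind == "binary_cross_entropy":
        return binary_cross_entropy_loss(pred, batch.labels)
    if loss_spec.kind == "residue_cross_entropy":
        return residue_cross_entropy_loss(pred, batch.labels, batch.label_mask)
    raise ValueError(f"unknown loss {loss_spec.kind!r}")


# -- history --------------------------------------------------------------

@dataclass
class TrainHistory:
    """Per-epoch training loss and validation metrics."""

    epochs: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    valid_metrics: List[dict] = field(default_factory=list)

    def append(self, epoch: int, loss: float, metrics: dict) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(loss)
        self.valid_metrics.append(metrics)

    def __len__(self) -> int:
        return len(self.epochs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, l, m in zip(self.epochs, self.train_loss, self.valid_metrics):
            rows.append({"epoch": e, "loss": l, **m})
        return pd.DataFrame(rows)


# -- training loop --------------------------------------------------------

def _length_key(rec) -> int:
    if hasattr(rec, "sequence_a"):
        return len(rec.sequence_a) + len(rec.sequence_b)
    return len(rec.sequence)


def _bucketed_batches(rng: np.random.Generator, lengths: np.ndarray,
                      batch_size: int, bucket_factor: int = 8):
    """Seeded length-bucketed mini-batches.

    Records are shuffled, grouped into buckets of ``bucket_factor`` batches,
    sorted by length within each bucket, cut into batches, and the batch
    order reshuffled.  Batch composition stays randomized across epochs
    while padded batch length (hence attention/convolution cost) drops.
    """
    n = len(lengths)
    order = rng.permutation(n)
    batches = []
    span = batch_size * bucket_factor
    for lo in range(0, n, span):
        chunk = order[lo:lo + span]
        chunk = chunk[np.argsort(lengths[chunk], kind="stable")]
        batches.extend(chunk[i:i + batch_size]
                       for i in range(0, len(chunk), batch_size))
    perm = rng.permutation(len(batches))
    return [batches[i] for i in perm]

def train(
    model: PredictorModel,
    split: DatasetSplit,
    task_spec: TaskSpec,
    train_config: Optional[TrainConfig] = None,
) -> Tuple[PredictorModel, TrainHistory]:
    """Seeded mini-batch Adam training; returns the final-epoch model and
    the full history (per-epoch validation metrics allow post-hoc
    best-epoch selection)."""
    from .evaluation import compute_metrics  # local import to avoid a cycle

    cfg = train_config or TrainConfig(learning_rate=model.config.learning_rate)
    if not split.train:
        raise ValueError("empty training split")
    loss_spec = loss_for_task(task_spec)
    rng = np.random.default_rng(cfg.seed)
    from .nn.layers import Dropout
    for mod in model.modules():  # TrainConfig owns the training-time rate
        if isinstance(mod, Dropout):
            mod.rate = cfg.dropout
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    n = len(split.train)
    lengths = np.asarray([_length_key(r) for r in split.train])
    from .evaluation import primary_metric
    watch_metric = primary_metric(task_spec)
    watch_lower_better = watch_metric in ("mse", "mae")
    best_score = best_state = None
    best_epoch = -1
    for epoch in range(cfg.max_epochs):
        model.set_training(True, rng)
        batches = _bucketed_batches(rng, lengths, cfg.batch_size)
        total, count = 0.0, 0
        for idx in batches:
            recs = [split.train[i] for i in idx]
            batch = model.prepare(recs)
            pred = model(batch)
            loss = compute_loss(loss_spec, pred, batch)
            if not np.isfinite(loss.data):
                raise NonFiniteLoss(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(recs)
            count += len(recs)
        model.set_training(False)
        metrics = {}
        if split.valid:
            from .errors import ProtbenchError
            preds = predict(model, split.valid, task_spec,
                            batch_size=cfg.batch_size)
            try:
                metrics = compute_metrics(task_spec, preds, split.valid).values
            except ProtbenchError:
                metrics = {}  # degenerate tiny validation split
        history.append(epoch, total / max(count, 1), metrics)
        if cfg.early_stop_patience is not None and metrics:
            value = metrics.get(watch_metric)
            if value is not None:
                score = -value if watch_lower_better else value
                if best_score is None or score > best_score:
                    best_score, best_epoch = score, epoch
                    best_state = model.state_dict()
                elif epoch - best_epoch >= cfg.early_stop_patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.set_training(False)
    return model, history


def predict(
    model: PredictorModel,
    records: Sequence[Record],
    task_spec: TaskSpec,
    batch_size: int = 32,
) -> pd.DataFrame:
    """Deterministic (eval-mode) prediction table.

    One row per record; residue-level tasks emit one row per (id, position).
    Classification rows carry class probabilities ``prob_0..`` (or ``prob``
    for the pair-binary sigmoid) next to the raw scores.
    """
    if model.task_spec != task_spec:
        raise IncompatibleTask(
            f"model was built for {model.task_spec.name!r}, not {task_spec.name!r}")
    model.set_training(False)
    rows: List[dict] = []
    records = list(records)
    for lo in range(0, len(records), batch_size):
        recs = records[lo:lo + batch_size]
        batch = model.prepare(recs)
        out = model(batch).data
        if task_spec.level == "residue":
            probs = _softmax_np(out)
            for i, rec in enumerate(recs):
                L = len(rec.sequence)
                for t in range(min(L, out.shape[1])):
                    row = {"id": rec.id, "position": t,
                           "pred": int(np.argmax(out[i, t]))}
                    for c in range(out.shape[2]):
                        row[f"score_{c}"] = float(out[i, t, c])
                        row[f"prob_{c}"] = float(probs[i, t, c])
                    rows.append(row)
        elif task_spec.objective == "regression":
            for rec, y in zip(recs, out):
                rows.append({"id": rec.id, "score": float(y),
                             "pred": float(y)})
        elif out.ndim == 1:  # pair binary logit
            p = 1.0 / (1.0 + np.exp(-out))
            for rec, z, pi in zip(recs, out, p):
                rows.append({"id": rec.id, "score": float(z),
                             "prob": float(pi), "pred": int(pi >= 0.5)})
        else:
            probs = _softmax_np(out)
            for i, rec in enumerate(recs):
                row = {"id": rec.id, "pred": int(np.argmax(out[i]))}
                for c in range(out.shape[1]):
                    row[f"score_{c}"] = float(out[i, c])
                    row[f"prob_{c}"] = float(probs[i, c])
                rows.append(row)
    return pd.DataFrame(rows)


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
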