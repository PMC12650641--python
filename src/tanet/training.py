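"""Loss, schedules and the seeded training loop.

The loss is class-weighted, label-smoothed cross-entropy: for true class y
and predicted probabilities p,

    L = - sum_i  w_i * [ (1 - eps) * 1{i=y} + eps / C ] * log p_i ,

averaged over the batch.  Class weights are inverse-frequency with mean-one
normalisation, recomputed on every training fold.  Optimisation is AdamW
(decoupled weight decay, beta1=0.9, beta2=0.999) with gradient accumulation,
global-norm clipping at 1.0, a cosine or one-cycle learning-rate schedule,
and early stopping on validation accuracy with best-weight restoration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .backbone import TANet
from .nn import Tensor, no_grad
from .nn.optim import AdamW, clip_grad_norm

__all__ = ["LossConfig", "TrainConfig", "compute_class_weights",
           "weighted_smoothed_ce", "lr_schedule", "train", "predict_proba"]

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12


@dataclass
class LossConfig:
    n_classes: int
    class_weights: np.ndarray = None
    label_smoothing: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")
        if self.class_weights is None:
            self.class_weights = np.ones(self.n_classes)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if (self.class_weights <= 0).any():
            raise ValueError("class weights must be positive")


@dataclass
class TrainConfig:
    lr: float = 0.002
    weight_decay: float = 1e-4
    batch_size: int = 96
    epochs: int = 100
    grad_clip_norm: float = 1.0
    accum_steps: int = 2
    scheduler: str = "one_cycle"
    early_stop_patience: int = 15
    label_smoothing: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if self.scheduler not in ("cosine", "one_cycle"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")

    @classmethod
    def seed_protocol(cls, **overrides) -> "TrainConfig":
        """Hyperparameters of the 3-class, 62-channel protocol."""
        defaults = dict(lr=0.002, weight_decay=1e-4, batch_size=96,
                        scheduler="one_cycle")
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def deap_protocol(cls, **overrides) -> "TrainConfig":
        """Hyperparameters of the binary, 32-channel protocol."""
        defaults = dict(lr=0.0005, weight_decay=1e-3, batch_size=32,
                        scheduler="cosine")
        defaults.update(overrides)
        return cls(**defaults)


def compute_class_weights(labels: np.ndarray,
                          n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency weights ``w_i = N / (C * n_i)`` (their count-
    weighted mean is exactly 1)."""
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0)
        raise ValueError(
            f"degenerate fold: classes {empty.tolist()} have no samples")
    return len(labels) / (n_classes * counts.astype(float))


def weighted_smoothed_ce(pred_probs: np.ndarray, y: np.ndarray,
                         cfg: LossConfig) -> float:
    """Batch-mean of the weighted, label-smoothed cross-entropy on
    probability rows.  ``y`` may be integer labels or one-hot rows.  Zero
    probabilities are floored before the log (and logged)."""
    p = np.atleast_2d(np.asarray(pred_probs, dtype=float))
    y = np.asarray(y)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    C = cfg.n_classes
    eps = cfg.label_smoothing
    onehot = np.eye(C)[y]
    target = cfg.class_weights[None, :] * ((1.0 - eps) * onehot + eps / C)
    if (p < _LOG_FLOOR).any() & (target[p < _LOG_FLOOR] > 0).any():
        logger.warning("flooring zero predicted probabilities before log")
    return float(-(target * np.log(np.maximum(p, _LOG_FLOOR))).sum(axis=1).mean())


def _loss_from_logits(logits: Tensor, y: np.ndarray, cfg: LossConfig) -> Tensor:
    """Autograd path: same loss evaluated through a log-softmax."""
    C = cfg.n_classes
    eps = cfg.label_smoothing
    onehot = np.eye(C)[np.asarray(y)]
    target = cfg.class_weights[None, :] * ((1.0 - eps) * onehot + eps / C)
    logp = logits.log_softmax(axis=-1)
    return -(Tensor(target) * logp).sum(axis=1).mean()


def lr_schedule(step: int, total_steps: int, kind: str, lr0: float,
                warmup_frac: float = 0.3) -> float:
    """Learning rate at optimiser step ``step`` of ``total_steps``.

    ``cosine``: half-cosine decay from lr0 to 0.  ``one_cycle``: linear
    warm-up from lr0/25 to the lr0 peak over ``warmup_frac`` of the run,
    then cosine annealing down to lr0/100.
    """
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    if kind == "cosine":
        return lr0 * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
    if kind == "one_cycle":
        warm = warmup_frac * total_steps
        start, final = lr0 / 25.0, lr0 / 100.0
        if step <= warm:
            frac = step / warm if warm > 0 else 1.0
            return start + (lr0 - start) * frac
        frac = (step - warm) / max(total_steps - warm, 1e-12)
        return final + (lr0 - final) * 0.5 * (1.0 + np.cos(np.pi * frac))
    raise ValueError(f"unknown scheduler kind {kind!r}")


def predict_proba(model: TANet, de: np.ndarray, psd: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Eval-mode class probabilities, batched to bound memory."""
    was_training = model.training
    model.eval()
    chunks = []
    with no_grad():
        for lo in range(0, len(de), batch_size):
            chunks.append(model.forward(de[lo:lo + batch_size],
                                        psd[lo:lo + batch_size]).numpy())
    if was_training:
        model.train()
    return np.concatenate(chunks, axis=0)


def train(model: TANet, train_set, val_set, cfg: TrainConfig):
    """Train ``model`` on ``train_set = (de, psd, labels)`` and early-stop
    on ``val_set`` accuracy.

    Returns ``(model, history)`` where the model carries the best-validation
    weights and ``history`` maps per-epoch lists: ``train_loss``,
    ``train_acc``, ``val_loss``, ``val_acc``, ``lr``, ``grad_norm`` (post
    clipping).
    """
    de_tr, psd_tr, y_tr = (np.asarray(a) for a in train_set)
    de_va, psd_va, y_va = (np.asarray(a) for a in val_set)
    n_classes = model.cfg.n_classes
    weights = compute_class_weights(y_tr, n_classes)
    loss_cfg = LossConfig(n_classes=n_classes, class_weights=weights,
                          label_smoothing=cfg.label_smoothing)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    n = len(y_tr)
    micro = max(1, cfg.batch_size // cfg.accum_steps)
    micro_per_epoch = int(np.ceil(n / micro))
    updates_per_epoch = int(np.ceil(micro_per_epoch / cfg.accum_steps))
    total_updates = cfg.epochs * updates_per_epoch

    history = {k: [] for k in ("train_loss", "train_acc", "val_loss",
                               "val_acc", "lr", "grad_norm")}
    best_acc, best_state, since_best = -np.inf, model.state_dict(), 0
    update = 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses, epoch_correct = [], 0
        pending = 0
        for start in range(0, n, micro):
            idx = order[start:start + micro]
            logits = model.forward_logits(de_tr[idx], psd_tr[idx])
            loss = _loss_from_logits(logits, y_tr[idx], loss_cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, update {update}: "
                    f"{loss.item()} (lr={opt.lr:.3g})")
            # scale so accumulated micro-batches average like one large batch
            (loss * (1.0 / cfg.accum_steps)).backward()
            epoch_losses.append(loss.item())
            epoch_correct += int((logits.data.argmax(axis=1) == y_tr[idx]).sum())
            pending += 1
            if pending == cfg.accum_steps or start + micro >= n:
                opt.lr = lr_schedule(update, total_updates, cfg.scheduler,
                                     cfg.lr)
                pre = clip_grad_norm(model.parameters(), cfg.grad_clip_norm)
                history["grad_norm"].append(min(pre, cfg.grad_clip_norm))
                opt.step()
                opt.zero_grad()
                history["lr"].append(opt.lr)
                update += 1
                pending = 0

        val_probs = predict_proba(model, de_va, psd_va)
        val_loss = weighted_smoothed_ce(val_probs, y_va, loss_cfg)
        val_acc = float((val_probs.argmax(axis=1) == y_va).mean())
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["train_acc"].append(epoch_correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        logger.info("epoch %d: train_loss=%.4f val_acc=%.4f", epoch,
                    history["train_loss"][-1], val_acc)

        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best val_acc %.4f)",
                            epoch, best_acc)
                break

    model.load_state_dict(best_state)
    model.eval()
    return model, history
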