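"""Losses and the optimization loop.

Training combines a supervised multi-label binary cross-entropy with an
InfoNCE contrastive term: each batch is forwarded twice, once clean and
once with sign-preserving bounded noise injected into the lifted node
features, and the two graph-level representations form the positive pairs.
The total loss is the (by default unweighted) sum of the two.  Adam with
early stopping on validation loss; everything is seeded and the loop is
single-threaded deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor
from .nn import Adam, clip_grad_norm
from .model import FunctionPredictor, batch_graphs

__all__ = ["TrainConfig", "TrainReport", "perturb_features", "info_nce",
           "bce_loss", "total_loss", "train"]


def perturb_features(h: np.ndarray, eps_max: float, seed: int) -> np.ndarray:
    """h' = h + |eps| * sign(h) with eps ~ U(0, eps_max) componentwise.

    Sign-preserving: nonzero entries keep their sign and move away from
    zero by at most eps_max; zero entries are unchanged (sign(0) = 0).
    """
    if eps_max < 0:
        raise ValueError("eps_max must be nonnegative")
    h = np.asarray(h, dtype=np.float64)
    rng = np.random.default_rng(seed)
    eps = rng.uniform(0.0, eps_max, size=h.shape)
    return h + np.abs(eps) * np.sign(h)


def info_nce(Z: Tensor | np.ndarray, Zp: Tensor | np.ndarray,
             tau: float = 0.5) -> Tensor:
    """InfoNCE over cosine similarities with temperature `tau`.

    Row m of Z (clean view) is pulled toward row m of Zp (perturbed view)
    and pushed from all other rows of Zp.  Returns a scalar Tensor; exactly
    zero when M = 1.
    """
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    Zp = Zp if isinstance(Zp, Tensor) else Tensor(Zp)
    M = Z.shape[0]
    if M < 1:
        raise ValueError("need at least one sample")
    if np.any(np.linalg.norm(Z.data, axis=1) == 0) or \
       np.any(np.linalg.norm(Zp.data, axis=1) == 0):
        raise ValueError("zero-norm representation row; cosine undefined")
    Zn = Z / Z.norm(axis=-1, keepdims=True)
    Zpn = Zp / Zp.norm(axis=-1, keepdims=True)
    S = (Zn @ Zpn.transpose()) / tau                      # (M, M)
    # stable log-sum-exp with a detached shift
    shift = S.data.max(axis=1, keepdims=True)
    lse = (S - Tensor(shift)).exp().sum(axis=1).log() + Tensor(shift[:, 0])
    diag = S[np.arange(M), np.arange(M)]
    return (lse - diag).mean()


def bce_loss(y: np.ndarray, y_hat: Tensor | np.ndarray,
             clip: float = 1e-12) -> Tensor:
    """Mean binary cross-entropy over all protein-term pairs.

    Predictions are clipped away from {0, 1} by `clip` before the logs.
    """
    y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(y_hat)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {y_hat.shape}")
    p = y_hat.clip_min(clip)
    q = (1.0 - y_hat).clip_min(clip)
    yt = Tensor(y)
    return -(yt * p.log() + (1.0 - yt) * q.log()).mean()


def total_loss(l_sup, l_reg, weights: tuple = (1.0, 1.0)):
    """Weighted sum of the supervised and contrastive terms (default 1:1)."""
    w1, w2 = weights
    return w1 * l_sup + w2 * l_reg


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    tau: float = 0.5
    eps_max: float = 0.1
    seed: int = 0
    loss_weights: tuple = (1.0, 1.0)
    grad_clip: float = 1.0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        for name in ("learning_rate", "batch_size", "max_epochs", "patience", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eps_max < 0:
            raise ValueError("eps_max must be nonnegative")


@dataclass
class TrainReport:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    initial_train_loss: float = float("nan")   # at initialization, pre-update
    stopping_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainReport":
        return cls(**json.loads(text))


def _epoch_loss(model: FunctionPredictor, graphs, labels, cfg: TrainConfig,
                rng: np.random.Generator, optimizer: Adam | None):
    """One pass over `graphs`; updates parameters when `optimizer` is given."""
    training = optimizer is not None
    model.set_training(training)
    n = len(graphs)
    order = rng.permutation(n) if training else np.arange(n)
    losses, sizes = [], []
    use_contrastive = cfg.loss_weights[1] != 0.0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        batch = batch_graphs([graphs[i] for i in idx])
        y = labels[idx]
        out = model.forward(batch, rng=rng)
        l_sup = bce_loss(y, out["scores"])
        if use_contrastive and len(idx) > 0:
            out_p = model.forward(batch, rng=rng, perturb_eps=cfg.eps_max)
            l_reg = info_nce(out["z"], out_p["z"], cfg.tau)
        else:
            l_reg = Tensor(0.0)
        loss = total_loss(l_sup, l_reg, cfg.loss_weights)
        if training:
            optimizer.zero_grad()
            loss.backward()
            clip_grad_norm(optimizer.params, cfg.grad_clip)
            optimizer.step()
        losses.append(float(loss.data))
        sizes.append(len(idx))
    return float(np.average(losses, weights=sizes))


def train(model: FunctionPredictor, train_graphs: list, train_labels: np.ndarray,
          val_graphs: list, val_labels: np.ndarray,
          cfg: TrainConfig | None = None,
          validation_hook=None) -> tuple:
    """Optimize `model` in place; returns (best_state_dict, TrainReport).

    Early stopping: training halts after `cfg.patience` consecutive epochs
    without improvement of the validation loss; the best-validation
    parameter snapshot is returned (and loaded back into the model).
    `validation_hook(model, epoch) -> float`, if given, replaces the
    built-in validation loss (used by tests to engineer plateaus).
    """
    cfg = cfg or TrainConfig()
    if len(train_graphs) == 0 or len(val_graphs) == 0:
        raise ValueError("empty training or validation split")
    train_labels = np.asarray(train_labels, dtype=np.float64)
    val_labels = np.asarray(val_labels, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    val_rng_seed = int(rng.integers(2**31))
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    report = TrainReport(seed=cfg.seed)
    report.initial_train_loss = _epoch_loss(
        model, train_graphs, train_labels, cfg, np.random.default_rng(cfg.seed), None)
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        train_loss = _epoch_loss(model, train_graphs, train_labels, cfg, rng, optimizer)
        if validation_hook is not None:
            val_loss = float(validation_hook(model, epoch))
        else:
            val_rng = np.random.default_rng(val_rng_seed)
            val_loss = _epoch_loss(model, val_graphs, val_labels, cfg, val_rng, None)
        report.train_losses.append(train_loss)
        report.val_losses.append(val_loss)
        report.stopping_epoch = epoch
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model.set_training(False)
    return best_state, report
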