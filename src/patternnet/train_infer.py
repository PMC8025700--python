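"""Training loop (Adam + augmentation + exponential lr decay) and inference.

Training follows the published protocol: Adam starting at learning rate
1e-3, decayed exponentially per epoch to a floor of 1e-4, batch size 10,
random rotation / scale / translation augmentation so the learned model is
transformation robust.  The random decomposition seed is refreshed every
epoch during training (an extra regularizer — the decomposition is random
by construction) and fixed at inference so predictions are deterministic.

All clouds in a run must share the same point count ``M``; resample first
with :func:`patternnet.pointcloud_io.resample_to_count` if they do not.
Clouds are centroid-centered and unit-sphere scaled internally.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import loss as loss_mod
from .metrics import evaluate_segmentation
from .network import (ForwardResult, ModelParams, NetworkConfig, backward,
                      forward, init_params)
from .pointcloud_io import LabeledCloud, normalize

__all__ = ["TrainConfig", "TrainHistory", "augment", "fit", "predict"]


@dataclass
class TrainConfig:
    lr_start: float = 0.001
    lr_end: float = 0.0001
    batch_size: int = 10
    epochs: int = 30
    seed: int = 0
    rotation_range: tuple[float, float] = (0.0, 2.0 * np.pi)   # about vertical axis
    scale_range: tuple[float, float] = (0.8, 1.25)
    translation_range: tuple[float, float] = (-0.1, 0.1)       # normalized units
    augment_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("need lr_start >= lr_end > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        """Exponential decay from lr_start to lr_end over the configured epochs."""
        if self.epochs <= 1 or self.lr_start == self.lr_end:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return float(self.lr_start * (self.lr_end / self.lr_start) ** min(frac, 1.0))


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    segmentation_loss: list[float] = field(default_factory=list)
    mapping_loss: list[float] = field(default_factory=list)
    total_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    val_mean_accuracy: list[float] = field(default_factory=list)
    val_mean_iou: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.__dict__.items()}


def augment(cloud: LabeledCloud, rng: np.random.Generator,
            cfg: TrainConfig) -> LabeledCloud:
    """Random rotation about +z, isotropic scale and per-axis translation.

    Labels are untouched; the draw order (angle, scale, translation) is
    fixed so a seeded generator reproduces the same transform.
    """
    angle = rng.uniform(*cfg.rotation_range)
    scale = rng.uniform(*cfg.scale_range)
    trans = rng.uniform(cfg.translation_range[0], cfg.translation_range[1], 3)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    coords = cloud.coords @ rot.T * scale + trans
    return LabeledCloud(coords, cloud.labels.copy(), cloud.id)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


def _prepare(clouds: list[LabeledCloud]) -> list[LabeledCloud]:
    out = []
    for c in clouds:
        norm, _ = normalize(c)
        out.append(norm)
    return out


def fit(train_set: list[LabeledCloud], val_set: list[LabeledCloud],
        net_cfg: NetworkConfig, train_cfg: TrainConfig,
        loss_cfg: loss_mod.OmegaConfig | None = None,
        log=None) -> tuple[ModelParams, TrainHistory]:
    """Train on labeled clouds; returns the best-validation-mIoU parameters.

    Fully reproducible from ``train_cfg.seed``: parameter init, shuffling,
    augmentation, dropout and the per-epoch partition seeds all derive from
    it.  Divergence (non-finite loss) aborts with the offending epoch.
    """
    loss_cfg = loss_cfg or loss_mod.OmegaConfig()
    if not train_set:
        raise ValueError("empty training set")
    sizes = {c.n_points for c in train_set} | {c.n_points for c in val_set}
    if len(sizes) > 1:
        raise ValueError(f"all clouds must share one point count, got {sorted(sizes)}")
    for c in train_set + val_set:
        if not c.is_labeled:
            raise ValueError(f"cloud {c.id} has unlabeled points")

    train_norm = _prepare(train_set)
    val_norm = _prepare(val_set)
    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(net_cfg, int(rng.integers(2 ** 31 - 1)))
    opt = _Adam(params.trainable)
    history = TrainHistory()
    best = params.copy()
    best_miou = -1.0

    n = len(train_norm)
    for epoch in range(train_cfg.epochs):
        lr = train_cfg.learning_rate(epoch)
        part_seed = int(rng.integers(2 ** 31 - 1))
        order = rng.permutation(n)
        epoch_seg, epoch_map, epoch_tot = [], [], []
        for start in range(0, n, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            grads_sum = None
            for i in batch:
                cloud = train_norm[i]
                if train_cfg.augment_enabled:
                    cloud = augment(cloud, rng, train_cfg)
                res = forward(cloud, net_cfg, params, part_seed, training=True,
                              dropout_rng=rng, want_cache=True)
                breakdown, dlogits, dpsi, dphi = loss_mod.total_loss_and_grads(
                    res.logits, cloud.labels, res.descriptors, loss_cfg)
                if not np.isfinite(breakdown.total):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}")
                grads = backward(res, dlogits, dpsi, dphi)
                if grads_sum is None:
                    grads_sum = grads
                else:
                    for k in grads_sum:
                        grads_sum[k] += grads[k]
                epoch_seg.append(breakdown.segmentation_loss)
                epoch_map.append(breakdown.mapping_loss)
                epoch_tot.append(breakdown.total)
            for k in grads_sum:
                grads_sum[k] /= len(batch)
            opt.step(params.trainable, grads_sum, lr)

        val_ma, val_miou = _validate(val_norm, net_cfg, params)
        history.epochs.append(epoch)
        history.segmentation_loss.append(float(np.mean(epoch_seg)))
        history.mapping_loss.append(float(np.mean(epoch_map)))
        history.total_loss.append(float(np.mean(epoch_tot)))
        history.learning_rate.append(lr)
        history.val_mean_accuracy.append(val_ma)
        history.val_mean_iou.append(val_miou)
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.6f}  loss {history.total_loss[-1]:.4f}  "
                f"val mA {val_ma:.4f}  val mIoU {val_miou:.4f}")
        if val_miou >= best_miou:
            best_miou = val_miou
            best = params.copy()
    return best, history


def _validate(val_norm, net_cfg, params, partition_seed: int = 0):
    if not val_norm:
        return float("nan"), float("nan")
    mas, mious = [], []
    for cloud in val_norm:
        labels, _ = _predict_normalized(cloud, net_cfg, params, partition_seed)
        rep = evaluate_segmentation(cloud.labels, labels, net_cfg.num_classes)
        mas.append(rep.mean_accuracy)
        mious.append(rep.mean_iou)
    return float(np.mean(mas)), float(np.mean(mious))


def _predict_normalized(cloud, net_cfg, params, partition_seed):
    res = forward(cloud, net_cfg, params, partition_seed, training=False)
    labels = res.logits.argmax(axis=1) + 1
    z = res.logits - res.logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    return labels.astype(np.int64), probs


def predict(cloud: LabeledCloud, net_cfg: NetworkConfig, params: ModelParams,
            partition_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-point labels (1..N) and softmax probabilities.

    The cloud is normalized internally; dropout is disabled and batch-norm
    uses its running statistics.
    """
    norm, _ = normalize(cloud)
    return _predict_normalized(norm, net_cfg, params, partition_seed)
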