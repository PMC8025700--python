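"""Pattern-Net forward computation and its manual backward pass.

The network segments a point cloud by (i) randomly decomposing it into ``L``
structurally similar subsets, (ii) inside each subset repeatedly searching
K-nearest-neighbor graphs in the current feature space and learning edge
patterns with shared conv–BN–max blocks, (iii) pooling per-level descriptors
``ψ_l`` and a global descriptor ``φ`` that ties the levels together, and
(iv) decoding per-point features concatenated with their level descriptor
and the global descriptor into class logits.

Everything is plain NumPy.  Each forward pass in training mode records a
cache from which :func:`backward` produces exact gradients of the logits,
``Ψ`` and ``φ`` with respect to every trainable array (dense weights and
biases, batch-norm scale and shift).  Max-pooling gradients are routed to
the argmax entries; the KNN graph indices are treated as constants, as is
standard for dynamic-graph edge-convolution architectures.

Weights are shared across the ``L`` levels: the subsets are exchangeable
random samples, so level-specific weights would both break resolution
robustness and inflate the parameter count.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .decomposition import Partition, decompose
from .pointcloud_io import LabeledCloud

__all__ = [
    "NetworkConfig",
    "ModelParams",
    "DescriptorSet",
    "ForwardResult",
    "knn_graph",
    "build_neighbor_features",
    "lp_block",
    "forward",
    "backward",
    "count_parameters",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class ConfigurationError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``descriptor_dim`` is the per-point concatenated feature length — the sum
    of the edge-block widths (128 for the default ``[32, 32, 32, 32]``).  The
    last global-MLP width must equal ``descriptor_dim`` so the per-level and
    global descriptors live in the same space (the linear linkage ``φ = Ψω``
    requires it).
    """

    L: int = 8
    K: int = 20
    lp_widths: tuple[int, ...] = (32, 32, 32, 32)
    global_mlp_widths: tuple[int, ...] = (128,)
    decoder_widths: tuple[int, ...] = (256, 256)
    num_classes: int = 2
    drop_rate: float = 2.0 / 3.0
    lrelu_slope: float = 0.2
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        self.lp_widths = tuple(int(w) for w in self.lp_widths)
        self.global_mlp_widths = tuple(int(w) for w in self.global_mlp_widths)
        self.decoder_widths = tuple(int(w) for w in self.decoder_widths)
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if any(w <= 0 for w in self.lp_widths) or not self.lp_widths:
            raise ConfigurationError("lp_widths must be positive")
        if any(w <= 0 for w in self.global_mlp_widths + self.decoder_widths):
            raise ConfigurationError("widths must be positive")
        if self.global_mlp_widths and self.global_mlp_widths[-1] != self.descriptor_dim:
            raise ConfigurationError(
                f"last global MLP width {self.global_mlp_widths[-1]} must equal "
                f"descriptor_dim {self.descriptor_dim}"
            )
        if not 0.0 <= self.drop_rate < 1.0:
            raise ConfigurationError("drop_rate must be in [0, 1)")

    @property
    def descriptor_dim(self) -> int:
        return sum(self.lp_widths)

    @classmethod
    def light(cls, L: int = 8, K: int = 20, **kw) -> "NetworkConfig":
        """Half-width edge blocks (the reduced-memory variant)."""
        return cls(L=L, K=K, lp_widths=(16, 16, 16, 16), global_mlp_widths=(64,), **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class DescriptorSet:
    """Per-level descriptors stacked column-wise plus the global descriptor."""

    psi: np.ndarray   # (D, L)
    phi: np.ndarray   # (D,)


@dataclass
class ForwardResult:
    logits: np.ndarray               # (M, N)
    descriptors: DescriptorSet
    per_point_features: np.ndarray   # (M, D)
    partition: Partition
    cache: dict | None = None


@dataclass
class ModelParams:
    """Trainable arrays plus batch-norm running statistics, keyed by name."""

    trainable: dict[str, np.ndarray]
    running: dict[str, np.ndarray]
    version: int = CHECKPOINT_VERSION

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.trainable.items()},
                           {k: v.copy() for k, v in self.running.items()},
                           self.version)


# ---------------------------------------------------------------------------
# layer bookkeeping


def _layer_specs(cfg: NetworkConfig):
    """Yield (prefix, fan_in, fan_out, has_bn) for every dense layer."""
    c = 3
    for b, w in enumerate(cfg.lp_widths):
        yield f"lp{b}_1", 2 * c, w, True
        yield f"lp{b}_2", w, w, True
        c = w
    d = cfg.descriptor_dim
    fan = d
    for j, w in enumerate(cfg.global_mlp_widths):
        yield f"glob{j}", fan, w, False
        fan = w
    fan = 3 * d
    for j, w in enumerate(cfg.decoder_widths):
        yield f"dec{j}", fan, w, True
        fan = w
    yield "out", fan, cfg.num_classes, False


def count_parameters(cfg: NetworkConfig) -> int:
    """Exact number of trainable scalars (dense W+b, BN scale+shift)."""
    total = 0
    for _, fan_in, fan_out, has_bn in _layer_specs(cfg):
        total += fan_in * fan_out + fan_out
        if has_bn:
            total += 2 * fan_out
    return total


def init_params(cfg: NetworkConfig, seed: int) -> ModelParams:
    """He-initialized weights, unit BN scale, zero shift/bias."""
    rng = np.random.default_rng(seed)
    trainable: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    for prefix, fan_in, fan_out, has_bn in _layer_specs(cfg):
        trainable[f"{prefix}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        trainable[f"{prefix}_b"] = np.zeros(fan_out)
        if has_bn:
            trainable[f"{prefix}_gamma"] = np.ones(fan_out)
            trainable[f"{prefix}_beta"] = np.zeros(fan_out)
            running[f"{prefix}_mean"] = np.zeros(fan_out)
            running[f"{prefix}_var"] = np.ones(fan_out)
    return ModelParams(trainable, running)


def save_checkpoint(path, cfg: NetworkConfig, params: ModelParams) -> None:
    header = json.dumps({"version": params.version, "config": cfg.to_dict()})
    arrays = {f"t__{k}": v for k, v in params.trainable.items()}
    arrays.update({f"r__{k}": v for k, v in params.running.items()})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[NetworkConfig, ModelParams]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg = NetworkConfig.from_dict(header["config"])
        trainable = {k[3:]: data[k].copy() for k in data.files if k.startswith("t__")}
        running = {k[3:]: data[k].copy() for k in data.files if k.startswith("r__")}
    return cfg, ModelParams(trainable, running, header["version"])


# ---------------------------------------------------------------------------
# primitive ops


def knn_graph(features: np.ndarray, K: int) -> np.ndarray:
    """K nearest neighbors (self excluded) per point, ascending distance.

    Ties are broken by lexicographic comparison of feature rows and then by
    the canonical (ascending-index) order, so the neighbor multiset is
    invariant to input permutation.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("features must be 2-D")
    m = F.shape[0]
    if m <= K:
        raise ConfigurationError(f"need more than K={K} points, got {m}")
    order = np.lexsort(F.T[::-1])          # canonical lexicographic row order
    inv = np.empty(m, dtype=np.int64)
    inv[order] = np.arange(m)
    d2 = cdist(F, F[order], "sqeuclidean")
    d2[np.arange(m), inv] = np.inf         # exclude self (duplicates remain)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :K]
    return order[nn]


def build_neighbor_features(features: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Edge feature table: row = (f_q, f_i − f_q), width ``2C`` per neighbor.

    For raw coordinates (C=3) this is the K×6 search-pattern feature space:
    the query point stacked with the three edge components to each neighbor.
    """
    F = np.asarray(features, dtype=np.float64)
    nbr = np.asarray(neighbors, dtype=np.int64)
    fq = np.repeat(F[:, None, :], nbr.shape[1], axis=1)      # (M, K, C)
    edges = F[nbr] - fq
    return np.concatenate([fq, edges], axis=2)               # (M, K, 2C)


def _lrelu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _bn_forward(x, prefix, params: ModelParams, cfg: NetworkConfig, training: bool):
    gamma = params.trainable[f"{prefix}_gamma"]
    beta = params.trainable[f"{prefix}_beta"]
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        mom = cfg.bn_momentum
        params.running[f"{prefix}_mean"] = mom * params.running[f"{prefix}_mean"] + (1 - mom) * mu
        params.running[f"{prefix}_var"] = mom * params.running[f"{prefix}_var"] + (1 - mom) * var
    else:
        mu = params.running[f"{prefix}_mean"]
        var = params.running[f"{prefix}_var"]
    inv_std = 1.0 / np.sqrt(var + cfg.bn_eps)
    x_hat = (x - mu) * inv_std
    out = gamma * x_hat + beta
    cache = {"x_hat": x_hat, "inv_std": inv_std, "gamma": gamma, "training": training}
    return out, cache


def _bn_backward(dout, cache):
    x_hat, inv_std, gamma = cache["x_hat"], cache["inv_std"], cache["gamma"]
    dgamma = (dout * x_hat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    if cache["training"]:
        n = x_hat.shape[0]
        dx = (gamma * inv_std / n) * (n * dout - dbeta - x_hat * dgamma)
    else:
        dx = dout * gamma * inv_std
    return dx, dgamma, dbeta


def _dense_bn_act(x, prefix, params, cfg, training, has_bn=True):
    W = params.trainable[f"{prefix}_W"]
    b = params.trainable[f"{prefix}_b"]
    z = x @ W + b
    cache = {"x": x, "prefix": prefix}
    if has_bn:
        z, cache["bn"] = _bn_forward(z, prefix, params, cfg, training)
    cache["pre_act"] = z
    out = _lrelu(z, cfg.lrelu_slope)
    return out, cache


def _dense_bn_act_backward(dout, cache, params, cfg, grads):
    prefix = cache["prefix"]
    z = cache["pre_act"]
    dz = np.where(z > 0, dout, cfg.lrelu_slope * dout)
    if "bn" in cache:
        dz, dgamma, dbeta = _bn_backward(dz, cache["bn"])
        grads[f"{prefix}_gamma"] += dgamma
        grads[f"{prefix}_beta"] += dbeta
    W = params.trainable[f"{prefix}_W"]
    grads[f"{prefix}_W"] += cache["x"].T @ dz
    grads[f"{prefix}_b"] += dz.sum(axis=0)
    return dz @ W.T


def lp_block(nf: np.ndarray, block_params: dict[str, np.ndarray], width: int,
             cfg: NetworkConfig | None = None, training: bool = False):
    """One edge-pattern block: two 1×1 convs with BN + leaky-ReLU, max over K.

    ``nf`` is the (M, K, 2C) neighbor-feature tensor; ``block_params`` holds
    the arrays for the two layers keyed ``1_W, 1_b, 1_gamma, ... 2_beta``
    plus running statistics ``1_mean, 1_var, 2_mean, 2_var``.  Because the
    max over the K neighbor rows is a symmetric function, the output is
    invariant to neighbor ordering.
    """
    cfg = cfg or NetworkConfig()
    trainable = {k: v for k, v in block_params.items() if not k.endswith(("_mean", "_var"))}
    running = {k: v for k, v in block_params.items() if k.endswith(("_mean", "_var"))}
    for layer in ("1", "2"):
        running.setdefault(f"{layer}_mean", np.zeros(width))
        running.setdefault(f"{layer}_var", np.ones(width))
    params = ModelParams(trainable, running)
    out, _ = _lp_block_forward(nf, params, "", cfg, training, width)
    return out


def _lp_block_forward(nf, params, prefix, cfg, training, width):
    m, k, c2 = nf.shape
    rows = nf.reshape(m * k, c2)
    a1, c1 = _dense_bn_act(rows, f"{prefix}1", params, cfg, training)
    a2, c2_ = _dense_bn_act(a1, f"{prefix}2", params, cfg, training)
    a2 = a2.reshape(m, k, width)
    arg = a2.argmax(axis=1)                                   # (m, width)
    out = np.take_along_axis(a2, arg[:, None, :], axis=1)[:, 0, :]
    cache = {"c1": c1, "c2": c2_, "argmax": arg, "shape": (m, k, width)}
    return out, cache


def _lp_block_backward(dout, cache, params, cfg, grads, prefix):
    m, k, width = cache["shape"]
    da2 = np.zeros((m, k, width))
    np.put_along_axis(da2, cache["argmax"][:, None, :], dout[:, None, :], axis=1)
    da1 = _dense_bn_act_backward(da2.reshape(m * k, width), cache["c2"], params, cfg, grads)
    dnf = _dense_bn_act_backward(da1, cache["c1"], params, cfg, grads)
    return dnf.reshape(m, k, -1)


# ---------------------------------------------------------------------------
# full forward / backward


def forward(cloud: LabeledCloud, cfg: NetworkConfig, params: ModelParams,
            partition_seed: int, training: bool = False,
            dropout_rng: np.random.Generator | None = None,
            want_cache: bool = False) -> ForwardResult:
    """Full segmentation forward pass; row order of logits matches the input.

    The KNN graph is recomputed in the current feature space before each
    edge block (dynamic links), restricted to points of the same
    decomposition subset.
    """
    coords = cloud.coords
    m_total = coords.shape[0]
    # Attach the seeded random partition to canonical (lexicographic) point
    # ranks rather than input row indices: permuting the input rows then
    # leaves the level membership of every point unchanged, which is what
    # makes the predicted labels permutation-equivariant.
    ranks = decompose(m_total, cfg.L, partition_seed)
    canon = np.lexsort(coords.T[::-1])
    part = Partition([np.sort(canon[s]) for s in ranks.subsets], m_total, partition_seed)
    min_sub = min(len(s) for s in part.subsets)
    if min_sub <= cfg.K:
        raise ConfigurationError(
            f"subset size {min_sub} must exceed K={cfg.K} (M={m_total}, L={cfg.L})"
        )
    if training and dropout_rng is None:
        dropout_rng = np.random.default_rng(0)

    feats = coords
    block_outs = []
    block_caches = []
    for b, width in enumerate(cfg.lp_widths):
        neigh = np.empty((m_total, cfg.K), dtype=np.int64)
        for idx in part.subsets:
            neigh[idx] = idx[knn_graph(feats[idx], cfg.K)]
        nf = build_neighbor_features(feats, neigh)
        out, bc = _lp_block_forward(nf, params, f"lp{b}_", cfg, training, width)
        bc["neigh"] = neigh
        bc["in_channels"] = feats.shape[1]
        block_outs.append(out)
        block_caches.append(bc)
        feats = out
    H = np.concatenate(block_outs, axis=1)                     # (M, D)
    d = cfg.descriptor_dim

    psi = np.empty((d, cfg.L))
    psi_arg = np.empty((d, cfg.L), dtype=np.int64)
    for l, idx in enumerate(part.subsets):
        sub = H[idx]
        a = sub.argmax(axis=0)
        psi[:, l] = sub[a, np.arange(d)]
        psi_arg[:, l] = idx[a]

    u_arg = H.argmax(axis=0)
    u = H[u_arg, np.arange(d)]
    g = u[None, :]
    glob_caches = []
    for j in range(len(cfg.global_mlp_widths)):
        g, gc = _dense_bn_act(g, f"glob{j}", params, cfg, training, has_bn=False)
        glob_caches.append(gc)
    phi = g[0]

    lev = part.level_of_point()
    x = np.concatenate([H, psi[:, lev].T, np.broadcast_to(phi, (m_total, d))], axis=1)
    dec_caches = []
    drop_masks = []
    for j in range(len(cfg.decoder_widths)):
        x, dc = _dense_bn_act(x, f"dec{j}", params, cfg, training)
        dec_caches.append(dc)
        if training and cfg.drop_rate > 0:
            mask = (dropout_rng.random(x.shape) >= cfg.drop_rate) / (1.0 - cfg.drop_rate)
            x = x * mask
            drop_masks.append(mask)
        else:
            drop_masks.append(None)
    w_out = params.trainable["out_W"]
    logits = x @ w_out + params.trainable["out_b"]

    cache = None
    if want_cache:
        cache = {
            "cfg": cfg, "params": params, "partition": part, "lev": lev,
            "block_caches": block_caches, "psi_arg": psi_arg, "u_arg": u_arg,
            "glob_caches": glob_caches, "dec_caches": dec_caches,
            "drop_masks": drop_masks, "x_last": x, "d": d,
        }
    return ForwardResult(logits, DescriptorSet(psi, phi), H, part, cache)


def backward(result: ForwardResult, dlogits: np.ndarray,
             dpsi: np.ndarray | None = None,
             dphi: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every trainable array.

    ``dlogits`` is the loss gradient at the logits; ``dpsi``/``dphi`` are
    optional direct gradients at the descriptor matrix and global descriptor
    (used by the linear-mapping regularizer).
    """
    cache = result.cache
    if cache is None:
        raise ValueError("forward must be called with want_cache=True")
    cfg: NetworkConfig = cache["cfg"]
    params: ModelParams = cache["params"]
    part: Partition = cache["partition"]
    d = cache["d"]
    m_total = result.logits.shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.trainable.items()}

    grads["out_W"] += cache["x_last"].T @ dlogits
    grads["out_b"] += dlogits.sum(axis=0)
    dx = dlogits @ params.trainable["out_W"].T
    for j in reversed(range(len(cfg.decoder_widths))):
        mask = cache["drop_masks"][j]
        if mask is not None:
            dx = dx * mask
        dx = _dense_bn_act_backward(dx, cache["dec_caches"][j], params, cfg, grads)

    dh = dx[:, :d].copy()
    dpsi_total = np.zeros((d, cfg.L)) if dpsi is None else dpsi.copy()
    for l, idx in enumerate(part.subsets):
        dpsi_total[:, l] += dx[idx, d:2 * d].sum(axis=0)
    dphi_total = dx[:, 2 * d:].sum(axis=0) + (0 if dphi is None else dphi)

    dg = dphi_total[None, :]
    for j in reversed(range(len(cfg.global_mlp_widths))):
        dg = _dense_bn_act_backward(dg, cache["glob_caches"][j], params, cfg, grads)
    du = dg[0]

    cols = np.arange(d)
    for l in range(cfg.L):
        np.add.at(dh, (cache["psi_arg"][:, l], cols), dpsi_total[:, l])
    np.add.at(dh, (cache["u_arg"], cols), du)

    # split per-point feature gradient back into the four block outputs
    offsets = np.cumsum((0,) + cfg.lp_widths)
    dblock = [dh[:, offsets[b]:offsets[b + 1]].copy() for b in range(len(cfg.lp_widths))]
    for b in reversed(range(len(cfg.lp_widths))):
        bc = cache["block_caches"][b]
        dnf = _lp_block_backward(dblock[b], bc, params, cfg, grads, f"lp{b}_")
        if b > 0:
            c = bc["in_channels"]
            dfeat = dnf[:, :, :c].sum(axis=1) - dnf[:, :, c:].sum(axis=1)
            np.add.at(dfeat, bc["neigh"].ravel(),
                      dnf[:, :, c:].reshape(-1, c))
            dblock[b - 1] += dfeat
    return grads
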