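"""Training objective: weighted cross-entropy + descriptor-linkage penalty.

The network is trained so that every decomposition level tells the same
story: assuming a linear relationship ``φ = Ψω`` between the per-level
descriptor matrix ``Ψ`` (D×L) and the global descriptor ``φ``, the
coefficient vector ``ω`` is the minimum-norm least-squares solution from
the Moore–Penrose pseudo-inverse.  When all per-level descriptors are close
to the global one, the coefficients are equal and their spread is zero, so
the population standard deviation ``σ(ω)`` is added to the loss with weight
``λ`` (default 10,000).

Class imbalance (ears are a small minority of points) is handled by the
dynamic weight vector ``Ω_k = |C_k − n_k/M|`` where ``n_k`` is the number
of points of class ``k`` and ``C_k`` a per-class probability constant
(defaults: ear 1.0, non-ear 0.95), which up-weights the minority ear class.

Gradients: ``ω`` is held fixed (no differentiation through the SVD); the
mapping term's gradient reaches ``Ψ`` and ``φ`` through the first-order
least-squares relation ``δω ≈ Ψ⁺(δφ − δΨ ω)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DescriptorSet

__all__ = [
    "OmegaConfig",
    "LossBreakdown",
    "solve_omega",
    "mapping_loss",
    "class_weights",
    "total_loss",
    "total_loss_and_grads",
]

_RCOND = 1e-10
_PROB_CLIP = 1e-12


@dataclass
class OmegaConfig:
    """Per-class probability constants ``C_k`` and the mapping weight ``λ``."""

    C: tuple[float, ...] = (0.95, 1.0)   # index k-1: (non-ear, ear)
    lam: float = 10_000.0

    def __post_init__(self) -> None:
        self.C = tuple(float(c) for c in self.C)
        if any(not 0.0 <= c <= 1.0 for c in self.C):
            raise ValueError("C_k must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class LossBreakdown:
    segmentation_loss: float
    mapping_loss: float
    lam: float

    @property
    def total(self) -> float:
        return self.segmentation_loss + self.lam * self.mapping_loss


def solve_omega(psi_matrix: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solution of ``Ψω = φ`` via SVD.

    Singular values below ``rcond · σ_max`` (rcond = 1e-10) are treated as
    zero, matching the Moore–Penrose pseudo-inverse.
    """
    psi = np.asarray(psi_matrix, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if not (np.all(np.isfinite(psi)) and np.all(np.isfinite(phi))):
        raise ValueError("non-finite descriptor input")
    return np.linalg.pinv(psi, rcond=_RCOND) @ phi


def mapping_loss(psi_matrix: np.ndarray, phi: np.ndarray) -> float:
    """Population standard deviation σ(ω) of the linkage coefficients."""
    omega = solve_omega(psi_matrix, phi)
    return float(np.std(omega))


def class_weights(labels: np.ndarray, omega_cfg: OmegaConfig, n_classes: int) -> np.ndarray:
    """Dynamic imbalance weights ``Ω_k = |C_k − (#{γ_i = k})/M|``."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError("labels must lie in {1..N}")
    if len(omega_cfg.C) != n_classes:
        raise ValueError(f"need {n_classes} probability constants, got {len(omega_cfg.C)}")
    frac = np.bincount(labels - 1, minlength=n_classes) / labels.size
    return np.abs(np.asarray(omega_cfg.C) - frac)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def total_loss(logits: np.ndarray, labels: np.ndarray, descriptors: DescriptorSet,
               omega_cfg: OmegaConfig) -> LossBreakdown:
    """Weighted mean cross-entropy over points plus ``λ·σ(ω)``."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    m, n = logits.shape
    if labels.shape != (m,):
        raise ValueError("labels/logits shape mismatch")
    omega_w = class_weights(labels, omega_cfg, n)
    p = np.clip(_softmax(logits), _PROB_CLIP, None)
    seg = float(-(omega_w[labels - 1] * np.log(p[np.arange(m), labels - 1])).sum() / m)
    mapping = mapping_loss(descriptors.psi, descriptors.phi)
    return LossBreakdown(seg, mapping, omega_cfg.lam)


def total_loss_and_grads(logits: np.ndarray, labels: np.ndarray,
                         descriptors: DescriptorSet, omega_cfg: OmegaConfig):
    """Loss plus analytic gradients w.r.t. logits, Ψ and φ.

    Returns ``(breakdown, dlogits, dpsi, dphi)``.  The class weights Ω are
    hyperparameter-like constants of the current cloud and receive no
    gradient; ω is held fixed per the first-order treatment of the
    pseudo-inverse.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    m, n = logits.shape
    omega_w = class_weights(labels, omega_cfg, n)
    p = _softmax(logits)
    onehot = np.zeros_like(p)
    onehot[np.arange(m), labels - 1] = 1.0
    w_rows = omega_w[labels - 1][:, None]
    dlogits = w_rows * (p - onehot) / m

    p_clip = np.clip(p, _PROB_CLIP, None)
    seg = float(-(omega_w[labels - 1] * np.log(p_clip[np.arange(m), labels - 1])).sum() / m)

    psi = descriptors.psi
    phi = descriptors.phi
    pinv = np.linalg.pinv(psi, rcond=_RCOND)
    omega = pinv @ phi
    L = omega.size
    sigma = float(np.std(omega))
    if sigma > 0:
        dsig_domega = (omega - omega.mean()) / (L * sigma)
        back = pinv.T @ dsig_domega            # (D,)
        dphi = omega_cfg.lam * back
        dpsi = -omega_cfg.lam * np.outer(back, omega)
    else:
        dphi = np.zeros_like(phi)
        dpsi = np.zeros_like(psi)
    return LossBreakdown(seg, sigma, omega_cfg.lam), dlogits, dpsi, dphi
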