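"""Training objectives: symmetric cross-modal InfoNCE, cross-entropy, total.

The contrastive term aligns the two views of each cell line.  With
similarities s_ij = <h_omics_i, h_image_j> (rows L2-normalized by default,
which keeps s/gamma bounded for small temperatures such as the default
gamma = 0.01):

    L_o2I = -(1/N) sum_i log( exp(s_ii / g) / sum_j exp(s_ij / g) )
    L_I2o =  the transposed direction
    L_cl  =  (L_o2I + L_I2o) / 2

The classification term is the standard binary cross-entropy on predicted
sensitivity probabilities (probabilities clamped at 1e-7), and the total
training objective is the convex combination L = alpha * L_c + beta * L_cl
with alpha + beta = 1.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor
from .exceptions import ConfigError, ValidationError

PROB_CLAMP = 1e-7


def _l2_normalize_rows(h: Tensor) -> Tensor:
    norm = ((h * h).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return h / norm


def _info_nce_direction(logits: Tensor) -> Tensor:
    """-(1/N) sum_i [logit_ii - logsumexp_j(logit_ij)] over rows."""
    n = logits.shape[0]
    idx = (np.arange(n), np.arange(n))
    diag = logits[idx]
    row_max = logits.max(axis=1, keepdims=True).detach()
    lse = (logits - row_max).exp().sum(axis=1).log() + row_max.reshape(n)
    return (lse - diag).mean()


def contrastive_loss_t(
    h_omics: Tensor, h_image: Tensor, gamma: float, normalize: bool = True
) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable symmetric InfoNCE; returns (L_o2I, L_I2o, L_cl) tensors."""
    if gamma <= 0:
        raise ConfigError(f"temperature gamma must be > 0, got {gamma}")
    h_omics = as_tensor(h_omics)
    h_image = as_tensor(h_image)
    if h_omics.shape != h_image.shape or h_omics.ndim != 2:
        raise ValidationError(
            f"modality embeddings must share an (N, f) shape, got {h_omics.shape} vs {h_image.shape}"
        )
    if h_omics.shape[0] < 1:
        raise ValidationError("contrastive loss needs at least one pair")
    if normalize:
        h_omics = _l2_normalize_rows(h_omics)
        h_image = _l2_normalize_rows(h_image)
    logits = (h_omics @ h_image.T) * (1.0 / gamma)
    l_o2i = _info_nce_direction(logits)
    l_i2o = _info_nce_direction(logits.T)
    l_cl = (l_o2i + l_i2o) * 0.5
    return l_o2i, l_i2o, l_cl


def contrastive_loss(
    h_omics: np.ndarray, h_image: np.ndarray, gamma: float, normalize: bool = True
) -> tuple[float, float, float]:
    """Numeric (L_o2I, L_I2o, L_cl) for given embeddings; see contrastive_loss_t."""
    a, b, c = contrastive_loss_t(Tensor(h_omics), Tensor(h_image), gamma, normalize)
    return float(a.data), float(b.data), float(c.data)


def classification_loss_t(p: Tensor, y: np.ndarray, reduction: str = "mean") -> Tensor:
    """Differentiable binary cross-entropy on clamped probabilities."""
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValidationError(f"probability/label length mismatch: {p.shape} vs {y.shape}")
    if reduction not in ("mean", "sum"):
        raise ConfigError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    p = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    terms = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return terms.mean() if reduction == "mean" else terms.sum()


def classification_loss(p: np.ndarray, y: np.ndarray, reduction: str = "mean") -> float:
    """Binary cross-entropy -sum/mean_i [y_i log p_i + (1 - y_i) log(1 - p_i)]."""
    y_arr = np.asarray(y)
    if not np.isin(y_arr, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    return float(classification_loss_t(Tensor(p), y_arr, reduction).data)


def check_loss_weights(alpha: float, beta: float, tol: float = 1e-8) -> None:
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > tol:
        raise ConfigError(f"loss weights must satisfy alpha, beta >= 0 and alpha + beta = 1, got alpha={alpha}, beta={beta}")


def total_loss(l_c: float, l_cl: float, alpha: float, beta: float) -> float:
    """Weighted objective L = alpha * L_c + beta * L_cl (alpha + beta = 1)."""
    check_loss_weights(alpha, beta)
    return alpha * l_c + beta * l_cl
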