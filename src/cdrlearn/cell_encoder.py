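"""Multimodal cell-line representation.

Three pieces compose the cell-line embedding:

* two independent bias-free linear encoders map the standardized expression
  and copy-number matrices (m x d) to f-dimensional views z_g, z_c;
* a per-cell-line attention gate scores each omics view with a tanh of a
  learned linear functional, turns the two scores into a two-way softmax
  (alpha_g + alpha_c = 1), and fuses h_omics = alpha_g * z_g + alpha_c * z_c;
* a small convolutional network embeds the 224 x 224 x 3 morphology image:
  a fixed 8x8 average-pooling front end (224 -> 28, parameter-free), two
  conv(3x3) -> ReLU -> avg-pool(2x2) blocks with 16 and 32 channels, global
  average pooling, and a linear head to f dimensions.

The final cell representation is the concatenation [h_omics ; h_image] of
width 2f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, avg_pool2, concatenate, glorot_uniform, im2col3x3
from .exceptions import ValidationError

FRONT_POOL = 8  # fixed average-pool factor applied to 224x224 inputs
CONV_CHANNELS = (16, 32)


@dataclass
class AttentionState:
    """Pre-softmax scores and softmax weights of the two omics branches."""

    w_g: np.ndarray
    w_c: np.ndarray
    alpha_g: np.ndarray
    alpha_c: np.ndarray


def encode_omics(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bias-free linear embedding z = M W of a standardized omics matrix."""
    M = np.asarray(M, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if M.ndim != 2 or W.ndim != 2 or M.shape[1] != W.shape[0]:
        raise ValidationError(f"cannot multiply omics {M.shape} by weights {W.shape}")
    if not np.isfinite(W).all():
        raise ValidationError("encoder weights must be finite")
    return M @ W


def attention_fuse_t(
    z_g: Tensor,
    z_c: Tensor,
    W_g: Tensor,
    W_c: Tensor,
    b_g: Tensor,
    b_c: Tensor,
) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable attention fusion; returns (h_omics, alpha_g, alpha_c).

    One scalar score per cell line and branch: w = tanh(z W + b); the two-way
    softmax over (w_g, w_c) is computed as alpha_g = sigmoid(w_g - w_c).
    """
    if z_g.shape != z_c.shape:
        raise ValidationError(f"omics embeddings must share shape, got {z_g.shape} vs {z_c.shape}")
    m = z_g.shape[0]
    w_g = (z_g @ W_g + b_g).tanh()  # (m, 1)
    w_c = (z_c @ W_c + b_c).tanh()
    alpha_g = (w_g - w_c).sigmoid()
    alpha_c = 1.0 - alpha_g
    h = alpha_g * z_g + alpha_c * z_c
    return h, alpha_g.reshape(m), alpha_c.reshape(m)


def attention_fuse(
    z_g: np.ndarray,
    z_c: np.ndarray,
    W_g: np.ndarray,
    W_c: np.ndarray,
    b_g: float = 0.0,
    b_c: float = 0.0,
) -> tuple[np.ndarray, AttentionState]:
    """Attention-weighted fusion of the two omics views (numeric wrapper).

    W_g, W_c are (1, f) score functionals as in the model; b_g/b_c are the
    per-branch scalar biases (a shared bias is the special case b_g == b_c).
    """
    z_g_t, z_c_t = as_tensor(z_g), as_tensor(z_c)
    Wg = Tensor(np.asarray(W_g, dtype=np.float64).reshape(-1, 1))
    Wc = Tensor(np.asarray(W_c, dtype=np.float64).reshape(-1, 1))
    h, a_g, a_c = attention_fuse_t(z_g_t, z_c_t, Wg, Wc, Tensor(float(b_g)), Tensor(float(b_c)))
    m = z_g_t.shape[0]
    w_g = np.tanh(z_g_t.data @ Wg.data + b_g).reshape(m)
    w_c = np.tanh(z_c_t.data @ Wc.data + b_c).reshape(m)
    return h.data, AttentionState(w_g=w_g, w_c=w_c, alpha_g=a_g.data, alpha_c=a_c.data)


def softmax_pair(w_g: np.ndarray, w_c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-way softmax over per-cell-line scores: exp(w_g) / (exp(w_g) + exp(w_c))."""
    a_g = 1.0 / (1.0 + np.exp(np.asarray(w_c) - np.asarray(w_g)))
    return a_g, 1.0 - a_g


def build_cell_representation(h_omics: np.ndarray, h_image: np.ndarray) -> np.ndarray:
    """Column-wise concatenation [h_omics ; h_image] -> (m, 2f)."""
    h_omics = np.asarray(h_omics)
    h_image = np.asarray(h_image)
    if h_omics.shape != h_image.shape:
        raise ValidationError(
            f"modality embeddings must share (m, f), got {h_omics.shape} vs {h_image.shape}"
        )
    return np.concatenate([h_omics, h_image], axis=1)


def front_pool_images(images: np.ndarray) -> np.ndarray:
    """Fixed 8x8 average pooling of (m, 224, 224, 3) images -> (m, 28, 28, 3)."""
    images = np.asarray(images, dtype=np.float64)
    m, h, w, c = images.shape
    if h % FRONT_POOL or w % FRONT_POOL:
        raise ValidationError(f"image size {(h, w)} not divisible by front pool {FRONT_POOL}")
    return images.reshape(m, h // FRONT_POOL, FRONT_POOL, w // FRONT_POOL, FRONT_POOL, c).mean(
        axis=(2, 4)
    )


class CnnImageEncoder:
    """Two conv -> ReLU -> avg-pool blocks, global average pool, linear head.

    Deterministic given weights (no dropout / batch statistics).
    """

    def __init__(self, f: int, rng: np.random.Generator):
        c1, c2 = CONV_CHANNELS
        self.conv1_w = glorot_uniform(rng, (9 * 3, c1), fan_in=27, fan_out=c1)
        self.conv1_b = Tensor(np.zeros(c1), requires_grad=True)
        self.conv2_w = glorot_uniform(rng, (9 * c1, c2), fan_in=9 * c1, fan_out=c2)
        self.conv2_b = Tensor(np.zeros(c2), requires_grad=True)
        # the globally pooled conv features vary little across inputs at
        # init; an amplified head puts the image embedding on the same
        # variability scale as the omics embedding, so the cross-modal
        # alignment adapts both views instead of collapsing one onto the
        # near-constant other
        self.head_w = glorot_uniform(rng, (c2, f), fan_in=c2, fan_out=f)
        self.head_w.data *= 8.0
        self.head_b = Tensor(np.zeros(f), requires_grad=True)
        self.f = f

    def parameters(self) -> list[Tensor]:
        return [self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b, self.head_w, self.head_b]

    def forward(self, pooled: Tensor) -> Tensor:
        """(m, 28, 28, 3) front-pooled images -> (m, f) embeddings."""
        x = as_tensor(pooled)
        m, h, w, c = x.shape
        if (h, w, c) != (224 // FRONT_POOL, 224 // FRONT_POOL, 3):
            raise ValidationError(f"expected front-pooled (m, 28, 28, 3) input, got {x.shape}")
        x = self._conv(x, self.conv1_w, self.conv1_b).relu()
        x = avg_pool2(x)  # 28 -> 14
        x = self._conv(x, self.conv2_w, self.conv2_b).relu()
        x = avg_pool2(x)  # 14 -> 7
        x = x.mean(axis=(1, 2))  # global average pool -> (m, c2)
        return x @ self.head_w + self.head_b

    @staticmethod
    def _conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
        m, h, wd, c = x.shape
        cols = im2col3x3(x).reshape(m * h * wd, 9 * c)
        out = cols @ w + b
        return out.reshape(m, h, wd, w.shape[1])

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Embed raw (m, 224, 224, 3) images; numeric convenience wrapper."""
        return self.forward(Tensor(front_pool_images(images))).data


class CellLineEncoder:
    """Trainable multimodal cell-line encoder (omics + attention + image CNN)."""

    def __init__(self, d_expr: int, d_cnv: int, f: int, rng: np.random.Generator):
        self.f = f
        self.W_expr = glorot_uniform(rng, (d_expr, f), fan_in=d_expr, fan_out=f)
        self.W_cnv = glorot_uniform(rng, (d_cnv, f), fan_in=d_cnv, fan_out=f)
        # zero-init gate: attention starts at the unweighted mean (alpha = 1/2)
        # and learns to deviate; large random scores would saturate the tanh
        # and freeze arbitrary per-cell-line gates
        self.att_Wg = Tensor(np.zeros((f, 1)), requires_grad=True)
        self.att_Wc = Tensor(np.zeros((f, 1)), requires_grad=True)
        self.att_bg = Tensor(np.zeros(1), requires_grad=True)
        self.att_bc = Tensor(np.zeros(1), requires_grad=True)
        self.image_encoder = CnnImageEncoder(f, rng)

    def parameters(self) -> list[Tensor]:
        return [
            self.W_expr,
            self.W_cnv,
            self.att_Wg,
            self.att_Wc,
            self.att_bg,
            self.att_bc,
            *self.image_encoder.parameters(),
        ]

    def forward(
        self,
        expr: np.ndarray,
        cnv: np.ndarray,
        pooled_images: np.ndarray,
        use_expr: bool = True,
        use_cnv: bool = True,
        use_image: bool = True,
        use_attention: bool = True,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Return (Z_cell (m, 2f), h_omics (m, f), h_image (m, f)).

        Disabled branches are replaced by zero blocks of the same width so
        the downstream pair representation keeps a fixed 4f layout across
        ablation variants.
        """
        m = expr.shape[0]
        zero = Tensor(np.zeros((m, self.f)))
        if use_expr:
            z_g = Tensor(expr) @ self.W_expr
        if use_cnv:
            z_c = Tensor(cnv) @ self.W_cnv
        if use_expr and use_cnv:
            if use_attention:
                h_omics, _, _ = attention_fuse_t(
                    z_g, z_c, self.att_Wg, self.att_Wc, self.att_bg, self.att_bc
                )
            else:
                h_omics = (z_g + z_c) * 0.5
        elif use_expr:
            h_omics = z_g
        elif use_cnv:
            h_omics = z_c
        else:
            h_omics = zero
        h_image = self.image_encoder.forward(Tensor(pooled_images)) if use_image else zero
        z_cell = concatenate([h_omics, h_image], axis=1)
        return z_cell, h_omics, h_image
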