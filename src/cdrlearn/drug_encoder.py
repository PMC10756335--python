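"""Graph-convolutional drug encoder.

Each drug graph is encoded by two GCN layers over the symmetric-normalized
adjacency with self-loops, ReLU after each layer, followed by global max
pooling over atoms:

    H1 = ReLU(Â X W1)      X: (n, 75), W1: (75, 2f)
    H2 = ReLU(Â H1 W2)     W2: (2f, 2f)
    Z_drug = max over atoms of H2   -> vector of length 2f

Max pooling makes the representation invariant to atom ordering and
independent of molecule size.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, glorot_uniform, neighbor_sum
from .exceptions import ValidationError
from .graphs import MolecularGraph, N_ATOM_FEATURES

__all__ = ["gcn_layer", "GcnDrugEncoder"]


def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(Â H W)."""
    H = np.asarray(H, dtype=np.float64)
    A_hat = np.asarray(A_hat, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValidationError(
            f"gcn_layer shape mismatch: A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    return np.maximum(A_hat @ H @ W, 0.0)


class GcnDrugEncoder:
    """Two-layer GCN + global max pooling producing 2f-dimensional drug vectors."""

    def __init__(self, f: int, rng: np.random.Generator):
        width = 2 * f
        self.W1 = glorot_uniform(rng, (N_ATOM_FEATURES, width), fan_in=N_ATOM_FEATURES, fan_out=width)
        self.W2 = glorot_uniform(rng, (width, width), fan_in=width, fan_out=width)
        self.f = f

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2]

    @staticmethod
    def precompute(graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
        """Cache (Â, X) for a graph; both are constants during training."""
        return graph.normalized_adjacency, graph.atom_features

    def encode_graph_t(self, a_hat: np.ndarray, x: np.ndarray) -> Tensor:
        """Differentiable encoding of one precomputed graph -> (1, 2f).

        Neighbor aggregation sums contributions in value-sorted order so the
        encoding is bit-exactly invariant to atom relabeling.
        """
        if x.shape[0] == 0:
            raise ValidationError("cannot pool an empty molecular graph")
        h1 = neighbor_sum(a_hat, Tensor(x) @ self.W1).relu()
        h2 = neighbor_sum(a_hat, h1 @ self.W2).relu()
        return h2.max(axis=0, keepdims=True)

    def encode_library_t(self, precomputed: list[tuple[np.ndarray, np.ndarray]]) -> Tensor:
        """Encode a list of precomputed graphs into a stacked (n_drugs, 2f) tensor."""
        return concatenate([self.encode_graph_t(a, ax) for a, ax in precomputed], axis=0)

    def encode(self, graph: MolecularGraph) -> np.ndarray:
        """Numeric encoding of one drug graph -> vector of length 2f."""
        a_hat, ax = self.precompute(graph)
        return self.encode_graph_t(a_hat, ax).data.reshape(-1)
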