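"""Per-view graph convolutional classifier.

Each layer propagates sample features through the view's normalized graph
operator before the linear map: ``H(l+1) = sigma(A_hat H(l) W(l))``. On an
edgeless graph ``A_hat`` is the identity, so the stack reduces exactly to
a plain fully connected network applied row-wise — the k=1 degeneracy.

Default architecture: two hidden graph-convolution layers (64, 32 units,
leaky-rectifier slope 0.25, dropout 0.5 during training) and a final
graph-convolution to 2 class logits mapped through a softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._nn import glorot_uniform, leaky_relu, leaky_relu_grad, softmax
from .data_io import OmicsView
from .similarity import SimilarityGraph


@dataclass
class ViewGCN:
    """Stack of graph-convolution weight matrices for one view."""

    view_name: str
    weights: list[np.ndarray]
    leaky_slope: float = 0.25
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.weights[-1].shape[1] != 2:
            raise ValueError("final layer must output 2 class logits")
        for a, b in zip(self.weights, self.weights[1:]):
            if a.shape[1] != b.shape[0]:
                raise ValueError(f"incompatible consecutive layer dims {a.shape} -> {b.shape}")

    @property
    def d_in(self) -> int:
        return self.weights[0].shape[0]

    @property
    def dims(self) -> list[int]:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    def copy(self) -> "ViewGCN":
        return ViewGCN(self.view_name, [W.copy() for W in self.weights],
                       self.leaky_slope, self.dropout)


def init_view_gcn(
    d_in: int,
    hidden_dims: Sequence[int] = (64, 32),
    seed: int = 0,
    view_name: str = "species",
    leaky_slope: float = 0.25,
    dropout: float = 0.5,
) -> ViewGCN:
    """Reproducible Glorot-uniform initialization of a view GCN.

    ``hidden_dims=()`` gives the degenerate single linear layer d_in -> 2.
    """
    dims = [d_in, *hidden_dims, 2]
    if any(d <= 0 for d in dims):
        raise ValueError("all layer dimensions must be positive")
    rng = np.random.default_rng(seed)
    weights = [glorot_uniform(rng, a, b) for a, b in zip(dims, dims[1:])]
    return ViewGCN(view_name, weights, leaky_slope, dropout)


def gcn_layer_forward(
    H: np.ndarray, A_hat: np.ndarray, W: np.ndarray,
    sigma: Callable[[np.ndarray], np.ndarray] = lambda x: x,
) -> np.ndarray:
    """One graph-convolution layer: ``sigma(A_hat @ H @ W)``."""
    H, A_hat, W = np.asarray(H), np.asarray(A_hat), np.asarray(W)
    if A_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"dimension mismatch: A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    return sigma(A_hat @ H @ W)


def forward_cached(
    model: ViewGCN,
    X: np.ndarray,
    A_hat: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass returning class probabilities and a backprop cache."""
    if X.shape[1] != model.d_in:
        raise ValueError(f"input has {X.shape[1]} features, model expects {model.d_in}")
    if A_hat.shape[0] != X.shape[0]:
        raise ValueError("graph and feature matrix disagree on sample count")
    H = X
    cache = {"inputs": [], "pre": [], "masks": []}
    for li, W in enumerate(model.weights):
        last = li == len(model.weights) - 1
        cache["inputs"].append(H)
        Z = A_hat @ H @ W
        cache["pre"].append(Z)
        if last:
            H = Z  # logits
            cache["masks"].append(None)
        else:
            H = leaky_relu(Z, model.leaky_slope)
            if training and model.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an RNG for dropout")
                mask = (rng.random(H.shape) >= model.dropout) / (1.0 - model.dropout)
                H = H * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
    cache["logits"] = H
    probs = softmax(H)
    cache["probs"] = probs
    return probs, cache


def backward(model: ViewGCN, A_hat: np.ndarray, cache: dict,
             dlogits: np.ndarray) -> list[np.ndarray]:
    """Gradients of a scalar loss w.r.t. each weight, given dL/dlogits."""
    grads: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    dZ = dlogits
    for li in range(len(model.weights) - 1, -1, -1):
        H_in = cache["inputs"][li]
        AH = A_hat @ H_in
        grads[li] = AH.T @ dZ
        if li > 0:
            dH = A_hat @ (dZ @ model.weights[li].T)  # A_hat symmetric
            mask = cache["masks"][li - 1]
            if mask is not None:
                dH = dH * mask
            dZ = dH * leaky_relu_grad(cache["pre"][li - 1], model.leaky_slope)
    return grads


def gcn_forward(view: OmicsView, graph: SimilarityGraph, model: ViewGCN) -> np.ndarray:
    """Evaluation-mode per-sample class distribution for one view.

    The graph must have been built on the same samples in the same order
    as ``view``; a node-count mismatch is rejected.
    """
    if graph.n_nodes != view.n_samples:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but view has {view.n_samples} samples"
        )
    probs, _ = forward_cached(model, view.X, graph.A_hat, training=False)
    return probs


def save_checkpoint(model: ViewGCN, path: str | Path) -> None:
    """Serialize weights + config to a single JSON file."""
    payload = {
        "view_name": model.view_name,
        "leaky_slope": model.leaky_slope,
        "dropout": model.dropout,
        "dims": model.dims,
        "weights": [W.tolist() for W in model.weights],
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ViewGCN:
    payload = json.loads(Path(path).read_text())
    return ViewGCN(
        payload["view_name"],
        [np.asarray(W, dtype=float) for W in payload["weights"]],
        payload["leaky_slope"],
        payload["dropout"],
    )
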