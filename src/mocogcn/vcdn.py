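"""Cross-view label integration (VCDN) and the end-to-end training driver.

For each sample the two views' class distributions are combined into the
2x2 cross-view label-correlation tensor ``c_i = y_i^exposome (y_i^species)^T``,
flattened row-major to a length-4 vector and passed to a small fully
connected head that outputs the final two-class distribution. The model
is trained under the composite loss

    L = L_GCN_species + L_GCN_exposome + L_VCDN,

each term a summed cross-entropy over the labeled samples, by alternating
optimization: fix the VCDN head and update both GCNs (their own loss term
plus the VCDN loss gradient flowing through the tensor), then fix the
GCNs and update the head. A co-training stage runs first as a warm start
producing the initial per-view predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    cross_entropy_sum,
    glorot_uniform,
    leaky_relu,
    leaky_relu_grad,
    softmax,
    softmax_backprop,
    softmax_ce_grad,
)
from .config import TrainConfig
from .cotraining import CotrainState, cotrain
from .data_io import CohortLabels, OmicsView
from .similarity import SimilarityGraph, build_graph
from .view_gcn import ViewGCN, backward, forward_cached, init_view_gcn

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross-view tensor

def cross_view_tensor(y_exp: np.ndarray, y_sp: np.ndarray) -> np.ndarray:
    """Flattened outer product ``c[2a+b] = y_exp[a] * y_sp[b]`` (row-major).

    Accepts a single distribution pair (two length-2 vectors, returns a
    length-4 vector) or aligned batches (n x 2 each, returns n x 4). When
    both inputs are probability distributions the output sums to 1.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_sp = np.asarray(y_sp, dtype=float)
    if (y_exp < 0).any() or (y_sp < 0).any():
        raise ValueError("inputs must be non-negative")
    if y_exp.ndim == 1:
        if y_exp.shape != (2,) or y_sp.shape != (2,):
            raise ValueError("expected length-2 class distributions")
        return np.outer(y_exp, y_sp).reshape(4)
    if y_exp.shape != y_sp.shape or y_exp.shape[1] != 2:
        raise ValueError("batch inputs must both be (n, 2)")
    return np.einsum("na,nb->nab", y_exp, y_sp).reshape(len(y_exp), 4)


# ---------------------------------------------------------------------------
# VCDN head

@dataclass
class VCDNHead:
    """Fully connected head: input 4 -> hidden widths -> 2 classes."""

    weights: list[np.ndarray]
    leaky_slope: float = 0.25

    def __post_init__(self) -> None:
        if self.weights[0].shape[0] != 4 or self.weights[-1].shape[1] != 2:
            raise ValueError("head must map 4 inputs to 2 outputs")

    def copy(self) -> "VCDNHead":
        return VCDNHead([W.copy() for W in self.weights], self.leaky_slope)


def init_vcdn_head(hidden_dims: Sequence[int] = (8,), seed: int = 0,
                   leaky_slope: float = 0.25) -> VCDNHead:
    """Glorot-initialized head; ``hidden_dims=()`` gives a single 4->2 layer."""
    dims = [4, *hidden_dims, 2]
    rng = np.random.default_rng(seed)
    return VCDNHead([glorot_uniform(rng, a, b) for a, b in zip(dims, dims[1:])],
                    leaky_slope)


def _head_forward(head: VCDNHead, C: np.ndarray) -> tuple[np.ndarray, dict]:
    H = C
    cache = {"inputs": [], "pre": []}
    for li, W in enumerate(head.weights):
        cache["inputs"].append(H)
        Z = H @ W
        cache["pre"].append(Z)
        H = Z if li == len(head.weights) - 1 else leaky_relu(Z, head.leaky_slope)
    probs = softmax(H)
    return probs, cache


def _head_backward(head: VCDNHead, cache: dict, dlogits: np.ndarray
                   ) -> tuple[list[np.ndarray], np.ndarray]:
    """Returns (weight grads, gradient w.r.t. the head input C)."""
    grads: list[np.ndarray] = [None] * len(head.weights)  # type: ignore[list-item]
    dZ = dlogits
    for li in range(len(head.weights) - 1, -1, -1):
        grads[li] = cache["inputs"][li].T @ dZ
        dH = dZ @ head.weights[li].T
        if li > 0:
            dZ = dH * leaky_relu_grad(cache["pre"][li - 1], head.leaky_slope)
    return grads, dH


def vcdn_forward(c_vec: np.ndarray, head: VCDNHead) -> np.ndarray:
    """Final class distribution(s) from flattened cross-view tensor(s)."""
    c_vec = np.asarray(c_vec, dtype=float)
    single = c_vec.ndim == 1
    C = c_vec[None, :] if single else c_vec
    if C.shape[1] != 4:
        raise ValueError(f"cross-view vector must have length 4, got {C.shape[1]}")
    probs, _ = _head_forward(head, C)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# Composite loss

@dataclass
class CompositeLoss:
    """One epoch's loss decomposition; ``total`` is the exact sum."""

    loss_species: float
    loss_exposome: float
    loss_vcdn: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.loss_species + self.loss_exposome + self.loss_vcdn


def composite_loss(pred_sp: np.ndarray, pred_e: np.ndarray,
                   pred_vcdn: np.ndarray, y: np.ndarray) -> CompositeLoss:
    """Summed cross-entropy of each pathway on the labeled subset.

    All predictions must already be restricted to, and aligned with, the
    labeled samples ``y``.
    """
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("labeled subset is empty")
    return CompositeLoss(
        cross_entropy_sum(np.asarray(pred_sp), y),
        cross_entropy_sum(np.asarray(pred_e), y),
        cross_entropy_sum(np.asarray(pred_vcdn), y),
    )


# ---------------------------------------------------------------------------
# End-to-end training

@dataclass
class MocoGCNBundle:
    """Trained model bundle: the two view GCNs, the VCDN head, config echo."""

    gcn_species: ViewGCN
    gcn_exposome: ViewGCN
    head: VCDNHead
    config: TrainConfig
    cotrain_state: CotrainState | None = None
    initial_predictions: dict[str, np.ndarray] | None = None


def train_mocogcn(
    view_s: OmicsView,
    view_e: OmicsView,
    labels: CohortLabels,
    config: TrainConfig | None = None,
    graphs: dict[str, SimilarityGraph] | None = None,
) -> tuple[MocoGCNBundle, list[CompositeLoss]]:
    """Full pipeline: graphs -> co-training warm start -> alternating joint fit.

    Labels of samples outside ``labels.labeled_mask`` are never read; they
    enter only as unlabeled nodes of the transductive graphs.

    Returns the trained bundle and the per-epoch composite-loss trace of
    the joint stage (evaluation-mode losses, recorded each epoch).
    """
    config = config or TrainConfig()
    if graphs is None:
        graphs = {
            "species": build_graph(view_s, config.k, config.z_score),
            "exposome": build_graph(view_e, config.k, config.z_score),
        }
    rng = np.random.default_rng(config.seed)

    models = {
        "species": init_view_gcn(view_s.n_features, config.hidden_dims,
                                 seed=config.seed, view_name="species",
                                 leaky_slope=config.leaky_slope, dropout=config.dropout),
        "exposome": init_view_gcn(view_e.n_features, config.hidden_dims,
                                  seed=config.seed + 1, view_name="exposome",
                                  leaky_slope=config.leaky_slope, dropout=config.dropout),
    }
    optimizers = {v: Adam(models[v].weights, lr=config.lr_gcn) for v in models}

    # stage 1: co-training warm start (produces the initial predictions)
    gcn_s, gcn_e, initial_preds, state = cotrain(
        view_s, view_e, graphs, labels, config,
        models=models, optimizers=optimizers, rng=rng,
    )

    head = init_vcdn_head(config.vcdn_hidden, seed=config.seed + 2,
                          leaky_slope=config.leaky_slope)
    head_opt = Adam(head.weights, lr=config.lr_vcdn)

    X = {"species": view_s.X, "exposome": view_e.X}
    A = {v: graphs[v].A_hat for v in graphs}
    lab_idx = np.flatnonzero(labels.labeled_mask)
    y_lab = labels.y[lab_idx]
    n = view_s.n_samples
    trace: list[CompositeLoss] = []

    for epoch in range(config.joint_epochs):
        # --- phase (a): VCDN fixed, update both GCNs -----------------------
        probs, caches = {}, {}
        for v in ("species", "exposome"):
            probs[v], caches[v] = forward_cached(models[v], X[v], A[v],
                                                 training=True, rng=rng)
        C = cross_view_tensor(probs["exposome"], probs["species"])
        v_probs, v_cache = _head_forward(head, C)

        dv_logits = softmax_ce_grad(v_probs[lab_idx], y_lab, lab_idx, n)
        _, dC = _head_backward(head, v_cache, dv_logits)
        dC = dC.reshape(n, 2, 2)
        # c[a,b] = p_e[a] * p_s[b]
        dp_e = np.einsum("nab,nb->na", dC, probs["species"])
        dp_s = np.einsum("nab,na->nb", dC, probs["exposome"])
        for v, dp in (("species", dp_s), ("exposome", dp_e)):
            dlogits = softmax_ce_grad(probs[v][lab_idx], y_lab, lab_idx, n)
            dlogits += softmax_backprop(probs[v], dp)
            optimizers[v].step(backward(models[v], A[v], caches[v], dlogits))

        # --- phase (b): GCNs fixed, update the VCDN head -------------------
        eval_probs = {}
        for v in ("species", "exposome"):
            eval_probs[v], _ = forward_cached(models[v], X[v], A[v])
        C = cross_view_tensor(eval_probs["exposome"], eval_probs["species"])
        v_probs, v_cache = _head_forward(head, C)
        dv_logits = softmax_ce_grad(v_probs[lab_idx], y_lab, lab_idx, n)
        head_grads, _ = _head_backward(head, v_cache, dv_logits)
        head_opt.step(head_grads)

        # --- epoch record (evaluation mode, post-update) -------------------
        for v in ("species", "exposome"):
            eval_probs[v], _ = forward_cached(models[v], X[v], A[v])
        C = cross_view_tensor(eval_probs["exposome"], eval_probs["species"])
        v_probs, _ = _head_forward(head, C)
        rec = composite_loss(eval_probs["species"][lab_idx],
                             eval_probs["exposome"][lab_idx],
                             v_probs[lab_idx], y_lab)
        if not np.isfinite(rec.total):
            raise FloatingPointError(
                f"non-finite composite loss at joint epoch {epoch}: {rec}"
            )
        trace.append(rec)

    bundle = MocoGCNBundle(models["species"], models["exposome"], head, config,
                           cotrain_state=state, initial_predictions=initial_preds)
    return bundle, trace


def predict(
    bundle: MocoGCNBundle,
    view_s: OmicsView,
    view_e: OmicsView,
    graphs: dict[str, SimilarityGraph],
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Final VCDN distribution plus the per-view distributions.

    The final matrix's second column is the class-1 (case) probability
    used for AUROC.
    """
    if view_s.n_features != bundle.gcn_species.d_in:
        raise ValueError("species view width does not match the trained model")
    if view_e.n_features != bundle.gcn_exposome.d_in:
        raise ValueError("exposome view width does not match the trained model")
    p_s, _ = forward_cached(bundle.gcn_species, view_s.X, graphs["species"].A_hat)
    p_e, _ = forward_cached(bundle.gcn_exposome, view_e.X, graphs["exposome"].A_hat)
    C = cross_view_tensor(p_e, p_s)
    final, _ = _head_forward(bundle.head, C)
    return final, {"species": p_s, "exposome": p_e}
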