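"""Two-view co-training of the per-view GCNs.

Each round, both view GCNs are fitted (full-batch Adam, cross-entropy) on
their current labeled pools; each view then pseudo-labels its most
confident unlabeled samples and hands them to the *partner* view's pool.
Originally labeled samples keep their true labels in every round.
Training ends when the unlabeled pool is exhausted and assignments are
stable, or at ``max_rounds`` (with a warning).

Ground-truth labels of unlabeled samples are never read here: callers
pass a :class:`~mocogcn.data_io.CohortLabels` whose masked entries are the
only labels consulted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, softmax_ce_grad
from .config import TrainConfig
from .data_io import CohortLabels, OmicsView
from .similarity import SimilarityGraph
from .view_gcn import ViewGCN, backward, forward_cached, init_view_gcn

logger = logging.getLogger(__name__)


@dataclass
class PseudoLabelEvent:
    round: int
    view: str  # proposing view
    sample_index: int
    sample_id: str
    pseudo_label: int
    confidence: float


@dataclass
class CotrainState:
    """Bookkeeping of the co-training loop."""

    round: int
    labeled_pools: dict[str, dict[int, int]]  # view -> {sample index: label}
    unlabeled: list[int]
    predictions: dict[str, np.ndarray]  # view -> (n, 2) snapshot
    events: list[PseudoLabelEvent] = field(default_factory=list)
    converged: bool = False

    def event_log_rows(self) -> list[tuple]:
        return [
            (e.round, e.view, e.sample_id, e.pseudo_label, e.confidence)
            for e in self.events
        ]


def confident_pseudolabels(
    probs: np.ndarray, candidate_idx: np.ndarray, m: int, tau: float
) -> list[tuple[int, int, float]]:
    """Up to ``m`` candidates whose max-class probability reaches ``tau``.

    Returns ``(sample_index, argmax_label, confidence)`` tuples in
    descending confidence order (ties broken by lower sample index, so the
    selection is deterministic). An empty result is valid.
    """
    if not 0.5 <= tau <= 1.0:
        raise ValueError("tau must be in [0.5, 1]")
    if m < 0:
        raise ValueError("m must be non-negative")
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    if m == 0 or candidate_idx.size == 0:
        return []
    p = probs[candidate_idx]
    conf = p.max(axis=1)
    labels = p.argmax(axis=1)
    keep = conf >= tau
    order = sorted(
        (int(i) for i in np.flatnonzero(keep)),
        key=lambda i: (-conf[i], candidate_idx[i]),
    )[:m]
    return [(int(candidate_idx[i]), int(labels[i]), float(conf[i])) for i in order]


def _fit_view(
    model: ViewGCN,
    X: np.ndarray,
    A_hat: np.ndarray,
    pool: dict[int, int],
    optimizer: Adam,
    epochs: int,
    rng: np.random.Generator,
) -> None:
    idx = np.fromiter(sorted(pool), dtype=int)
    y = np.asarray([pool[i] for i in sorted(pool)], dtype=int)
    n = X.shape[0]
    for _ in range(epochs):
        probs, cache = forward_cached(model, X, A_hat, training=True, rng=rng)
        dlogits = softmax_ce_grad(probs[idx], y, idx, n)
        optimizer.step(backward(model, A_hat, cache, dlogits))


def cotrain(
    view_s: OmicsView,
    view_e: OmicsView,
    graphs: dict[str, SimilarityGraph],
    labels: CohortLabels,
    config: TrainConfig,
    models: dict[str, ViewGCN] | None = None,
    optimizers: dict[str, Adam] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ViewGCN, ViewGCN, dict[str, np.ndarray], CotrainState]:
    """Run the co-training loop; returns trained views, predictions, state.

    ``models``/``optimizers``/``rng`` may be supplied by an outer training
    driver (to keep one seed stream end to end); otherwise they are
    created here from ``config.seed``.
    """
    if view_s.sample_ids != view_e.sample_ids or view_s.sample_ids != labels.sample_ids:
        raise ValueError("views and labels must share one sample order")
    n = view_s.n_samples
    labeled_idx = np.flatnonzero(labels.labeled_mask)
    if labeled_idx.size == 0:
        raise ValueError("co-training needs a non-empty labeled set")
    if len(np.unique(labels.y[labeled_idx])) < 2:
        raise ValueError("labeled set must contain both classes")

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if models is None:
        models = {
            "species": init_view_gcn(view_s.n_features, config.hidden_dims,
                                     seed=config.seed, view_name="species",
                                     leaky_slope=config.leaky_slope, dropout=config.dropout),
            "exposome": init_view_gcn(view_e.n_features, config.hidden_dims,
                                      seed=config.seed + 1, view_name="exposome",
                                      leaky_slope=config.leaky_slope, dropout=config.dropout),
        }
    if optimizers is None:
        optimizers = {v: Adam(models[v].weights, lr=config.lr_gcn) for v in models}

    X = {"species": view_s.X, "exposome": view_e.X}
    true_pool = {int(i): int(labels.y[i]) for i in labeled_idx}
    pools: dict[str, dict[int, int]] = {
        "species": dict(true_pool),
        "exposome": dict(true_pool),
    }
    unlabeled: set[int] = set(range(n)) - set(true_pool)
    partner = {"species": "exposome", "exposome": "species"}
    events: list[PseudoLabelEvent] = []
    predictions: dict[str, np.ndarray] = {}
    converged = False
    rnd = 0

    for rnd in range(1, config.max_rounds + 1):
        for v in ("species", "exposome"):
            _fit_view(models[v], X[v], graphs[v].A_hat, pools[v],
                      optimizers[v], config.pretrain_epochs, rng)
        for v in ("species", "exposome"):
            predictions[v], _ = forward_cached(models[v], X[v], graphs[v].A_hat)
        # originally labeled samples must still carry their true labels
        for v in ("species", "exposome"):
            assert all(pools[v][int(i)] == int(labels.y[i]) for i in labeled_idx)

        if not unlabeled:
            converged = True
            break

        cand = np.asarray(sorted(unlabeled), dtype=int)
        m = max(1, math.ceil(config.m_fraction * len(unlabeled)))
        proposals: dict[int, list[tuple[str, int, float]]] = {}
        for v in ("species", "exposome"):
            for i, lab, conf in confident_pseudolabels(predictions[v], cand, m, config.tau):
                proposals.setdefault(i, []).append((v, lab, conf))

        accepted = 0
        for i, props in sorted(proposals.items()):
            if len(props) == 2 and props[0][1] != props[1][1]:
                if props[0][2] == props[1][2]:
                    continue  # cross-view tie: defer to a later round
                props = [max(props, key=lambda t: t[2])]
            for v, lab, conf in props:
                dest = partner[v]
                if i in pools[dest]:
                    continue
                pools[dest][i] = lab
                events.append(PseudoLabelEvent(rnd, v, i, labels.sample_ids[i], lab, conf))
                accepted += 1
            unlabeled.discard(i)

        if accepted == 0:
            # below-tau stall: confidences may still move as training continues
            logger.debug("round %d: no pseudo-label reached tau=%.2f", rnd, config.tau)

    else:
        logger.warning(
            "co-training hit max_rounds=%d with %d samples still unlabeled",
            config.max_rounds, len(unlabeled),
        )

    state = CotrainState(
        round=rnd,
        labeled_pools=pools,
        unlabeled=sorted(unlabeled),
        predictions=predictions,
        events=events,
        converged=converged,
    )
    return models["species"], models["exposome"], predictions, state


def write_event_log(state: CotrainState, path) -> None:
    """Write the pseudo-label event log as TSV."""
    with open(path, "w") as fh:
        fh.write("round\tview\tsample_id\tpseudo_label\tconfidence\n")
        for row in state.event_log_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")
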