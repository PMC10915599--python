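"""Training configuration (YAML/JSON loadable)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class TrainConfig:
    """All tunables of the two-view co-training + VCDN pipeline.

    Attributes
    ----------
    k : edge-density parameter; average retained edges per node sets the
        similarity threshold per view (k=1 means no edges).
    hidden_dims : hidden layer widths of each view GCN.
    vcdn_hidden : hidden widths of the VCDN head (empty tuple = one linear
        layer 4 -> 2).
    tau : minimum max-class probability for a pseudo-label (in [0.5, 1]).
    m_fraction : per round each view proposes
        ``max(1, ceil(m_fraction * n_unlabeled))`` pseudo-labels.
    pretrain_epochs : full-batch Adam epochs per co-training round.
    joint_epochs : alternating GCN/VCDN epochs after the warm start.
    lr_gcn, lr_vcdn : Adam learning rates.
    max_rounds : co-training round cap (termination guarantee).
    dropout : dropout rate on GCN hidden activations during training.
    leaky_slope : negative slope of the leaky-rectifier activation.
    z_score : per-feature standardization before cosine similarity.
    seed : master seed for every stochastic element (init, dropout).
    """

    k: float = 5.0
    hidden_dims: tuple[int, ...] = (64, 32)
    vcdn_hidden: tuple[int, ...] = (8,)
    tau: float = 0.8
    m_fraction: float = 0.05
    pretrain_epochs: int = 200
    joint_epochs: int = 100
    lr_gcn: float = 1e-3
    lr_vcdn: float = 1e-2
    max_rounds: int = 50
    dropout: float = 0.5
    leaky_slope: float = 0.25
    z_score: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(self.hidden_dims)
        self.vcdn_hidden = tuple(self.vcdn_hidden)
        if not 0.5 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0.5, 1]")
        if not 0 < self.m_fraction <= 1:
            raise ValueError("m_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        d["vcdn_hidden"] = list(self.vcdn_hidden)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**{k: v for k, v in (data or {}).items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
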