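"""Graph regression backbones for complex quality prediction.

Two variants are supported: a stack of graph transformer layers, each
followed by ReLU and TopK pooling, or a stack of MetaLayer blocks. Either
way a global attention pooling readout produces the graph embedding X,
and a fully connected head squashes X to a quality score in (0, 1) through
the logistic function. Backbones are trained with a weighted L1 loss
(inverse-frequency weights over 10 score bins) under Adam with AutoClip
adaptive gradient clipping. The embedding X doubles as the input feature
vector for the downstream energy-based regressor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import EDGE_WIDTH, NODE_WIDTH
from .nn import (Adam, AutoClip, GlobalAttentionPool, LayerNorm, MetaLayer,
                 MLP, Module, ModuleList, Tensor, TopKPool, TransformerConv,
                 concat)


@dataclass
class GraphData:
    """A featurized graph ready for the network.

    ``edge_index`` is directed with both orientations of every undirected
    contact; ``edge_attr`` rows are aligned with its columns.
    """

    x: np.ndarray            # (n, node_dim)
    edge_index: np.ndarray   # (2, 2E) int
    edge_attr: np.ndarray    # (2E, edge_dim)
    model_id: str = ""
    label: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def to_graph_data(graph, node_feats: np.ndarray, edge_feats: np.ndarray,
                  model_id: str = "", label: float | None = None) -> GraphData:
    """Assemble directed message-passing input from an undirected graph."""
    e = graph.edges
    if len(e):
        edge_index = np.hstack([e.T, e.T[::-1]])
        edge_attr = np.vstack([edge_feats, _swap_directional(edge_feats)])
    else:
        edge_index = np.zeros((2, 0), dtype=int)
        edge_attr = np.zeros((0, edge_feats.shape[1] if edge_feats.ndim == 2
                              else EDGE_WIDTH))
    return GraphData(x=node_feats, edge_index=edge_index, edge_attr=edge_attr,
                     model_id=model_id, label=label)


def _swap_directional(edge_feats: np.ndarray) -> np.ndarray:
    """Swap direction-dependent feature pairs for the reversed edge copy.

    theta_ij/theta_ji, phi_ij/phi_ji and rsap_i/rsap_j exchange places;
    d, alpha, omega and cdp are symmetric.
    """
    out = edge_feats.copy()
    out[:, [3, 4]] = edge_feats[:, [4, 3]]
    out[:, [5, 6]] = edge_feats[:, [6, 5]]
    out[:, [8, 9]] = edge_feats[:, [9, 8]]
    return out


@dataclass
class BackboneConfig:
    variant: str = "transformer"         # or "metalayer"
    n_layers: int = 2
    hidden: int = 32
    heads: int = 4
    topk_ratio: float = 0.8              # transformer variant only
    use_norm: bool = False
    score_type: str = "fold"             # or "interface"
    dropout: float = 0.0
    node_dim: int = NODE_WIDTH
    edge_dim: int = EDGE_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("transformer", "metalayer"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (0.0 < self.topk_ratio <= 1.0):
            raise ValueError("topk_ratio must be in (0, 1]")
        if self.score_type not in ("fold", "interface"):
            raise ValueError(f"unknown score_type {self.score_type!r}")


class Backbone(Module):
    """Graph network mapping a featurized complex to (score, embedding)."""

    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden
        if cfg.variant == "transformer":
            convs, pools, norms = [], [], []
            in_dim = cfg.node_dim
            for _ in range(cfg.n_layers):
                convs.append(TransformerConv(in_dim, h, cfg.edge_dim,
                                             cfg.heads, rng))
                pools.append(TopKPool(h, cfg.topk_ratio, rng))
                norms.append(LayerNorm(h))
                in_dim = h
            self.convs = ModuleList(convs)
            self.pools = ModuleList(pools)
            self.norms = ModuleList(norms) if cfg.use_norm else None
        else:
            metas = []
            nd, ed, gd = cfg.node_dim, cfg.edge_dim, h
            for _ in range(cfg.n_layers):
                metas.append(MetaLayer(nd, ed, gd, h, rng,
                                       layernorm=cfg.use_norm))
                nd = ed = h
            self.metas = ModuleList(metas)
        self.readout = GlobalAttentionPool(h, rng)
        self.head = MLP([h, h // 2, 1], rng, dropout=cfg.dropout)

    def embed(self, g: GraphData) -> Tensor:
        """Global embedding X of the graph, shape (1, hidden)."""
        x = Tensor(g.x)
        edge_index = g.edge_index
        edge_attr = Tensor(g.edge_attr)
        if self.cfg.variant == "transformer":
            for i, (conv, pool) in enumerate(zip(self.convs, self.pools)):
                x = conv(x, edge_index, edge_attr).relu()
                if self.norms is not None:
                    x = self.norms[i](x)
                x, edge_index, edge_attr, _ = pool(x, edge_index, edge_attr)
        else:
            u = Tensor(np.zeros((1, self.cfg.hidden)))
            for meta in self.metas:
                x, edge_attr, u = meta(x, edge_index, edge_attr, u)
                x = x.relu()
        return self.readout(x)

    def __call__(self, g: GraphData) -> tuple[Tensor, Tensor]:
        """Predicted score in (0, 1) plus the global embedding."""
        emb = self.embed(g)
        score = self.head(emb).sigmoid()
        return score.reshape(1), emb


def predict(backbone: Backbone, g: GraphData) -> tuple[float, np.ndarray]:
    """Evaluation-mode prediction: (score, embedding row)."""
    backbone.eval()
    score, emb = backbone(g)
    return float(score.data.reshape(())), emb.data[0].copy()


def weighted_l1_loss(pred: Tensor, true: np.ndarray,
                     weights: np.ndarray) -> Tensor:
    """Sum_i w_i |pred_i - true_i| / Sum_i w_i."""
    true = np.asarray(true, dtype=float).reshape(-1)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if pred.data.reshape(-1).shape != true.shape or true.shape != weights.shape:
        raise ValueError("pred, true and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    resid = (pred.reshape(-1) - true).abs()
    return (resid * weights).sum() * (1.0 / total)


def inverse_frequency_weights(labels: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Per-sample weights proportional to the inverse bin frequency of the
    label over ``n_bins`` equal bins of [0, 1], normalized to mean 1."""
    labels = np.asarray(labels, dtype=float)
    bins = np.clip((labels * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    w = np.where(counts[bins] > 0, 1.0 / counts[bins], 0.0)
    return w / w.mean()


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss"]
        lines += [f"{e},{t:.6f},{v:.6f}" for e, t, v in
                  zip(self.epochs, self.train_loss, self.val_loss)]
        return "\n".join(lines) + "\n"


def train_backbone(
    backbone: Backbone,
    train_set: list[GraphData],
    val_set: list[GraphData],
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 8,
    clip_percentile: float = 10.0,
    seed: int = 0,
    patience: int = 10,
) -> TrainLog:
    """Weighted-L1 training with Adam and AutoClip; early stop on a
    validation plateau."""
    rng = np.random.default_rng(seed)
    params = backbone.parameters()
    opt = Adam(params, lr=lr)
    clipper = AutoClip(clip_percentile)
    labels = np.array([g.label for g in train_set], dtype=float)
    weights = inverse_frequency_weights(labels)
    log = TrainLog()
    best_val = np.inf
    best_state = None
    stall = 0
    n = len(train_set)
    for epoch in range(1, epochs + 1):
        backbone.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            preds = [backbone(train_set[i])[0] for i in idx]
            pred = concat(preds, axis=0)
            loss = weighted_l1_loss(pred, labels[idx], weights[idx])
            opt.zero_grad()
            loss.backward()
            clipper(params)
            opt.step()
            epoch_loss += loss.item() * len(idx)
        val = evaluate_l1(backbone, val_set)
        log.epochs.append(epoch)
        log.train_loss.append(epoch_loss / n)
        log.val_loss.append(val)
        if val < best_val - 1e-4:
            best_val = val
            best_state = backbone.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    if best_state is not None:
        backbone.load_state_dict(best_state)
    return log


def evaluate_l1(backbone: Backbone, dataset: list[GraphData]) -> float:
    """Plain mean absolute error over a labelled dataset."""
    backbone.eval()
    errs = [abs(predict(backbone, g)[0] - g.label) for g in dataset]
    return float(np.mean(errs))


def save_checkpoint(backbone: Backbone, path: str | Path) -> None:
    doc = {"config": asdict(backbone.cfg), "weights": backbone.state_dict()}
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: str | Path) -> Backbone:
    doc = json.loads(Path(path).read_text())
    backbone = Backbone(BackboneConfig(**doc["config"]))
    backbone.load_state_dict(doc["weights"])
    return backbone
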