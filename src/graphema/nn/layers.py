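"""Neural building blocks: dense layers, graph message passing and pooling.

Layers mirror the familiar graph-learning constructions: a graph
transformer convolution (multi-head attention over neighbourhoods with
edge features injected into keys and values), a MetaLayer block with
separate edge / node / global update networks, TopK pooling under a
learned scalar projection, and global attention pooling for the graph
readout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Array, Tensor, concat, segment_mean, segment_softmax,
                       segment_sum)


class Module:
    """Base class with automatic parameter / submodule registration."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name: str, value) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, list]:
        return {n: p.data.tolist() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for n, p in params.items():
            arr = np.asarray(state[n], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {arr.shape} vs {p.data.shape}")
            p.data = arr


class ModuleList(Module):
    def __init__(self, modules: list[Module]):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> Module:
        return self.items[i]


class Linear(Module):
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Randomness comes from the
    generator handed in at construction so runs are seed-reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.g + self.b


class MLP(Module):
    """Fully connected stack with ReLU between hidden layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 dropout: float = 0.0, layernorm: bool = False):
        super().__init__()
        layers: list[Module] = []
        self.norms = ModuleList([LayerNorm(d) for d in dims[1:-1]]) if layernorm \
            else None
        self.layers = ModuleList([Linear(a, b, rng)
                                  for a, b in zip(dims[:-1], dims[1:])])
        self.drop = Dropout(dropout, rng) if dropout > 0 else None

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, lin in enumerate(self.layers):
            x = lin(x)
            if i < n - 1:
                if self.norms is not None:
                    x = self.norms[i](x)
                x = x.relu()
                if self.drop is not None:
                    x = self.drop(x)
        return x


class TransformerConv(Module):
    """Multi-head graph attention with edge features in keys and values.

    For a directed edge j -> i the unnormalized attention score is
    q_i . (k_j + k_e) / sqrt(d); messages (v_j + v_e) are combined with
    attention weights softmax-normalized over each node's in-neighbours,
    and a root transform of the node's own features is added, so isolated
    nodes reduce to the root term.
    """

    def __init__(self, in_dim: int, out_dim: int, edge_dim: int,
                 heads: int, rng: np.random.Generator):
        super().__init__()
        if out_dim % heads != 0:
            raise ValueError("out_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = out_dim // heads
        self.q = Linear(in_dim, out_dim, rng)
        self.k = Linear(in_dim, out_dim, rng)
        self.v = Linear(in_dim, out_dim, rng)
        self.ek = Linear(edge_dim, out_dim, rng)
        self.ev = Linear(edge_dim, out_dim, rng)
        self.root = Linear(in_dim, out_dim, rng)

    def __call__(self, x: Tensor, edge_index: Array, edge_attr: Tensor) -> Tensor:
        n = x.shape[0]
        h, d = self.heads, self.head_dim
        out = self.root(x)
        if edge_index.shape[1] == 0:
            return out
        src, dst = edge_index[0], edge_index[1]
        q = self.q(x).gather(dst).reshape(-1, h, d)
        k = (self.k(x).gather(src) + self.ek(edge_attr)).reshape(-1, h, d)
        v = (self.v(x).gather(src) + self.ev(edge_attr)).reshape(-1, h, d)
        score = (q * k).sum(axis=-1) * (1.0 / np.sqrt(d))       # (E, h)
        alpha = segment_softmax(score, dst, n)                   # (E, h)
        msg = v * alpha.reshape(-1, h, 1)
        agg = segment_sum(msg, dst, n).reshape(n, h * d)
        return out + agg


class MetaLayer(Module):
    """Edge, node and global update networks applied in sequence.

    Edge update sees (src, dst, edge, global); node update sees the node,
    the mean of its incident updated edges and the global state; the
    global update sees mean node, mean edge and the previous global state.
    All three updates are small fully connected networks.
    """

    def __init__(self, node_dim: int, edge_dim: int, global_dim: int,
                 out_dim: int, rng: np.random.Generator,
                 layernorm: bool = False):
        super().__init__()
        self.edge_mlp = MLP([2 * node_dim + edge_dim + global_dim, out_dim, out_dim],
                            rng, layernorm=layernorm)
        self.node_mlp = MLP([node_dim + out_dim + global_dim, out_dim, out_dim],
                            rng, layernorm=layernorm)
        self.global_mlp = MLP([2 * out_dim + global_dim, out_dim, out_dim],
                              rng, layernorm=layernorm)

    def __call__(self, x: Tensor, edge_index: Array, edge_attr: Tensor,
                 u: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        n = x.shape[0]
        n_edges = edge_index.shape[1]
        if n_edges:
            src, dst = edge_index[0], edge_index[1]
            e_in = concat([x.gather(src), x.gather(dst), edge_attr,
                           _expand(u, n_edges)], axis=1)
            e_out = self.edge_mlp(e_in)
            node_agg = segment_mean(e_out, dst, n)
        else:
            e_out = Tensor(np.zeros((0, self.edge_mlp.layers[-1].b.shape[0])))
            node_agg = Tensor(np.zeros((n, self.node_mlp.layers[0].W.shape[0]
                                        - x.shape[1] - u.shape[1])))
        x_in = concat([x, node_agg, _expand(u, n)], axis=1)
        x_out = self.node_mlp(x_in)
        e_mean = e_out.mean(axis=0, keepdims=True) if n_edges else Tensor(
            np.zeros((1, x_out.shape[1])))
        u_in = concat([x_out.mean(axis=0, keepdims=True), e_mean, u], axis=1)
        u_out = self.global_mlp(u_in)
        return x_out, e_out, u_out


def _expand(u: Tensor, rows: int) -> Tensor:
    """Broadcast the (1, d) global row to ``rows`` rows."""
    return u.gather(np.zeros(rows, dtype=int))


class TopKPool(Module):
    """Keep the ceil(ratio * n) highest-scoring nodes under a learned
    projection; retained features are gated by tanh of the score. Ties are
    broken toward the lower node index (stable ordering), and at least one
    node is always kept."""

    def __init__(self, in_dim: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 < ratio <= 1.0):
            raise ValueError("ratio must be in (0, 1]")
        self.ratio = float(ratio)
        self.p = Tensor(rng.standard_normal(in_dim) / np.sqrt(in_dim),
                        requires_grad=True)

    def __call__(self, x: Tensor, edge_index: Array, edge_attr: Tensor
                 ) -> tuple[Tensor, Array, Tensor, Array]:
        n = x.shape[0]
        pn = self.p.reshape(-1, 1)
        norm = (self.p * self.p).sum().pow(0.5)
        score = (x @ pn) * norm.pow(-1.0)          # (n, 1)
        k = max(1, int(np.ceil(self.ratio * n)))
        order = np.argsort(-score.data[:, 0], kind="stable")
        keep = np.sort(order[:k])                  # preserve original order
        gate = score.gather(keep).tanh()
        x_out = x.gather(keep) * gate
        # restrict edges to kept nodes, relabel
        relabel = -np.ones(n, dtype=int)
        relabel[keep] = np.arange(k)
        if edge_index.shape[1]:
            src, dst = edge_index
            mask = (relabel[src] >= 0) & (relabel[dst] >= 0)
            new_index = np.stack([relabel[src[mask]], relabel[dst[mask]]])
            new_attr = edge_attr.gather(np.nonzero(mask)[0]) if mask.any() else \
                Tensor(np.zeros((0, edge_attr.shape[1])))
        else:
            new_index = np.zeros((2, 0), dtype=int)
            new_attr = edge_attr
        return x_out, new_index, new_attr, keep


class GlobalAttentionPool(Module):
    """Graph readout: softmax over a learned per-node gate, weighted sum of
    transformed node features."""

    def __init__(self, in_dim: int, rng: np.random.Generator):
        super().__init__()
        self.gate_nn = MLP([in_dim, in_dim, 1], rng)
        self.feat_nn = MLP([in_dim, in_dim], rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        gate = segment_softmax(self.gate_nn(x), np.zeros(n, dtype=int), 1)
        pooled = segment_sum(self.feat_nn(x) * gate, np.zeros(n, dtype=int), 1)
        return pooled  # (1, in_dim)
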