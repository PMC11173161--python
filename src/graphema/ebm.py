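"""Energy-based regression of quality scores in logit space.

The regressor learns a scalar energy f(X, y) over pairs of a fixed graph
embedding X and a candidate quality score expressed as a logit y. Training
uses a noise-contrastive objective: for each example the true score (with
a little added noise of intensity beta) is contrasted against M-1
adversarial logits drawn from a normal proposal centred on the true logit.
The proposal's standard deviation "slides" with the true score so that its
quartiles sit approximately +/- gamma away in probability space — this
counteracts the logit function's asymptotes near 0 and 1. Inference is a
brute-force scan: the energy is evaluated on a uniform grid of candidate
scores and the score of minimum energy is returned.

All proposal densities live in logit space; scores move between (0, 1)
and the real line through the sigmoid/logit pair with a small clamp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (Adam, AutoClip, Dropout, LayerNorm, Linear, Module,
                 ModuleList, Tensor, concat)

#: Standard-normal distance from the mean to the first/third quartile;
#: norm.ppf(0.75) = 0.67449, used here at the conventional 3-digit value.
QUARTILE_Z = 0.675


@dataclass
class EBMConfig:
    """Hyper-parameters of the energy-based regressor.

    ``m_total`` counts all contrastive samples per example including the
    noisy-true one, so there are ``m_total - 1`` adversarial draws. ``beta``
    scales the variance of the noise added to the true logit; ``gamma`` is
    the quartile offset (in score space) that sets the sliding proposal
    standard deviation. The proposal is a single normal (K = 1 mixture
    components, held fixed).
    """

    m_total: int = 65
    beta: float = 0.05
    gamma: float = 0.1
    k_components: int = 1
    grid_n: int = 1000
    eps_clamp: float = 1e-6
    skip_depth: int = 2
    hidden: tuple[int, ...] = (64, 64)
    dropout: float = 0.0
    layernorm: bool = False
    x_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_total < 2:
            raise ValueError("m_total must be >= 2 (at least one adversarial)")
        if self.k_components != 1:
            raise ValueError("only K = 1 proposal components are supported")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if not (0.0 < self.eps_clamp < 0.5):
            raise ValueError("eps_clamp must be in (0, 0.5)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")


def logit(p, eps: float = 1e-6):
    """ln(p / (1 - p)) with p clamped to [eps, 1 - eps]."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def sigmoid(y):
    y = np.asarray(y, dtype=float)
    out = 1.0 / (1.0 + np.exp(-y))
    return float(out) if out.ndim == 0 else out


def sliding_sigma(mu: float, gamma: float, eps: float = 1e-6) -> float:
    """Proposal standard deviation in logit space for a true score ``mu``.

    Chosen so the proposal's third (or first) quartile maps back to
    approximately mu + gamma (or mu - gamma) in score space:
    sigma = (logit(mu + gamma) - logit(mu)) / 0.675 when mu + gamma < 1,
    else the mirrored first-quartile form.
    """
    if mu + gamma < 1.0:
        s = (logit(mu + gamma, eps) - logit(mu, eps)) / QUARTILE_Z
    else:
        s = (logit(mu, eps) - logit(mu - gamma, eps)) / QUARTILE_Z
    return float(s)


@dataclass
class LogitSample:
    value: float
    log_density: float


def _norm_logpdf(x, mu: float, sd: float):
    return -0.5 * ((np.asarray(x) - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def sample_targets(
    yi_score: float, cfg: EBMConfig, rng: np.random.Generator
) -> tuple[LogitSample, list[LogitSample]]:
    """Draw the noisy-true sample and M-1 adversarial logits for one example.

    The noisy-true sample adds N(0, beta * sigma^2) noise to the true
    logit; adversarial samples come from N(true logit, sigma^2). Every
    sample carries its log-density under the adversarial proposal, which
    is the correction the contrastive loss needs.
    """
    mu_l = logit(yi_score, cfg.eps_clamp)
    sd = sliding_sigma(yi_score, cfg.gamma, cfg.eps_clamp)
    y0 = mu_l + rng.normal(0.0, np.sqrt(cfg.beta) * sd)
    adv = mu_l + rng.normal(0.0, sd, size=cfg.m_total - 1)
    y0_s = LogitSample(float(y0), float(_norm_logpdf(y0, mu_l, sd)))
    adv_s = [LogitSample(float(v), float(_norm_logpdf(v, mu_l, sd)))
             for v in adv]
    return y0_s, adv_s


def nce_loss(energies: Tensor, log_densities: np.ndarray) -> Tensor:
    """Noise-contrastive regression loss over a batch.

    ``energies`` is (B, M) with column 0 the noisy-true sample;
    ``log_densities`` holds the matching proposal log-densities. The loss
    is the mean negative log-probability of picking column 0 under the
    softmax of (energy - log density), computed with a stable log-sum-exp.
    """
    log_densities = np.asarray(log_densities, dtype=float)
    if energies.shape != log_densities.shape:
        raise ValueError("energies and log_densities must have equal shape")
    if not np.all(np.isfinite(energies.data)):
        raise FloatingPointError("non-finite energy encountered")
    u = energies - log_densities
    m = u.data.max(axis=1, keepdims=True)  # constant shift, gradient-free
    lse = ((u - m).exp().sum(axis=1, keepdims=True)).log() + m
    picked = (u * _first_column_mask(u.shape)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def _first_column_mask(shape: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(shape)
    m[:, 0] = 1.0
    return m


class EnergyNet(Module):
    """Fully connected energy network f(X, y) with logit skip connections.

    The embedding X and logit y are concatenated at the input; the logit is
    re-concatenated before each of the first ``skip_depth`` hidden layers
    after the first, and each hidden layer is followed by dropout and ReLU
    (optionally LayerNorm). The output is a single unconstrained energy.
    """

    def __init__(self, cfg: EBMConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        dims_in = cfg.x_dim + 1
        layers: list[Linear] = []
        norms: list[LayerNorm] = []
        prev = dims_in
        for i, h in enumerate(cfg.hidden):
            if 1 <= i <= cfg.skip_depth:
                prev += 1  # re-appended logit
            layers.append(Linear(prev, h, rng))
            norms.append(LayerNorm(h))
            prev = h
        self.layers = ModuleList(layers)
        self.norms = ModuleList(norms) if cfg.layernorm else None
        self.out = Linear(prev, 1, rng)
        self.drop = Dropout(cfg.dropout, rng) if cfg.dropout > 0 else None

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        """Energies for rows of embeddings ``x`` (B, d) and logits ``y`` (B, 1)."""
        h = concat([x, y], axis=1)
        for i, lin in enumerate(self.layers):
            if 1 <= i <= self.cfg.skip_depth:
                h = concat([h, y], axis=1)
            h = lin(h)
            if self.drop is not None:
                h = self.drop(h)
            h = h.relu()
            if self.norms is not None:
                h = self.norms[i](h)
        return self.out(h)


def energy_forward(net: EnergyNet, x_row: np.ndarray, y: float) -> float:
    """Single-pair energy in evaluation mode."""
    net.eval()
    e = net(Tensor(x_row.reshape(1, -1)), Tensor([[y]]))
    return float(e.data)


def grid_scores(grid_n: int) -> np.ndarray:
    """Evenly distributed candidate scores (k - 0.5) / grid_n, k = 1..grid_n."""
    return (np.arange(1, grid_n + 1) - 0.5) / grid_n


def grid_inference(net: EnergyNet, x_row: np.ndarray,
                   grid_n: int | None = None) -> float:
    """Brute-force inference: score on the grid with minimal energy.

    Ties resolve to the smallest score (the grid is scanned in increasing
    order).
    """
    cfg = net.cfg
    n = grid_n or cfg.grid_n
    scores = grid_scores(n)
    ys = logit(scores, cfg.eps_clamp)
    net.eval()
    x_tile = np.tile(np.asarray(x_row, dtype=float).reshape(1, -1), (n, 1))
    e = net(Tensor(x_tile), Tensor(ys.reshape(-1, 1))).data[:, 0]
    return float(scores[int(np.argmin(e))])


@dataclass
class EBMTrainLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss"]
        lines += [f"{e},{t:.6f},{v:.6f}" for e, t, v in
                  zip(self.epochs, self.train_loss, self.val_loss)]
        return "\n".join(lines) + "\n"


def _contrastive_batch(scores: np.ndarray, cfg: EBMConfig,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sampling for a batch: (B, M) logits and log-densities."""
    b = len(scores)
    mu = logit(scores, cfg.eps_clamp)
    sd = np.array([sliding_sigma(s, cfg.gamma, cfg.eps_clamp) for s in scores])
    y = np.empty((b, cfg.m_total))
    y[:, 0] = mu + rng.normal(0.0, np.sqrt(cfg.beta) * sd)
    y[:, 1:] = mu[:, None] + rng.normal(0.0, 1.0, (b, cfg.m_total - 1)) * sd[:, None]
    logp = -0.5 * ((y - mu[:, None]) / sd[:, None]) ** 2 \
        - np.log(sd[:, None] * np.sqrt(2 * np.pi))
    return y, logp


def train_ebm(
    net: EnergyNet,
    embeddings: np.ndarray,
    scores: np.ndarray,
    val_embeddings: np.ndarray | None = None,
    val_scores: np.ndarray | None = None,
    epochs: int = 40,
    lr: float = 1e-3,
    batch_size: int = 64,
    clip_percentile: float = 10.0,
    seed: int = 0,
    patience: int = 8,
) -> EBMTrainLog:
    """Train the energy network with the contrastive objective."""
    cfg = net.cfg
    rng = np.random.default_rng(seed)
    params = net.parameters()
    opt = Adam(params, lr=lr)
    clipper = AutoClip(clip_percentile)
    n = len(scores)
    log = EBMTrainLog()
    best_val = np.inf
    best_state = None
    stall = 0
    for epoch in range(1, epochs + 1):
        net.train()
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            b = len(idx)
            y, logp = _contrastive_batch(scores[idx], cfg, rng)
            x_rep = np.repeat(embeddings[idx], cfg.m_total, axis=0)
            # the contrastive objective rewards high f at the truth; with
            # f = -energy, minimizing it drives the true pair's energy down,
            # matching argmin-energy inference
            e = net(Tensor(x_rep), Tensor(y.reshape(-1, 1)))
            loss = nce_loss((-e).reshape(b, cfg.m_total), logp)
            opt.zero_grad()
            loss.backward()
            clipper(params)
            opt.step()
            total += loss.item() * b
        log.epochs.append(epoch)
        log.train_loss.append(total / n)
        if val_embeddings is not None and val_scores is not None:
            val = _validation_nce(net, val_embeddings, val_scores, cfg, epoch)
            log.val_loss.append(val)
            if val < best_val - 1e-4:
                best_val, best_state, stall = val, net.state_dict(), 0
            else:
                stall += 1
                if stall >= patience:
                    break
        else:
            log.val_loss.append(float("nan"))
    if best_state is not None:
        net.load_state_dict(best_state)
    return log


def _validation_nce(net: EnergyNet, embeddings: np.ndarray,
                    scores: np.ndarray, cfg: EBMConfig, epoch: int) -> float:
    net.eval()
    rng = np.random.default_rng(10_000 + epoch)  # fixed stream per epoch
    y, logp = _contrastive_batch(scores, cfg, rng)
    x_rep = np.repeat(embeddings, cfg.m_total, axis=0)
    e = net(Tensor(x_rep), Tensor(y.reshape(-1, 1)))
    return float(nce_loss((-e).reshape(len(scores), cfg.m_total), logp).data)


def predict_scores(net: EnergyNet, embeddings: np.ndarray,
                   grid_n: int | None = None) -> np.ndarray:
    """Grid inference over many embeddings at once."""
    cfg = net.cfg
    n_grid = grid_n or cfg.grid_n
    scores = grid_scores(n_grid)
    ys = logit(scores, cfg.eps_clamp)
    net.eval()
    out = np.empty(len(embeddings))
    for i, row in enumerate(np.asarray(embeddings, dtype=float)):
        x_tile = np.tile(row.reshape(1, -1), (n_grid, 1))
        e = net(Tensor(x_tile), Tensor(ys.reshape(-1, 1))).data[:, 0]
        out[i] = scores[int(np.argmin(e))]
    return out


def save_ebm(net: EnergyNet, path: str | Path) -> None:
    doc = {"config": asdict(net.cfg), "weights": net.state_dict()}
    Path(path).write_text(json.dumps(doc))


def load_ebm(path: str | Path) -> EnergyNet:
    doc = json.loads(Path(path).read_text())
    cfg = doc["config"]
    cfg["hidden"] = tuple(cfg["hidden"])
    net = EnergyNet(EBMConfig(**cfg))
    net.load_state_dict(doc["weights"])
    return net
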