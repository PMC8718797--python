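"""Heterogeneous skip-gram embeddings with type-constrained negative sampling.

Walk sequences are treated as sentences: every ordered node pair within a
window of size ``b`` is a (center, context) training example.  The objective
for one pair is the standard negative-sampling likelihood

    log sigma(Phi(v_j) . Psi(v_i)) + sum_u log sigma(-Phi(neg_u) . Psi(v_i))

with the crucial heterogeneous twist that the ``U`` negatives are drawn only
from nodes *of the same type as the context node* -- the sampled softmax is
normalised within a node type, so lncRNA contexts compete with lncRNAs and
disease contexts with diseases.

Training is plain SGD with a linearly decaying learning rate.  A numba
kernel performs the inner loop; a single-pair numpy reference update
(:func:`sgns_update`) carries the same arithmetic and is what the gradient
tests exercise.  Negative noise within a type follows unigram frequency
raised to the 3/4 power by default (uniform available via config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "TrainConfig",
    "EmbeddingTable",
    "context_pairs",
    "pair_loss",
    "pair_gradients",
    "sgns_update",
    "train",
]


@dataclass
class TrainConfig:
    """Skip-gram hyperparameters.

    window: context radius b (positions at distance <= b pair with the center).
    dim: embedding dimension d.
    negatives: negative samples U per (center, context) pair.
    lr / lr_min: initial learning rate, decayed linearly to lr_min over all updates.
    epochs: full passes over the pair stream.
    noise: 'unigram75' (count^0.75 within type) or 'uniform'.
    """

    window: int = 5
    dim: int = 64
    negatives: int = 5
    lr: float = 0.025
    lr_min: float = 1e-4
    epochs: int = 5
    seed: int = 0
    noise: str = "unigram75"

    def __post_init__(self) -> None:
        if self.window < 1 or self.dim < 2 or self.negatives < 1:
            raise ValueError("require window >= 1, dim >= 2, negatives >= 1")
        if self.lr <= 0 or self.lr_min < 0:
            raise ValueError("learning rates must be positive")
        if self.noise not in ("unigram75", "uniform"):
            raise ValueError("noise must be 'unigram75' or 'uniform'")


@dataclass
class EmbeddingTable:
    """Input (Psi) and context (Phi) vectors plus the node -> type map."""

    ids: list[str]
    types: list[str]
    Psi: np.ndarray
    Phi: np.ndarray
    epoch_losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.types) != n or self.Psi.shape[0] != n or self.Phi.shape != self.Psi.shape:
            raise ValueError("table dimensions disagree")
        if not (np.isfinite(self.Psi).all() and np.isfinite(self.Phi).all()):
            raise ValueError("embedding vectors must be finite")
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.Psi.shape[1]

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def vector(self, node_id: str) -> np.ndarray:
        return self.Psi[self._index[node_id]]

    def to_word2vec_text(self) -> str:
        lines = [f"{len(self.ids)} {self.dim}"]
        for i, v in enumerate(self.ids):
            lines.append(v + " " + " ".join(repr(float(x)) for x in self.Psi[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_word2vec_text(cls, text: str, types: dict[str, str] | None = None) -> "EmbeddingTable":
        lines = [l for l in text.splitlines() if l.strip()]
        n, d = (int(x) for x in lines[0].split())
        ids, vecs = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            ids.append(parts[0])
            vecs.append([float(x) for x in parts[1 : d + 1]])
        tlist = [types.get(v, "?") if types else "?" for v in ids]
        Psi = np.asarray(vecs, dtype=np.float64)
        return cls(ids, tlist, Psi, np.zeros_like(Psi))


def context_pairs(walks, window: int):
    """Yield every ordered (center, context) pair within the window."""
    if window < 1:
        raise ValueError("window must be at least 1")
    for walk in walks:
        n = len(walk)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    yield walk[i], walk[j]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def pair_loss(Psi: np.ndarray, Phi: np.ndarray, center: int, context: int,
              negatives: np.ndarray) -> float:
    """Negative log of the single-pair negative-sampling objective."""
    x = Psi[center]
    loss = -np.log(max(_sigmoid(float(Phi[context] @ x)), 1e-300))
    for u in negatives:
        if u == context:
            continue
        loss -= np.log(max(_sigmoid(-float(Phi[u] @ x)), 1e-300))
    return float(loss)


def pair_gradients(Psi: np.ndarray, Phi: np.ndarray, center: int, context: int,
                   negatives: np.ndarray):
    """Analytic gradients of :func:`pair_loss` w.r.t. Psi[center] and each Phi row."""
    x = Psi[center]
    g_x = np.zeros_like(x)
    g_phi: dict[int, np.ndarray] = {}
    s = _sigmoid(float(Phi[context] @ x))
    g_x += -(1.0 - s) * Phi[context]
    g_phi[context] = -(1.0 - s) * x
    for u in negatives:
        u = int(u)
        if u == context:
            continue
        su = _sigmoid(float(Phi[u] @ x))
        g_x += su * Phi[u]
        g_phi[u] = g_phi.get(u, 0.0) + su * x
    return g_x, g_phi


def sgns_update(pair: tuple[str, str], table: EmbeddingTable, cfg: TrainConfig,
                rng: np.random.Generator, lr: float | None = None) -> EmbeddingTable:
    """One in-place SGD step on a single (center, context) pair.

    Negatives are drawn uniformly among nodes sharing the context node's
    type (the trainer's batched path additionally supports unigram^0.75
    noise); pairs whose context type has no other member are skipped.
    """
    i, j = table.index(pair[0]), table.index(pair[1])
    tj = table.types[j]
    candidates = np.array([k for k, t in enumerate(table.types) if t == tj and k != j])
    if candidates.size < 1:
        warnings.warn(f"no negative candidates of type {tj!r}; pair skipped",
                      stacklevel=2)
        return table
    negs = candidates[rng.integers(0, candidates.size, size=cfg.negatives)]
    step = cfg.lr if lr is None else lr
    g_x, g_phi = pair_gradients(table.Psi, table.Phi, i, j, negs)
    table.Psi[i] -= step * g_x
    for u, g in g_phi.items():
        table.Phi[u] -= step * g
    return table


@njit(cache=False)
def _sgns_epoch(Psi, Phi, centers, contexts, negs, lrs):  # pragma: no cover - numba
    """SGD over one epoch of pre-sampled pairs; returns the summed pre-update loss."""
    d = Psi.shape[1]
    n_pairs = centers.shape[0]
    U = negs.shape[1]
    total = 0.0
    for p in range(n_pairs):
        c = centers[p]
        t = contexts[p]
        lr = lrs[p]
        gx = np.zeros(d)
        # positive term
        f = 0.0
        for k in range(d):
            f += Phi[t, k] * Psi[c, k]
        s = 1.0 / (1.0 + np.exp(-f))
        total += -np.log(max(s, 1e-300))
        g = (1.0 - s) * lr
        for k in range(d):
            gx[k] += g * Phi[t, k]
            Phi[t, k] += g * Psi[c, k]
        # negative terms
        for u in range(U):
            nd = negs[p, u]
            if nd == t:
                continue
            f = 0.0
            for k in range(d):
                f += Phi[nd, k] * Psi[c, k]
            s = 1.0 / (1.0 + np.exp(-f))
            total += -np.log(max(1.0 - s, 1e-300))
            g = -s * lr
            for k in range(d):
                gx[k] += g * Phi[nd, k]
                Phi[nd, k] += g * Psi[c, k]
        for k in range(d):
            Psi[c, k] += gx[k]
    return total


def _build_pair_arrays(walks, window, index):
    centers, contexts = [], []
    for vi, vj in context_pairs(walks, window):
        centers.append(index[vi])
        contexts.append(index[vj])
    return (np.asarray(centers, dtype=np.int64),
            np.asarray(contexts, dtype=np.int64))


def train(corpus, node_types: dict[str, str], cfg: TrainConfig,
          node_ids: list[str] | None = None) -> EmbeddingTable:
    """Train embeddings on a walk corpus.

    ``node_types`` maps node id -> type; ``node_ids`` fixes the table order
    (and may include nodes absent from the corpus, which keep their random
    initial vectors).  Deterministic for a given config seed: pairs are
    visited in corpus order and all sampling flows from one seeded generator.
    """
    walks = corpus.walks if hasattr(corpus, "walks") else list(corpus)
    if not walks or all(len(w) == 0 for w in walks):
        raise ValueError("corpus is empty")
    if node_ids is None:
        node_ids = list(dict.fromkeys(v for w in walks for v in w))
    index = {v: i for i, v in enumerate(node_ids)}
    missing = {v for w in walks for v in w if v not in index}
    if missing:
        raise ValueError(f"corpus nodes missing from node_ids: {sorted(missing)[:5]}")
    types = [node_types[v] for v in node_ids]
    n = len(node_ids)

    rng = np.random.default_rng(cfg.seed)
    Psi = rng.uniform(-0.5 / cfg.dim, 0.5 / cfg.dim, size=(n, cfg.dim))
    Phi = np.zeros((n, cfg.dim))

    centers, contexts = _build_pair_arrays(walks, cfg.window, index)
    n_pairs = centers.size
    if n_pairs == 0:
        raise ValueError("corpus yields no context pairs (walks too short?)")

    # per-type negative noise tables
    counts = np.zeros(n)
    for w in walks:
        for v in w:
            counts[index[v]] += 1
    type_nodes: dict[str, np.ndarray] = {}
    type_cum: dict[str, np.ndarray] = {}
    for t in sorted(set(types)):
        members = np.array([i for i in range(n) if types[i] == t], dtype=np.int64)
        w = counts[members] ** 0.75 if cfg.noise == "unigram75" else (
            (counts[members] > 0).astype(float))
        if w.sum() == 0:
            w = np.ones(members.size)
        type_nodes[t] = members
        type_cum[t] = np.cumsum(w / w.sum())
    ctx_type = np.array([types[c] for c in contexts])

    total_updates = cfg.epochs * n_pairs
    losses: list[float] = []
    done = 0
    for _ in range(cfg.epochs):
        negs = np.empty((n_pairs, cfg.negatives), dtype=np.int64)
        for t, members in type_nodes.items():
            mask = ctx_type == t
            m = int(mask.sum())
            if m == 0:
                continue
            r = rng.random((m, cfg.negatives))
            picks = np.searchsorted(type_cum[t], r, side="right")
            np.clip(picks, 0, members.size - 1, out=picks)
            negs[mask] = members[picks]
        frac = (done + np.arange(n_pairs)) / total_updates
        lrs = np.maximum(cfg.lr_min, cfg.lr * (1.0 - frac))
        loss = _sgns_epoch(Psi, Phi, centers, contexts, negs, lrs)
        losses.append(float(loss) / n_pairs)
        done += n_pairs
    return EmbeddingTable(node_ids, types, Psi, Phi, epoch_losses=losses)
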