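"""node2vec embeddings of the heterogeneous graph.

Second-order biased random walks (return parameter p, in-out parameter q)
are generated over the weighted graph, and the resulting node sequences are
fed to a skip-gram model with negative sampling (SGNS), trained by
mini-batched SGD in numpy.  Walks and training are fully deterministic
given the seed and single-threaded execution.

The walk bias: standing at ``cur`` having arrived from ``prev``, the
unnormalised probability of stepping to neighbour ``x`` is w(cur, x) * alpha
with alpha = 1/p if x == prev, 1 if x is adjacent to prev, and 1/q
otherwise; on the first step (no ``prev``) alpha = 1 for every neighbour.
Small p keeps the walk local (breadth-first flavour), small q pushes it
outward (depth-first flavour).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit


@dataclass
class Node2vecConfig:
    p: float = 1.0
    q: float = 1.0
    dim: int = 64
    num_walks: int = 10
    walk_length: int = 30
    window: int = 5
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025  # initial SGD learning rate
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.p, self.q, self.alpha) <= 0:
            raise ValueError("p, q and the learning rate must be positive")
        if min(self.dim, self.num_walks, self.walk_length, self.window, self.epochs) < 1:
            raise ValueError("dim, num_walks, walk_length, window and epochs must be >= 1")


@dataclass
class WalkCorpus:
    walks: list[list[str]]

    def __len__(self) -> int:
        return len(self.walks)


def transition_distribution(
    g: nx.Graph, prev: str | None, cur: str, cfg: Node2vecConfig
) -> dict[str, float]:
    """Normalised second-order step distribution over cur's neighbours."""
    nbrs = list(g[cur])
    if not nbrs:
        raise ValueError(f"node {cur!r} is isolated; no transition exists")
    prev_adj = set(g[prev]) if prev is not None else set()
    weights = []
    for x in nbrs:
        w = g[cur][x].get("weight", 1.0)
        if prev is None:
            alpha = 1.0
        elif x == prev:
            alpha = 1.0 / cfg.p
        elif x in prev_adj:
            alpha = 1.0
        else:
            alpha = 1.0 / cfg.q
        weights.append(w * alpha)
    total = float(sum(weights))
    return {x: w / total for x, w in zip(nbrs, weights)}


class _WalkSampler:
    """Indexed adjacency with cached weights for fast biased stepping."""

    def __init__(self, g: nx.Graph):
        self.nodes = list(g.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.nbrs: list[np.ndarray] = []
        self.wts: list[np.ndarray] = []
        self.nbr_sets: list[set[int]] = []
        for n in self.nodes:
            nb = [self.index[x] for x in g[n]]
            self.nbrs.append(np.array(nb, dtype=np.int64))
            self.wts.append(np.array([g[n][x].get("weight", 1.0) for x in g[n]], dtype=float))
            self.nbr_sets.append(set(nb))

    def walk(self, start: int, length: int, p: float, q: float, rng: np.random.Generator) -> list[int]:
        path = [start]
        if len(self.nbrs[start]) == 0:
            return path
        while len(path) < length:
            cur = path[-1]
            nb, w = self.nbrs[cur], self.wts[cur]
            if len(nb) == 0:
                break
            if len(path) == 1:
                probs = w / w.sum()
            else:
                prev = path[-2]
                prev_set = self.nbr_sets[prev]
                alpha = np.array(
                    [1.0 / p if x == prev else (1.0 if x in prev_set else 1.0 / q) for x in nb]
                )
                biased = w * alpha
                probs = biased / biased.sum()
            path.append(int(nb[rng.choice(len(nb), p=probs)]))
        return path


def generate_walks(g: nx.Graph, cfg: Node2vecConfig) -> WalkCorpus:
    """num_walks biased walks from every node; isolated nodes give length-1 walks."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    sampler = _WalkSampler(g)
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[str]] = []
    for _ in range(cfg.num_walks):
        order = rng.permutation(len(sampler.nodes))
        for start in order:
            idx_walk = sampler.walk(int(start), cfg.walk_length, cfg.p, cfg.q, rng)
            walks.append([sampler.nodes[i] for i in idx_walk])
    return WalkCorpus(walks)


@njit(cache=False)
def _sgns_epoch(w_in, w_out, centers, contexts, negatives, lr_start, lr_end):  # pragma: no cover
    """Sequential SGD over one epoch of (center, context) pairs."""
    n_pairs, dim = centers.shape[0], w_in.shape[1]
    n_neg = negatives.shape[1]
    grad = np.empty(dim)
    for t in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * t / n_pairs
        c = centers[t]
        for k in range(n_neg + 1):
            if k == 0:
                o, label = contexts[t], 1.0
            else:
                o = negatives[t, k - 1]
                if o == contexts[t]:
                    continue
                label = 0.0
            dot = 0.0
            for d in range(dim):
                dot += w_in[c, d] * w_out[o, d]
            if dot > 8.0:
                dot = 8.0
            elif dot < -8.0:
                dot = -8.0
            g = 1.0 / (1.0 + np.exp(-dot)) - label
            for d in range(dim):
                grad[d] = g * w_out[o, d]
                w_out[o, d] -= lr * g * w_in[c, d]
            for d in range(dim):
                w_in[c, d] -= lr * grad[d]


def train_embeddings(walks: WalkCorpus, cfg: Node2vecConfig) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling over the walk corpus.

    Sequential SGD (one update per pair, jit-compiled) with a linearly
    decaying learning rate; negatives are drawn from the unigram
    distribution raised to 3/4.  Only nodes occurring in the corpus
    receive vectors.
    """
    if not walks.walks:
        raise ValueError("walk corpus is empty")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for walk in walks.walks:
        for node in walk:
            if node not in vocab:
                vocab[node] = len(vocab)
                counts.append(0)
            counts[vocab[node]] += 1
    v = len(vocab)
    rng = np.random.default_rng(cfg.seed + 1)

    centers, contexts = [], []
    for walk in walks.walks:
        idx = [vocab[n] for n in walk]
        for pos, c in enumerate(idx):
            lo = max(0, pos - cfg.window)
            hi = min(len(idx), pos + cfg.window + 1)
            for k in range(lo, hi):
                if k != pos:
                    centers.append(c)
                    contexts.append(idx[k])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    n_pairs = len(centers)

    noise = np.array(counts, dtype=float) ** 0.75
    noise /= noise.sum()

    w_in = (rng.random((v, cfg.dim)) - 0.5) / cfg.dim
    w_out = np.zeros((v, cfg.dim))

    final_lr = cfg.alpha * 1e-3
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        negs = rng.choice(v, size=(n_pairs, cfg.negative), p=noise)
        lr_hi = cfg.alpha + (final_lr - cfg.alpha) * epoch / cfg.epochs
        lr_lo = cfg.alpha + (final_lr - cfg.alpha) * (epoch + 1) / cfg.epochs
        _sgns_epoch(w_in, w_out, centers[order], contexts[order], negs, lr_hi, lr_lo)
    return {node: w_in[i].copy() for node, i in vocab.items()}


def embed_graph(g: nx.Graph, cfg: Node2vecConfig) -> dict[str, np.ndarray]:
    """Walks plus skip-gram in one call."""
    return train_embeddings(generate_walks(g, cfg), cfg)


def write_embeddings(table: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for node in sorted(table):
            vec = "\t".join(f"{x:.6g}" for x in table[node])
            fh.write(f"{node}\t{vec}\n")


def hyperparameter_grid(dataset_scale: str = "small") -> list[Node2vecConfig]:
    """The published search grid: p, q in {0.25..4}, d in {16..128}, 5-20
    walks per node, and scale-dependent walk lengths (10-40 for the small
    benchmark networks, 60-120 for the large one)."""
    if dataset_scale not in ("small", "large"):
        raise ValueError("dataset_scale must be 'small' or 'large'")
    lengths = (10, 20, 30, 40) if dataset_scale == "small" else (60, 80, 100, 120)
    grid = []
    for p, q, d, nw, wl in itertools.product(
        (0.25, 0.5, 1, 2, 4), (0.25, 0.5, 1, 2, 4), (16, 32, 64, 128), (5, 10, 15, 20), lengths
    ):
        grid.append(Node2vecConfig(p=p, q=q, dim=d, num_walks=nw, walk_length=wl))
    return grid
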