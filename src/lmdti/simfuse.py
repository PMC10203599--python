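"""Integration of multiple similarity matrices into one.

Four integrators are offered: elementwise average (AVG), geometric average
(GeoM), maximum (MAX), and similarity network fusion (SNF).  SNF is the
iterative cross-diffusion of Wang et al.: each input matrix is turned into
a row-normalised full kernel P and a K-nearest-neighbour sparse kernel S,
and the full kernels are repeatedly diffused through each other's local
neighbourhood structure until they agree.

Inputs are already similarities in [0, 1]; they are used directly as
affinities (no distance-kernel construction step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import SimilarityMatrix


@dataclass
class FusionConfig:
    method: str = "SNF"  # one of AVG, GeoM, MAX, SNF
    snf_neighbors: int = 20
    snf_iterations: int = 20
    snf_kernel_mu: float = 0.5  # reserved for affinity-kernel construction

    def __post_init__(self) -> None:
        if self.method not in ("AVG", "GeoM", "MAX", "SNF"):
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.snf_neighbors < 1 or self.snf_iterations < 0 or self.snf_kernel_mu <= 0:
            raise ValueError("invalid SNF parameters: need K >= 1, t >= 0, mu > 0")


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-normalised kernel with half the probability mass off-diagonal.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) for j != i, and P(i,i) = 1/2.
    """
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0  # isolated row: keep all mass on the diagonal
    p = w / (2.0 * rs)
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Sparse kernel: each row keeps its K most similar neighbours, renormalised."""
    n = w.shape[0]
    k = min(k, n - 1)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    s = np.zeros_like(w)
    for i in range(n):
        nn = np.argsort(-w[i])[:k]
        s[i, nn] = w[i, nn]
    rs = s.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return s / rs


def snf(matrices: list[np.ndarray], k: int = 20, t: int = 20) -> np.ndarray:
    """Cross-diffuse a list of affinity matrices into a single fused matrix.

    Performs ``t`` parallel updates P_v <- S_v @ mean(P_u, u != v) @ S_v.T
    (symmetrised after each step) and returns the average of the diffused
    kernels.  With a single input the kernel is returned after normalisation
    only; with t = 0 the result is the plain average of the full kernels.
    """
    m = len(matrices)
    ps = [_full_kernel(w) for w in matrices]
    if m == 1:
        return ps[0]
    ss = [_knn_kernel(w, k) for w in matrices]
    for _ in range(t):
        nxt = []
        for v in range(m):
            other = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p = ss[v] @ other @ ss[v].T
            nxt.append((p + p.T) / 2.0)
        ps = nxt
    fused = sum(ps) / m
    return (fused + fused.T) / 2.0


def _rescale(w: np.ndarray) -> np.ndarray:
    """Min-max rescale off-diagonals to [0, 1] and force a unit diagonal."""
    w = (w + w.T) / 2.0
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    if off.any():
        lo, hi = w[off].min(), w[off].max()
        if hi > lo:
            w = w.copy()
            w[off] = (w[off] - lo) / (hi - lo)
        elif lo < 0 or hi > 1:
            w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return w


def fuse_similarities(
    matrices: list[SimilarityMatrix], config: FusionConfig | None = None
) -> SimilarityMatrix:
    """Fuse one or more aligned similarity matrices into one.

    A single input matrix is returned unchanged for every method.
    """
    if config is None:
        config = FusionConfig()
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.ids != first.ids or m.kind != first.kind:
            raise ValueError("similarity matrices must share kind and id order")
    if len(matrices) == 1:
        return first
    stack = np.stack([m.values for m in matrices])
    if config.method == "AVG":
        fused = stack.mean(axis=0)
    elif config.method == "MAX":
        fused = stack.max(axis=0)
    elif config.method == "GeoM":
        if stack.min() < 0:
            raise ValueError("geometric mean requires non-negative similarities")
        fused = np.exp(np.log(stack + 1e-300).mean(axis=0))
        fused[np.any(stack == 0, axis=0)] = 0.0
    else:  # SNF
        fused = snf(
            [m.values for m in matrices],
            k=min(config.snf_neighbors, first.n - 1) if first.n > 1 else 1,
            t=config.snf_iterations,
        )
        fused = _rescale(fused)
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(first.kind, list(first.ids), fused)
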