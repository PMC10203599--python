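"""Synthetic heterogeneous networks with planted drug-target structure.

The generator emulates the shape of the benchmark inputs: a bipartite
drug-target layer with block (cluster) structure, drug-drug and
target-target similarity matrices correlated with cluster membership, and
sparse lncRNA/miRNA satellite layers attached to drugs, targets and each
other.  Ground-truth cluster assignments are returned so tests can verify
bookkeeping and signal recovery.

Drugs, targets and ncRNAs are assigned to clusters round-robin.  A DTI
edge (d, t) is Bernoulli(p_within) when d and t share a cluster and
Bernoulli(p_between) otherwise.  Similarities are base 0.2 plus sim_signal
for same-cluster pairs plus Gaussian noise, clipped to [0, 1], symmetrised,
unit diagonal.  ncRNA layers use a cluster-preference bias: same-cluster
edges appear at four times the base density, so the satellite layers carry
cluster signal into the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hetnet import DTISubnetwork
from .netio import (
    InteractionNetwork,
    SimilarityMatrix,
    write_interaction_edges,
    write_similarity_matrix,
)

NCRNA_WITHIN_FACTOR = 4.0


@dataclass
class PlantedConfig:
    n_drugs: int = 60
    n_targets: int = 50
    n_lncrna: int = 20
    n_mirna: int = 20
    n_clusters: int = 4
    p_within: float = 0.3
    p_between: float = 0.02
    sim_signal: float = 0.5
    sim_noise: float = 0.1
    sim_base: float = 0.2
    ncrna_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_within <= self.p_between:
            raise ValueError("p_within must exceed p_between")
        for p in (self.p_within, self.p_between, self.ncrna_density, self.sim_signal):
            if not 0 <= p <= 1:
                raise ValueError("probabilities and sim_signal must be in [0, 1]")
        if min(self.n_drugs, self.n_targets, self.n_lncrna, self.n_mirna) < self.n_clusters:
            raise ValueError("every entity universe must have at least n_clusters members")


@dataclass
class PlantedTruth:
    """Ground-truth cluster assignments and per-layer edge tallies."""

    drug_clusters: np.ndarray
    target_clusters: np.ndarray
    lncrna_clusters: np.ndarray
    mirna_clusters: np.ndarray
    edge_counts: dict[str, int]


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def _round_robin(n: int, k: int) -> np.ndarray:
    return np.arange(n) % k


def _planted_similarity(
    ids: list[str], clusters: np.ndarray, kind: str, cfg: PlantedConfig, rng: np.random.Generator
) -> SimilarityMatrix:
    n = len(ids)
    same = clusters[:, None] == clusters[None, :]
    s = cfg.sim_base + cfg.sim_signal * same.astype(float)
    noise = rng.normal(0.0, cfg.sim_noise, size=(n, n)) if cfg.sim_noise > 0 else np.zeros((n, n))
    noise = np.triu(noise, 1)
    s = np.clip(s + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(kind, ids, s)


def _bipartite_layer(
    src_ids: list[str],
    tgt_ids: list[str],
    src_clusters: np.ndarray,
    tgt_clusters: np.ndarray,
    p_within: float,
    p_between: float,
    src_kind: str,
    tgt_kind: str,
    rng: np.random.Generator,
) -> InteractionNetwork:
    same = src_clusters[:, None] == tgt_clusters[None, :]
    prob = np.where(same, p_within, p_between)
    draw = rng.random(prob.shape) < prob
    edges = {(src_ids[i], tgt_ids[j]) for i, j in zip(*np.nonzero(draw))}
    return InteractionNetwork(src_kind, tgt_kind, list(src_ids), list(tgt_ids), edges)


def generate_planted_hetnet(
    cfg: PlantedConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix, dict[str, InteractionNetwork], PlantedTruth]:
    """Generate (dd_sim, tt_sim, six interaction layers, truth).

    The layer dict keys are 'dti', 'dl', 'dm', 'lt', 'mt', 'lm'.
    """
    if cfg is None:
        cfg = PlantedConfig()
    rng = np.random.default_rng(cfg.seed)
    drugs = _ids("D", cfg.n_drugs)
    targets = _ids("T", cfg.n_targets)
    lncrnas = _ids("L", cfg.n_lncrna)
    mirnas = _ids("M", cfg.n_mirna)
    dc = _round_robin(cfg.n_drugs, cfg.n_clusters)
    tc = _round_robin(cfg.n_targets, cfg.n_clusters)
    lc = _round_robin(cfg.n_lncrna, cfg.n_clusters)
    mc = _round_robin(cfg.n_mirna, cfg.n_clusters)

    dd_sim = _planted_similarity(drugs, dc, "drug", cfg, rng)
    tt_sim = _planted_similarity(targets, tc, "target", cfg, rng)

    nc_within = min(NCRNA_WITHIN_FACTOR * cfg.ncrna_density, 1.0)
    layers = {
        "dti": _bipartite_layer(drugs, targets, dc, tc, cfg.p_within, cfg.p_between, "drug", "target", rng),
        "dl": _bipartite_layer(drugs, lncrnas, dc, lc, nc_within, cfg.ncrna_density, "drug", "lncRNA", rng),
        "dm": _bipartite_layer(drugs, mirnas, dc, mc, nc_within, cfg.ncrna_density, "drug", "miRNA", rng),
        "lt": _bipartite_layer(lncrnas, targets, lc, tc, nc_within, cfg.ncrna_density, "lncRNA", "target", rng),
        "mt": _bipartite_layer(mirnas, targets, mc, tc, nc_within, cfg.ncrna_density, "miRNA", "target", rng),
        "lm": _bipartite_layer(lncrnas, mirnas, lc, mc, nc_within, cfg.ncrna_density, "lncRNA", "miRNA", rng),
    }
    truth = PlantedTruth(
        drug_clusters=dc,
        target_clusters=tc,
        lncrna_clusters=lc,
        mirna_clusters=mc,
        edge_counts={name: net.n_edges for name, net in layers.items()},
    )
    return dd_sim, tt_sim, layers, truth


def write_planted_dataset(out_dir: str | Path, cfg: PlantedConfig | None = None) -> Path:
    """Write the eight input files plus a cluster-truth TSV; returns the dir."""
    if cfg is None:
        cfg = PlantedConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dd_sim, tt_sim, layers, truth = generate_planted_hetnet(cfg)
    write_similarity_matrix(dd_sim, out / "drug_similarity.csv")
    write_similarity_matrix(tt_sim, out / "target_similarity.csv")
    names = {
        "dti": "drug_target.tsv",
        "dl": "drug_lncrna.tsv",
        "dm": "drug_mirna.tsv",
        "lt": "lncrna_target.tsv",
        "mt": "mirna_target.tsv",
        "lm": "lncrna_mirna.tsv",
    }
    for key, fname in names.items():
        write_interaction_edges(layers[key], out / fname)
    with (out / "truth_clusters.tsv").open("w") as fh:
        fh.write("id\tkind\tcluster\n")
        for ids, clusters, kind in (
            (dd_sim.ids, truth.drug_clusters, "drug"),
            (tt_sim.ids, truth.target_clusters, "target"),
            (_ids("L", cfg.n_lncrna), truth.lncrna_clusters, "lncRNA"),
            (_ids("M", cfg.n_mirna), truth.mirna_clusters, "miRNA"),
        ):
            for i, c in zip(ids, clusters):
                fh.write(f"{i}\t{kind}\t{c}\n")
    return out


def generate_toy_fixture() -> DTISubnetwork:
    """The fixed 3-drug / 1-target instance used throughout the examples.

    Sd(d1,d2) = 0.5, Sd(d2,d3) = 0.4; d1 and d3 interact with t1.  The
    D-D-T structure scored for (d2, t1) then has two paths, with Sum 0.9
    and Max 0.5.
    """
    sd = np.zeros((3, 3))
    sd[0, 1] = sd[1, 0] = 0.5
    sd[1, 2] = sd[2, 1] = 0.4
    st = np.zeros((1, 1))
    a = np.array([[1.0], [0.0], [1.0]])
    return DTISubnetwork(["d1", "d2", "d3"], ["t1"], sd, st, a)
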