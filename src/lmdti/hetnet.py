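"""Assembly of the weighted heterogeneous network and its drug-target core.

The merged graph G(V, E) is undirected, with four node kinds (drug, target,
lncRNA, miRNA) and two edge classes: *interaction* edges (weight exactly
1.0) from the six bipartite layers, and *similarity* edges (weight in
(0, 1], the similarity value) from thresholded drug-drug and target-target
similarity matrices.

Path scoring operates on a reduced view — the :class:`DTISubnetwork` — that
keeps only drug and target nodes: the drug similarity matrix Sd, the target
similarity matrix St (both with zero diagonal) and the binary interaction
matrix A.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netio import InteractionNetwork, SimilarityMatrix

INTERACTION = "interaction"
SIMILARITY = "similarity"


class HeteroGraph(nx.Graph):
    """Undirected graph with 'kind' node attributes and classed, weighted edges."""

    def add_kind_node(self, node: str, kind: str) -> None:
        existing = self.nodes.get(node, {}).get("kind")
        if existing is not None and existing != kind:
            raise ValueError(f"node {node!r} used with two kinds: {existing!r} and {kind!r}")
        self.add_node(node, kind=kind)

    def kind_of(self, node: str) -> str:
        return self.nodes[node]["kind"]

    def add_classed_edge(self, u: str, v: str, weight: float, edge_class: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if self.has_edge(u, v) and self[u][v]["edge_class"] != edge_class:
            raise ValueError(f"edge ({u!r}, {v!r}) carries both edge classes")
        self.add_edge(u, v, weight=float(weight), edge_class=edge_class)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.nodes(data=True) if d["kind"] == kind]


@dataclass
class DTISubnetwork:
    """Drug/target-only view: similarities (zero diagonal) plus interactions."""

    drug_ids: list[str]
    target_ids: list[str]
    Sd: np.ndarray  # n x n, symmetric, zero diagonal, values in [0, 1]
    St: np.ndarray  # m x m, likewise
    A: np.ndarray  # n x m binary interaction matrix

    def __post_init__(self) -> None:
        n, m = len(self.drug_ids), len(self.target_ids)
        self.Sd = np.asarray(self.Sd, dtype=float)
        self.St = np.asarray(self.St, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.Sd.shape != (n, n) or self.St.shape != (m, m) or self.A.shape != (n, m):
            raise ValueError("matrix shapes inconsistent with identifier lists")
        for s, name in ((self.Sd, "Sd"), (self.St, "St")):
            if not np.allclose(s, s.T):
                raise ValueError(f"{name} is not symmetric")
            if np.any(np.diag(s) != 0):
                raise ValueError(f"{name} diagonal must be zero")
            if s.min() < 0 or s.max() > 1:
                raise ValueError(f"{name} values outside [0, 1]")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("A must be binary")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


def filter_similarity_edges(
    sim: SimilarityMatrix, threshold: float = 0.0
) -> list[tuple[str, str, float]]:
    """Off-diagonal pairs with similarity strictly above ``threshold``.

    Returned as (id_i, id_j, weight) triples with i < j in id-list order.
    """
    if threshold >= 1:
        raise ValueError("threshold >= 1 would drop every similarity edge")
    if threshold < 0:
        raise ValueError("threshold must be in [0, 1)")
    edges = []
    v = sim.values
    for i in range(sim.n):
        for j in range(i + 1, sim.n):
            if v[i, j] > threshold:
                edges.append((sim.ids[i], sim.ids[j], float(v[i, j])))
    return edges


def build_heterogeneous_network(
    dd_sim: SimilarityMatrix,
    tt_sim: SimilarityMatrix,
    dti: InteractionNetwork,
    dl: InteractionNetwork,
    dm: InteractionNetwork,
    lt: InteractionNetwork,
    mt: InteractionNetwork,
    lm: InteractionNetwork,
    sim_threshold: float = 0.0,
) -> HeteroGraph:
    """Merge the eight constituent networks into one weighted graph.

    Node set is the union of all identifiers declared in any layer or
    similarity matrix; interaction edges get weight 1, similarity edges get
    the (thresholded) similarity as weight.  Connectivity is not required.
    """
    expected = {
        "dti": ("drug", "target"),
        "dl": ("drug", "lncRNA"),
        "dm": ("drug", "miRNA"),
        "lt": ("lncRNA", "target"),
        "mt": ("miRNA", "target"),
        "lm": ("lncRNA", "miRNA"),
    }
    layers = {"dti": dti, "dl": dl, "dm": dm, "lt": lt, "mt": mt, "lm": lm}
    g = HeteroGraph()
    for sim, kind in ((dd_sim, "drug"), (tt_sim, "target")):
        if sim.kind != kind:
            raise ValueError(f"similarity matrix kind {sim.kind!r}, expected {kind!r}")
        for node in sim.ids:
            g.add_kind_node(node, kind)
    for name, net in layers.items():
        sk, tk = expected[name]
        if (net.source_kind, net.target_kind) != (sk, tk):
            raise ValueError(
                f"layer {name} has kinds ({net.source_kind}, {net.target_kind}); expected ({sk}, {tk})"
            )
        for node in net.source_ids:
            g.add_kind_node(node, sk)
        for node in net.target_ids:
            g.add_kind_node(node, tk)
        for u, v in net.edges:
            g.add_classed_edge(u, v, 1.0, INTERACTION)
    for sim in (dd_sim, tt_sim):
        for u, v, w in filter_similarity_edges(sim, sim_threshold):
            g.add_classed_edge(u, v, w, SIMILARITY)
    return g


def drop_ncrna_layers(g: HeteroGraph) -> HeteroGraph:
    """The 'original network' ablation: remove every lncRNA and miRNA node."""
    keep = [n for n in g.nodes if g.kind_of(n) in ("drug", "target")]
    h = HeteroGraph()
    h.add_nodes_from((n, g.nodes[n]) for n in keep)
    h.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if u in h.nodes and v in h.nodes
    )
    return h


def dti_subnetwork(g: HeteroGraph) -> DTISubnetwork:
    """Extract (Sd, St, A) over drug and target nodes only."""
    drugs = g.nodes_of_kind("drug")
    targets = g.nodes_of_kind("target")
    if not drugs or not targets:
        raise ValueError("graph must contain at least one drug and one target")
    di = {d: i for i, d in enumerate(drugs)}
    ti = {t: j for j, t in enumerate(targets)}
    sd = np.zeros((len(drugs), len(drugs)))
    st = np.zeros((len(targets), len(targets)))
    a = np.zeros((len(drugs), len(targets)))
    for u, v, d in g.edges(data=True):
        ku, kv = g.kind_of(u), g.kind_of(v)
        if d["edge_class"] == SIMILARITY:
            if ku == kv == "drug":
                sd[di[u], di[v]] = sd[di[v], di[u]] = d["weight"]
            elif ku == kv == "target":
                st[ti[u], ti[v]] = st[ti[v], ti[u]] = d["weight"]
        elif {ku, kv} == {"drug", "target"}:
            dn, tn = (u, v) if ku == "drug" else (v, u)
            a[di[dn], ti[tn]] = 1.0
    np.fill_diagonal(sd, 0.0)
    np.fill_diagonal(st, 0.0)
    return DTISubnetwork(drugs, targets, sd, st, a)


def export_edge_list(g: HeteroGraph, path) -> None:
    """Write the merged graph as TSV: src, dst, weight, class (sorted)."""
    rows = sorted((min(u, v), max(u, v), d["weight"], d["edge_class"]) for u, v, d in g.edges(data=True))
    with open(path, "w") as fh:
        fh.write("src\tdst\tweight\tclass\n")
        for u, v, w, c in rows:
            fh.write(f"{u}\t{v}\t{w:.6g}\t{c}\n")
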