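"""Readers, writers and bookkeeping for the network input files.

The predictor consumes six bipartite interaction layers (drug-target,
drug-lncRNA, drug-miRNA, lncRNA-target, miRNA-target, lncRNA-miRNA) given
as two-column edge lists, plus square drug-drug and target-target
similarity matrices with values in [0, 1].  Identifiers are opaque strings
(DrugBank accessions, gene symbols, ...); no namespace validation is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENTITY_KINDS = ("drug", "target", "lncRNA", "miRNA")


class ParseError(ValueError):
    """A malformed input file (bad line, bad shape, bad values)."""


def _check_kind(kind: str) -> str:
    if kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {kind!r}; expected one of {ENTITY_KINDS}")
    return kind


@dataclass
class InteractionNetwork:
    """A typed bipartite edge list with implied unit edge weights."""

    source_kind: str
    target_kind: str
    source_ids: list[str]
    target_ids: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        _check_kind(self.source_kind)
        _check_kind(self.target_kind)
        if self.source_kind == self.target_kind:
            raise ValueError("interaction layers join two distinct entity kinds")
        src, tgt = set(self.source_ids), set(self.target_ids)
        if len(src) != len(self.source_ids) or len(tgt) != len(self.target_ids):
            raise ValueError("duplicate identifiers in id lists")
        for a, b in self.edges:
            if a not in src or b not in tgt:
                raise ValueError(f"edge ({a!r}, {b!r}) references an undeclared identifier")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] for one entity kind, unit diagonal."""

    kind: str
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_kind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ParseError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers in similarity matrix")
        if n == 0:
            return
        if not np.allclose(self.values, self.values.T, atol=1e-6):
            raise ParseError("similarity matrix is asymmetric beyond 1e-6")
        if self.values.min() < -1e-6 or self.values.max() > 1 + 1e-6:
            raise ParseError("similarity values outside [0, 1] beyond 1e-6")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-6):
            raise ParseError("similarity matrix diagonal is not 1.0")
        # symmetrise and clip the sub-tolerance numeric noise
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DatasetStats:
    """Counts of the drug-target universe: known and unknown pairs."""

    n_drugs: int
    n_targets: int
    known_dtis: int
    unknown_dtis: int = field(init=False)

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.known_dtis) < 0:
            raise ValueError("counts must be non-negative")
        self.unknown_dtis = self.n_drugs * self.n_targets - self.known_dtis
        if self.unknown_dtis < 0:
            raise ValueError("more known DTIs than drug-target pairs")


def _split_line(line: str) -> list[str]:
    # tab or comma, auto-detected per line; falls back to whitespace
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_interaction_edges(path: str | Path, source_kind: str, target_kind: str) -> InteractionNetwork:
    """Read a two-column edge list (TSV/CSV, ``#`` comments) into a network.

    Duplicate edges are deduplicated with a logged warning; identifier lists
    keep first-appearance order.
    """
    path = Path(path)
    source_ids: list[str] = []
    target_ids: list[str] = []
    seen_s: set[str] = set()
    seen_t: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected at least 2 delimited fields, got {line!r}")
            s, t = fields[0], fields[1]
            if (s, t) in edges:
                n_dup += 1
                continue
            edges.add((s, t))
            if s not in seen_s:
                seen_s.add(s)
                source_ids.append(s)
            if t not in seen_t:
                seen_t.add(t)
                target_ids.append(t)
    if n_dup:
        logger.warning("%s: dropped %d duplicate edges", path, n_dup)
    return InteractionNetwork(source_kind, target_kind, source_ids, target_ids, edges)


def write_interaction_edges(net: InteractionNetwork, path: str | Path) -> None:
    """Write an interaction network as a 2-column TSV (sorted for stability)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {net.source_kind}\t{net.target_kind}\n")
        for s, t in sorted(net.edges):
            fh.write(f"{s}\t{t}\n")


def read_similarity_matrix(path: str | Path, kind: str) -> SimilarityMatrix:
    """Read a square similarity table (CSV/TSV, id header row and column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: similarity table is not square: {df.shape}")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ParseError(f"{path}: header row and index column identifiers differ")
    values = df.to_numpy(dtype=float)
    try:
        return SimilarityMatrix(kind, ids, values)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path)


def dataset_statistics(dti: InteractionNetwork, n_drugs: int, n_targets: int) -> DatasetStats:
    """Known/unknown pair counts over a declared drug x target universe."""
    if n_drugs < len(dti.source_ids) or n_targets < len(dti.target_ids):
        raise ValueError(
            "declared universe smaller than the identifiers observed in edges: "
            f"{n_drugs} drugs / {n_targets} targets vs "
            f"{len(dti.source_ids)} / {len(dti.target_ids)} observed"
        )
    return DatasetStats(n_drugs=n_drugs, n_targets=n_targets, known_dtis=dti.n_edges)


# canonical file names for an on-disk dataset directory
DATASET_FILES = {
    "dd_sim": "drug_similarity.csv",
    "tt_sim": "target_similarity.csv",
    "dti": "drug_target.tsv",
    "dl": "drug_lncrna.tsv",
    "dm": "drug_mirna.tsv",
    "lt": "lncrna_target.tsv",
    "mt": "mirna_target.tsv",
    "lm": "lncrna_mirna.tsv",
}

_LAYER_KINDS = {
    "dti": ("drug", "target"),
    "dl": ("drug", "lncRNA"),
    "dm": ("drug", "miRNA"),
    "lt": ("lncRNA", "target"),
    "mt": ("miRNA", "target"),
    "lm": ("lncRNA", "miRNA"),
}


def read_dataset_dir(
    directory: str | Path,
) -> tuple[SimilarityMatrix, SimilarityMatrix, dict[str, InteractionNetwork]]:
    """Read the eight canonical input files from a dataset directory."""
    d = Path(directory)
    dd = read_similarity_matrix(d / DATASET_FILES["dd_sim"], "drug")
    tt = read_similarity_matrix(d / DATASET_FILES["tt_sim"], "target")
    layers = {
        key: read_interaction_edges(d / DATASET_FILES[key], *_LAYER_KINDS[key])
        for key in _LAYER_KINDS
    }
    return dd, tt, layers


def write_prediction_table(
    pairs: Sequence[tuple[str, str]],
    scores: Iterable[float],
    path: str | Path,
) -> None:
    """Write ranked (drug, target, score) rows, best first, ties lexicographic."""
    scores = list(scores)
    if len(pairs) != len(scores):
        raise ValueError(f"{len(pairs)} pairs but {len(scores)} scores")
    if not all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i][0], pairs[i][1]))
    with Path(path).open("w") as fh:
        fh.write("drug\ttarget\tscore\n")
        for i in order:
            d, t = pairs[i]
            fh.write(f"{d}\t{t}\t{scores[i]:.6g}\n")
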