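"""Labelled pair construction, classifiers, and the end-to-end pipeline.

Known drug-target interactions are the positive class; negatives are drawn
uniformly at random from the unobserved pairs (a configurable multiple of
the positive count).  Each pair's feature vector merges the node2vec
embeddings of its drug and target with the 12 meta-path score features,
and a gradient-boosted tree ensemble (XGBoost by default; random forest
and AdaBoost as alternatives) scores the pair.

Two embedding scopes are supported by the cross-validation stage:

* ``per_fold`` (default): embeddings and path scores are recomputed for
  every fold with the fold's positive test edges removed from the graph,
  so no test-edge information reaches the features;
* ``full``: embeddings are trained once on the entire graph including all
  known interactions, matching the protocol the published tool describes
  (which lets test edges shape the embedding space).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier

from . import evalx
from .embed import Node2vecConfig, embed_graph
from .hetnet import (
    DTISubnetwork,
    HeteroGraph,
    build_heterogeneous_network,
    drop_ncrna_layers,
    dti_subnetwork,
)
from .metapath import PathScoreSet, compute_path_scores, pair_path_features
from .netio import InteractionNetwork, SimilarityMatrix
from .simfuse import FusionConfig, fuse_similarities

logger = logging.getLogger(__name__)


@dataclass
class PairDataset:
    pairs: list[tuple[int, int]]
    labels: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not (len(self.pairs) == len(self.labels) == len(self.features)):
            raise ValueError("pairs, labels and features must align")


@dataclass
class ClassifierSpec:
    family: Literal["gradient_boosting", "random_forest", "adaboost"] = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gradient_boosting", "random_forest", "adaboost"):
            raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class TrainedModel:
    estimator: object
    spec: ClassifierSpec
    feature_arity: int


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "gradient_boosting":
        from xgboost import XGBClassifier

        defaults = dict(
            n_estimators=500,
            max_depth=6,
            learning_rate=0.1,
            subsample=0.8,
            reg_lambda=1.0,
            reg_alpha=0.0,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
        defaults.update(hp)
        return XGBClassifier(random_state=spec.seed, **defaults)
    if spec.family == "random_forest":
        defaults = dict(n_estimators=500, n_jobs=1)
        defaults.update(hp)
        return RandomForestClassifier(random_state=spec.seed, **defaults)
    defaults = dict(n_estimators=200, learning_rate=0.5)
    defaults.update(hp)
    return AdaBoostClassifier(random_state=spec.seed, **defaults)


def sample_negative_pairs(
    dti: np.ndarray, ratio: float = 1.0, seed: int = 0
) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of zero cells of the DTI matrix.

    Draws round(ratio * #positives) pairs; raises if the zero-cell pool is
    too small.
    """
    dti = np.asarray(dti)
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    zeros = np.argwhere(dti == 0)
    n_pos = int(dti.sum())
    n_neg = int(round(ratio * n_pos))
    if n_neg > len(zeros):
        raise ValueError(f"requested {n_neg} negatives but only {len(zeros)} unknown pairs exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=n_neg, replace=False)
    return [(int(i), int(j)) for i, j in zeros[chosen]]


def assemble_pair_features(
    emb: dict[str, np.ndarray],
    scores: PathScoreSet | None,
    sub: DTISubnetwork,
    pair: tuple[str, str],
    merge: str = "concat",
) -> np.ndarray:
    """Feature vector for one (drug id, target id) pair.

    ``concat`` stacks the two embeddings and the 12 path features;
    ``hadamard_plus_psm`` uses the elementwise product of the embeddings
    instead of the stack.
    """
    drug_id, target_id = pair
    for node in pair:
        if node not in emb:
            raise KeyError(f"no embedding for node {node!r}")
    i = sub.drug_ids.index(drug_id)
    j = sub.target_ids.index(target_id)
    psm = pair_path_features(scores, i, j) if scores is not None else np.empty(0)
    ed, et = emb[drug_id], emb[target_id]
    if merge == "concat":
        return np.concatenate([ed, et, psm])
    if merge == "hadamard_plus_psm":
        return np.concatenate([ed * et, psm])
    raise ValueError(f"unknown merge {merge!r}")


def train_dti_classifier(data: PairDataset, spec: ClassifierSpec) -> TrainedModel:
    """Fit the configured classifier on a labelled pair dataset."""
    y = np.asarray(data.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = _build_estimator(spec)
    est.fit(np.asarray(data.features), y)
    return TrainedModel(estimator=est, spec=spec, feature_arity=data.features.shape[1])


def predict_dti_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Interaction probabilities in [0, 1] for each feature row."""
    features = np.asarray(features)
    if features.size == 0:
        return np.empty(0)
    if features.shape[1] != model.feature_arity:
        raise ValueError(f"feature arity {features.shape[1]} != model arity {model.feature_arity}")
    return model.estimator.predict_proba(features)[:, 1]


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run."""

    network: Literal["integrating", "original"] = "integrating"
    sim_threshold: float = 0.0
    fusion: FusionConfig = field(default_factory=FusionConfig)
    features: Literal["both", "node2vec", "psm"] = "both"
    merge: str = "concat"
    embed: Node2vecConfig = field(default_factory=Node2vecConfig)
    embed_scope: Literal["per_fold", "full"] = "per_fold"
    exclude_direct: bool = True
    negative_ratio: float = 1.0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0

    def resolve_seeds(self) -> None:
        """Derive per-stage seeds deterministically from the master seed."""
        self.embed.seed = self.seed * 1000 + 1
        self.classifier.seed = self.seed * 1000 + 2


@dataclass
class PipelineResult:
    cv: evalx.CVResult
    predictions: list[tuple[str, str, float]]
    n_positives: int
    n_negatives: int
    feature_arity: int


def _features_for_pairs(
    cfg: PipelineConfig,
    sub: DTISubnetwork,
    pairs: list[tuple[int, int]],
    emb: dict[str, np.ndarray] | None,
    scores: PathScoreSet | None,
) -> np.ndarray:
    rows = []
    for i, j in pairs:
        if cfg.features == "psm":
            rows.append(pair_path_features(scores, i, j))
        else:
            pair = (sub.drug_ids[i], sub.target_ids[j])
            rows.append(
                assemble_pair_features(
                    emb, scores if cfg.features == "both" else None, sub, pair, cfg.merge
                )
            )
    return np.asarray(rows)


def _fold_artifacts(
    cfg: PipelineConfig,
    g: HeteroGraph,
    sub: DTISubnetwork,
    removed_pairs: list[tuple[int, int]],
) -> tuple[dict[str, np.ndarray] | None, PathScoreSet | None]:
    """Embeddings and path scores with the given positive edges removed."""
    if removed_pairs:
        g = g.copy()
        a = sub.A.copy()
        for i, j in removed_pairs:
            d, t = sub.drug_ids[i], sub.target_ids[j]
            if g.has_edge(d, t):
                g.remove_edge(d, t)
            a[i, j] = 0.0
        sub = DTISubnetwork(sub.drug_ids, sub.target_ids, sub.Sd, sub.St, a)
    emb = embed_graph(g, cfg.embed) if cfg.features in ("both", "node2vec") else None
    scores = (
        compute_path_scores(sub, exclude_direct=cfg.exclude_direct)
        if cfg.features in ("both", "psm")
        else None
    )
    return emb, scores


def run_pipeline(
    dd_sims: list[SimilarityMatrix],
    tt_sims: list[SimilarityMatrix],
    layers: dict[str, InteractionNetwork],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full workflow.

    read -> fuse -> build network -> embed -> path scores -> sample
    negatives -> assemble features -> 11-part cross-validation -> refit on
    all labelled pairs -> score every unknown pair.
    """
    cfg = copy.deepcopy(config) if config is not None else PipelineConfig()
    cfg.resolve_seeds()

    dd = fuse_similarities(dd_sims, cfg.fusion)
    tt = fuse_similarities(tt_sims, cfg.fusion)
    g = build_heterogeneous_network(
        dd, tt, layers["dti"], layers["dl"], layers["dm"],
        layers["lt"], layers["mt"], layers["lm"], sim_threshold=cfg.sim_threshold,
    )
    if cfg.network == "original":
        g = drop_ncrna_layers(g)
    sub = dti_subnetwork(g)

    positives = [(int(i), int(j)) for i, j in np.argwhere(sub.A == 1)]
    negatives = sample_negative_pairs(sub.A, cfg.negative_ratio, seed=cfg.seed * 1000 + 3)
    assert not set(positives) & set(negatives), "negative sample collides with positives"
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    logger.info("pipeline: %d positives, %d negatives, scope=%s, features=%s",
                len(positives), len(negatives), cfg.embed_scope, cfg.features)

    if cfg.embed_scope == "full":
        emb, scores = _fold_artifacts(cfg, g, sub, [])
        x_all = _features_for_pairs(cfg, sub, pairs, emb, scores)

        def scorer(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
            data = PairDataset([pairs[k] for k in train_idx], labels[train_idx], x_all[train_idx])
            model = train_dti_classifier(data, cfg.classifier)
            return predict_dti_scores(model, x_all[test_idx])

    else:  # per_fold: recompute embeddings/path scores without test positives

        def scorer(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
            removed = [pairs[k] for k in test_idx if labels[k] == 1]
            emb, scores = _fold_artifacts(cfg, g, sub, removed)
            x_tr = _features_for_pairs(cfg, sub, [pairs[k] for k in train_idx], emb, scores)
            x_te = _features_for_pairs(cfg, sub, [pairs[k] for k in test_idx], emb, scores)
            data = PairDataset([pairs[k] for k in train_idx], labels[train_idx], x_tr)
            model = train_dti_classifier(data, cfg.classifier)
            return predict_dti_scores(model, x_te)

    cv = evalx.cross_validate(labels, scorer, seed=cfg.seed)

    # refit on all labelled pairs; score the unknown pairs de novo
    emb, _ = _fold_artifacts(cfg, g, sub, [])
    denovo_scores = (
        compute_path_scores(sub, exclude_direct=False) if cfg.features in ("both", "psm") else None
    )
    train_scores = (
        compute_path_scores(sub, exclude_direct=cfg.exclude_direct)
        if cfg.features in ("both", "psm")
        else None
    )
    x_all = _features_for_pairs(cfg, sub, pairs, emb, train_scores)
    model = train_dti_classifier(PairDataset(pairs, labels, x_all), cfg.classifier)
    unknown = [(int(i), int(j)) for i, j in np.argwhere(sub.A == 0)]
    preds: list[tuple[str, str, float]] = []
    if unknown:
        x_unknown = _features_for_pairs(cfg, sub, unknown, emb, denovo_scores)
        u_scores = predict_dti_scores(model, x_unknown)
        preds = sorted(
            (
                (sub.drug_ids[i], sub.target_ids[j], float(s))
                for (i, j), s in zip(unknown, u_scores)
            ),
            key=lambda r: (-r[2], r[0], r[1]),
        )
    return PipelineResult(
        cv=cv,
        predictions=preds,
        n_positives=len(positives),
        n_negatives=len(negatives),
        feature_arity=x_all.shape[1],
    )
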