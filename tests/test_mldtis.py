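import numpy as np
import pytest

from lmdti.embed import Node2vecConfig
from lmdti.metapath import compute_path_scores
from lmdti.mldtis import (
    ClassifierSpec,
    PairDataset,
    PipelineConfig,
    assemble_pair_features,
    predict_dti_scores,
    run_pipeline,
    sample_negative_pairs,
    train_dti_classifier,
)
from lmdti.synthgen import generate_toy_fixture


def small_embed_cfg():
    return Node2vecConfig(dim=16, num_walks=4, walk_length=10, epochs=2)


class TestNegativeSampling:
    def test_pool_too_small_rejected(self):
        dti = np.array([[1, 1], [1, 0]])
        with pytest.raises(ValueError, match="negatives"):
            sample_negative_pairs(dti, ratio=1.0, seed=0)

    def test_contract_on_10x10(self):
        rng = np.random.default_rng(0)
        dti = np.zeros((10, 10))
        ones = rng.choice(100, 10, replace=False)
        dti[np.unravel_index(ones, (10, 10))] = 1
        negs = sample_negative_pairs(dti, ratio=1.0, seed=5)
        assert len(negs) == 10
        assert all(dti[i, j] == 0 for i, j in negs)
        assert negs == sample_negative_pairs(dti, ratio=1.0, seed=5)
        assert len(set(negs)) == 10

    def test_nr_shaped_instance(self):
        """54 x 26 with 90 positives: 90 negatives drawn from the 1314 unknowns."""
        rng = np.random.default_rng(1)
        dti = np.zeros((54, 26))
        ones = rng.choice(54 * 26, 90, replace=False)
        dti[np.unravel_index(ones, (54, 26))] = 1
        negs = sample_negative_pairs(dti, ratio=1.0, seed=2)
        assert len(negs) == 90
        assert all(dti[i, j] == 0 for i, j in negs)

    def test_ratio_scales_count(self):
        dti = np.zeros((20, 20))
        dti[0, :10] = 1
        assert len(sample_negative_pairs(dti, ratio=2.0, seed=0)) == 20


class TestFeatureAssembly:
    def _setup(self, dim):
        sub = generate_toy_fixture()
        rng = np.random.default_rng(0)
        emb = {n: rng.random(dim) for n in sub.drug_ids + sub.target_ids}
        scores = compute_path_scores(sub)
        return sub, emb, scores

    def test_concat_length(self):
        sub, emb, scores = self._setup(16)
        v = assemble_pair_features(emb, scores, sub, ("d2", "t1"), "concat")
        assert v.shape == (44,)
        assert v[32] == pytest.approx(0.9)  # Sum(P1) follows the two embeddings

    def test_hadamard_length(self):
        sub, emb, scores = self._setup(16)
        v = assemble_pair_features(emb, scores, sub, ("d2", "t1"), "hadamard_plus_psm")
        assert v.shape == (28,)

    def test_zero_inputs_give_zero_vector(self):
        sub, _, _ = self._setup(4)
        emb = {n: np.zeros(4) for n in sub.drug_ids + sub.target_ids}
        zero_scores = compute_path_scores(
            type(sub)(sub.drug_ids, sub.target_ids, np.zeros((3, 3)), np.zeros((1, 1)), np.zeros((3, 1)))
        )
        v = assemble_pair_features(emb, zero_scores, sub, ("d1", "t1"), "concat")
        assert not v.any()

    def test_missing_embedding_names_node(self):
        sub, emb, scores = self._setup(8)
        del emb["d2"]
        with pytest.raises(KeyError, match="d2"):
            assemble_pair_features(emb, scores, sub, ("d2", "t1"))


class TestClassifier:
    def test_separable_toy_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        model = train_dti_classifier(PairDataset([(i, 0) for i in range(20)], y, x), ClassifierSpec())
        scores = predict_dti_scores(model, x)
        assert (scores[y == 1].min() > scores[y == 0].max())

    def test_permuted_labels_give_null_auc(self):
        """Labels independent of features: held-out AUC is near chance."""
        from lmdti.evalx import compute_auc

        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.random((200, 8))
            y = rng.integers(0, 2, 200)
            y[:2] = [0, 1]
            model = train_dti_classifier(
                PairDataset([(i, 0) for i in range(150)], y[:150], x[:150]),
                ClassifierSpec(seed=seed),
            )
            aucs.append(compute_auc(y[150:], predict_dti_scores(model, x[150:])))
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        x = rng.random((60, 5))
        y = np.array([0, 1] * 30)
        data = PairDataset([(i, 0) for i in range(60)], y, x)
        s1 = predict_dti_scores(train_dti_classifier(data, ClassifierSpec(seed=4)), x)
        s2 = predict_dti_scores(train_dti_classifier(data, ClassifierSpec(seed=4)), x)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_dti_classifier(PairDataset([(i, 0) for i in range(5)], np.ones(5), x), ClassifierSpec())

    def test_prediction_contracts(self):
        rng = np.random.default_rng(1)
        x = rng.random((40, 3))
        y = np.array([0, 1] * 20)
        model = train_dti_classifier(PairDataset([(i, 0) for i in range(40)], y, x), ClassifierSpec())
        scores = predict_dti_scores(model, x)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert predict_dti_scores(model, np.empty((0, 3))).size == 0
        perm = rng.permutation(40)
        assert np.allclose(predict_dti_scores(model, x[perm]), scores[perm])
        with pytest.raises(ValueError, match="arity"):
            predict_dti_scores(model, np.zeros((2, 7)))

    @pytest.mark.parametrize("family", ["random_forest", "adaboost"])
    def test_alternative_families_fit(self, family):
        rng = np.random.default_rng(2)
        x = rng.random((50, 4))
        y = np.array([0, 1] * 25)
        data = PairDataset([(i, 0) for i in range(50)], y, x)
        spec = ClassifierSpec(family=family, hyperparameters={"n_estimators": 20})
        scores = predict_dti_scores(train_dti_classifier(data, spec), x)
        assert ((scores >= 0) & (scores <= 1)).all()


class TestPipeline:
    def test_end_to_end_smoke_leak_free(self, planted_small):
        """Default leak-free protocol completes and emits CV metrics and
        a ranked prediction table on a small planted network."""
        dd, tt, layers, _ = planted_small
        cfg = PipelineConfig(
            embed=small_embed_cfg(),
            classifier=ClassifierSpec(hyperparameters={"n_estimators": 60}),
            seed=0,
        )
        res = run_pipeline([dd], [tt], layers, cfg)
        assert len(res.cv.fold_reports) == 10
        assert 0 <= res.cv.mean_aupr <= 1
        assert res.feature_arity == 2 * 16 + 12
        assert res.predictions == sorted(res.predictions, key=lambda r: (-r[2], r[0], r[1]))
        # predictions cover exactly the unknown pairs
        assert len(res.predictions) == dd.n * tt.n - layers["dti"].n_edges

    def test_ablation_original_network_keeps_arity(self, planted_small):
        dd, tt, layers, _ = planted_small
        cfg = PipelineConfig(
            network="original",
            embed_scope="full",
            embed=small_embed_cfg(),
            classifier=ClassifierSpec(hyperparameters={"n_estimators": 60}),
        )
        res = run_pipeline([dd], [tt], layers, cfg)
        assert res.feature_arity == 2 * 16 + 12

    def test_ablation_psm_only_arity_12(self, planted_small):
        dd, tt, layers, _ = planted_small
        cfg = PipelineConfig(
            features="psm",
            embed_scope="full",
            classifier=ClassifierSpec(hyperparameters={"n_estimators": 60}),
        )
        res = run_pipeline([dd], [tt], layers, cfg)
        assert res.feature_arity == 12

    def test_node2vec_only_arity(self, planted_small):
        dd, tt, layers, _ = planted_small
        cfg = PipelineConfig(
            features="node2vec",
            embed_scope="full",
            embed=small_embed_cfg(),
            classifier=ClassifierSpec(hyperparameters={"n_estimators": 60}),
        )
        res = run_pipeline([dd], [tt], layers, cfg)
        assert res.feature_arity == 32
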