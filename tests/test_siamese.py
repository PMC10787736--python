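import numpy as np
import pytest

from npnamematch import nn, normalize, pairgen, siamese
from npnamematch.errors import IncompatibleManifest, InvalidConfig, ZeroVector


class TestCosineDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
            ((1.0, 0.0), (0.0, 1.0), 1.0),
            ((1.0, 0.0), (-1.0, 0.0), 2.0),
        ],
    )
    def test_closed_forms(self, u, v, expected):
        assert siamese.cosine_distance(u, v) == pytest.approx(expected)

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroVector):
            siamese.cosine_distance((0.0, 0.0), (1.0, 0.0))


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "d,label,expected",
        [(0.0, 0, 0.0), (1.0, 1, 0.0), (0.3, 1, 0.49), (0.3, 0, 0.09), (1.7, 1, 0.0)],
    )
    def test_closed_forms(self, d, label, expected):
        assert siamese.contrastive_loss(d, label, margin=1.0) == pytest.approx(expected)

    def test_batch_mean(self):
        loss = siamese.contrastive_loss([0.0, 0.3], [0, 1], margin=1.0)
        assert loss == pytest.approx(0.49 / 2)


class TestModelContracts:
    def test_towers_share_parameters(self, toy_model):
        a, b = toy_model.tower_params
        assert all(a[k] is b[k] for k in a)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfig):
            siamese.ModelConfig(margin=0.0)
        with pytest.raises(InvalidConfig):
            siamese.ModelConfig(embed_layers=3)

    def test_distance_zero_on_identical_inputs_untrained(self, toy_model):
        for name in ("GINGER", "GLYCYRRHIZA GLABRA", "A"):
            assert siamese.pair_distance(toy_model, name, name) == 0.0

    def test_distance_symmetric_and_bounded(self, toy_model, rng):
        letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(1, 30)))
            b = "".join(rng.choice(letters, size=rng.integers(1, 30)))
            dab = siamese.pair_distance(toy_model, a, b)
            dba = siamese.pair_distance(toy_model, b, a)
            assert dab == dba
            assert 0.0 <= dab <= 1.0

    def test_padding_tail_does_not_change_embedding(self, toy_model):
        X = normalize.encode_batch(["GINGER"])
        v65 = toy_model.embed(X)
        v6 = toy_model.embed(X[:, :6])
        np.testing.assert_allclose(v65, v6, atol=1e-7)


class TestGradients:
    def test_numerical_gradient_check(self, rng):
        """Analytic backprop through embed+BiLSTM+merge+loss matches
        central finite differences."""
        params = nn.init_params(6, 5, 4, 3, rng, dtype=np.float64)
        for k in params:  # move biases off the exact ReLU kink at 0
            if k.endswith("_b") or "_b" in k:
                params[k] = params[k] + rng.normal(0, 0.05, params[k].shape)
        Xa = rng.integers(1, 6, size=(3, 5))
        Xb = rng.integers(1, 6, size=(3, 5))
        Xa[0, 3:] = 0
        Xb[2, 2:] = 0
        y = np.array([0, 1, 1])
        _, _, grads = nn.loss_and_grads(params, Xa, Xb, y, 1.0, dtype=np.float64)
        eps = 1e-6
        for k, p in params.items():
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _, _ = nn.loss_and_grads(params, Xa, Xb, y, 1.0, dtype=np.float64)
                p[idx] = orig - eps
                lm, _, _ = nn.loss_and_grads(params, Xa, Xb, y, 1.0, dtype=np.float64)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_gradient_step_moves_distances_the_right_way(self):
        """One optimizer step pulls a matching pair closer and pushes a
        distant pair (inside the margin) further apart."""
        config = siamese.ModelConfig(embed_hidden=8, embed_dim=4, recurrent_units=4,
                                     learning_rate=1e-2, seed=5)
        for label in (0, 1):
            model = siamese.build_model(config)
            Xa = normalize.encode_batch(["GINGER"])[:, :10]
            Xb = normalize.encode_batch(["GINSENG"])[:, :10]
            y = np.array([label])
            d_before = siamese.pair_distance(model, "GINGER", "GINSENG")
            assert d_before < config.margin
            opt = nn.Adam(model.params, lr=1e-2)
            _, _, grads = nn.loss_and_grads(model.params, Xa, Xb, y, config.margin)
            opt.step(model.params, grads)
            d_after = siamese.pair_distance(model, "GINGER", "GINSENG")
            if label == 0:
                assert d_after < d_before
            else:
                assert d_after > d_before


class TestTraining:
    def test_toy_training_separates_pairs(self, trained_toy):
        history = trained_toy["history"]
        assert history.best_val_accuracy > 0.9
        assert history.best_epoch >= 1
        # best-epoch weights are the ones kept: recomputed accuracy matches
        model, data = trained_toy["model"], trained_toy["data"]
        d = siamese.pair_distances(model, data.validation)
        labels = np.array([p.label for p in data.validation])
        acc = siamese.pair_accuracy_from_distances(d, labels)
        assert acc == pytest.approx(max(history.val_accuracy), abs=1e-9)

    def test_matched_closer_than_unmatched_on_holdout(self, trained_toy):
        model, data = trained_toy["model"], trained_toy["data"]
        d = siamese.pair_distances(model, data.holdout)
        labels = np.array([p.label for p in data.holdout])
        assert d[labels == 0].mean() < d[labels == 1].mean()

    def test_patience_zero_stops_after_first_non_improving_epoch(self, small_lexicon):
        config = pairgen.PerturbationConfig(rng_seed=2)
        data = pairgen.build_dataset(small_lexicon, config, pairs_per_group=10, seed=2)
        mc = siamese.ModelConfig(embed_hidden=8, embed_dim=4, recurrent_units=4,
                                 max_epochs=50, patience=0, min_delta=10.0, seed=2)
        model = siamese.build_model(mc)
        # min_delta so large that no epoch counts as an improvement
        _, history = siamese.train(model, data, mc)
        assert history.stopped_epoch == 2

    def test_identical_train_and_validation_losses_track(self, small_lexicon):
        config = pairgen.PerturbationConfig(rng_seed=3)
        data = pairgen.build_dataset(small_lexicon, config, pairs_per_group=10, seed=3)
        data = pairgen.PairDataset(data.train, data.train, [], {})
        mc = siamese.ModelConfig(embed_hidden=8, embed_dim=4, recurrent_units=4,
                                 max_epochs=3, seed=3)
        model = siamese.build_model(mc)
        _, history = siamese.train(model, data, mc)
        # validation loss is computed post-epoch, train loss mid-epoch, so
        # they differ but stay on the same scale
        assert history.val_loss[-1] == pytest.approx(history.train_loss[-1], rel=0.5)


class TestRetrieval:
    def test_query_in_corpus_ranks_first_with_zero_distance(self, toy_model):
        corpus = ["GINGER", "LICORICE", "CINNAMON"]
        ranked = siamese.sm_top_k(toy_model, "GINGER", corpus, k=3)
        cand, score, rank = ranked.entries[0]
        assert cand == "GINGER" and score == 0.0 and rank == 1

    def test_k_larger_than_corpus(self, toy_model):
        ranked = siamese.sm_top_k(toy_model, "GINGER", ["A", "B"], k=20)
        assert len(ranked.entries) == 2

    def test_trained_model_retrieves_planted_misspelling(self, trained_toy, rng):
        model, lexicon = trained_toy["model"], trained_toy["lexicon"]
        config = pairgen.PerturbationConfig(rng_seed=21)
        query = lexicon.groups[0].preferred_term
        planted = pairgen.perturb_name(query, config, np.random.default_rng(21))
        decoys = pairgen.synth_decoy_corpus(100, seed=22, avoid={planted})
        ranked = siamese.sm_top_k(model, query, decoys + [planted], k=5)
        assert planted in ranked.candidates


class TestPersistence:
    def test_save_load_round_trip_bit_identical(self, trained_toy, tmp_path):
        model = trained_toy["model"]
        siamese.save_model(model, tmp_path / "run", history=trained_toy["history"],
                          data=trained_toy["data"])
        loaded = siamese.load_model(tmp_path / "run")
        for a, b in (("GINGER", "GINSENG"), ("LICORICE", "LIQUORICE")):
            assert siamese.pair_distance(loaded, a, b) == siamese.pair_distance(model, a, b)

    def test_manifest_records_provenance(self, trained_toy, tmp_path):
        import json

        siamese.save_model(trained_toy["model"], tmp_path / "run",
                          history=trained_toy["history"], data=trained_toy["data"])
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == trained_toy["model"].config.seed
        assert manifest["data_hash"]
        assert manifest["best_epoch"] == trained_toy["history"].best_epoch

    def test_incompatible_manifest_rejected(self, toy_model, tmp_path):
        import json

        siamese.save_model(toy_model, tmp_path / "run")
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        manifest["config"]["vocab_size"] = 99
        (tmp_path / "run" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(IncompatibleManifest):
            siamese.load_model(tmp_path / "run")
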