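import numpy as np
import pytest

from distressfuse.baselines import (CNNModalityModel, ModalityClassifierModel,
                                    SequenceVariantModel, build_cnn_modality,
                                    ensemble_scores, feature_matrix,
                                    late_fuse_stacking, session_features,
                                    train_modality_classifier)
from distressfuse.preprocess import fit_text_featurizer
from distressfuse.synthetic import SignalModel
from tests.conftest import make_aligned_cohort


class TestModalityClassifier:
    def test_separable_toy_set_fits_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.repeat([0, 1], 10)
        res = train_modality_classifier(X, y, kind="max-margin", seed=0)
        _, calls = res.predict(X)
        assert (calls == y).mean() == 1.0

    @pytest.mark.parametrize("kind", ["max-margin", "random-forest"])
    def test_null_features_give_chance_oof_accuracy(self, kind):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 5))
            y = np.repeat([0, 1], 20)
            res = train_modality_classifier(X, y, kind=kind, seed=seed)
            accs.append(((res.oof_scores >= 0.5).astype(int) == y).mean())
        se = 0.5 / np.sqrt(40 * 5)
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        y = np.repeat([0, 1], 10)
        a = train_modality_classifier(X, y, seed=4)
        b = train_modality_classifier(X, y, seed=4)
        assert np.array_equal(a.oof_scores, b.oof_scores)
        assert np.array_equal(a.predict(X)[0], b.predict(X)[0])

    def test_oof_scores_come_from_held_out_folds(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = np.repeat([0, 1], 10)
        res = train_modality_classifier(X, y, seed=0)
        assert res.fold_of.min() >= 0  # every session was held out exactly once
        assert not np.isnan(res.oof_scores).any()
        assert len(np.unique(res.fold_of)) >= 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ModalityClassifierModel(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_unknown_kind_rejected(self):
        X = np.zeros((8, 2))
        y = np.repeat([0, 1], 4)
        with pytest.raises(ValueError, match="unknown classifier kind"):
            ModalityClassifierModel(X, y, kind="boosted").fit()


class TestSessionFeatures:
    def test_audio_video_summary_widths(self, tiny_bundles):
        f = fit_text_featurizer(["hello there"])
        assert session_features(tiny_bundles[0], "audio", f).shape == (148,)
        assert session_features(tiny_bundles[0], "video", f).shape == (776,)

    def test_text_features_include_lexical_stats(self, tiny_bundles):
        from distressfuse.preprocess import participant_corpus
        f = fit_text_featurizer(participant_corpus(tiny_bundles))
        v = session_features(tiny_bundles[0], "text", f)
        assert v.shape == (len(f.vocabulary) + 3,)
        assert v[-1] > 0  # type-token ratio

    def test_feature_matrix_stacks_sessions(self, tiny_bundles):
        f = fit_text_featurizer(["hello"])
        X = feature_matrix(tiny_bundles, "audio", f)
        assert X.shape == (len(tiny_bundles), 148)


class TestStacking:
    def test_second_stage_input_width_is_number_of_modalities(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=(20, 3))
        y = np.repeat([0, 1], 10)
        res = late_fuse_stacking(scores, y, seed=0)
        assert res.classifier.n_features_in_ == 3

    def test_missing_scores_error_lists_sessions(self):
        scores = np.ones((4, 3))
        scores[2, 1] = np.nan
        with pytest.raises(ValueError, match=r"\[2\]"):
            late_fuse_stacking(scores, np.array([0, 1, 0, 1]))

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            late_fuse_stacking(np.ones((4, 2)), np.array([0, 1, 0, 1]))

    def test_informative_modality_dominates_fusion(self):
        # one perfectly informative column, two pure-noise columns
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            informative = y * 0.8 + 0.1 + rng.normal(0, 0.02, 60)
            scores = np.column_stack([informative,
                                      rng.uniform(size=60), rng.uniform(size=60)])
            tr = np.concatenate([np.arange(0, 20), np.arange(30, 50)])
            te = np.concatenate([np.arange(20, 30), np.arange(50, 60)])
            res = late_fuse_stacking(scores[tr], y[tr], seed=seed)
            _, fused_calls = res.predict(scores[te])
            from distressfuse.evaluate import confusion_counts, precision_recall_f1
            fused_f1 = precision_recall_f1(confusion_counts(fused_calls, y[te]))[2]
            solo_calls = (scores[te, 0] >= 0.5).astype(int)
            solo_f1 = precision_recall_f1(confusion_counts(solo_calls, y[te]))[2]
            deltas.append(fused_f1 - solo_f1)
        assert np.mean(deltas) >= -0.05


class TestEnsembleScores:
    def test_mean_of_two_members(self):
        assert ensemble_scores([np.array([0.2]), np.array([0.8])])[0] == 0.5

    def test_single_member_identity(self):
        s = np.array([0.1, 0.9])
        assert np.array_equal(ensemble_scores([s]), s)

    def test_member_order_symmetry(self):
        a, b = np.array([0.2, 0.4]), np.array([0.6, 0.8])
        assert np.array_equal(ensemble_scores([a, b]), ensemble_scores([b, a]))

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="session ids"):
            ensemble_scores([np.array([0.5]), np.array([0.5])],
                            session_ids=[["a"], ["b"]])


class TestCNN:
    @pytest.mark.parametrize("modality", ["audio", "text"])
    def test_exactly_six_weight_bearing_layers(self, modality):
        _, ds, _ = make_aligned_cohort(6, SignalModel.null(), L=20, seed=0)
        model = build_cnn_modality(ds, modality)
        model._build(seed=0)
        assert len(model.weight_bearing_layers()) == 6

    def test_output_is_probability(self):
        _, ds, _ = make_aligned_cohort(6, SignalModel.null(), L=20, seed=1)
        res = build_cnn_modality(ds, "audio").fit(epochs=1, seed=0)
        probs, _ = res.predict(ds)
        assert np.all((probs > 0) & (probs < 1))

    def test_strong_audio_signal_learned(self):
        _, ds, _ = make_aligned_cohort(16, SignalModel.single_modality("audio", 2.5),
                                       L=20, seed=2)
        res = build_cnn_modality(ds, "audio").fit(epochs=30, seed=0,
                                                  early_stop_accuracy=0.95)
        assert max(res.history["accuracy"]) > 0.9

    def test_unknown_modality_rejected(self):
        _, ds, _ = make_aligned_cohort(4, SignalModel.null(), L=20, seed=3)
        with pytest.raises(ValueError):
            CNNModalityModel(ds, "haptics")


class TestSequenceVariants:
    def test_gating_level_changes_parameter_total_by_block_counts(self):
        _, ds, _ = make_aligned_cohort(4, SignalModel.null(), L=6, seed=0)
        gated = SequenceVariantModel(ds, gating_level="sentence")
        plain = SequenceVariantModel(ds, gating_level="none")
        from distressfuse.fusion import account_for_spec
        total_gated = account_for_spec(gated.inner.spec).total
        total_plain = account_for_spec(plain.inner.spec).total
        block74 = 2 * (74 * 74 + 6 * 74)
        block388 = 2 * (388 * 388 + 6 * 388)
        assert total_gated - total_plain == 3 * (block74 + block388)

    def test_bidirectional_doubles_recurrent_count(self):
        _, ds, _ = make_aligned_cohort(4, SignalModel.null(), L=6, seed=1)
        bi = SequenceVariantModel(ds, kind="bidirectional")
        from distressfuse.fusion import account_for_spec
        acct = account_for_spec(bi.inner.spec).by_name()
        assert acct["recurrent"] == 2 * 103_936
        assert acct["output"] == 257  # affine on the 256-d concatenated state

    def test_word_level_dataset_trains(self):
        bundles, _, feat = make_aligned_cohort(6, SignalModel.null(), L=6, seed=2)
        from distressfuse.preprocess import AlignedDataset, align_word_level
        ds_word = AlignedDataset([align_word_level(b, feat, L=24)
                                  for b in bundles])
        res = SequenceVariantModel(ds_word, gating_level="word").fit(epochs=1,
                                                                     seed=0)
        assert len(res.history["loss"]) == 1

    def test_unknown_combination_rejected(self):
        _, ds, _ = make_aligned_cohort(4, SignalModel.null(), L=6, seed=3)
        with pytest.raises(ValueError):
            SequenceVariantModel(ds, kind="transformer")
        with pytest.raises(ValueError):
            SequenceVariantModel(ds, gating_level="phoneme")
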