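import logging
import math

import numpy as np
import pytest

from distressfuse.io_formats import (CohortIndex, FrameTable, SessionBundle,
                                     Speaker, TranscriptRecord)
from distressfuse.preprocess import (EMBED_DIM, TEXT_DIM, AlignedDataset,
                                     align_sentence_level, align_word_level,
                                     fit_text_featurizer, lexical_profile,
                                     slice_frames, tokenize, upsample_minority)


class TestSliceFrames:
    def test_half_open_window_convention(self):
        ft = FrameTable(0.010, np.arange(500 * 2, dtype=float).reshape(500, 2))
        sl = slice_frames(ft, 2.5, 4.0)
        assert sl.shape[0] == 150
        assert sl[0, 0] == ft.features[250, 0]
        assert sl[-1, 0] == ft.features[399, 0]

    def test_single_period_window_is_one_row(self):
        ft = FrameTable(0.010, np.zeros((100, 3)))
        assert slice_frames(ft, 0.0, 0.010).shape[0] == 1

    def test_window_past_end_truncates_with_warning(self, caplog):
        ft = FrameTable(0.010, np.zeros((10, 3)))
        with caplog.at_level(logging.WARNING):
            out = slice_frames(ft, 0.5, 1.0)
        assert out.shape[0] == 0
        assert any("truncated" in r.message for r in caplog.records)

    def test_invalid_window_rejected(self):
        ft = FrameTable(0.010, np.zeros((10, 3)))
        with pytest.raises(ValueError):
            slice_frames(ft, 2.0, 1.0)


class TestTextFeaturizer:
    def test_idf_formula_on_tiny_corpus(self):
        f = fit_text_featurizer(["a b", "a"])
        assert f.idf[f.vocabulary["a"]] == pytest.approx(math.log(3 / 3) + 1)
        assert f.idf[f.vocabulary["b"]] == pytest.approx(math.log(3 / 2) + 1,
                                                         abs=1e-6)

    def test_token_in_every_utterance_has_idf_one(self):
        f = fit_text_featurizer(["x y", "x z", "x"])
        assert f.idf[f.vocabulary["x"]] == pytest.approx(1.0)

    def test_embedding_table_deterministic_given_seed(self):
        corpus = ["one two three", "two three four"]
        a = fit_text_featurizer(corpus, seed=5)
        b = fit_text_featurizer(corpus, seed=5)
        c = fit_text_featurizer(corpus, seed=6)
        assert np.array_equal(a.embedding_table, b.embedding_table)
        assert not np.array_equal(a.embedding_table, c.embedding_table)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_text_featurizer([])

    def test_tfidf_matches_sklearn(self):
        # independent oracle: sklearn's smoothed-idf l2-normalised tf-idf
        from sklearn.feature_extraction.text import TfidfVectorizer
        corpus = ["the cat sat", "the dog sat down", "a cat and a dog", "down he sat"]
        f = fit_text_featurizer(corpus)
        vec = TfidfVectorizer(norm="l2", smooth_idf=True, sublinear_tf=False,
                              token_pattern=r"[a-z0-9']+")
        ref = vec.fit_transform(corpus).toarray()
        ref_cols = vec.get_feature_names_out()
        for i, doc in enumerate(corpus):
            mine = f.tfidf_vector(doc)
            for j, tok in enumerate(ref_cols):
                assert mine[f.vocabulary[tok]] == pytest.approx(ref[i, j], abs=1e-9)

    def test_embed_text_is_mean_embedding_plus_count(self):
        f = fit_text_featurizer(["aa bb", "aa"])
        v = f.embed_text("aa bb")
        expected = (f.embedding_table[f.vocabulary["aa"]]
                    + f.embedding_table[f.vocabulary["bb"]]) / 2
        assert np.allclose(v[:EMBED_DIM], expected)
        assert v[EMBED_DIM] == 2.0


class TestLexicalProfile:
    def test_counts_and_ttr(self):
        recs = [TranscriptRecord(0, 1, Speaker.PARTICIPANT, "the cat"),
                TranscriptRecord(1, 2, Speaker.PARTICIPANT, "the dog")]
        prof = lexical_profile(recs)
        assert prof["word_count"] == 4
        assert prof["type_token_ratio"] == pytest.approx(3 / 4)
        assert prof["mean_sentence_length"] == pytest.approx(2.0)

    def test_single_word_ttr_is_one(self):
        recs = [TranscriptRecord(0, 1, Speaker.PARTICIPANT, "hello")]
        assert lexical_profile(recs)["type_token_ratio"] == 1.0

    def test_repeats_drive_ttr_down(self):
        recs = [TranscriptRecord(i, i + 1, Speaker.PARTICIPANT, "same")
                for i in range(10)]
        assert lexical_profile(recs)["type_token_ratio"] == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lexical_profile([])


def _toy_bundle(n_utts=3, label=0, c_audio=2.0, n_frames=1000):
    """Bundle with constant audio features and simple utterances."""
    transcript = []
    for k in range(n_utts):
        t0 = 2.0 * k
        transcript.append(TranscriptRecord(t0, t0 + 0.9, Speaker.INTERVIEWER,
                                           "question here"))
        transcript.append(TranscriptRecord(t0 + 1.0, t0 + 1.9,
                                           Speaker.PARTICIPANT, f"word{k} reply"))
    audio = FrameTable(0.010, np.full((n_frames, 74), c_audio))
    video = FrameTable(1 / 30, np.zeros((n_frames // 10, 388)))
    return SessionBundle(session_id="T1", transcript=transcript, audio=audio,
                         video=video, label=label, duration=2.0 * n_utts)


class TestSentenceAlignment:
    def test_padding_contract(self):
        b = _toy_bundle(n_utts=3)
        f = fit_text_featurizer(["word reply"])
        a = align_sentence_level(b, f, L=10)
        assert a.valid_steps == 3
        assert np.all(a.text_seq[3:] == 0)
        assert np.all(a.audio_seq[3:] == 0)
        assert np.all(a.video_seq[3:] == 0)

    def test_truncation_keeps_earliest_steps(self):
        b = _toy_bundle(n_utts=5)
        f = fit_text_featurizer(["reply"])
        a = align_sentence_level(b, f, L=2)
        assert a.valid_steps == 2
        # first step covers the first utterance's window
        assert np.allclose(a.audio_seq[0], 2.0)

    def test_constant_audio_gives_constant_steps(self):
        b = _toy_bundle(c_audio=3.5)
        f = fit_text_featurizer(["reply"])
        a = align_sentence_level(b, f, L=8)
        assert np.allclose(a.audio_seq[:a.valid_steps], 3.5)

    def test_no_participant_content_rejected(self):
        b = _toy_bundle()
        b2 = SessionBundle(session_id="T2",
                           transcript=[r for r in b.transcript
                                       if r.speaker is Speaker.INTERVIEWER],
                           audio=b.audio, video=b.video, label=0,
                           duration=b.duration)
        f = fit_text_featurizer(["x"])
        with pytest.raises(ValueError, match="no participant content"):
            align_sentence_level(b2, f, L=8)

    def test_alignment_is_label_independent(self):
        f = fit_text_featurizer(["reply word0 word1 word2"])
        a0 = align_sentence_level(_toy_bundle(label=0), f, L=8)
        a1 = align_sentence_level(_toy_bundle(label=1), f, L=8)
        assert np.array_equal(a0.text_seq, a1.text_seq)
        assert np.array_equal(a0.audio_seq, a1.audio_seq)
        assert (a0.label, a1.label) == (0, 1)

    def test_padding_conservation(self, tiny_aligned):
        ds, _ = tiny_aligned
        for s in ds.sessions:
            v = s.valid_steps
            assert np.isclose(s.audio_seq[:v].sum(), s.audio_seq.sum())
            assert np.isclose(s.text_seq[:v].sum(), s.text_seq.sum())

    def test_text_step_width_is_301(self, tiny_aligned):
        ds, _ = tiny_aligned
        assert ds.sessions[0].text_seq.shape[1] == TEXT_DIM == 301

    def test_disjoint_utterances_use_disjoint_frames(self):
        b = _toy_bundle(n_utts=3)
        total = sum(
            len(range(math.floor(r.start_time / 0.010),
                      math.floor(r.stop_time / 0.010)))
            for r in b.participant_utterances())
        assert total <= b.audio.n_frames


class TestWordAlignment:
    def test_word_steps_at_least_sentence_steps(self):
        b = _toy_bundle(n_utts=3)
        f = fit_text_featurizer(["word reply"])
        sent = align_sentence_level(b, f, L=50)
        word = align_word_level(b, f, L=50)
        assert word.valid_steps >= sent.valid_steps

    def test_word_steps_repeat_sentence_audio(self):
        b = _toy_bundle(n_utts=1, c_audio=1.25)
        f = fit_text_featurizer(["word0 reply"])
        word = align_word_level(b, f, L=10)
        assert word.valid_steps == 2  # two tokens in the utterance
        assert np.allclose(word.audio_seq[0], word.audio_seq[1])


class TestUpsampleMinority:
    @staticmethod
    def make_index(n0, n1):
        entries = [(f"n{i}", f"n{i}", 0) for i in range(n0)]
        entries += [(f"d{i}", f"d{i}", 1) for i in range(n1)]
        return CohortIndex(entries=entries)

    def test_cohort_imbalance_maps_130_59_to_130_130(self):
        out = upsample_minority(self.make_index(130, 59), seed=1)
        assert out.class_counts == (130, 130)

    def test_already_balanced_unchanged(self):
        idx = self.make_index(50, 50)
        assert upsample_minority(idx).entries == idx.entries

    def test_single_minority_session_repeats(self):
        out = upsample_minority(self.make_index(3, 1), seed=0)
        assert out.class_counts == (3, 3)
        dep_paths = [p for _, p, lab in out.entries if lab == 1]
        assert dep_paths == ["d0", "d0", "d0"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            upsample_minority(self.make_index(4, 0))

    @pytest.mark.parametrize("n0,n1", [(7, 2), (2, 9), (5, 5), (1, 4)])
    def test_balance_to_majority_for_any_counts(self, n0, n1):
        out = upsample_minority(self.make_index(n0, n1), seed=3)
        m = max(n0, n1)
        assert out.class_counts == (m, m)

    def test_majority_entries_untouched(self):
        idx = self.make_index(4, 2)
        out = upsample_minority(idx, seed=2)
        assert [e for e in out.entries[:6]] == idx.entries


def test_tokenize_strips_punctuation_and_case():
    assert tokenize("Hello, World! it's me.") == ["hello", "world", "it's", "me"]
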