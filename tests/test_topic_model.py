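"""Collapsed Gibbs LDA: estimators, coherence, model selection, embeddings."""

import numpy as np
import pytest

from phenotyper.corpus_builder import build_corpus, combine_encounter_tokens
from phenotyper.topic_model import (
    coherence,
    embed_encounters,
    fit_lda,
    matched_mean_tv,
    select_topic_count,
    top_words,
)


def corpus_of(docs):
    bags = [combine_encounter_tokens([d], encounter_id=f"E{i}")
            for i, d in enumerate(docs)]
    vocab = {t for d in docs for t in d}
    return build_corpus(bags, vocab)


class TestFitLda:
    def test_k1_theta_is_one_and_phi_is_smoothed_empirical(self):
        corpus = corpus_of([["a", "a", "b"], ["b", "c"]])
        model = fit_lda(corpus, K=1, n_iterations=5, seed=0)
        assert np.allclose(model.theta, 1.0)
        counts = np.asarray(corpus.counts.sum(axis=0)).ravel()
        expected = (counts + model.beta) / (counts.sum() + corpus.n_terms * model.beta)
        assert np.allclose(model.phi[0], expected)

    def test_posterior_mean_theta_closed_form(self):
        """theta is (n_dk + alpha) / (len + K*alpha) on the final counts."""
        corpus = corpus_of([["a"] * 10])
        model = fit_lda(corpus, K=2, alpha=0.1, n_iterations=50, seed=3)
        k_hot = int(np.argmax(model.n_dk[0]))
        if model.n_dk[0, k_hot] == 10:  # all tokens on one topic
            expect = np.array([0.1 / 10.2, 0.1 / 10.2])
            expect[k_hot] = 10.1 / 10.2
            assert np.allclose(model.theta[0], expect)
        assert model.theta[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_count_consistency_and_simplex_invariants(self, planted_corpus):
        _, corpus, _ = planted_corpus
        model = fit_lda(corpus, K=3, n_iterations=30, seed=5)
        doc_len = np.asarray(corpus.counts.sum(axis=1)).ravel()
        assert (model.n_dk.sum(axis=1) == doc_len).all()
        assert (model.n_kw.sum(axis=1) == model.n_k).all()
        assert np.abs(model.phi.sum(axis=1) - 1).max() < 1e-9
        assert np.abs(model.theta.sum(axis=1) - 1).max() < 1e-9

    def test_seed_determinism_bitwise(self, planted_corpus):
        _, corpus, _ = planted_corpus
        m1 = fit_lda(corpus, K=3, n_iterations=20, seed=11)
        m2 = fit_lda(corpus, K=3, n_iterations=20, seed=11)
        assert np.array_equal(m1.phi, m2.phi) and np.array_equal(m1.theta, m2.theta)

    def test_planted_topic_recovery(self, planted_corpus):
        _, corpus, phi_true = planted_corpus
        model = fit_lda(corpus, K=3, n_iterations=300, seed=2)
        assert matched_mean_tv(model.phi, phi_true) <= 0.10

    def test_label_permutation_equivalence_across_seeds(self, planted_corpus):
        _, corpus, _ = planted_corpus
        m1 = fit_lda(corpus, K=3, n_iterations=300, seed=21)
        m2 = fit_lda(corpus, K=3, n_iterations=300, seed=22)
        assert matched_mean_tv(m1.phi, m2.phi) <= 0.15

    def test_empty_document_gets_uniform_theta(self):
        corpus = build_corpus(
            [combine_encounter_tokens([["x"]], encounter_id="E0"),
             combine_encounter_tokens([["a", "a"]], encounter_id="E1")],
            {"a"},
        )
        model = fit_lda(corpus, K=4, n_iterations=10, seed=0)
        assert np.allclose(model.theta[0], 0.25)

    def test_k_exceeding_vocab_warns(self):
        corpus = corpus_of([["a", "b"]])
        with pytest.warns(UserWarning):
            fit_lda(corpus, K=5, n_iterations=2, seed=0)


class TestCoherence:
    def test_perfect_cooccurrence_near_zero(self):
        # both top words in every document containing them
        corpus = corpus_of([["a", "b"]] * 10)
        model = fit_lda(corpus, K=1, n_iterations=5, seed=0)
        _per, mean = coherence(model, corpus, top_m=2)
        assert mean == pytest.approx(np.log(11 / 10))

    def test_direct_formula_evaluation(self):
        """Pair with zero co-occurrence contributes log(1 / D(w_j))."""
        docs = [["a"]] * 50 + [["b"]] * 50
        corpus = corpus_of(docs)
        model = fit_lda(corpus, K=1, n_iterations=5, seed=0)
        _per, mean = coherence(model, corpus, top_m=2)
        assert mean == pytest.approx(np.log(1 / 50))

    def test_oracle_equivalence(self, planted_corpus):
        _, corpus, _ = planted_corpus
        model = fit_lda(corpus, K=3, n_iterations=50, seed=8)
        per, mean = coherence(model, corpus, top_m=8)
        dense = (corpus.counts.toarray() > 0).astype(int)
        vidx = {w: j for j, w in enumerate(corpus.vocabulary)}
        for k, got in enumerate(per):
            words = [vidx[w] for w, _ in top_words(model, k, 8)]
            score = 0.0
            for i in range(len(words)):
                for j in range(i + 1, len(words)):
                    dj = dense[:, words[j]].sum()
                    co = (dense[:, words[i]] & dense[:, words[j]]).sum()
                    score += np.log((co + 1) / dj)
            assert got == pytest.approx(score, abs=1e-10)
        assert mean == pytest.approx(np.mean(per), abs=1e-12)

    def test_top_m_clamped_with_warning(self):
        corpus = corpus_of([["a", "b"]])
        model = fit_lda(corpus, K=1, n_iterations=2, seed=0)
        with pytest.warns(UserWarning):
            coherence(model, corpus, top_m=99)


class TestSelectTopicCount:
    def test_plateau_rule_arithmetic(self, monkeypatch):
        """Profile [-5, -3, -2.9, -2.85], eps=0.1 -> cutoff -3.065 -> K=20."""
        import phenotyper.topic_model as tm

        scores = dict(zip([10, 20, 30, 40], [-5.0, -3.0, -2.9, -2.85]))

        monkeypatch.setattr(tm, "fit_lda", lambda corpus, K, **kw: K)
        monkeypatch.setattr(tm, "coherence", lambda K, corpus: ([scores[K]], scores[K]))
        profile = select_topic_count(None, [10, 20, 30, 40], plateau_epsilon=0.1)
        assert profile.chosen_k == 20

    def test_tie_rule_smallest_k(self, monkeypatch):
        import phenotyper.topic_model as tm

        monkeypatch.setattr(tm, "fit_lda", lambda corpus, K, **kw: K)
        monkeypatch.setattr(tm, "coherence", lambda K, corpus: ([-2.0], -2.0))
        profile = select_topic_count(None, [5, 10, 20], plateau_epsilon=0.05)
        assert profile.chosen_k == 5

    def test_singleton_grid_warns(self, monkeypatch):
        import phenotyper.topic_model as tm

        monkeypatch.setattr(tm, "fit_lda", lambda corpus, K, **kw: K)
        monkeypatch.setattr(tm, "coherence", lambda K, corpus: ([-1.0], -1.0))
        with pytest.warns(UserWarning):
            profile = select_topic_count(None, [7])
        assert profile.chosen_k == 7

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            select_topic_count(None, [10, 5])


class TestEmbeddings:
    def test_rows_sum_to_one(self, planted_corpus):
        _, corpus, _ = planted_corpus
        model = fit_lda(corpus, K=3, n_iterations=20, seed=4)
        emb = embed_encounters(model, corpus)
        assert np.abs(emb.sum(axis=1) - 1).max() < 1e-9
        assert (emb.to_numpy() >= 0).all()

    def test_k1_embeddings_all_one(self):
        corpus = corpus_of([["a", "b"], ["b"]])
        model = fit_lda(corpus, K=1, n_iterations=2, seed=0)
        assert np.allclose(embed_encounters(model, corpus).to_numpy(), 1.0)

    def test_closed_form_from_final_counts(self):
        corpus = corpus_of([["a"] * 6 + ["b"] * 4])
        model = fit_lda(corpus, K=2, alpha=0.1, n_iterations=40, seed=1)
        n0, n1 = model.n_dk[0]
        expect = np.array([(n0 + 0.1) / 10.2, (n1 + 0.1) / 10.2])
        assert np.allclose(embed_encounters(model, corpus).to_numpy()[0], expect)

    def test_mismatched_corpus_rejected(self, planted_corpus):
        _, corpus, _ = planted_corpus
        model = fit_lda(corpus, K=2, n_iterations=5, seed=0)
        other = corpus_of([["a", "b"]])
        with pytest.raises(ValueError):
            embed_encounters(model, other)


class TestTopWords:
    def make_model(self, phi_row, words):
        corpus = corpus_of([words])
        model = fit_lda(corpus, K=1, n_iterations=2, seed=0)
        model.phi = np.array([phi_row], dtype=float)
        model.vocabulary = words
        return model

    def test_sorted_by_probability(self):
        model = self.make_model([0.3, 0.2, 0.5], ["a", "b", "c"])
        assert top_words(model, 0, m=2) == [("c", 0.5), ("a", 0.3)]

    def test_m_larger_than_vocab_returns_all(self):
        model = self.make_model([0.6, 0.4], ["a", "b"])
        assert len(top_words(model, 0, m=99)) == 2

    def test_ties_lexicographic(self):
        model = self.make_model([0.25, 0.25, 0.5], ["b", "a", "c"])
        assert [w for w, _ in top_words(model, 0, m=3)] == ["c", "a", "b"]

    def test_invalid_args(self):
        model = self.make_model([1.0], ["a"])
        with pytest.raises(ValueError):
            top_words(model, 0, m=0)
        with pytest.raises(IndexError):
            top_words(model, 5)
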