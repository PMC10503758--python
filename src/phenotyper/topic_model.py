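"""LDA topic modeling of encounter term-frequency corpora.

Inference is collapsed Gibbs sampling (single chain). By default the
topic-word matrix phi and document-topic matrix theta are the posterior means
computed from the final sweep's assignment counts,

    phi[k, w]  = (n_kw + beta) / (n_k + V*beta)
    theta[d, k] = (n_dk + alpha) / (len_d + K*alpha),

which is deterministic given the seed; averaging over post-burn-in sweeps is
available via ``average_samples=True``. Hyperparameter defaults follow common
LDA practice: symmetric alpha = 50/K, beta = 0.01.

Topic quality is scored with UMass coherence — for a topic's top-m words
ranked by phi, sum over ordered pairs (w_i, w_j), i < j, of
log[(D(w_i, w_j) + 1) / D(w_j)] where D counts document (co-)occurrence.
The topic count is chosen where mean coherence plateaus: the smallest K on
the grid whose coherence is within ``plateau_epsilon`` of the grid maximum,
measured as a fraction of the coherence range over the grid.

Each encounter's embedding is its theta row — a point on the (K-1)-simplex
giving the share of each topic within that encounter's notes; rows sum to 1,
and empty documents fall back to the uniform prior 1/K.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gibbs import init_assignments, run_gibbs
from .corpus_builder import Corpus

__all__ = [
    "TopicModel",
    "CoherenceProfile",
    "fit_lda",
    "coherence",
    "select_topic_count",
    "embed_encounters",
    "top_words",
    "matched_mean_tv",
]


@dataclass
class TopicModel:
    """A fitted LDA model: phi (K x V), theta (D x K), and sampler state."""

    K: int
    alpha: float
    beta: float
    phi: np.ndarray
    theta: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    vocabulary: list[str]
    encounter_ids: list[str]
    n_iterations: int
    seed: int

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = {
            "K": self.K,
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "vocabulary": self.vocabulary,
            "encounter_ids": self.encounter_ids,
        }
        (outdir / "model.json").write_text(json.dumps(header))
        np.savez(
            outdir / "arrays.npz",
            phi=self.phi, theta=self.theta,
            n_dk=self.n_dk, n_kw=self.n_kw, n_k=self.n_k,
        )

    @classmethod
    def load(cls, indir: str | Path) -> "TopicModel":
        indir = Path(indir)
        header = json.loads((indir / "model.json").read_text())
        arrays = np.load(indir / "arrays.npz")
        return cls(
            K=header["K"], alpha=header["alpha"], beta=header["beta"],
            phi=arrays["phi"], theta=arrays["theta"],
            n_dk=arrays["n_dk"], n_kw=arrays["n_kw"], n_k=arrays["n_k"],
            vocabulary=header["vocabulary"], encounter_ids=header["encounter_ids"],
            n_iterations=header["n_iterations"], seed=header["seed"],
        )


@dataclass
class CoherenceProfile:
    """Mean UMass coherence across a grid of topic counts, and the chosen K."""

    k_grid: list[int]
    mean_coherence: list[float]
    per_topic: dict[int, list[float]]
    chosen_k: int
    plateau_epsilon: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.k_grid, "mean_coherence": self.mean_coherence,
             "chosen": [k == self.chosen_k for k in self.k_grid]}
        )


def _flatten(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    """Expand the sparse count matrix into flat token streams (doc_id, word_id)."""
    coo = sp.coo_matrix(corpus.counts)
    reps = coo.data.astype(np.int64)
    doc_ids = np.repeat(coo.row.astype(np.int64), reps)
    word_ids = np.repeat(coo.col.astype(np.int64), reps)
    order = np.lexsort((word_ids, doc_ids))
    return doc_ids[order], word_ids[order]


def fit_lda(
    corpus: Corpus,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    average_samples: bool = False,
) -> TopicModel:
    """Fit LDA with K topics by collapsed Gibbs sampling.

    ``alpha`` defaults to 50/K (symmetric). A fixed seed reproduces the
    fitted model exactly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if corpus.n_docs == 0 or corpus.total_tokens() == 0:
        raise ValueError("corpus is empty")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    n_distinct = int((np.asarray(corpus.counts.sum(axis=0)).ravel() > 0).sum())
    if K > n_distinct:
        warnings.warn(f"K={K} exceeds the {n_distinct} distinct tokens in the corpus",
                      stacklevel=2)

    D, V = corpus.n_docs, corpus.n_terms
    doc_ids, word_ids = _flatten(corpus)
    # seed arithmetic kept in int32 range
    z, n_dk, n_kw, n_k = init_assignments(doc_ids, word_ids, K, D, V, seed % (2**31 - 1))
    theta_sum = np.zeros((D, K))
    phi_sum = np.zeros((K, V))
    n_samples = run_gibbs(
        doc_ids, word_ids, z, n_dk, n_kw, n_k,
        float(alpha), float(beta), int(n_iterations),
        (seed + 1) % (2**31 - 1),
        theta_sum, phi_sum, int(burn_in), average_samples,
    )
    if average_samples and n_samples > 0:
        phi = phi_sum / n_samples
        theta = theta_sum / n_samples
    else:
        phi = (n_kw + beta) / (n_k[:, None] + V * beta)
        doc_len = n_dk.sum(axis=1)
        theta = (n_dk + alpha) / (doc_len[:, None] + K * alpha)
    return TopicModel(
        K=K, alpha=float(alpha), beta=float(beta), phi=phi, theta=theta,
        n_dk=n_dk, n_kw=n_kw, n_k=n_k,
        vocabulary=list(corpus.vocabulary), encounter_ids=list(corpus.encounter_ids),
        n_iterations=n_iterations, seed=seed,
    )


def top_words(model: TopicModel, topic: int, m: int = 30) -> list[tuple[str, float]]:
    """Top-m (word, probability) pairs for one topic, phi-descending,
    ties broken lexicographically."""
    if not 0 <= topic < model.K:
        raise IndexError(f"topic {topic} out of range [0, {model.K})")
    if m <= 0:
        raise ValueError("m must be positive")
    row = model.phi[topic]
    ranked = sorted(zip(model.vocabulary, row), key=lambda wp: (-wp[1], wp[0]))
    return [(w, float(p)) for w, p in ranked[:m]]


def coherence(
    model: TopicModel, corpus: Corpus, top_m: int = 10
) -> tuple[list[float], float]:
    """UMass coherence per topic and its mean over topics."""
    if top_m > corpus.n_terms:
        warnings.warn(f"top_m={top_m} exceeds vocabulary size; clamped", stacklevel=2)
        top_m = corpus.n_terms
    presence = sp.csc_matrix((corpus.counts > 0).astype(np.int64))
    doc_freq = np.asarray(presence.sum(axis=0)).ravel()
    vocab_index = {w: j for j, w in enumerate(corpus.vocabulary)}
    per_topic = []
    for k in range(model.K):
        words = [vocab_index[w] for w, _ in top_words(model, k, top_m)]
        score = 0.0
        for i in range(len(words)):
            for j in range(i + 1, len(words)):
                wi, wj = words[i], words[j]
                if doc_freq[wj] == 0:
                    continue
                co = int(presence[:, wi].multiply(presence[:, wj]).sum())
                score += np.log((co + 1) / doc_freq[wj])
        per_topic.append(float(score))
    return per_topic, float(np.mean(per_topic))


def select_topic_count(
    corpus: Corpus,
    k_grid: Sequence[int],
    plateau_epsilon: float = 0.05,
    seed: int = 0,
    **fit_kwargs,
) -> CoherenceProfile:
    """Choose the topic count at the coherence plateau.

    Each K on the (ascending) grid is fitted with the same seed and sampler
    settings; the chosen K is the smallest whose mean coherence is at least
    max − plateau_epsilon * (max − min) over the grid.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    if len(k_grid) == 1:
        warnings.warn("grid of size 1: that K is chosen by default", stacklevel=2)
    means, per_topic = [], {}
    for K in k_grid:
        model = fit_lda(corpus, K, seed=seed, **fit_kwargs)
        topic_scores, mean_score = coherence(model, corpus)
        means.append(mean_score)
        per_topic[K] = topic_scores
    best = max(means)
    cutoff = best - plateau_epsilon * (best - min(means))
    chosen = next(k for k, c in zip(k_grid, means) if c >= cutoff)
    return CoherenceProfile(
        k_grid=k_grid, mean_coherence=means, per_topic=per_topic,
        chosen_k=chosen, plateau_epsilon=plateau_epsilon,
    )


def matched_mean_tv(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """Mean total-variation distance between two topic-word matrices after
    optimal one-to-one topic matching (Hungarian assignment).

    Used to score planted-topic recovery: fitted topics are identifiable only
    up to label permutation, so distances are taken under the best matching.
    """
    from scipy.optimize import linear_sum_assignment

    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError("topic matrices must have identical shapes")
    cost = 0.5 * np.abs(phi_a[:, None, :] - phi_b[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def embed_encounters(model: TopicModel, corpus: Corpus) -> pd.DataFrame:
    """Per-encounter topic-proportion embeddings (rows of theta).

    Returns a DataFrame indexed by encounter_id with columns topic_0..topic_{K-1};
    every row sums to 1, empty documents sit at the uniform prior.
    """
    if model.theta.shape[0] != corpus.n_docs or model.encounter_ids != list(
        corpus.encounter_ids
    ):
        raise ValueError("model was not fitted on this corpus")
    cols = [f"topic_{k}" for k in range(model.K)]
    return pd.DataFrame(model.theta, index=pd.Index(corpus.encounter_ids, name="encounter_id"),
                        columns=cols)
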