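"""Cohort-contrastive corpus construction.

Merges per-note concept tokens with structured-data tokens (diagnosis-group
names, medication-class names, and lab names carrying "high"/"low" modifiers
at two background standard deviations), then applies the two-cohort
vocabulary filters:

1. a ubiquity filter — drop tokens whose document frequency exceeds a
   threshold (default 5%) in BOTH the opioid and the background cohort, which
   removes template boilerplate and care-process jargon; and
2. a chi-square keep-word test — among survivors, keep tokens whose
   document-level presence differs between cohorts (Pearson chi-square on the
   2x2 cohort x presence table, no continuity correction, p < alpha).

The result is a per-encounter term-frequency corpus over the kept vocabulary,
the input to topic modeling. Term frequencies count repeated mentions; the
cohort statistics use document-level presence only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.stats import chi2_contingency

__all__ = [
    "LabReference",
    "EncounterBag",
    "VocabularyDecision",
    "Corpus",
    "compute_lab_reference",
    "structured_tokens",
    "combine_encounter_tokens",
    "frequency_filter",
    "chisq_keep_words",
    "build_corpus",
    "decisions_to_frame",
]


@dataclass
class LabReference:
    """Background-cohort lab statistics: name -> (mean, sample SD, n)."""

    stats: dict[str, tuple[float, float, int]]

    def __contains__(self, name: str) -> bool:
        return name in self.stats

    def mean(self, name: str) -> float:
        return self.stats[name][0]

    def sd(self, name: str) -> float:
        return self.stats[name][1]


@dataclass
class EncounterBag:
    """Term-frequency multiset for one encounter."""

    encounter_id: str
    counts: Counter
    cohort: str = "opioid"  # "opioid" | "background"

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class VocabularyDecision:
    """Audit record for one token's path through the vocabulary filters."""

    token: str
    df_opioid: int
    df_background: int
    removed_by_frequency: bool
    chi2: float
    p_value: float
    keep: bool


def compute_lab_reference(background_labs: pd.DataFrame) -> LabReference:
    """Per-lab sample mean and SD (ddof=1) over the background cohort.

    A lab observed once gets SD 0 (with a warning); it can then never earn a
    high/low modifier. Expects columns ``lab_name`` and ``value``.
    """
    if background_labs.empty:
        raise ValueError("background lab table is empty; cannot build lab reference")
    stats: dict[str, tuple[float, float, int]] = {}
    for name, grp in background_labs.groupby("lab_name"):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"lab {name!r} has a single observation; SD set to 0", stacklevel=2)
            stats[str(name)] = (float(vals[0]), 0.0, 1)
        else:
            stats[str(name)] = (float(vals.mean()), float(vals.std(ddof=1)), len(vals))
    return LabReference(stats)


def structured_tokens(
    diagnosis_groups: Iterable[str],
    medication_classes: Iterable[str],
    labs: Iterable[tuple[str, float]],
    lab_reference: LabReference,
) -> list[str]:
    """Tokens contributed by one encounter's structured data.

    Each diagnosis-group and medication-class name is one token. Each lab
    contributes its plain name token, plus a single combined "high <name>" /
    "low <name>" token when the value lies strictly beyond two background
    standard deviations from the background mean.
    """
    tokens = list(diagnosis_groups) + list(medication_classes)
    for name, value in labs:
        if name not in lab_reference:
            raise KeyError(f"lab {name!r} missing from lab reference")
        mean, sd, _n = lab_reference.stats[name]
        tokens.append(name)
        if sd == 0:
            warnings.warn(f"lab {name!r} has zero reference SD; no modifier emitted", stacklevel=2)
            continue
        if value > mean + 2 * sd:
            tokens.append(f"high {name}")
        elif value < mean - 2 * sd:
            tokens.append(f"low {name}")
    return tokens


def combine_encounter_tokens(
    note_token_lists: Sequence[Iterable[str]],
    structured: Iterable[str] = (),
    encounter_id: str = "",
    cohort: str = "opioid",
) -> EncounterBag:
    """Multiset union of all notes' concept tokens plus structured tokens."""
    counts: Counter = Counter()
    for toks in note_token_lists:
        counts.update(toks)
    counts.update(structured)
    return EncounterBag(encounter_id=encounter_id, counts=counts, cohort=cohort)


def _doc_frequencies(bags: Sequence[EncounterBag]) -> Counter:
    df: Counter = Counter()
    for bag in bags:
        df.update(set(bag.counts))
    return df


def frequency_filter(
    opioid_bags: Sequence[EncounterBag],
    background_bags: Sequence[EncounterBag],
    threshold: float = 0.05,
) -> set[str]:
    """Tokens whose document frequency exceeds ``threshold`` in BOTH cohorts.

    Returns the removed set. Strict ">" at the boundary: a token in exactly
    threshold fraction of documents survives.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not opioid_bags or not background_bags:
        raise ValueError("both corpora must be non-empty")
    df_op = _doc_frequencies(opioid_bags)
    df_bg = _doc_frequencies(background_bags)
    n_op, n_bg = len(opioid_bags), len(background_bags)
    removed = set()
    for token in set(df_op) | set(df_bg):
        if df_op[token] / n_op > threshold and df_bg[token] / n_bg > threshold:
            removed.add(token)
    return removed


def chisq_keep_words(
    opioid_bags: Sequence[EncounterBag],
    background_bags: Sequence[EncounterBag],
    removed: set[str],
    alpha: float = 0.05,
) -> list[VocabularyDecision]:
    """Chi-square keep-word test on every token surviving the frequency filter.

    Builds a 2x2 cohort-by-presence contingency table per token and applies
    Pearson's chi-square (1 df, no Yates correction). Tokens with p < alpha
    are kept. Decisions for all surviving tokens (kept and not) are returned
    for audit; degenerate tables (token in no or in all documents of both
    cohorts) are skipped with a warning.
    """
    df_op = _doc_frequencies(opioid_bags)
    df_bg = _doc_frequencies(background_bags)
    n_op, n_bg = len(opioid_bags), len(background_bags)
    decisions = []
    for token in sorted(set(df_op) | set(df_bg)):
        if token in removed:
            decisions.append(
                VocabularyDecision(token, df_op[token], df_bg[token], True, np.nan, np.nan, False)
            )
            continue
        a, c = df_op[token], df_bg[token]
        table = np.array([[a, n_op - a], [c, n_bg - c]], dtype=float)
        if table.sum(axis=0).min() == 0:  # present nowhere, or everywhere, in both
            warnings.warn(f"token {token!r}: degenerate contingency table; skipped", stacklevel=2)
            continue
        stat, p, _dof, _exp = chi2_contingency(table, correction=False)
        decisions.append(
            VocabularyDecision(token, a, c, False, float(stat), float(p), bool(p < alpha))
        )
    return decisions


def decisions_to_frame(decisions: Sequence[VocabularyDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in decisions])


@dataclass
class Corpus:
    """Encounter-by-token term-frequency matrix over the kept vocabulary.

    ``vocabulary`` is sorted lexicographically; ``empty`` flags encounters
    whose bag contained no keep words (retained so every encounter still gets
    a topic embedding — it falls back to the uniform prior).
    """

    counts: sp.csr_matrix
    vocabulary: list[str]
    encounter_ids: list[str]
    empty: np.ndarray = field(default=None)  # bool per encounter

    def __post_init__(self):
        if self.empty is None:
            self.empty = np.asarray(self.counts.sum(axis=1)).ravel() == 0

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "corpus.mtx"), sp.coo_matrix(self.counts))
        (outdir / "vocabulary.txt").write_text("\n".join(self.vocabulary) + "\n")
        (outdir / "encounters.txt").write_text("\n".join(self.encounter_ids) + "\n")

    @classmethod
    def load(cls, indir: str | Path) -> "Corpus":
        indir = Path(indir)
        counts = sp.csr_matrix(mmread(str(indir / "corpus.mtx")))
        vocab = (indir / "vocabulary.txt").read_text().splitlines()
        encs = (indir / "encounters.txt").read_text().splitlines()
        return cls(counts=counts, vocabulary=vocab, encounter_ids=encs)


def build_corpus(
    opioid_bags: Sequence[EncounterBag],
    keep: Iterable[str] | Mapping[str, object],
) -> Corpus:
    """Restrict each opioid-cohort bag to the keep words.

    Every encounter keeps a row even when nothing survives (flagged empty);
    the vocabulary index is sorted for reproducibility.
    """
    vocab = sorted(set(keep))
    if not vocab:
        raise ValueError("keep set is empty; no corpus can be built")
    index = {tok: j for j, tok in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for i, bag in enumerate(opioid_bags):
        for tok, cnt in bag.counts.items():
            j = index.get(tok)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(cnt)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(opioid_bags), len(vocab)), dtype=np.int64
    )
    return Corpus(
        counts=counts,
        vocabulary=vocab,
        encounter_ids=[b.encounter_id for b in opioid_bags],
    )
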