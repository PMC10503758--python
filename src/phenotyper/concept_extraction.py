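"""Dictionary-based clinical concept extraction.

Maps free-text note spans to concept identifiers (CUIs) using a packaged
lexicon of surface forms, then filters mentions by UMLS-style semantic type.
The matcher is a deterministic, token-boundary, greedy longest-match scanner:
it is intentionally simple so that pipelines are reproducible end-to-end and
so that output from a full NLP annotator (e.g. MedCAT) can be substituted via
the same mentions file format at the pipeline boundary.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Lexicon",
    "ConceptMention",
    "LexiconError",
    "normalize",
    "load_lexicon",
    "extract_concepts",
    "filter_by_semantic_type",
    "read_mentions_jsonl",
    "write_mentions_jsonl",
    "default_lexicon_path",
    "default_allowlist_path",
    "load_allowlist",
]

_DATA_DIR = Path(__file__).parent / "data"

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"\w+")


class LexiconError(ValueError):
    """Raised for malformed or internally inconsistent lexicon files."""


def normalize(text: str) -> str:
    """Lowercase, strip punctuation to spaces, collapse whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", text.lower())).strip()


@dataclass(frozen=True)
class ConceptMention:
    """One concept hit in a note.

    Spans are 0-based half-open character offsets into the original text;
    the text at the span normalizes to the matched surface form.
    """

    encounter_id: str
    note_index: int
    concept_id: str
    surface: str
    start: int
    end: int
    semantic_type: str


@dataclass
class Lexicon:
    """Surface-form dictionary: normalized form -> (cui, name, semantic type)."""

    entries: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def semantic_types(self) -> set[str]:
        return {styp for _, _, styp in self.entries.values()}

    @property
    def max_tokens(self) -> int:
        """Longest entry, in tokens — bounds the matcher's window."""
        if not self.entries:
            return 0
        return max(len(form.split()) for form in self.entries)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a CSV lexicon (surface_form, concept_id, name, semantic_type).

    Surface forms are normalized on load; two rows that collide after
    normalization are an error (the lexicon must be unambiguous).
    """
    path = Path(path)
    entries: dict[str, tuple[str, str, str]] = {}
    raw_form: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"surface_form", "concept_id", "name", "semantic_type"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LexiconError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            form = normalize(row["surface_form"])
            if not form:
                raise LexiconError(f"{path}: empty surface form in row {row}")
            styp = row["semantic_type"].strip()
            if not styp:
                raise LexiconError(f"{path}: missing semantic_type for {row['surface_form']!r}")
            if form in entries:
                raise LexiconError(
                    f"{path}: duplicate surface form after normalization: "
                    f"{row['surface_form']!r} collides with {raw_form[form]!r} ({form!r})"
                )
            entries[form] = (row["concept_id"].strip(), row["name"].strip(), styp)
            raw_form[form] = row["surface_form"]
    if not entries:
        raise LexiconError(f"{path}: lexicon is empty")
    return Lexicon(entries)


def default_lexicon_path() -> Path:
    return _DATA_DIR / "demo_lexicon.csv"


def default_allowlist_path() -> Path:
    return _DATA_DIR / "semantic_types.yaml"


def load_allowlist(path: str | Path | None = None) -> set[str]:
    """Load the semantic-type allow-list (YAML list under key ``semantic_types``)."""
    import yaml

    path = Path(path) if path is not None else default_allowlist_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("semantic_types", [])
    return set(doc or [])


def extract_concepts(
    text: str,
    lexicon: Lexicon,
    encounter_id: str = "",
    note_index: int = 0,
) -> list[ConceptMention]:
    """Greedy longest-match, left-to-right, non-overlapping concept matching.

    Matching is at token boundaries: "tension" never fires inside
    "hypertension". Returned mentions are ordered by span start and never
    overlap. Deterministic and idempotent.
    """
    if not text:
        return []
    tokens = [(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    window = lexicon.max_tokens
    mentions: list[ConceptMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(window, n - i), 0, -1):
            form = " ".join(tok for tok, _, _ in tokens[i : i + length])
            entry = lexicon.entries.get(form)
            if entry is not None:
                hit = (length, form, entry)
                break
        if hit is None:
            i += 1
            continue
        length, form, (cui, _name, styp) = hit
        mentions.append(
            ConceptMention(
                encounter_id=encounter_id,
                note_index=note_index,
                concept_id=cui,
                surface=form,
                start=tokens[i][1],
                end=tokens[i + length - 1][2],
                semantic_type=styp,
            )
        )
        i += length
    return mentions


def filter_by_semantic_type(
    mentions: list[ConceptMention], allowlist: set[str]
) -> list[ConceptMention]:
    """Keep only mentions whose semantic type is in the allow-list (order kept)."""
    if not allowlist:
        warnings.warn("empty semantic-type allow-list: all mentions removed", stacklevel=2)
        return []
    return [m for m in mentions if m.semantic_type in allowlist]


def write_mentions_jsonl(mentions: list[ConceptMention], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mentions:
            fh.write(json.dumps(m.__dict__, sort_keys=True) + "\n")


def read_mentions_jsonl(path: str | Path) -> list[ConceptMention]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(ConceptMention(**json.loads(line)))
    return out
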