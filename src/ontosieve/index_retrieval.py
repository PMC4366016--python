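"""Positional concept-token vector space and exact-boundary annotation.

Each lexical representation (original or generated variant) becomes a row
mapping its tokens to the positional value ``L - i + 1`` (1-based index
``i``, length ``L``); repeated tokens accumulate by summation, so the row's
value sum is ``L(L+1)/2``.  A query matches a row exactly when it contains
no out-of-vocabulary tokens, has the row's token count and reaches the row's
positional sum — i.e. when the retrieval score equals 1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .lexicon_io import TokenSequence, normalize
from .variant_generation import VariantSet

__all__ = [
    "positional_encoding",
    "IndexRow",
    "ConceptTokenIndex",
    "build_index",
    "score",
    "split_sentences",
    "generate_candidates",
    "Annotation",
    "annotate",
]


def positional_encoding(tokens: Sequence[str]) -> dict[str, int]:
    """Map each token to ``L - i + 1``; repeats accumulate by summation."""
    if not tokens:
        raise ValueError("tokens must be non-empty")
    L = len(tokens)
    values: dict[str, int] = {}
    for i, token in enumerate(tokens, start=1):
        values[token] = values.get(token, 0) + (L - i + 1)
    return values


def _value_lists(tokens: Sequence[str]) -> dict[str, tuple[int, ...]]:
    """Per-token positional values, one entry per occurrence, descending."""
    L = len(tokens)
    lists: dict[str, list[int]] = {}
    for i, token in enumerate(tokens, start=1):
        lists.setdefault(token, []).append(L - i + 1)
    return {t: tuple(sorted(v, reverse=True)) for t, v in lists.items()}


@dataclass(frozen=True)
class IndexRow:
    concept_id: str
    tokens: tuple[str, ...]
    values: dict[str, int]
    is_variant: bool = False

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def value_sum(self) -> int:
        # permutation sum L(L+1)/2, cached nowhere: rows are tiny
        return sum(self.values.values())


@dataclass
class ConceptTokenIndex:
    rows: list[IndexRow]
    inverted: dict[str, set[int]]
    case_sensitive: bool
    max_len: int
    metadata: dict = field(default_factory=dict)

    def postings(self, token: str) -> set[int]:
        return self.inverted.get(token, set())

    def to_json(self) -> str:
        payload = {
            "case_sensitive": self.case_sensitive,
            "max_len": self.max_len,
            "metadata": self.metadata,
            "rows": [
                {
                    "concept_id": r.concept_id,
                    "tokens": list(r.tokens),
                    "is_variant": r.is_variant,
                }
                for r in self.rows
            ],
        }
        return json.dumps(payload, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "ConceptTokenIndex":
        payload = json.loads(text)
        rows = [
            IndexRow(
                concept_id=r["concept_id"],
                tokens=tuple(r["tokens"]),
                values=positional_encoding(r["tokens"]),
                is_variant=r["is_variant"],
            )
            for r in payload["rows"]
        ]
        index = cls(
            rows=rows,
            inverted={},
            case_sensitive=payload["case_sensitive"],
            max_len=payload["max_len"],
            metadata=payload.get("metadata", {}),
        )
        index._rebuild_inverted()
        return index

    @classmethod
    def load(cls, path: str | Path) -> "ConceptTokenIndex":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def _rebuild_inverted(self) -> None:
        self.inverted = {}
        for row_id, row in enumerate(self.rows):
            for token in row.values:
                self.inverted.setdefault(token, set()).add(row_id)


def build_index(
    profiles: Iterable,
    variants: VariantSet | None = None,
    case_sensitive: bool = False,
    metadata: dict | None = None,
) -> ConceptTokenIndex:
    """Assemble the vector space from entity profiles plus optional variants.

    One row per distinct (concept, token sequence); identical sequences under
    different concepts each keep their row — ambiguity surfaces at
    annotation time as multiple matches.
    """
    rows: list[IndexRow] = []
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for profile in profiles:
        for rep in profile.representations:
            key = (profile.concept_id, tuple(rep.tokens))
            if key in seen or not rep.tokens:
                continue
            seen.add(key)
            rows.append(
                IndexRow(profile.concept_id, tuple(rep.tokens),
                         positional_encoding(rep.tokens))
            )
    if variants is not None:
        for record in variants:
            key = (record.concept_id, record.variant_tokens)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                IndexRow(record.concept_id, record.variant_tokens,
                         positional_encoding(record.variant_tokens),
                         is_variant=True)
            )
    index = ConceptTokenIndex(
        rows=rows,
        inverted={},
        case_sensitive=case_sensitive,
        max_len=max((r.length for r in rows), default=0),
        metadata=metadata or {},
    )
    index._rebuild_inverted()
    return index


def score(query_tokens: Sequence[str], row: IndexRow) -> Fraction:
    """Retrieval score ``((Q_N - Q_NF)/Q_N) * (sum C_qi / sum C_ti)``.

    ``Q_NF`` counts query tokens absent from the row; ``C_qi`` is the row's
    positional value of the i-th query token (0 when absent).  The j-th
    occurrence of a repeated query token consumes the row's j-th positional
    value of that token, so the numerator can never exceed the denominator
    and ``score == 1`` (plus the token-count guard) is equivalent to
    multiset equality.  Computed as an exact rational: no epsilon needed.
    """
    if not query_tokens:
        raise ValueError("query must be non-empty")
    q_n = len(query_tokens)
    lists = _value_lists(row.tokens)
    q_nf = sum(1 for t in query_tokens if t not in lists)
    seen: dict[str, int] = {}
    num = 0
    for t in query_tokens:
        j = seen.get(t, 0)
        seen[t] = j + 1
        occurrences = lists.get(t, ())
        if j < len(occurrences):
            num += occurrences[j]
    return Fraction(q_n - q_nf, q_n) * Fraction(num, row.value_sum)


def exact_match(query_tokens: Sequence[str], row: IndexRow) -> bool:
    """Score-1 test with the token-count guard.

    With summed positional values, ``score == 1`` alone would let distinct
    multisets of equal positional sum collide; requiring ``Q_N == C_N`` as
    well makes score 1 equivalent to multiset equality of query and row.
    """
    return (
        len(query_tokens) == row.length
        and score(query_tokens, row) == 1
    )


# ---------------------------------------------------------------------------
# Candidate generation

_ABBREVIATIONS = (
    "e.g.", "i.e.", "cf.", "et al.", "etc.", "fig.", "figs.", "dr.", "vs.",
    "approx.", "no.", "al.",
)
_SENT_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")
_RAW_TOKEN_RE = re.compile(r"\S+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans (0-based half-open): terminal punctuation
    followed by whitespace or end of text, skipping a fixed abbreviation
    list."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end()
        tail = text[start:end].lower()
        if any(tail.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def generate_candidates(
    text: str,
    max_len: int,
    case_sensitive: bool = False,
    sentence_splitter: Callable[[str], list[tuple[int, int]]] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> list[tuple[tuple[int, int], TokenSequence]]:
    """All sentence-bounded raw-token windows of 1..max_len tokens, each
    normalized under the index's case mode.

    The reported span covers only the tokens surviving normalization, so
    stripped determiners or punctuation at window edges never widen the
    boundary.  Windows that normalize to nothing are skipped.
    """
    splitter = sentence_splitter or split_sentences
    candidates: list[tuple[tuple[int, int], TokenSequence]] = []
    for s_start, s_end in splitter(text):
        sentence = text[s_start:s_end]
        raw = [(m.start(), m.end()) for m in _RAW_TOKEN_RE.finditer(sentence)]
        for i in range(len(raw)):
            for j in range(i, min(i + max_len, len(raw))):
                w_start, w_end = raw[i][0], raw[j][1]
                seq = normalize(
                    sentence[w_start:w_end], case_sensitive, lemmatizer
                )
                if seq.is_empty or len(seq) > max_len:
                    continue
                span = (
                    s_start + w_start + seq.char_spans[0][0],
                    s_start + w_start + seq.char_spans[-1][1],
                )
                candidates.append((span, seq))
    return candidates


# ---------------------------------------------------------------------------
# Annotation

@dataclass(frozen=True, order=True)
class Annotation:
    """An exact-boundary concept mention: 0-based half-open char span."""

    doc_id: str
    start: int
    end: int
    concept_id: str
    score: float = 1.0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.doc_id, self.start, self.end, self.concept_id)


def annotate(
    doc_id: str,
    text: str,
    index: ConceptTokenIndex,
    sentence_splitter: Callable[[str], list[tuple[int, int]]] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> list[Annotation]:
    """Find every exact match of an indexed representation in the document.

    All overlapping and nested matches are reported; a span matching one
    concept through both its label and a variant yields a single annotation.
    """
    if index.max_len == 0:
        return []
    found: set[tuple[str, int, int, str]] = set()
    for span, seq in generate_candidates(
        text, index.max_len, index.case_sensitive, sentence_splitter, lemmatizer
    ):
        row_ids: set[int] | None = None
        for token in set(seq.tokens):
            postings = index.postings(token)
            row_ids = postings if row_ids is None else row_ids & postings
            if not row_ids:
                break
        if not row_ids:
            continue
        for row_id in row_ids:
            row = index.rows[row_id]
            if exact_match(seq.tokens, row):
                found.add((doc_id, span[0], span[1], row.concept_id))
    return sorted(Annotation(*key) for key in found)
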