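"""Ontology lexicon parsing, text normalization and entity-profile construction.

An *entity profile* aggregates every lexical representation (preferred label,
alternative labels, synonyms of any scope) of a single ontology concept, each
normalized into a token sequence.  Profile-level and corpus-level token
statistics (``tf``, ``TF``, ``df``, ``dl``, ``sl``) feed the downstream
information-gain and mutual-information machinery.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .case_sensitivity import is_case_sensitive_token

__all__ = [
    "RawConcept",
    "TokenSequence",
    "EntityProfile",
    "CorpusStats",
    "LexiconError",
    "OboParseError",
    "parse_obo",
    "parse_json_lexicon",
    "load_stoplist",
    "default_lemmatizer",
    "normalize",
    "build_profiles",
]


class LexiconError(ValueError):
    """Raised for empty or structurally invalid lexicons."""


class OboParseError(LexiconError):
    """Raised for malformed OBO stanzas; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class RawConcept:
    """A concept as read from the lexicon, before normalization."""

    concept_id: str
    labels: tuple[str, ...]
    synonyms: tuple[str, ...] = ()

    @property
    def representations(self) -> tuple[str, ...]:
        return self.labels + self.synonyms


@dataclass(frozen=True)
class TokenSequence:
    """Normalized tokens with character spans into the source text.

    Spans are 0-based half-open intervals on ``source_text``.
    """

    tokens: tuple[str, ...]
    source_text: str
    char_spans: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.tokens) != len(self.char_spans):
            raise ValueError("tokens and char_spans must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def is_empty(self) -> bool:
        return not self.tokens


@dataclass
class EntityProfile:
    """All lexical representations of one concept plus its mean length ``dl``."""

    concept_id: str
    representations: list[TokenSequence]
    raw_texts: list[str] = field(default_factory=list)

    @property
    def dl(self) -> float:
        return sum(len(r) for r in self.representations) / len(self.representations)

    def token_counts(self) -> Counter:
        """Token frequency ``tf`` summed over all representations."""
        c: Counter = Counter()
        for rep in self.representations:
            c.update(rep.tokens)
        return c


@dataclass
class CorpusStats:
    """Collection-level token statistics over a set of entity profiles."""

    N: int
    TF: Counter
    df: Counter
    sl: float

    @property
    def p(self) -> float:
        return 1.0 / self.N

    @property
    def q(self) -> float:
        return 1.0 - 1.0 / self.N


# ---------------------------------------------------------------------------
# OBO / JSON parsing

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def parse_obo(path: str | Path) -> list[RawConcept]:
    """Parse an OBO 1.2/1.4 flat file into raw concepts.

    Only ``[Term]`` stanzas are read; obsolete terms are dropped.  The
    ``name`` goes to ``labels``; every ``synonym`` line, regardless of scope,
    goes to ``synonyms``.  File order is preserved.
    """
    path = Path(path)
    concepts: list[RawConcept] = []
    seen_ids: set[str] = set()

    in_term = False
    cur_id: str | None = None
    cur_name: str | None = None
    cur_syns: list[str] = []
    cur_alts: list[str] = []
    obsolete = False
    stanza_line = 0

    def flush(line_no: int):
        nonlocal in_term, cur_id, cur_name, cur_syns, cur_alts, obsolete
        if in_term and not obsolete:
            if cur_id is None:
                raise OboParseError("[Term] stanza missing id", stanza_line)
            if cur_id in seen_ids:
                raise OboParseError(f"duplicate concept id {cur_id!r}", line_no)
            seen_ids.add(cur_id)
            labels = tuple([cur_name] if cur_name else []) + tuple(cur_alts)
            concepts.append(
                RawConcept(concept_id=cur_id, labels=labels, synonyms=tuple(cur_syns))
            )
        in_term = False
        cur_id = None
        cur_name = None
        cur_syns = []
        cur_alts = []
        obsolete = False

    line_no = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("!"):
                continue
            if line.startswith("["):
                flush(line_no)
                if line == "[Term]":
                    in_term = True
                    stanza_line = line_no
                continue
            if not in_term or not line:
                continue
            if ":" not in line:
                raise OboParseError(f"malformed tag line {line!r}", line_no)
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.split(" !")[0].strip()
            if tag == "id":
                cur_id = value
            elif tag == "name":
                cur_name = value
            elif tag == "synonym":
                m = _SYNONYM_RE.match(value)
                if not m:
                    raise OboParseError(f"malformed synonym line {line!r}", line_no)
                cur_syns.append(_unescape(m.group("text")))
            elif tag == "is_obsolete" and value.lower() == "true":
                obsolete = True
        flush(line_no)

    if not concepts:
        raise LexiconError(f"no [Term] stanzas found in {path}")
    return concepts


def parse_json_lexicon(path: str | Path) -> list[RawConcept]:
    """Read a plain JSON lexicon.

    Accepts ``{id: {"labels": [...], "synonyms": [...]}}`` or the short form
    ``{id: [strings]}`` where all strings are treated as labels.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not data:
        raise LexiconError(f"empty JSON lexicon: {path}")
    concepts = []
    for cid, entry in data.items():
        if isinstance(entry, dict):
            labels = tuple(entry.get("labels", ()))
            synonyms = tuple(entry.get("synonyms", ()))
        else:
            labels, synonyms = tuple(entry), ()
        concepts.append(RawConcept(concept_id=cid, labels=labels, synonyms=synonyms))
    return concepts


def load_lexicon(path: str | Path) -> list[RawConcept]:
    """Dispatch on file extension: ``.json`` -> JSON lexicon, else OBO."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return parse_json_lexicon(path)
    return parse_obo(path)


# ---------------------------------------------------------------------------
# Normalization

_DEFAULT_STOPLIST: frozenset[str] | None = None


def load_stoplist(path: str | Path | None = None) -> frozenset[str]:
    """Load the stoplist (one token per line; '#' comments allowed).

    Without a path, the packaged determiner + preposition list is used.
    """
    global _DEFAULT_STOPLIST
    if path is None:
        if _DEFAULT_STOPLIST is None:
            text = (
                resources.files("ontosieve").joinpath("data/stoplist.txt").read_text("utf-8")
            )
            _DEFAULT_STOPLIST = frozenset(
                w.strip().lower()
                for w in text.splitlines()
                if w.strip() and not w.startswith("#")
            )
        return _DEFAULT_STOPLIST
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            w.strip().lower() for w in fh if w.strip() and not w.startswith("#")
        )


_IRREGULAR_PLURALS = {
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "children": "child",
    "nuclei": "nucleus",
    "fungi": "fungus",
    "bacteria": "bacterium",
    "mitochondria": "mitochondrion",
    "genera": "genus",
    "analyses": "analysis",
    "hypotheses": "hypothesis",
}

_NO_STRIP_S = ("ss", "us", "is")


def default_lemmatizer(token: str) -> str:
    """Rule-based English lemmatizer: plural stripping plus a small
    irregular table.  Operates on lowercase tokens; anything it does not
    recognize is returned unchanged."""
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith(("ches", "shes", "xes", "zes", "sses")):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith(_NO_STRIP_S):
        if token[-2].isalpha():
            return token[:-1]
    return token


_RAW_TOKEN_RE = re.compile(r"\S+")
_SEPARATOR_RE = re.compile(r"[-/,]")
_EDGE_STRIP = "\"'`.,;:!?()[]{}<>«»‘’“”"


def _strip_edges(token: str, start: int) -> tuple[str, int]:
    """Strip punctuation from both ends, returning (core, new_start)."""
    lead = len(token) - len(token.lstrip(_EDGE_STRIP))
    core = token.strip(_EDGE_STRIP)
    return core, start + lead


def normalize(
    text: str,
    case_sensitive_mode: bool = False,
    lemmatizer: Callable[[str], str] | None = None,
    stoplist: Iterable[str] | None = None,
) -> TokenSequence:
    """Normalize free text into a :class:`TokenSequence`.

    Whitespace-delimited raw tokens are shape-checked first; in case-sensitive
    mode a token matching a case-sensitive shape is kept verbatim (not split,
    lemmatized or lowercased).  Every other raw token is split on separator
    characters (hyphen, slash, comma), lowercased, lemmatized, and dropped if
    it is a stoplist word.  Char spans point back into ``text``.
    """
    if lemmatizer is None:
        lemmatizer = default_lemmatizer
    stop = frozenset(stoplist) if stoplist is not None else load_stoplist()

    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _RAW_TOKEN_RE.finditer(text):
        core, start = _strip_edges(m.group(), m.start())
        if not core:
            continue
        # shape check precedes separator splitting so e.g. "C3/C5" stays whole
        if case_sensitive_mode and is_case_sensitive_token(core):
            tokens.append(core)
            spans.append((start, start + len(core)))
            continue
        pos = 0
        for piece in _SEPARATOR_RE.split(core):
            p_start = start + core.index(piece, pos)
            pos = p_start - start + len(piece)
            piece_core, p_start = _strip_edges(piece, p_start)
            if not piece_core:
                continue
            lowered = piece_core.lower()
            if lowered in stop:
                continue
            lemma = lemmatizer(lowered)
            tokens.append(lemma)
            spans.append((p_start, p_start + len(piece_core)))
    return TokenSequence(tuple(tokens), text, tuple(spans))


# ---------------------------------------------------------------------------
# Profile construction

def build_profiles(
    concepts: Sequence[RawConcept],
    case_sensitive_mode: bool = False,
    lemmatizer: Callable[[str], str] | None = None,
    stoplist: Iterable[str] | None = None,
) -> tuple[list[EntityProfile], CorpusStats]:
    """Build one entity profile per concept plus collection statistics.

    ``dl`` is the mean token count of a concept's representations; ``sl``
    averages over all representations in the lexicon.  ``TF`` and ``df`` are
    tallied per profile (a profile's tf sums over its representations).
    Concepts whose every representation normalizes to zero tokens are
    excluded with a warning.
    """
    if not concepts:
        raise LexiconError("cannot build profiles from an empty concept list")

    profiles: list[EntityProfile] = []
    TF: Counter = Counter()
    df: Counter = Counter()
    total_len = 0
    total_reps = 0

    for concept in concepts:
        reps: list[TokenSequence] = []
        raws: list[str] = []
        for rep_text in concept.representations:
            seq = normalize(rep_text, case_sensitive_mode, lemmatizer, stoplist)
            if seq.is_empty:
                continue
            reps.append(seq)
            raws.append(rep_text)
        if not reps:
            warnings.warn(
                f"concept {concept.concept_id} has no non-empty representations; skipped",
                stacklevel=2,
            )
            continue
        profile = EntityProfile(concept.concept_id, reps, raws)
        counts = profile.token_counts()
        TF.update(counts)
        df.update(counts.keys())
        total_len += sum(len(r) for r in reps)
        total_reps += len(reps)
        profiles.append(profile)

    if not profiles:
        raise LexiconError("every concept normalized to zero tokens")
    stats = CorpusStats(N=len(profiles), TF=TF, df=df, sl=total_len / total_reps)
    return profiles, stats
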