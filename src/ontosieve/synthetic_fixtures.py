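"""Seeded synthetic ontologies and annotated corpora.

The generator plants the statistical structure the recognizer exploits: a
Zipf-like token distribution, a high-prevalence low-information-gain suffix
token, and a controllable fraction and placement of case-sensitive concepts.
Documents embed concept mentions verbatim (or deliberately mutated) between
filler sentences built from a word list disjoint from the ontology
vocabulary, so every false positive is attributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lexicon_io import RawConcept, default_lemmatizer

__all__ = ["FixtureSpec", "CorpusFixture", "make_ontology", "make_corpus", "write_obo"]

#: Filler vocabulary for documents; kept disjoint from the generated
#: pseudo-word ontology vocabulary (asserted at generation time).
FILLER_WORDS = (
    "meanwhile", "observed", "results", "were", "recorded", "carefully",
    "during", "several", "repeated", "measurements", "which", "appeared",
    "consistent", "overall", "findings", "suggested", "further", "analysis",
    "confirmed", "earlier", "reports", "broadly", "similar", "patterns",
)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudo_word(index: int) -> str:
    """Deterministic CV-syllable pseudo-word for a vocabulary rank."""
    syllables = []
    n = index
    for _ in range(3):
        c = _CONSONANTS[n % len(_CONSONANTS)]
        n //= len(_CONSONANTS)
        v = _VOWELS[n % len(_VOWELS)]
        n //= len(_VOWELS)
        syllables.append(c + v)
    return "".join(syllables)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic ontology + corpus."""

    n_concepts: int = 150
    vocab_size: int = 300
    zipf_exponent: float = 1.1
    cs_fraction: float = 0.0
    cs_placement: str = "uniform"  # or "clustered"
    suffix_token: str = "activityx"
    suffix_prevalence: float = 0.0
    synonyms_per_concept: int = 0
    docs: int = 5
    mentions_per_doc: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("cs_fraction", "suffix_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cs_placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown cs_placement {self.cs_placement!r}")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be positive")


def _vocabulary(spec: FixtureSpec) -> list[str]:
    vocab = [_pseudo_word(i) for i in range(spec.vocab_size)]
    if len(set(vocab)) < spec.vocab_size:
        raise ValueError(f"vocab_size {spec.vocab_size} exceeds distinct pseudo-words")
    lemmas = {default_lemmatizer(w) for w in vocab}
    forbidden = set(FILLER_WORDS) | {default_lemmatizer(w) for w in FILLER_WORDS}
    assert not lemmas & forbidden, "ontology vocabulary collides with filler words"
    assert spec.suffix_token not in forbidden
    return vocab


def _cs_indices(spec: FixtureSpec) -> set[int]:
    n_cs = round(spec.cs_fraction * spec.n_concepts)
    if n_cs == 0:
        return set()
    if spec.cs_placement == "clustered":
        return set(range(n_cs))
    # uniform: evenly spaced across the concept order
    return {int(i * spec.n_concepts / n_cs) for i in range(n_cs)}


def make_ontology(spec: FixtureSpec) -> list[RawConcept]:
    """Deterministically generate the concept list for a fixture spec.

    Labels draw 1-3 Zipf-weighted vocabulary tokens without replacement;
    the suffix token is appended to ``suffix_prevalence`` of labels (those
    keep 1-2 base tokens, others 2-3, so no plain single-token labels
    exist); case-sensitive concepts get a unique upper-case token prepended.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _vocabulary(spec)
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    weights = ranks ** -spec.zipf_exponent
    weights /= weights.sum()
    cs_set = _cs_indices(spec)

    def sample_tokens(k: int) -> tuple[str, ...]:
        idx = rng.choice(spec.vocab_size, size=k, replace=False, p=weights)
        return tuple(vocab[i] for i in idx)

    def make_representation(concept_idx: int, with_cs: bool) -> tuple[str, ...]:
        has_suffix = bool(rng.random() < spec.suffix_prevalence)
        base_len = int(rng.integers(1, 3)) if has_suffix else int(rng.integers(2, 4))
        tokens = sample_tokens(base_len)
        if has_suffix:
            tokens = tokens + (spec.suffix_token,)
        if with_cs:
            tokens = (f"ZQX{concept_idx}T",) + tokens
        return tokens

    def nests(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
        """True if a is a contiguous sub-run of b."""
        if len(a) > len(b):
            return False
        return any(b[i:i + len(a)] == a for i in range(len(b) - len(a) + 1))

    concepts: list[RawConcept] = []
    used_labels: list[tuple[str, ...]] = []

    def fresh(make) -> tuple[str, ...]:
        # reject labels nesting inside (or containing) existing ones so that
        # every verbatim-corpus match is attributable to exactly one concept
        for _attempt in range(500):
            tokens = make()
            if not any(nests(tokens, u) or nests(u, tokens) for u in used_labels):
                used_labels.append(tokens)
                return tokens
        raise ValueError("vocabulary too small for nesting-free labels")

    for i in range(spec.n_concepts):
        with_cs = i in cs_set
        tokens = fresh(lambda: make_representation(i, with_cs))
        synonyms = [
            " ".join(fresh(lambda: make_representation(i, with_cs=False)))
            for _ in range(spec.synonyms_per_concept)
        ]
        concepts.append(
            RawConcept(
                concept_id=f"SYN:{i + 1:07d}",
                labels=(" ".join(tokens),),
                synonyms=tuple(synonyms),
            )
        )
    return concepts


def write_obo(concepts: list[RawConcept], path: str | Path) -> None:
    """Serialize concepts as a minimal OBO 1.2 flat file."""
    lines = ["format-version: 1.2", ""]
    for concept in concepts:
        lines.append("[Term]")
        lines.append(f"id: {concept.concept_id}")
        if concept.labels:
            lines.append(f"name: {concept.labels[0]}")
        for label in concept.labels[1:]:
            lines.append(f'synonym: "{label}" EXACT []')
        for syn in concept.synonyms:
            lines.append(f'synonym: "{syn}" RELATED []')
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


@dataclass
class CorpusFixture:
    """Documents plus gold standoff rows (doc_id, start, end, concept_id)."""

    documents: dict[str, str] = field(default_factory=dict)
    gold: list[tuple[str, int, int, str]] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for doc_id, text in self.documents.items():
            (out_dir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        gold_path = out_dir / "gold.tsv"
        with open(gold_path, "w", encoding="utf-8") as fh:
            for row in self.gold:
                fh.write("\t".join(map(str, row)) + "\n")
        return gold_path


def _mention_surface(label: str, form: str, suffix_token: str) -> str | None:
    tokens = label.split()
    if form == "verbatim":
        return label
    if form == "short":
        if tokens[-1] != suffix_token or len(tokens) < 2:
            return None
        return " ".join(tokens[:-1])
    if form == "lowercase":
        if label == label.lower():
            return None
        return label.lower()
    raise ValueError(f"unknown mention form {form!r}")


def make_corpus(
    concepts: list[RawConcept],
    spec: FixtureSpec,
    form: str = "verbatim",
) -> CorpusFixture:
    """Embed concept mentions between filler sentences, recording exact spans.

    ``form`` selects the mention surface: ``verbatim`` (the label as
    defined), ``short`` (suffix token dropped; only suffix-bearing concepts
    are eligible) or ``lowercase`` (lower-cased labels of case-sensitive
    concepts — planted homograph false positives).  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    eligible: list[tuple[str, str]] = []
    for concept in concepts:
        surface = _mention_surface(concept.labels[0], form, spec.suffix_token)
        if surface is not None:
            eligible.append((concept.concept_id, surface))
    if not eligible:
        raise ValueError(f"no concepts eligible for mention form {form!r}")

    fixture = CorpusFixture()
    for d in range(spec.docs):
        doc_id = f"doc{d:03d}"
        parts: list[str] = []
        offset = 0
        for _ in range(spec.mentions_per_doc):
            pre = " ".join(rng.choice(FILLER_WORDS, size=3)).capitalize()
            post = " ".join(rng.choice(FILLER_WORDS, size=2))
            cid, surface = eligible[int(rng.integers(len(eligible)))]
            sentence_head = f"{pre} "
            start = offset + len(sentence_head)
            end = start + len(surface)
            sentence = f"{sentence_head}{surface} {post}. "
            parts.append(sentence)
            offset += len(sentence)
            fixture.gold.append((doc_id, start, end, cid))
        fixture.documents[doc_id] = "".join(parts).rstrip()
    return fixture
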