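"""Case-sensitivity detection: token shapes, concept flags and the
ontology-level CSS statistic with its classification threshold."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon_io import EntityProfile

__all__ = [
    "is_case_sensitive_token",
    "concept_is_case_sensitive",
    "compute_css",
    "CaseReport",
    "CSS_THRESHOLD",
]

#: Classification threshold: an ontology is case sensitive iff CSS > -1.
CSS_THRESHOLD = -1.0

_HAS_LOWER = re.compile(r"[a-z]")
_HAS_DIGIT_OR_SYMBOL = re.compile(r"[^a-zA-Z]")
_RAW_TOKEN_RE = re.compile(r"\S+")
_EDGE_STRIP = "\"'`.,;:!?()[]{}<>«»‘’“”"


def is_case_sensitive_token(token: str) -> bool:
    """True iff the token has a case-sensitive shape.

    The shapes are: (a) camel case — a lowercase letter plus an uppercase
    letter beyond the first position (``MetaMap``); (b) all upper case — at
    least two characters, at least two uppercase letters, no lowercase
    (``STAR``, ``FGFR3``); (c) capitalisation mixed with digits or symbols
    (``Tyr336``).  Ordinary initial capitalisation (``Protein``) matches
    none of them.
    """
    if not token:
        raise ValueError("token must be non-empty")
    n_upper = sum(1 for c in token if c.isupper() and c.isascii())
    has_lower = bool(_HAS_LOWER.search(token))
    # camel case
    if has_lower and any(c.isupper() for c in token[1:]):
        return True
    # all upper case
    if len(token) >= 2 and n_upper >= 2 and not has_lower:
        return True
    # capitalisation mixed with digits / symbols
    if n_upper >= 1 and _HAS_DIGIT_OR_SYMBOL.search(token):
        return True
    return False


def concept_is_case_sensitive(profile: "EntityProfile") -> bool:
    """True iff any raw token of any representation is case sensitive.

    The shape check runs on the unnormalized representation text, because
    normalization in case-insensitive mode destroys the evidence.
    """
    texts = profile.raw_texts or [r.source_text for r in profile.representations]
    for text in texts:
        for m in _RAW_TOKEN_RE.finditer(text):
            core = m.group().strip(_EDGE_STRIP)
            if core and is_case_sensitive_token(core):
                return True
    return False


@dataclass
class CaseReport:
    """Case-sensitivity census of an ontology."""

    n_c: int
    freq_cs: int
    gaps: list[int]
    delta_cs: float | None
    css: float | None
    is_case_sensitive: bool

    #: alias used by the windowed average: number of case-sensitive concepts
    @property
    def n_cs(self) -> int:
        return self.freq_cs


def compute_css(flags: Sequence[bool]) -> CaseReport:
    """Compute the ontology case-sensitivity status from per-concept flags.

    ``CSS = 1/2 * (exp(-delta) - delta/e + Freq_CS/N_C)`` where ``delta`` is
    the population standard deviation of the window gaps ``W_i`` (number of
    non-case-sensitive concepts between consecutive case-sensitive concepts,
    in the given order).  CSS peaks at 1 when every concept is case
    sensitive.  With fewer than two case-sensitive concepts the statistic is
    undefined and the ontology is classified non-case-sensitive; otherwise
    the classification is ``css > -1``.
    """
    if not flags:
        raise ValueError("flags must be non-empty")
    n_c = len(flags)
    cs_positions = [i for i, f in enumerate(flags) if f]
    freq_cs = len(cs_positions)

    if freq_cs < 2:
        return CaseReport(
            n_c=n_c, freq_cs=freq_cs, gaps=[], delta_cs=None, css=None,
            is_case_sensitive=False,
        )

    gaps = [b - a - 1 for a, b in zip(cs_positions, cs_positions[1:])]
    mean_gap = sum(gaps) / len(gaps)
    delta = math.sqrt(sum((g - mean_gap) ** 2 for g in gaps) / len(gaps))
    css = 0.5 * (math.exp(-delta) - delta / math.e + freq_cs / n_c)
    return CaseReport(
        n_c=n_c, freq_cs=freq_cs, gaps=gaps, delta_cs=delta, css=css,
        is_case_sensitive=css > CSS_THRESHOLD,
    )


def assess_profiles(profiles: Sequence["EntityProfile"], order: str = "id") -> CaseReport:
    """Flag every profile and compute CSS.

    ``order`` selects the concept ordering used for the window gaps:
    ``"id"`` (ascending concept-id, the reproducible default) or ``"file"``
    (as supplied).
    """
    if order == "id":
        ordered = sorted(profiles, key=lambda p: p.concept_id)
    elif order == "file":
        ordered = list(profiles)
    else:
        raise ValueError(f"unknown order {order!r} (expected 'id' or 'file')")
    flags = [concept_is_case_sensitive(p) for p in ordered]
    return compute_css(flags)
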