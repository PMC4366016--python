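"""Exact-boundary evaluation of predicted annotations against gold standoff.

A prediction is a true positive only when document id, both character
offsets and the concept id all match a gold record; precision, recall and F1
are micro-averaged over the whole corpus.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .index_retrieval import Annotation

__all__ = ["EvalResult", "GoldFormatError", "load_gold", "compare", "write_tsv"]


class GoldFormatError(ValueError):
    """Raised for rows with invalid spans or non-integer offsets."""


_ID_NORM = re.compile(r"^([A-Za-z_]+)[:_](\d+)$")


def normalize_concept_id(concept_id: str) -> str:
    """Canonical ``PREFIX:number`` form (``GO_0000010`` -> ``GO:0000010``)."""
    m = _ID_NORM.match(concept_id.strip())
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return concept_id.strip()


def load_gold(path: str | Path) -> list[Annotation]:
    """Read standoff TSV (doc_id, start, end, concept_id); extra columns are
    ignored, duplicate rows deduplicated with a warning."""
    annotations: list[Annotation] = []
    seen: set[tuple] = set()
    dupes = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GoldFormatError(f"line {line_no}: expected >=4 columns")
            doc_id, start_s, end_s, concept_id = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GoldFormatError(
                    f"line {line_no}: non-integer offsets {start_s!r}/{end_s!r}"
                ) from None
            if start >= end or start < 0:
                raise GoldFormatError(
                    f"line {line_no}: invalid span [{start}, {end})"
                )
            ann = Annotation(doc_id, start, end, normalize_concept_id(concept_id))
            if ann.key in seen:
                dupes += 1
                continue
            seen.add(ann.key)
            annotations.append(ann)
    if dupes:
        warnings.warn(f"{dupes} duplicate gold rows dropped", stacklevel=2)
    return annotations


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _keyset(annotations: Iterable[Annotation]) -> set[tuple]:
    return {
        (a.doc_id, a.start, a.end, normalize_concept_id(a.concept_id))
        for a in annotations
    }


def compare(predicted: Sequence[Annotation], gold: Sequence[Annotation]) -> EvalResult:
    """Micro-averaged exact matching over (doc_id, start, end, concept_id)."""
    pred_keys = _keyset(predicted)
    gold_keys = _keyset(gold)
    tp = len(pred_keys & gold_keys)
    return EvalResult(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


def write_tsv(annotations: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in sorted(annotations):
            fh.write(f"{a.doc_id}\t{a.start}\t{a.end}\t{a.concept_id}\n")
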