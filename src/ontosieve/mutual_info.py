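"""Bigram collocation statistics over the lexicon.

Pointwise mutual information (natural log) of adjacent token pairs, the
interquartile-range "independence interval", per-token positional MI, and the
balance scores that decide which side of a bigram survives a split.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .lexicon_io import EntityProfile

__all__ = [
    "Position",
    "BigramCounts",
    "MIStats",
    "count_bigrams",
    "pairwise_mi",
    "independence_interval",
    "position_mi",
    "compute_mi_stats",
    "sign_balance",
    "balance_correlated",
    "balance_independent",
]


class Position(Enum):
    LEFT = "L"
    RIGHT = "R"


@dataclass
class BigramCounts:
    """Raw unigram / adjacent-bigram occurrence counts over all
    representations in a lexicon."""

    unigram: Counter
    bigram: Counter
    total_tokens: int
    total_bigrams: int


def count_bigrams(profiles: Sequence[EntityProfile]) -> BigramCounts:
    unigram: Counter = Counter()
    bigram: Counter = Counter()
    for profile in profiles:
        for rep in profile.representations:
            unigram.update(rep.tokens)
            bigram.update(zip(rep.tokens, rep.tokens[1:]))
    return BigramCounts(
        unigram=unigram,
        bigram=bigram,
        total_tokens=sum(unigram.values()),
        total_bigrams=sum(bigram.values()),
    )


def pairwise_mi(x: str, y: str, counts: BigramCounts) -> float:
    """Pointwise MI ``ln p(x,y) / (p(x) p(y))`` of an observed bigram.

    ``p(x,y)`` is the adjacent-bigram count over total bigram occurrences;
    the marginals are unigram occurrence counts over total token occurrences.
    """
    c_xy = counts.bigram.get((x, y), 0)
    if c_xy == 0:
        raise KeyError(f"bigram ({x!r}, {y!r}) was never observed")
    p_xy = c_xy / counts.total_bigrams
    p_x = counts.unigram[x] / counts.total_tokens
    p_y = counts.unigram[y] / counts.total_tokens
    return math.log(p_xy / (p_x * p_y))


def independence_interval(
    mi_values: Sequence[float], m: float = 1.0, n: float = 0.0
) -> tuple[float, float]:
    """IQR-rule band ``[m*Q1 - n*IQR, m*Q3 + n*IQR]``.

    Quartiles use linear interpolation (NumPy's default, "type 7").  MI
    values strictly outside the band mark correlated bigrams; values inside
    (inclusive) mark independent ones.
    """
    if len(mi_values) < 4:
        raise ValueError("need at least 4 MI values for quartiles")
    q1, q3 = np.percentile(np.asarray(mi_values, dtype=float), [25.0, 75.0])
    iqr = q3 - q1
    return (m * q1 - n * iqr, m * q3 + n * iqr)


@dataclass
class MIStats:
    """Lexicon-wide bigram MI distribution and derived quantities."""

    bigram_mi: dict[tuple[str, str], float]
    q1: float
    q3: float
    ii: tuple[float, float]
    m: float
    n: float
    pos_mi: dict[tuple[str, Position], float] = field(default_factory=dict)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def is_correlated(self, left: str, right: str) -> bool:
        """A bigram is correlated iff its MI lies strictly outside the
        independence interval.  Unseen bigrams count as independent."""
        mi = self.bigram_mi.get((left, right))
        if mi is None:
            return False
        return mi < self.ii[0] or mi > self.ii[1]

    def position(self, token: str, position: Position) -> float:
        """Positional MI; 0 when the token never occupies that side."""
        return self.pos_mi.get((token, position), 0.0)


def position_mi(token: str, position: Position, counts: BigramCounts) -> float:
    """Mean pairwise MI over all distinct bigrams with the token on the
    given side; 0 when there are none."""
    if position is Position.LEFT:
        partners = [r for (l, r) in counts.bigram if l == token]
        values = [pairwise_mi(token, r, counts) for r in partners]
    else:
        partners = [l for (l, r) in counts.bigram if r == token]
        values = [pairwise_mi(l, token, counts) for l in partners]
    if not values:
        return 0.0
    return sum(values) / len(values)


def compute_mi_stats(
    profiles: Sequence[EntityProfile], m: float = 1.0, n: float = 0.0
) -> MIStats | None:
    """Full MI census of a lexicon; ``None`` when fewer than 4 distinct
    bigrams exist (interval undefined, variant generation disabled)."""
    counts = count_bigrams(profiles)
    bigram_mi = {pair: pairwise_mi(*pair, counts) for pair in counts.bigram}
    if len(bigram_mi) < 4:
        return None
    values = list(bigram_mi.values())
    q1, q3 = np.percentile(np.asarray(values), [25.0, 75.0])
    ii = (m * q1 - n * (q3 - q1), m * q3 + n * (q3 - q1))

    left_sums: dict[str, list[float]] = defaultdict(list)
    right_sums: dict[str, list[float]] = defaultdict(list)
    for (l, r), mi in bigram_mi.items():
        left_sums[l].append(mi)
        right_sums[r].append(mi)
    pos_mi: dict[tuple[str, Position], float] = {}
    for token, vals in left_sums.items():
        pos_mi[(token, Position.LEFT)] = sum(vals) / len(vals)
    for token, vals in right_sums.items():
        pos_mi[(token, Position.RIGHT)] = sum(vals) / len(vals)

    return MIStats(
        bigram_mi=bigram_mi, q1=float(q1), q3=float(q3), ii=ii, m=m, n=n,
        pos_mi=pos_mi,
    )


def sign_balance(lt_pos_r: float, rt_pos_l: float) -> int:
    """Sign of ``MI(LT at RIGHT) - MI(RT at LEFT)``: +1, -1 or 0."""
    diff = lt_pos_r - rt_pos_l
    return (diff > 0) - (diff < 0)


def balance_correlated(
    lt: dict[Position, float],
    rt: dict[Position, float],
    s: int,
    form: str = "example",
) -> float | None:
    """Balance score for a correlated bigram; ``None`` when undefined.

    ``form="example"`` (normative): for S=+1 the value is
    ``(MI(LT,L)/MI(LT,R)) * (MI(RT,L)*MI(RT,R))``; for S=-1 the mirrored
    expression with the token roles swapped, negated.  ``form="ratio"`` is
    the alternative double-ratio reading
    ``(MI(LT,L)/MI(LT,R)) * (MI(RT,L)/MI(RT,R))`` (kept as a documented
    switch; both readings agree on the worked-example decision).
    """
    if s == 0:
        raise ValueError("balance requires S != 0")
    L, R = Position.LEFT, Position.RIGHT
    if form == "example":
        if s > 0:
            if lt[R] == 0:
                return None
            return (lt[L] / lt[R]) * (rt[L] * rt[R])
        if rt[L] == 0:
            return None
        return -(rt[R] / rt[L]) * (lt[L] * lt[R])
    if form == "ratio":
        if lt[R] == 0 or rt[R] == 0:
            return None
        return s * (lt[L] / lt[R]) * (rt[L] / rt[R]) ** s
    raise ValueError(f"unknown form {form!r}")


def balance_independent(
    lt: dict[Position, float], rt: dict[Position, float], s: int
) -> float | None:
    """Balance score for an independent bigram:
    ``S * MI(LT at RIGHT) / MI(RT at LEFT)``; ``None`` when the denominator
    is 0."""
    if s == 0:
        raise ValueError("balance requires S != 0")
    if rt[Position.LEFT] == 0:
        return None
    return s * lt[Position.RIGHT] / rt[Position.LEFT]
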