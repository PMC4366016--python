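"""Alternative-label generation from low-information-gain tokens.

Multi-token representations drop local gain outliers that are statistically
independent of their neighbours; bigrams are split either through the global
low-IG token list or through the positional-MI balance scores.  Generated
variants never feed back into the corpus statistics.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .dfr_gain import GainTable
from .lexicon_io import EntityProfile
from .mutual_info import (
    MIStats,
    Position,
    balance_correlated,
    balance_independent,
    sign_balance,
)

__all__ = [
    "VariantParams",
    "GlobalIGStats",
    "VariantRecord",
    "VariantSet",
    "VariantRule",
    "OutlierDecision",
    "outlier_stats",
    "label_outliers",
    "resolve_outlier",
    "global_low_ig",
    "process_bigram",
    "generate_variants",
]


@dataclass(frozen=True)
class VariantParams:
    """Tuning constants: ``m``/``n`` widen the independence interval, ``k``
    sets the global outlier threshold ``mean - k*SD``."""

    m: float = 1.0
    n: float = 0.0
    k: float = 3.0
    enable_bigram_split: bool = True
    enable_balance_split: bool = True
    correlated_form: str = "example"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")


class VariantRule(Enum):
    MULTI_TOKEN_DROP = "MULTI_TOKEN_DROP"
    BIGRAM_LOW_IG_SPLIT = "BIGRAM_LOW_IG_SPLIT"
    BIGRAM_BALANCE_SPLIT = "BIGRAM_BALANCE_SPLIT"


class OutlierDecision(Enum):
    RETAIN = "RETAIN"
    DISCARD = "DISCARD"


@dataclass(frozen=True)
class VariantRecord:
    concept_id: str
    source_tokens: tuple[str, ...]
    variant_tokens: tuple[str, ...]
    rule: VariantRule


@dataclass
class VariantSet:
    records: list[VariantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_concept(self, concept_id: str) -> list[VariantRecord]:
        return [r for r in self.records if r.concept_id == concept_id]


# ---------------------------------------------------------------------------
# Local (within-representation) outlier detection

def outlier_stats(ig_values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, population SD, mean - SD threshold) of the gain values."""
    mean = sum(ig_values) / len(ig_values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in ig_values) / len(ig_values))
    return mean, sd, mean - sd


def label_outliers(ig_values: Sequence[float]) -> set[int]:
    """Indices whose gain falls strictly below mean minus one population SD.

    Applies to representations of three or more tokens; a bigram's two
    values are never more than one SD from their mean.
    """
    if len(ig_values) < 3:
        raise ValueError("outlier detection needs at least 3 tokens")
    _, _, threshold = outlier_stats(ig_values)
    return {i for i, v in enumerate(ig_values) if v < threshold}


def resolve_outlier(
    tokens: Sequence[str], index: int, mi_stats: MIStats
) -> OutlierDecision:
    """Keep an outlier token iff it forms a correlated bigram with a
    neighbour (MI strictly outside the independence interval); otherwise it
    is independent of its context and can be discarded.  Unseen bigrams
    count as independent."""
    if not 0 <= index < len(tokens):
        raise IndexError(index)
    if len(tokens) < 2:
        raise ValueError("outlier must have at least one neighbour")
    tok = tokens[index]
    if index > 0 and mi_stats.is_correlated(tokens[index - 1], tok):
        return OutlierDecision.RETAIN
    if index < len(tokens) - 1 and mi_stats.is_correlated(tok, tokens[index + 1]):
        return OutlierDecision.RETAIN
    return OutlierDecision.DISCARD


# ---------------------------------------------------------------------------
# Global low-IG token list

@dataclass
class GlobalIGStats:
    token_global_ig: dict[str, float]
    mean_ig: float
    sd_ig: float
    low_ig_threshold: float
    low_ig_tokens: set[str]


def global_low_ig(gain_table: GainTable, params: VariantParams) -> GlobalIGStats:
    """Global low-IG token census.

    A token's global IG is the unweighted mean of its per-profile gains,
    counting only profiles where it appears in a multi-token representation
    (single-token labels say nothing about droppability).  Tokens strictly
    below ``mean - k*SD`` of the global-IG distribution form the low-IG set.
    """
    per_token: dict[str, dict[str, float]] = defaultdict(dict)  # token -> {cid: gain}
    for (cid, _rep, token), entry in gain_table.entries.items():
        if entry.rep_len >= 2:
            per_token[token][cid] = entry.gain
    token_global_ig = {
        t: sum(by_cid.values()) / len(by_cid) for t, by_cid in per_token.items()
    }
    if len(token_global_ig) < 2:
        return GlobalIGStats(token_global_ig, 0.0, 0.0, 0.0, set())
    mean_ig, sd_ig, _ = outlier_stats(list(token_global_ig.values()))
    threshold = mean_ig - params.k * sd_ig
    low = {t for t, v in token_global_ig.items() if v < threshold}
    return GlobalIGStats(token_global_ig, mean_ig, sd_ig, threshold, low)


# ---------------------------------------------------------------------------
# Bigram processing

def _in_interval(value: float, ii: tuple[float, float]) -> bool:
    return ii[0] <= value <= ii[1]


def process_bigram(
    tokens: Sequence[str],
    global_stats: GlobalIGStats,
    mi_stats: MIStats,
    params: VariantParams,
) -> tuple[int, VariantRule] | None:
    """Decide whether a two-token representation splits.

    Returns the index of the retained token plus the rule that fired, or
    ``None`` for no split.  Low-IG bigrams split when their MI is inside the
    independence interval, keeping the globally more informative token.
    Other bigrams go through the sign/balance machinery: a positive
    subunitary balance retains the right token, a negative one (subunitary
    for correlated, overunitary for independent) the left; anything else —
    including undefined balances — leaves the label whole.
    """
    if len(tokens) != 2:
        raise ValueError("process_bigram requires exactly 2 tokens")
    left, right = tokens
    mi = mi_stats.bigram_mi.get((left, right))

    has_low = left in global_stats.low_ig_tokens or right in global_stats.low_ig_tokens
    if has_low:
        if mi is None or not _in_interval(mi, mi_stats.ii):
            return None
        ig_l = global_stats.token_global_ig.get(left, 0.0)
        ig_r = global_stats.token_global_ig.get(right, 0.0)
        return (0 if ig_l >= ig_r else 1), VariantRule.BIGRAM_LOW_IG_SPLIT

    if not params.enable_balance_split:
        return None

    lt = {p: mi_stats.position(left, p) for p in Position}
    rt = {p: mi_stats.position(right, p) for p in Position}
    s = sign_balance(lt[Position.RIGHT], rt[Position.LEFT])
    if s == 0:
        return None

    correlated = mi is not None and not _in_interval(mi, mi_stats.ii)
    if correlated:
        value = balance_correlated(lt, rt, s, form=params.correlated_form)
        if value is None:
            return None
        if 0 < value < 1:
            return 1, VariantRule.BIGRAM_BALANCE_SPLIT
        if -1 < value < 0:
            return 0, VariantRule.BIGRAM_BALANCE_SPLIT
        return None
    value = balance_independent(lt, rt, s)
    if value is None:
        return None
    if 0 < value < 1:
        return 1, VariantRule.BIGRAM_BALANCE_SPLIT
    if value < -1:
        return 0, VariantRule.BIGRAM_BALANCE_SPLIT
    return None


# ---------------------------------------------------------------------------
# Driver

def generate_variants(
    profiles: Sequence[EntityProfile],
    gain_table: GainTable,
    mi_stats: MIStats | None,
    params: VariantParams = VariantParams(),
) -> VariantSet:
    """Generate alternative token sequences for every eligible representation.

    Representations of three or more tokens drop all DISCARD-resolved
    outliers in one pass (one joint variant); two-token representations go
    through :func:`process_bigram`.  Single-token representations are left
    alone.  Results are deduplicated per (concept, sequence) and never equal
    their source.
    """
    result = VariantSet()
    if mi_stats is None:
        return result
    global_stats = global_low_ig(gain_table, params)
    seen: set[tuple[str, tuple[str, ...]]] = set()

    for profile in profiles:
        existing = {tuple(r.tokens) for r in profile.representations}
        for rep_idx, rep in enumerate(profile.representations):
            tokens = tuple(rep.tokens)
            variant: tuple[str, ...] | None = None
            rule: VariantRule | None = None
            if len(tokens) >= 3:
                gains = gain_table.representation_gains(
                    profile.concept_id, rep_idx, tokens
                )
                outliers = label_outliers(gains)
                drop = {
                    i
                    for i in outliers
                    if resolve_outlier(tokens, i, mi_stats) is OutlierDecision.DISCARD
                }
                if drop:
                    candidate = tuple(t for i, t in enumerate(tokens) if i not in drop)
                    if candidate and candidate != tokens:
                        variant, rule = candidate, VariantRule.MULTI_TOKEN_DROP
            elif len(tokens) == 2 and params.enable_bigram_split:
                decision = process_bigram(tokens, global_stats, mi_stats, params)
                if decision is not None:
                    keep_idx, rule = decision
                    variant = (tokens[keep_idx],)
            if variant is None or rule is None:
                continue
            key = (profile.concept_id, variant)
            if key in seen or variant in existing:
                continue
            seen.add(key)
            result.records.append(
                VariantRecord(profile.concept_id, tokens, variant, rule)
            )
    return result
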