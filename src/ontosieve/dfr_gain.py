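"""Divergence-from-randomness information gain of tokens within entity
profiles.

The collection is the set of entity profiles; a token diverging strongly from
its collection-wide random (binomial) expectation inside a profile carries
high information gain there.  The gain is the binomial self-information
weighted by the Bernoulli risk factor ``TF / (df * (tfn + 1))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .lexicon_io import CorpusStats, EntityProfile

__all__ = [
    "normalized_tf",
    "binomial_weight",
    "gain",
    "GainEntry",
    "GainTable",
    "compute_gain_table",
]


def _log(x: float, base: float) -> float:
    return math.log(x) / math.log(base)


def normalized_tf(tf: float, dl: float, sl: float, log_base: float = 2.0) -> float:
    """Length-normalized term frequency ``tfn = tf * log(1 + sl/dl)``."""
    if dl <= 0:
        raise ValueError("dl must be positive")
    if sl <= 0:
        raise ValueError("sl must be positive")
    if tf < 0:
        raise ValueError("tf must be non-negative")
    return tf * _log(1.0 + sl / dl, log_base)


def binomial_weight(TF: int, tfn: float, N: int, log_base: float = 2.0) -> float:
    """``-log`` of the binomial probability of observing frequency ``tfn``
    out of ``TF`` collection occurrences with success probability ``1/N``.

    The binomial coefficient is continuously extended via log-gamma so that
    non-integer ``tfn`` (produced by length normalization) is handled; for
    integer ``tfn`` this agrees with the exact pmf.  ``tfn > TF`` is clamped
    with a warning (possible when ``sl >> dl``).
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if TF < 0:
        raise ValueError("TF must be non-negative")
    if tfn < 0:
        raise ValueError("tfn must be non-negative")
    if tfn > TF:
        warnings.warn(
            f"tfn={tfn:.4g} exceeds TF={TF}; clamping to TF", stacklevel=2
        )
        tfn = float(TF)
    p = 1.0 / N
    q = 1.0 - p
    log_coeff = (
        math.lgamma(TF + 1) - math.lgamma(tfn + 1) - math.lgamma(TF - tfn + 1)
    )
    log_prob = log_coeff + tfn * math.log(p) + (TF - tfn) * math.log(q)
    return -log_prob / math.log(log_base)


def gain(
    tf: int,
    TF: int,
    df: int,
    dl: float,
    sl: float,
    N: int,
    log_base: float = 2.0,
) -> float:
    """Risk-weighted information gain of a token within one profile.

    ``gain = weight(TF, tfn, N) * TF / (df * (tfn + 1))``, clamped at 0 so
    rounding in the continuous binomial extension can never yield a
    (meaningless) negative gain.
    """
    if df <= 0:
        raise ValueError("df must be positive for an occurring token")
    if tf < 1:
        raise ValueError("gain is defined for occurring tokens (tf >= 1)")
    tfn = normalized_tf(tf, dl, sl, log_base)
    tfn = min(tfn, float(TF))
    w = binomial_weight(TF, tfn, N, log_base)
    return max(w * TF / (df * (tfn + 1.0)), 0.0)


@dataclass(frozen=True)
class GainEntry:
    tf: int
    tfn: float
    weight: float
    p_risk: float
    gain: float
    rep_len: int


@dataclass
class GainTable:
    """Per-(concept, representation, token) gain entries.

    The gain itself is a profile-level quantity (``tf`` sums over the
    profile's representations); it is recorded once per representation
    containing the token so that representation lengths remain available to
    the variant generator.
    """

    entries: dict[tuple[str, int, str], GainEntry]
    log_base: float

    def profile_gain(self, concept_id: str, token: str) -> float:
        for (cid, _rep, tok), entry in self.entries.items():
            if cid == concept_id and tok == token:
                return entry.gain
        raise KeyError((concept_id, token))

    def representation_gains(
        self, concept_id: str, rep_index: int, tokens: Sequence[str]
    ) -> list[float]:
        return [self.entries[(concept_id, rep_index, t)].gain for t in tokens]


def compute_gain_table(
    profiles: Sequence[EntityProfile],
    stats: CorpusStats,
    log_base: float = 2.0,
) -> GainTable:
    """Evaluate the gain of every token of every representation."""
    entries: dict[tuple[str, int, str], GainEntry] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tfn clamping is routine at scale
        for profile in profiles:
            counts = profile.token_counts()
            for rep_idx, rep in enumerate(profile.representations):
                for token in set(rep.tokens):
                    tf = counts[token]
                    TF = stats.TF[token]
                    df = stats.df[token]
                    if df == 0:
                        raise RuntimeError(
                            f"token {token!r} occurs but df=0: inconsistent stats"
                        )
                    tfn = min(normalized_tf(tf, profile.dl, stats.sl, log_base), float(TF))
                    w = binomial_weight(TF, tfn, stats.N, log_base)
                    p_risk = TF / (df * (tfn + 1.0))
                    entries[(profile.concept_id, rep_idx, token)] = GainEntry(
                        tf=tf,
                        tfn=tfn,
                        weight=w,
                        p_risk=p_risk,
                        gain=max(w * p_risk, 0.0),
                        rep_len=len(rep),
                    )
    return GainTable(entries=entries, log_base=log_base)
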