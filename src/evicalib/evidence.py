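"""Mapping scores to benign / deleterious / no evidence.

Two rules are implemented: the two-sided threshold rule (score at or below
T_BE gives benign evidence, at or above T_DE deleterious evidence, in
between no evidence), and the SIFT/PolyPhen2 agreement comparator
(deleterious only when both individual predictors call damaging, benign
only when both call benign).  Missing input always yields no evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .records import POLYPHEN_CATEGORIES
from .thresholds import ThresholdPair

__all__ = ["Evidence", "EvidenceCall", "assign_evidence", "sift_polyphen_agreement"]

#: SIFT scores strictly below this are "damaging" calls.
SIFT_DAMAGING_CUTOFF = 0.05

_DAMAGING_POLYPHEN = frozenset({"possibly_damaging", "probably_damaging"})


class Evidence(str, Enum):
    BE = "BE"  # benign evidence
    NE = "NE"  # no evidence
    DE = "DE"  # deleterious evidence


@dataclass(frozen=True)
class EvidenceCall:
    """An evidence category plus the rule that produced it."""

    evidence: Evidence
    rule: str


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def assign_evidence(score: float | None, thresholds: ThresholdPair) -> EvidenceCall:
    """Two-sided threshold rule; boundary scores receive evidence.

    A score exactly at T_BE or T_DE sits at predicted probability exactly
    p_lower / p_upper and qualifies.  For a negatively oriented pair (flagged
    at derivation: slope < 0, benign side numerically above the deleterious
    side) the comparisons run in the reversed direction.
    """
    rule = f"{thresholds.predictor}@{thresholds.scope}"
    if _is_missing(score):
        return EvidenceCall(Evidence.NE, rule)
    if thresholds.orientation == "positive":
        if score <= thresholds.t_be:
            return EvidenceCall(Evidence.BE, rule)
        if score >= thresholds.t_de:
            return EvidenceCall(Evidence.DE, rule)
    else:
        if thresholds.t_be <= thresholds.t_de:
            raise ValueError(
                "negatively oriented thresholds require t_be > t_de, got "
                f"({thresholds.t_be}, {thresholds.t_de})"
            )
        if score >= thresholds.t_be:
            return EvidenceCall(Evidence.BE, rule)
        if score <= thresholds.t_de:
            return EvidenceCall(Evidence.DE, rule)
    return EvidenceCall(Evidence.NE, rule)


def sift_polyphen_agreement(
    sift_score: float | None, polyphen_call: str | None
) -> EvidenceCall:
    """Agreement rule over the two individual predictors.

    Deleterious iff SIFT < 0.05 and PolyPhen2 is possibly/probably damaging;
    benign iff SIFT >= 0.05 and PolyPhen2 is benign; anything else —
    discordance or a missing input — gives no evidence.  The SIFT boundary
    value 0.05 itself falls on the benign side.
    """
    if polyphen_call is not None and polyphen_call not in POLYPHEN_CATEGORIES:
        raise ValueError(f"unknown PolyPhen2 category {polyphen_call!r}")
    rule = "sift_polyphen2_agreement"
    if _is_missing(sift_score) or polyphen_call is None:
        return EvidenceCall(Evidence.NE, rule)
    if sift_score < SIFT_DAMAGING_CUTOFF and polyphen_call in _DAMAGING_POLYPHEN:
        return EvidenceCall(Evidence.DE, rule)
    if sift_score >= SIFT_DAMAGING_CUTOFF and polyphen_call == "benign":
        return EvidenceCall(Evidence.BE, rule)
    return EvidenceCall(Evidence.NE, rule)
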