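"""Consensus classification of variants from per-submitter clinical calls.

Each submitter classifies a variant as benign (B), likely benign (LB),
uncertain (VUS), likely pathogenic (LP) or pathogenic (P).  B/LB and P/LP
are pooled, and a variant's consensus class is the most supported of the
three groups, with variants excluded when submitters conflict outright or
when VUS calls dominate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

__all__ = [
    "SubmissionRecord",
    "ClassCounts",
    "ConsensusClass",
    "tally_submissions",
    "consensus_class",
    "assign_consensus",
]

#: Recognised per-submitter classification tokens.
VALID_CLASSIFICATIONS = frozenset({"B", "LB", "VUS", "LP", "P"})

_BENIGN_CALLS = frozenset({"B", "LB"})
_PATHOGENIC_CALLS = frozenset({"LP", "P"})


class ConsensusClass(str, Enum):
    """Consensus group of a variant, or the reason it was excluded."""

    BLB = "BLB"
    PLP = "PLP"
    EXCLUDED_CONFLICT = "EXCLUDED_CONFLICT"
    EXCLUDED_VUS = "EXCLUDED_VUS"
    EXCLUDED_EMPTY = "EXCLUDED_EMPTY"

    @property
    def included(self) -> bool:
        return self in (ConsensusClass.BLB, ConsensusClass.PLP)


@dataclass(frozen=True)
class SubmissionRecord:
    """One submitter's classification of one variant."""

    variant_id: str
    submitter: str
    classification: str
    date: str | None = None

    def __post_init__(self) -> None:
        if self.classification not in VALID_CLASSIFICATIONS:
            raise ValueError(
                f"unknown classification token {self.classification!r} "
                f"for variant {self.variant_id!r}; expected one of "
                f"{sorted(VALID_CLASSIFICATIONS)}"
            )


@dataclass(frozen=True)
class ClassCounts:
    """Pooled per-variant tallies: N_B/LB, N_P/LP and N_VUS."""

    n_blb: int = 0
    n_plp: int = 0
    n_vus: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blb", "n_plp", "n_vus"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_blb + self.n_plp + self.n_vus


def tally_submissions(
    submissions: Iterable[SubmissionRecord], variant_id: str
) -> ClassCounts:
    """Pool a variant's submitter calls into (N_B/LB, N_P/LP, N_VUS).

    All records must refer to ``variant_id``; B and LB are pooled, as are
    LP and P.
    """
    n_blb = n_plp = n_vus = 0
    for rec in submissions:
        if rec.variant_id != variant_id:
            raise ValueError(
                f"submission for {rec.variant_id!r} passed while tallying "
                f"{variant_id!r}"
            )
        if rec.classification in _BENIGN_CALLS:
            n_blb += 1
        elif rec.classification in _PATHOGENIC_CALLS:
            n_plp += 1
        else:  # VUS; SubmissionRecord already rejects unknown tokens
            n_vus += 1
    return ClassCounts(n_blb=n_blb, n_plp=n_plp, n_vus=n_vus)


def consensus_class(counts: ClassCounts) -> ConsensusClass:
    """Map pooled call counts to a consensus class or an exclusion.

    Rule order:

    1. any B/LB call together with any P/LP call -> conflict, excluded;
    2. VUS calls strictly outnumbering both groups -> excluded as VUS;
    3. P/LP if ``n_plp >= max(n_vus, 1)`` and ``n_blb == 0``;
    4. B/LB if ``n_blb >= max(n_vus, 1)`` and ``n_plp == 0``;
    5. otherwise (no calls at all) excluded as empty.

    The rules are exhaustive and mutually exclusive; a VUS/positive tie
    (``n_vus == n_plp >= 1``, ``n_blb == 0``) classifies as PLP because
    the VUS exclusion requires a strict majority.
    """
    if counts.n_plp >= 1 and counts.n_blb >= 1:
        return ConsensusClass.EXCLUDED_CONFLICT
    if counts.n_vus > max(counts.n_blb, counts.n_plp):
        return ConsensusClass.EXCLUDED_VUS
    if counts.n_plp >= max(counts.n_vus, 1) and counts.n_blb == 0:
        return ConsensusClass.PLP
    if counts.n_blb >= max(counts.n_vus, 1) and counts.n_plp == 0:
        return ConsensusClass.BLB
    return ConsensusClass.EXCLUDED_EMPTY


@dataclass(frozen=True)
class ConsensusResult:
    counts: ClassCounts
    consensus: ConsensusClass


def assign_consensus(
    submissions: Iterable[SubmissionRecord],
) -> dict[str, ConsensusResult]:
    """Tally and classify every variant appearing in ``submissions``.

    Returns a mapping variant_id -> (counts, consensus), keyed in first-seen
    order of the variant ids.
    """
    grouped: dict[str, list[SubmissionRecord]] = defaultdict(list)
    for rec in submissions:
        grouped[rec.variant_id].append(rec)
    out: dict[str, ConsensusResult] = {}
    for vid, recs in grouped.items():
        counts = tally_submissions(recs, vid)
        out[vid] = ConsensusResult(counts=counts, consensus=consensus_class(counts))
    return out
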