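"""Core per-variant record type shared across the pipeline.

A variant is an opaque identifier plus a gene symbol, a consensus class
(benign/likely benign pooled vs pathogenic/likely pathogenic pooled), and
per-predictor numeric scores with explicit missingness, mirroring a
dbNSFP-style score extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusClass

__all__ = [
    "VariantRecord",
    "PREDICTORS",
    "META_PREDICTORS",
    "POLYPHEN_CATEGORIES",
    "GENERALIZED",
    "split_scores_labels",
]

#: Numeric score columns handled by the pipeline (SIFT is the one
#: negatively oriented predictor: low scores mean deleterious).
PREDICTORS = ("sift", "cadd", "metasvm", "eigen", "revel", "bayesdel")

#: The five meta-predictors compared head-to-head.
META_PREDICTORS = ("cadd", "metasvm", "eigen", "revel", "bayesdel")

POLYPHEN_CATEGORIES = frozenset({"benign", "possibly_damaging", "probably_damaging"})

#: Scope marker for thresholds fit on all genes pooled.
GENERALIZED = "GENERALIZED"


@dataclass(frozen=True)
class VariantRecord:
    """One scored missense variant.

    ``scores`` maps predictor name to a finite float, with ``None`` for a
    missing value; ``polyphen2_call`` is the categorical PolyPhen2
    prediction.  ``consensus`` may be ``None`` before the consensus stage
    has run.
    """

    variant_id: str
    gene: str
    consensus: ConsensusClass | None = None
    scores: dict[str, float | None] = field(default_factory=dict)
    polyphen2_call: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"variant {self.variant_id!r} has an empty gene symbol")
        # canonical form: a missing score and an absent entry are the same
        object.__setattr__(
            self, "scores", {k: v for k, v in self.scores.items() if v is not None}
        )
        for name, value in self.scores.items():
            if value is not None and not math.isfinite(value):
                raise ValueError(
                    f"variant {self.variant_id!r}: non-finite {name} score {value!r}"
                )
        revel = self.scores.get("revel")
        if revel is not None and not (0.0 <= revel <= 1.0):
            raise ValueError(
                f"variant {self.variant_id!r}: REVEL score {revel} outside [0, 1]"
            )
        if (
            self.polyphen2_call is not None
            and self.polyphen2_call not in POLYPHEN_CATEGORIES
        ):
            raise ValueError(
                f"variant {self.variant_id!r}: unknown PolyPhen2 category "
                f"{self.polyphen2_call!r}"
            )

    def score(self, predictor: str) -> float | None:
        return self.scores.get(predictor)

    @property
    def is_blb(self) -> bool:
        return self.consensus is ConsensusClass.BLB

    @property
    def is_plp(self) -> bool:
        return self.consensus is ConsensusClass.PLP


def split_scores_labels(
    variants, predictor: str
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (scores, labels) arrays for fitting, dropping missing scores.

    Labels code P/LP as 1 and B/LB as 0; variants with any other (or no)
    consensus class are skipped.
    """
    xs: list[float] = []
    ys: list[float] = []
    for v in variants:
        if not (v.is_blb or v.is_plp):
            continue
        s = v.scores.get(predictor)
        if s is None:
            continue
        xs.append(s)
        ys.append(1.0 if v.is_plp else 0.0)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
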