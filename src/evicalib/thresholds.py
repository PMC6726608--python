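"""Two-sided evidence thresholds from inverted logistic fits.

A fitted per-gene (or pooled) model ``logit P(pathogenic) = b0 + b1 * x``
is inverted at two predicted probabilities — 0.2 on the benign side and
0.8 on the deleterious side — giving a score interval: at or below T_BE a
variant receives benign evidence, at or above T_DE deleterious evidence,
and in between no evidence.  Confidence intervals for the thresholds come
from a bootstrap stratified by classification status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .firth import FirthFit, SingleClassError, _fit_arrays, fit_firth_logistic
from .records import GENERALIZED, VariantRecord, split_scores_labels

__all__ = [
    "ThresholdPair",
    "ThresholdCI",
    "DegenerateFitError",
    "derive_thresholds",
    "gene_level_thresholds",
    "generalized_thresholds",
    "bootstrap_threshold_ci",
]

logger = logging.getLogger(__name__)

#: Default predicted probabilities bounding the no-evidence band.
P_LOWER_DEFAULT = 0.2
P_UPPER_DEFAULT = 0.8
#: Minimum B/LB and P/LP variants for a gene-level fit.
MIN_PER_CLASS_DEFAULT = 10

# |beta1| below this is treated as an uninformative (flat) fit.
_BETA1_TOL = 1e-10


class DegenerateFitError(ValueError):
    """Raised when a fit's slope is (numerically) zero."""


@dataclass(frozen=True)
class ThresholdPair:
    """Two-sided limits T_BE / T_DE for one predictor and scope.

    ``orientation`` is "positive" when higher scores mean more deleterious
    (t_be < t_de); a "negative" pair comes from a fit with beta1 < 0 (a
    SIFT-like predictor) and is flagged rather than silently swapped — for
    such a pair t_be is numerically *above* t_de and evidence assignment
    compares in the reversed direction.
    """

    predictor: str
    scope: str
    t_be: float
    t_de: float
    p_lower: float = P_LOWER_DEFAULT
    p_upper: float = P_UPPER_DEFAULT
    orientation: str = "positive"
    fit: FirthFit | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.orientation not in ("positive", "negative"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "positive" and not self.t_be < self.t_de:
            raise ValueError(
                f"positively oriented thresholds require t_be < t_de, "
                f"got ({self.t_be}, {self.t_de})"
            )


@dataclass(frozen=True)
class ThresholdCI:
    """Bootstrap confidence intervals for one threshold pair."""

    predictor: str
    scope: str
    level: float
    be_lower: float
    be_upper: float
    de_lower: float
    de_upper: float
    n_boot_requested: int
    n_boot_used: int
    unreliable: bool = False

    def __post_init__(self) -> None:
        if self.n_boot_used > self.n_boot_requested:
            raise ValueError("replicates used cannot exceed requested")
        if self.be_lower > self.be_upper or self.de_lower > self.de_upper:
            raise ValueError("CI lower bound exceeds upper bound")


def derive_thresholds(
    fit: FirthFit,
    p_lower: float = P_LOWER_DEFAULT,
    p_upper: float = P_UPPER_DEFAULT,
    *,
    predictor: str = "",
    scope: str = "",
) -> ThresholdPair:
    """Invert a fit at the two evidence probabilities.

    ``t_be`` solves ``expit(b0 + b1 t) = p_lower`` and ``t_de`` the same at
    ``p_upper``; with a negative slope the pair is flagged as reversed
    (orientation "negative") instead of being swapped.
    """
    if not (0.0 < p_lower < p_upper < 1.0):
        raise ValueError("need 0 < p_lower < p_upper < 1")
    if not fit.converged:
        raise ValueError("cannot derive thresholds from a non-converged fit")
    if abs(fit.beta1) < _BETA1_TOL:
        raise DegenerateFitError("score uninformative, thresholds undefined")
    t_be = (logit(p_lower) - fit.beta0) / fit.beta1
    t_de = (logit(p_upper) - fit.beta0) / fit.beta1
    orientation = "positive" if fit.beta1 > 0 else "negative"
    return ThresholdPair(
        predictor=predictor,
        scope=scope,
        t_be=float(t_be),
        t_de=float(t_de),
        p_lower=p_lower,
        p_upper=p_upper,
        orientation=orientation,
        fit=fit,
    )


def _eligible_genes(
    variants: Sequence[VariantRecord], min_per_class: int
) -> dict[str, tuple[int, int]]:
    """Per-gene (n_blb, n_plp) on consensus classes, before score filtering."""
    counts: dict[str, list[int]] = {}
    for v in variants:
        c = counts.setdefault(v.gene, [0, 0])
        if v.is_blb:
            c[0] += 1
        elif v.is_plp:
            c[1] += 1
    return {g: (c[0], c[1]) for g, c in counts.items()}


def gene_level_thresholds(
    variants: Sequence[VariantRecord],
    predictor: str,
    min_per_class: int = MIN_PER_CLASS_DEFAULT,
    p_lower: float = P_LOWER_DEFAULT,
    p_upper: float = P_UPPER_DEFAULT,
) -> dict[str, ThresholdPair]:
    """Fit and invert one model per eligible gene.

    A gene is eligible when it has at least ``min_per_class`` B/LB and
    P/LP consensus variants (counted before dropping missing scores, which
    are excluded only from the fit itself).  Ineligible genes, and genes
    whose fit degenerates after missing-score removal, are omitted with a
    logged reason.
    """
    out: dict[str, ThresholdPair] = {}
    eligibility = _eligible_genes(variants, min_per_class)
    for gene in sorted(eligibility):
        n_blb, n_plp = eligibility[gene]
        if n_blb < min_per_class or n_plp < min_per_class:
            logger.info(
                "gene %s skipped: %d B/LB and %d P/LP consensus variants "
                "(need >=%d of each)",
                gene, n_blb, n_plp, min_per_class,
            )
            continue
        gene_variants = [v for v in variants if v.gene == gene]
        scores, labels = split_scores_labels(gene_variants, predictor)
        try:
            fit = fit_firth_logistic(scores, labels)
            out[gene] = derive_thresholds(
                fit, p_lower, p_upper, predictor=predictor, scope=gene
            )
        except (SingleClassError, DegenerateFitError) as exc:
            logger.info("gene %s skipped for %s: %s", gene, predictor, exc)
    return out


def generalized_thresholds(
    variants: Sequence[VariantRecord],
    predictor: str,
    p_lower: float = P_LOWER_DEFAULT,
    p_upper: float = P_UPPER_DEFAULT,
) -> ThresholdPair:
    """Single pooled fit over all provided variants (no gene terms)."""
    scores, labels = split_scores_labels(variants, predictor)
    fit = fit_firth_logistic(scores, labels)
    return derive_thresholds(
        fit, p_lower, p_upper, predictor=predictor, scope=GENERALIZED
    )


def bootstrap_threshold_ci(
    variants: Sequence[VariantRecord],
    predictor: str,
    scope: str,
    n_boot: int,
    level: float = 0.90,
    seed: int | np.random.Generator | None = 0,
    p_lower: float = P_LOWER_DEFAULT,
    p_upper: float = P_UPPER_DEFAULT,
) -> ThresholdCI:
    """Percentile bootstrap CI for (t_be, t_de), stratified by class.

    Resamples with replacement separately within the B/LB and the P/LP
    stratum (within the named gene when ``scope`` is a gene symbol; pooled
    when ``scope`` is GENERALIZED), refits and re-inverts each replicate.
    Replicates that fail to converge or have a non-positive slope are
    excluded and counted; the CI is flagged unreliable when more than half
    are excluded.  Stratum sizes are preserved exactly in every replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if scope == GENERALIZED:
        pool = variants
    else:
        pool = [v for v in variants if v.gene == scope]
        if not pool:
            raise ValueError(f"no variants in scope {scope!r}")
    scores, labels = split_scores_labels(pool, predictor)
    idx_blb = np.flatnonzero(labels == 0)
    idx_plp = np.flatnonzero(labels == 1)
    if len(idx_blb) == 0 or len(idx_plp) == 0:
        raise SingleClassError("single-class input: need both strata to bootstrap")

    lo_q = logit(p_lower)
    hi_q = logit(p_upper)
    t_be_reps: list[float] = []
    t_de_reps: list[float] = []
    n_excluded = 0
    for _ in range(n_boot):
        take_b = rng.integers(0, len(idx_blb), size=len(idx_blb))
        take_p = rng.integers(0, len(idx_plp), size=len(idx_plp))
        rows = np.concatenate((idx_blb[take_b], idx_plp[take_p]))
        b0, b1, converged = _fit_arrays(scores[rows], labels[rows])
        if not converged or b1 <= 0.0:
            n_excluded += 1
            continue
        t_be_reps.append((lo_q - b0) / b1)
        t_de_reps.append((hi_q - b0) / b1)

    n_used = len(t_be_reps)
    if n_used == 0:
        raise RuntimeError("all bootstrap replicates excluded; no CI available")
    alpha = (1.0 - level) / 2.0
    be_lo, be_hi = np.quantile(t_be_reps, [alpha, 1.0 - alpha])
    de_lo, de_hi = np.quantile(t_de_reps, [alpha, 1.0 - alpha])
    unreliable = n_excluded > n_boot / 2
    if unreliable:
        logger.warning(
            "bootstrap CI for %s/%s unreliable: %d of %d replicates excluded",
            predictor, scope, n_excluded, n_boot,
        )
    return ThresholdCI(
        predictor=predictor,
        scope=scope,
        level=level,
        be_lower=float(be_lo),
        be_upper=float(be_hi),
        de_lower=float(de_lo),
        de_upper=float(de_hi),
        n_boot_requested=n_boot,
        n_boot_used=n_used,
        unreliable=unreliable,
    )
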