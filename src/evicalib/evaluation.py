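"""Cross-validated evaluation of evidence-assignment schemes.

Evidence is assigned by leave-one-out cross-validation (each variant's
thresholds come from a model fit without that variant), tallied against
the consensus classes into a confusion table whose positive calls are
deleterious evidence, and summarized by:

* PPV  = TP / (TP + FP)          accuracy of deleterious evidence
* NPV  = TN / (TN + FN)          accuracy of benign evidence
* YR   = (TP+TN+FP+FN) / total   fraction of variants receiving evidence
* OPP  = sqrt((PPV^2 + NPV^2 + YR^2) / 3)   root-mean-square of the three

Pairwise differences in PPV/NPV/YR are tested by Fisher's exact test and
differences in OPP by a Monte Carlo permutation test that exchanges the
two methods' evidence calls per variant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import logit
from scipy.stats import fisher_exact

from .consensus import ConsensusClass
from .evidence import Evidence, EvidenceCall, assign_evidence
from .firth import _fit_arrays
from .records import GENERALIZED, VariantRecord, split_scores_labels
from .thresholds import (
    MIN_PER_CLASS_DEFAULT,
    P_LOWER_DEFAULT,
    P_UPPER_DEFAULT,
    ThresholdPair,
    _eligible_genes,
)

__all__ = [
    "ConfusionCounts",
    "PerformanceStats",
    "opp_rms",
    "loocv_assign",
    "confusion_counts",
    "performance",
    "fisher_test_metric",
    "permutation_test_opp",
    "rank_methods",
    "Rank",
]

logger = logging.getLogger(__name__)

Mode = Literal["GENE", "GENERALIZED", "COMBINED"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Evidence-vs-consensus tallies; positive means deleterious evidence.

    tp: deleterious evidence on a P/LP variant; tn: benign evidence on a
    B/LB variant; fp/fn: the corresponding errors; ne: no evidence on
    either class.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    ne: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "ne"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.ne

    @property
    def assigned(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceStats:
    ppv: float
    npv: float
    yr: float
    opp: float


def opp_rms(ppv: float, npv: float, yr: float) -> float:
    """Overall prediction performance: root mean square of PPV, NPV, YR."""
    return math.sqrt((ppv * ppv + npv * npv + yr * yr) / 3.0)


def performance(counts: ConfusionCounts) -> PerformanceStats:
    """PPV/NPV/YR/OPP at full precision (round only when reporting)."""
    if counts.tp + counts.fp == 0:
        raise ValueError("PPV undefined: no deleterious-evidence calls (tp+fp=0)")
    if counts.tn + counts.fn == 0:
        raise ValueError("NPV undefined: no benign-evidence calls (tn+fn=0)")
    if counts.total == 0:
        raise ValueError("no evaluated variants")
    ppv = counts.tp / (counts.tp + counts.fp)
    npv = counts.tn / (counts.tn + counts.fn)
    yr = counts.assigned / counts.total
    return PerformanceStats(ppv=ppv, npv=npv, yr=yr, opp=opp_rms(ppv, npv, yr))


def _thresholds_from_coeffs(
    b0: float, b1: float, predictor: str, scope: str, p_lower: float, p_upper: float
) -> ThresholdPair:
    t_be = (logit(p_lower) - b0) / b1
    t_de = (logit(p_upper) - b0) / b1
    return ThresholdPair(
        predictor=predictor,
        scope=scope,
        t_be=float(t_be),
        t_de=float(t_de),
        p_lower=p_lower,
        p_upper=p_upper,
        orientation="positive" if b1 > 0 else "negative",
    )


_BETA1_TOL = 1e-10


def loocv_assign(
    variants: Sequence[VariantRecord],
    predictor: str,
    mode: Mode = "GENE",
    p_lower: float = P_LOWER_DEFAULT,
    p_upper: float = P_UPPER_DEFAULT,
    min_per_class: int = MIN_PER_CLASS_DEFAULT,
    refit: bool = True,
) -> dict[str, EvidenceCall]:
    """Leave-one-out evidence assignment for every B/LB / P/LP variant.

    For each variant the relevant model — its gene's variants for GENE
    mode, the whole pooled set for GENERALIZED, the gene if eligible else
    the pooled set for COMBINED — is refit with that variant held out,
    inverted into thresholds, and applied to the variant's score.  Missing
    scores give no evidence without fitting, as does a held-out fit that
    degenerates (single class or flat slope), which is logged.

    ``refit=False`` keeps thresholds fixed at the full-data fit instead of
    refitting per held-out variant (no cross-validation).
    """
    if mode not in ("GENE", "GENERALIZED", "COMBINED"):
        raise ValueError(f"unknown mode {mode!r}")
    evaluated = [v for v in variants if v.is_blb or v.is_plp]
    eligibility = _eligible_genes(evaluated, min_per_class)
    eligible = {
        g
        for g, (nb, npp) in eligibility.items()
        if nb >= min_per_class and npp >= min_per_class
    }
    if mode == "GENE":
        ineligible = sorted(set(eligibility) - eligible)
        if ineligible:
            raise ValueError(
                f"GENE mode requires every gene to have >={min_per_class} "
                f"variants of each class; ineligible: {ineligible}"
            )

    # pre-extract fitting arrays per scope, with the variant ids they cover
    def arrays_for(pool: Sequence[VariantRecord]):
        ids = [
            v.variant_id
            for v in pool
            if (v.is_blb or v.is_plp) and v.scores.get(predictor) is not None
        ]
        x, y = split_scores_labels(pool, predictor)
        return ids, x, y

    pooled_ids, pooled_x, pooled_y = arrays_for(evaluated)
    pooled_pos = {vid: i for i, vid in enumerate(pooled_ids)}
    by_gene: dict[str, tuple[dict[str, int], np.ndarray, np.ndarray]] = {}
    for gene in eligible:
        ids, x, y = arrays_for([v for v in evaluated if v.gene == gene])
        by_gene[gene] = ({vid: i for i, vid in enumerate(ids)}, x, y)

    def assign_one(
        v: VariantRecord, pos: Mapping[str, int], x: np.ndarray, y: np.ndarray, scope: str
    ) -> EvidenceCall:
        score = v.scores.get(predictor)
        if refit:
            i = pos[v.variant_id]
            mask = np.ones(len(x), dtype=bool)
            mask[i] = False
            x_fit, y_fit = x[mask], y[mask]
        else:
            x_fit, y_fit = x, y
        if y_fit.sum() == 0 or y_fit.sum() == len(y_fit):
            logger.info(
                "LOOCV %s/%s: held-out fit for %s single-class; no evidence",
                predictor, scope, v.variant_id,
            )
            return EvidenceCall(Evidence.NE, f"{predictor}@{scope}")
        b0, b1, converged = _fit_arrays(x_fit, y_fit)
        if not converged or abs(b1) < _BETA1_TOL:
            logger.info(
                "LOOCV %s/%s: degenerate held-out fit for %s; no evidence",
                predictor, scope, v.variant_id,
            )
            return EvidenceCall(Evidence.NE, f"{predictor}@{scope}")
        pair = _thresholds_from_coeffs(b0, b1, predictor, scope, p_lower, p_upper)
        return assign_evidence(score, pair)

    out: dict[str, EvidenceCall] = {}
    for v in evaluated:
        if v.scores.get(predictor) is None:
            out[v.variant_id] = EvidenceCall(Evidence.NE, f"{predictor}@missing")
            continue
        use_gene = mode == "GENE" or (mode == "COMBINED" and v.gene in eligible)
        if use_gene:
            pos, x, y = by_gene[v.gene]
            out[v.variant_id] = assign_one(v, pos, x, y, v.gene)
        else:
            out[v.variant_id] = assign_one(
                v, pooled_pos, pooled_x, pooled_y, GENERALIZED
            )
    return out


def confusion_counts(
    evidence: Mapping[str, EvidenceCall],
    classes: Mapping[str, ConsensusClass],
) -> ConfusionCounts:
    """Tally evidence calls against consensus classes.

    Both mappings must share the same variant keys; classes must already be
    restricted to B/LB and P/LP (excluded variants are filtered upstream).
    """
    if set(evidence) != set(classes):
        raise ValueError("evidence and classes must cover the same variants")
    tp = tn = fp = fn = ne = 0
    for vid, call in evidence.items():
        cls = classes[vid]
        if cls not in (ConsensusClass.BLB, ConsensusClass.PLP):
            raise ValueError(
                f"variant {vid!r} has excluded class {cls}; filter upstream"
            )
        ev = call.evidence
        if ev is Evidence.NE:
            ne += 1
        elif ev is Evidence.DE:
            if cls is ConsensusClass.PLP:
                tp += 1
            else:
                fp += 1
        else:  # BE
            if cls is ConsensusClass.BLB:
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, ne=ne)


def fisher_test_metric(
    a: ConfusionCounts, b: ConfusionCounts, metric: Literal["PPV", "NPV", "YR"]
) -> float:
    """Two-sided Fisher exact test for a metric difference between methods.

    The 2x2 tables compare the proportions whose ratios are the metrics:
    PPV -> [[tp_a, fp_a], [tp_b, fp_b]]; NPV -> [[tn_a, fn_a], [tn_b, fn_b]];
    YR -> [[assigned_a, ne_a], [assigned_b, ne_b]].  A degenerate table
    (some margin zero) yields p = 1 with a warning.
    """
    if metric == "PPV":
        table = [[a.tp, a.fp], [b.tp, b.fp]]
    elif metric == "NPV":
        table = [[a.tn, a.fn], [b.tn, b.fn]]
    elif metric == "YR":
        table = [[a.assigned, a.ne], [b.assigned, b.ne]]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    t = np.asarray(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn(
            f"degenerate 2x2 table for {metric}: {table}; p set to 1",
            stacklevel=2,
        )
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


def _encode(
    evidence: Mapping[str, EvidenceCall],
    classes: Mapping[str, ConsensusClass],
    order: Sequence[str],
) -> np.ndarray:
    """Per-variant (tp, tn, fp, fn) indicator matrix, shape (n, 4)."""
    out = np.zeros((len(order), 4))
    for i, vid in enumerate(order):
        ev = evidence[vid].evidence
        plp = classes[vid] is ConsensusClass.PLP
        if ev is Evidence.DE:
            out[i, 0 if plp else 2] = 1.0
        elif ev is Evidence.BE:
            out[i, 3 if plp else 1] = 1.0
    return out


def _opp_from_counts(
    tp: np.ndarray, tn: np.ndarray, fp: np.ndarray, fn: np.ndarray, total: int
) -> np.ndarray:
    """Vectorized OPP; NaN where PPV or NPV is undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = tp / (tp + fp)
        npv = tn / (tn + fn)
    yr = (tp + tn + fp + fn) / total
    return np.sqrt((ppv**2 + npv**2 + yr**2) / 3.0)


def permutation_test_opp(
    evidence_a: Mapping[str, EvidenceCall],
    evidence_b: Mapping[str, EvidenceCall],
    classes: Mapping[str, ConsensusClass],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Monte Carlo permutation test for an OPP difference between 2 methods.

    The observed statistic is |OPP_a - OPP_b|.  Each permutation swaps the
    two methods' evidence calls independently per variant with probability
    1/2 and recomputes the statistic; p = (#{permuted >= observed} + 1) /
    (n_perm + 1).  A permuted replicate with an undefined PPV or NPV
    contributes a zero difference (counted, logged) — negligible at
    realistic sizes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(evidence_a) != set(evidence_b) or set(evidence_a) != set(classes):
        raise ValueError("both methods and classes must cover the same variants")
    order = list(evidence_a)
    n = len(order)
    ind_a = _encode(evidence_a, classes, order)
    ind_b = _encode(evidence_b, classes, order)

    stats_a = performance(confusion_counts(evidence_a, classes))
    stats_b = performance(confusion_counts(evidence_b, classes))
    observed = abs(stats_a.opp - stats_b.opp)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    n_undefined = 0
    chunk = 512
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        swap = rng.random((m, n)) < 0.5
        keep = ~swap
        # counts: rows = permutations, cols = (tp, tn, fp, fn)
        counts_a = keep @ ind_a + swap @ ind_b
        counts_b = swap @ ind_a + keep @ ind_b
        opp_a = _opp_from_counts(*counts_a.T, n)
        opp_b = _opp_from_counts(*counts_b.T, n)
        diff = np.abs(opp_a - opp_b)
        bad = ~np.isfinite(diff)
        if bad.any():
            n_undefined += int(bad.sum())
            diff = np.where(bad, 0.0, diff)
        n_extreme += int((diff >= observed - 1e-15).sum())
    if n_undefined:
        logger.info(
            "permutation test: %d of %d replicates had undefined PPV/NPV, "
            "counted as zero difference", n_undefined, n_perm,
        )
    return (n_extreme + 1) / (n_perm + 1)


@dataclass(frozen=True)
class Rank:
    rank: int
    tied: bool = False


def rank_methods(
    stats: Mapping[str, PerformanceStats]
) -> dict[str, dict[str, Rank]]:
    """Descending ranks (1 = best) per statistic; ties share the smaller rank."""
    if len(stats) < 2:
        raise ValueError("need at least 2 methods to rank")
    out: dict[str, dict[str, Rank]] = {m: {} for m in stats}
    for metric in ("ppv", "npv", "yr", "opp"):
        values = {m: getattr(s, metric) for m, s in stats.items()}
        # competition ranking: rank = 1 + number of strictly better methods
        n_better = {
            m: sum(1 for w in values.values() if w > v) for m, v in values.items()
        }
        tie_counts = {v: sum(1 for w in values.values() if w == v) for v in values.values()}
        for m, v in values.items():
            out[m][metric] = Rank(rank=n_better[m] + 1, tied=tie_counts[v] > 1)
    return out
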