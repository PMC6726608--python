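"""End-to-end pipeline: consensus -> thresholds -> LOOCV -> statistics.

``run_pipeline`` orchestrates the full analysis from a variant table (and
optionally a raw submissions table), writes every output TSV plus a run
manifest, and returns the in-memory results.  Reruns with the same config
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .consensus import ConsensusClass, assign_consensus
from .evaluation import (
    ConfusionCounts,
    PerformanceStats,
    confusion_counts,
    fisher_test_metric,
    performance,
    permutation_test_opp,
    rank_methods,
    loocv_assign,
)
from .evidence import EvidenceCall, sift_polyphen_agreement
from .records import META_PREDICTORS
from .tableio import (
    read_submissions,
    read_variant_table,
    write_consensus_table,
    write_evidence_table,
    write_performance_table,
    write_tests_table,
    write_thresholds_table,
)
from .thresholds import (
    ThresholdCI,
    ThresholdPair,
    bootstrap_threshold_ci,
    gene_level_thresholds,
    generalized_thresholds,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger(__name__)

AGREEMENT_METHOD = "sift_polyphen2_agreement"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    Fixed analysis constants live here: the evidence probabilities (0.2 /
    0.8), the 10-per-class gene eligibility floor, 10,000 bootstrap
    replicates for 90% threshold CIs and 10,000 permutations for OPP
    comparisons.
    """

    variants_path: str
    output_dir: str
    submissions_path: str | None = None
    predictors: tuple[str, ...] = META_PREDICTORS
    mode: str = "GENE"
    p_lower: float = 0.2
    p_upper: float = 0.8
    min_per_class: int = 10
    n_boot: int = 10_000
    n_perm: int = 10_000
    ci_level: float = 0.90
    include_agreement: bool = True
    bootstrap_cis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_lower < self.p_upper < 1.0):
            raise ValueError(
                f"need 0 < p_lower < p_upper < 1, got "
                f"({self.p_lower}, {self.p_upper})"
            )
        if self.min_per_class < 1 or self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("min_per_class, n_boot and n_perm must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.mode not in ("GENE", "GENERALIZED", "COMBINED"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value config file; keyword args override keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "predictors" in raw and not isinstance(raw["predictors"], tuple):
            raw["predictors"] = tuple(raw["predictors"])
        return cls(**raw)


@dataclass
class PipelineReport:
    config: PipelineConfig
    counts: dict[str, int]
    thresholds: list[ThresholdPair]
    threshold_cis: dict[tuple[str, str], ThresholdCI]
    evidence: dict[str, dict[str, EvidenceCall]]
    confusion: dict[str, ConfusionCounts]
    stats: dict[str, PerformanceStats]
    output_files: dict[str, str] = field(default_factory=dict)


def _boot_seed(config: PipelineConfig, p_idx: int, s_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(100 + p_idx, s_idx))
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write all outputs.

    Stages: read -> (consensus if submissions given) -> filter to B/LB and
    P/LP -> gene-level + generalized thresholds (+ bootstrap CIs) -> LOOCV
    evidence -> confusion/performance/ranks -> Fisher and permutation
    tests -> manifest.  Every filtering stage's before/after counts go in
    the manifest and reconcile (input = retained + excluded).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    variants = read_variant_table(config.variants_path)
    counts["variants_read"] = len(variants)

    if config.submissions_path is not None:
        submissions = read_submissions(config.submissions_path)
        counts["submissions_read"] = len(submissions)
        consensus = assign_consensus(submissions)
        variants = [
            replace(v, consensus=consensus[v.variant_id].consensus)
            if v.variant_id in consensus
            else replace(v, consensus=ConsensusClass.EXCLUDED_EMPTY)
            for v in variants
        ]
        path = outdir / "consensus.tsv"
        write_consensus_table(consensus, path)
        outputs["consensus"] = str(path)

    if any(v.consensus is None for v in variants):
        raise ValueError(
            "variants lack consensus classes; provide a class column or a "
            "submissions table"
        )

    evaluated = [v for v in variants if v.is_blb or v.is_plp]
    counts["consensus_blb"] = sum(v.is_blb for v in evaluated)
    counts["consensus_plp"] = sum(v.is_plp for v in evaluated)
    counts["excluded_by_consensus"] = len(variants) - len(evaluated)
    assert counts["excluded_by_consensus"] + len(evaluated) == len(variants)

    # -- thresholds ---------------------------------------------------------
    thresholds: list[ThresholdPair] = []
    cis: dict[tuple[str, str], ThresholdCI] = {}
    for p_idx, predictor in enumerate(config.predictors):
        per_gene = gene_level_thresholds(
            evaluated, predictor, config.min_per_class, config.p_lower, config.p_upper
        )
        pooled = generalized_thresholds(
            evaluated, predictor, config.p_lower, config.p_upper
        )
        scoped = list(per_gene.values()) + [pooled]
        thresholds.extend(scoped)
        if config.bootstrap_cis:
            for s_idx, pair in enumerate(scoped):
                cis[(predictor, pair.scope)] = bootstrap_threshold_ci(
                    evaluated,
                    predictor,
                    pair.scope,
                    config.n_boot,
                    config.ci_level,
                    _boot_seed(config, p_idx, s_idx),
                    config.p_lower,
                    config.p_upper,
                )
    counts["threshold_sets"] = len(thresholds)
    path = outdir / "thresholds.tsv"
    write_thresholds_table(thresholds, path, cis)
    outputs["thresholds"] = str(path)

    # -- evidence via LOOCV (agreement comparator needs no fitting) ---------
    evidence: dict[str, dict[str, EvidenceCall]] = {}
    for predictor in config.predictors:
        evidence[predictor] = loocv_assign(
            evaluated,
            predictor,
            config.mode,
            config.p_lower,
            config.p_upper,
            config.min_per_class,
        )
    if config.include_agreement:
        evidence[AGREEMENT_METHOD] = {
            v.variant_id: sift_polyphen_agreement(
                v.scores.get("sift"), v.polyphen2_call
            )
            for v in evaluated
        }
    path = outdir / "evidence.tsv"
    write_evidence_table(evidence, evaluated, path)
    outputs["evidence"] = str(path)

    # -- performance --------------------------------------------------------
    classes = {v.variant_id: v.consensus for v in evaluated}
    confusion = {m: confusion_counts(ev, classes) for m, ev in evidence.items()}
    stats = {m: performance(c) for m, c in confusion.items()}
    ranks = rank_methods(stats) if len(stats) >= 2 else {}
    perf_rows = []
    for m in evidence:
        c, s = confusion[m], stats[m]
        row = {
            "method": m,
            "mode": config.mode if m != AGREEMENT_METHOD else "agreement",
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn, "ne": c.ne,
            "ppv": round(s.ppv, 3), "npv": round(s.npv, 3),
            "yr": round(s.yr, 3), "opp": round(s.opp, 3),
        }
        if ranks:
            for metric in ("ppv", "npv", "yr", "opp"):
                row[f"rank_{metric}"] = ranks[m][metric].rank
        perf_rows.append(row)
    path = outdir / "performance.tsv"
    write_performance_table(perf_rows, path)
    outputs["performance"] = str(path)

    # -- pairwise tests ------------------------------------------------------
    test_rows = []
    methods = list(evidence)
    for k, (ma, mb) in enumerate(combinations(methods, 2)):
        for metric in ("PPV", "NPV", "YR"):
            test_rows.append(
                {
                    "method_a": ma, "method_b": mb, "metric": metric,
                    "p_value": fisher_test_metric(confusion[ma], confusion[mb], metric),
                    "test": "fisher_exact_two_sided",
                }
            )
        p_perm = permutation_test_opp(
            evidence[ma],
            evidence[mb],
            classes,
            config.n_perm,
            np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(200, k))),
        )
        test_rows.append(
            {
                "method_a": ma, "method_b": mb, "metric": "OPP",
                "p_value": p_perm,
                "test": f"monte_carlo_permutation_pairwise_n{config.n_perm}",
            }
        )
    path = outdir / "pairwise_tests.tsv"
    write_tests_table(test_rows, path)
    outputs["tests"] = str(path)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "evicalib": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = str(path)

    return PipelineReport(
        config=config,
        counts=counts,
        thresholds=thresholds,
        threshold_cis=cis,
        evidence=evidence,
        confusion=confusion,
        stats=stats,
        output_files=outputs,
    )
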