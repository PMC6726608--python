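"""Gene-stratified synthetic variant cohorts with known score-risk laws.

The generator emulates the structure of a ClinVar/dbNSFP-style evaluation
set: a list of genes, each with its own number of variants, pathogenic
prevalence, and per-predictor logistic score-risk relation; per-predictor
missingness applied independently of class; and per-variant submitter call
lists to exercise the consensus rules.

Within a gene, each predictor's scores are drawn from class-conditional
equal-variance Gaussians.  For a two-component equal-variance mixture the
posterior log-odds of the pathogenic class is *linear* in the score, so
every predictor follows an exactly logistic relation

    logit P(pathogenic | x) = beta0 + beta1 * x

with beta1 = (mu1 - mu0) / sd^2 and beta0 fixed by the prevalence and the
midpoint (mu0 + mu1) / 2.  This gives closed-form true thresholds for any
probability cutoff — the analytic truth the calibration tests recover.

One master seed is split into named substreams (classes, scores,
missingness, submissions, polyphen) so that adding or dropping one
component never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logit as _logit

from .consensus import ConsensusClass, SubmissionRecord
from .records import PREDICTORS, VariantRecord

__all__ = [
    "PredictorModel",
    "GeneSpec",
    "SimConfig",
    "ConfigError",
    "generate_variant_table",
    "generate_submissions",
    "default_study_config",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


_STREAMS = {
    "classes": 0,
    "scores": 1,
    "missingness": 2,
    "submissions": 3,
    "polyphen": 4,
}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class PredictorModel:
    """True score-risk law of one predictor within one gene.

    ``beta0``/``beta1`` are the logit-scale intercept and slope; ``sd`` is
    the class-conditional score standard deviation; ``support`` clips drawn
    scores to a realistic range (None = unbounded on that side).
    """

    beta0: float
    beta1: float
    sd: float
    support: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta0) and math.isfinite(self.beta1)):
            raise ConfigError(
                f"non-finite coefficients ({self.beta0}, {self.beta1})"
            )
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ConfigError(f"sd must be positive and finite, got {self.sd}")

    @classmethod
    def from_midpoint(
        cls,
        beta1: float,
        midpoint: float,
        prevalence: float,
        sd: float,
        support: tuple[float | None, float | None] = (None, None),
    ) -> "PredictorModel":
        """Build a law from its probability-0.5 score and slope.

        ``midpoint`` is the score at predicted probability 1/2 once the
        gene's prevalence is folded in: beta0 = logit(prev) - beta1 * midpoint.
        """
        p = min(max(prevalence, 1e-9), 1.0 - 1e-9)
        return cls(
            beta0=float(_logit(p) - beta1 * midpoint),
            beta1=float(beta1),
            sd=float(sd),
            support=support,
        )

    def class_means(self, prevalence: float) -> tuple[float, float]:
        """(mu_benign, mu_pathogenic) realizing this law at this prevalence."""
        p = min(max(prevalence, 1e-9), 1.0 - 1e-9)
        if self.beta1 == 0.0:
            lo, hi = self.support
            center = 0.0 if lo is None or hi is None else (lo + hi) / 2.0
            return center, center
        m = (_logit(p) - self.beta0) / self.beta1
        delta = self.beta1 * self.sd * self.sd
        return m - delta / 2.0, m + delta / 2.0


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    n_variants: int
    prevalence: float
    predictors: dict[str, PredictorModel]
    anchor: str = "revel"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ConfigError("gene symbol must be non-empty")
        if self.n_variants < 1:
            raise ConfigError(f"{self.symbol}: n_variants must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigError(f"{self.symbol}: prevalence must be in [0, 1]")
        if not self.predictors:
            raise ConfigError(f"{self.symbol}: needs at least one predictor")
        if self.anchor not in self.predictors:
            raise ConfigError(
                f"{self.symbol}: anchor {self.anchor!r} not among predictors"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort.

    ``missingness`` maps predictor name (plus optionally "polyphen2") to
    the probability that a score is masked; every predictor appearing in a
    gene spec must have a rate.  ``n_submitters`` and ``call_noise``
    control the simulated per-variant submitter call lists;
    ``polyphen_error`` is the chance a PolyPhen2 categorical call lands on
    the wrong side of the truth.
    """

    genes: tuple[GeneSpec, ...]
    missingness: dict[str, float] = field(default_factory=dict)
    n_submitters: int = 3
    call_noise: float = 0.1
    polyphen_error: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError("empty gene list")
        used = {p for g in self.genes for p in g.predictors}
        for p in sorted(used):
            if p not in self.missingness:
                raise ConfigError(f"no missingness rate configured for {p!r}")
        for p, rate in self.missingness.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"missingness rate for {p!r} outside [0, 1]: {rate}")
        if self.n_submitters < 1:
            raise ConfigError("n_submitters must be >= 1")
        if not (0.0 <= self.call_noise <= 1.0):
            raise ConfigError(f"call_noise outside [0, 1]: {self.call_noise}")
        if not (0.0 <= self.polyphen_error <= 1.0):
            raise ConfigError(f"polyphen_error outside [0, 1]: {self.polyphen_error}")


def _clip(x: np.ndarray, support: tuple[float | None, float | None]) -> np.ndarray:
    lo, hi = support
    if lo is None and hi is None:
        return x
    return np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)


def generate_variant_table(config: SimConfig) -> list[VariantRecord]:
    """Draw the full variant table; deterministic given the config seed.

    Per gene: classes are Bernoulli(prevalence); each configured
    predictor's score is drawn from its class-conditional Gaussian (then
    clipped to its support), which realizes the configured logistic law
    exactly; missingness masks are drawn from an independent stream at the
    per-predictor rates.  A categorical PolyPhen2 call is attached whenever
    a gene configures the "sift" predictor (the agreement comparator needs
    both inputs).
    """
    rng_class = _substream(config.seed, "classes")
    rng_score = _substream(config.seed, "scores")
    rng_miss = _substream(config.seed, "missingness")
    rng_pp2 = _substream(config.seed, "polyphen")

    pp2_rate = config.missingness.get("polyphen2", 0.0)
    records: list[VariantRecord] = []
    for gene in config.genes:
        n = gene.n_variants
        classes = rng_class.random(n) < gene.prevalence
        scores: dict[str, np.ndarray] = {}
        masks: dict[str, np.ndarray] = {}
        for name in PREDICTORS:
            model = gene.predictors.get(name)
            if model is None:
                continue
            mu0, mu1 = model.class_means(gene.prevalence)
            mu = np.where(classes, mu1, mu0)
            scores[name] = _clip(rng_score.normal(mu, model.sd), model.support)
            masks[name] = rng_miss.random(n) < config.missingness[name]

        polyphen: list[str | None] = [None] * n
        if "sift" in gene.predictors:
            err = rng_pp2.random(n) < config.polyphen_error
            kind = rng_pp2.random(n)  # splits probably vs possibly damaging
            pp2_missing = rng_miss.random(n) < pp2_rate
            for i in range(n):
                damaging_side = bool(classes[i]) != bool(err[i])
                if pp2_missing[i]:
                    polyphen[i] = None
                elif damaging_side:
                    polyphen[i] = (
                        "probably_damaging" if kind[i] < 0.7 else "possibly_damaging"
                    )
                else:
                    polyphen[i] = "benign"

        for i in range(n):
            rec_scores: dict[str, float | None] = {}
            for name, vals in scores.items():
                rec_scores[name] = None if masks[name][i] else float(vals[i])
            records.append(
                VariantRecord(
                    variant_id=f"{gene.symbol}:v{i:05d}",
                    gene=gene.symbol,
                    consensus=(
                        ConsensusClass.PLP if classes[i] else ConsensusClass.BLB
                    ),
                    scores=rec_scores,
                    polyphen2_call=polyphen[i],
                )
            )
    return records


_TRUTH_CALLS = {ConsensusClass.BLB: ("B", "LB"), ConsensusClass.PLP: ("LP", "P")}


def generate_submissions(
    variants: Sequence[VariantRecord], config: SimConfig
) -> list[SubmissionRecord]:
    """Simulate per-variant submitter call lists.

    Each of ``n_submitters`` submitters calls the truth-consistent category
    (uniformly B or LB for a benign truth, LP or P for a pathogenic one)
    with probability 1 - call_noise; otherwise the call is VUS or a
    uniformly chosen label of the opposing category, each with probability
    call_noise / 2.  Deterministic given the config seed.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    if not (0.0 <= config.call_noise <= 1.0):
        raise ConfigError(f"call_noise outside [0, 1]: {config.call_noise}")
    rng = _substream(config.seed, "submissions")
    noise = config.call_noise
    out: list[SubmissionRecord] = []
    for v in variants:
        if v.consensus not in _TRUTH_CALLS:
            raise ValueError(
                f"variant {v.variant_id!r} has no true class to submit against"
            )
        consistent = _TRUTH_CALLS[v.consensus]
        opposing = _TRUTH_CALLS[
            ConsensusClass.PLP if v.consensus is ConsensusClass.BLB else ConsensusClass.BLB
        ]
        for j in range(config.n_submitters):
            u = rng.random()
            pick = rng.random()  # consumed either way to keep streams aligned
            if u < 1.0 - noise:
                call = consistent[int(pick < 0.5)]
            elif u < 1.0 - noise / 2.0:
                call = "VUS"
            else:
                call = opposing[int(pick < 0.5)]
            out.append(
                SubmissionRecord(
                    variant_id=v.variant_id,
                    submitter=f"lab{j + 1}",
                    classification=call,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Default study conditions: a 20-gene cohort shaped like a curated ClinVar
# missense evaluation set (2,153 variants; clinically actionable genes; the
# observed per-predictor missingness rates of a dbNSFP extract).

_STUDY_GENES: tuple[tuple[str, int, float, float], ...] = (
    # (symbol, n_variants, pathogenic prevalence, midpoint offset); the
    # offsets span roughly +/-0.15 on unit-scale predictors, mirroring the
    # wide between-gene variation curated evaluation sets exhibit
    ("ATM", 200, 0.50, 0.000),
    ("ATP7B", 90, 0.42, 0.075),
    ("BRCA1", 250, 0.55, -0.100),
    ("BRCA2", 280, 0.60, 0.125),
    ("CFTR", 145, 0.45, -0.050),
    ("COL3A1", 60, 0.50, 0.025),
    ("FBN1", 135, 0.38, -0.150),
    ("KCNH2", 75, 0.52, 0.050),
    ("MLH1", 88, 0.65, 0.100),
    ("MSH2", 110, 0.48, -0.075),
    ("MSH6", 85, 0.55, 0.150),
    ("MUTYH", 55, 0.40, -0.125),
    ("MYBPC3", 92, 0.50, 0.000),
    ("NF1", 118, 0.62, 0.050),
    ("NSD1", 40, 0.45, -0.025),
    ("RET", 65, 0.58, 0.075),
    ("RYR2", 70, 0.35, -0.050),
    ("SCN5A", 100, 0.50, 0.100),
    ("TP53", 45, 0.44, -0.100),
    ("TSC2", 50, 0.56, 0.025),
)

#: Observed fraction of missing scores per predictor in a dbNSFP extract.
STUDY_MISSINGNESS = {
    "sift": 0.051,
    "polyphen2": 0.006,
    "metasvm": 0.001,
    "eigen": 0.021,
    "cadd": 0.0,
    "revel": 0.0,
    "bayesdel": 0.0,
}


def _study_predictors(i: int, prevalence: float, offset: float) -> dict[str, PredictorModel]:
    mk = PredictorModel.from_midpoint
    return {
        "revel": mk(20.0 + (i % 5), 0.5 + offset, prevalence, 0.12, (0.0, 1.0)),
        "bayesdel": mk(14.0 + (i % 4), 0.12 + offset, prevalence, 0.15, (-1.3, 0.8)),
        "cadd": mk(0.38 + 0.02 * (i % 3), 20.0 + 40.0 * offset, prevalence, 6.0, (0.0, 60.0)),
        "metasvm": mk(4.5 + 0.3 * (i % 4), 2.0 * offset, prevalence, 0.5),
        "eigen": mk(6.5 + 0.4 * (i % 3), 0.5 + 2.0 * offset, prevalence, 0.35),
        "sift": mk(-6.0, 0.35 + offset, prevalence, 0.25, (0.0, 1.0)),
    }


def default_study_config(seed: int = 0) -> SimConfig:
    """The cohort the analysis scripts and acceptance checks simulate.

    20 clinically actionable genes, 2,153 variants in total, pathogenic
    prevalence 0.35-0.65 per gene, every gene comfortably above the
    10 B/LB + 10 P/LP eligibility floor; all 6 numeric predictors plus the
    PolyPhen2 categorical call; per-predictor missingness at the observed
    dbNSFP-extract rates.
    """
    genes = tuple(
        GeneSpec(
            symbol=sym,
            n_variants=n,
            prevalence=prev,
            predictors=_study_predictors(i, prev, off),
            anchor="revel",
        )
        for i, (sym, n, prev, off) in enumerate(_STUDY_GENES)
    )
    return SimConfig(
        genes=genes,
        missingness=dict(STUDY_MISSINGNESS),
        n_submitters=3,
        call_noise=0.1,
        polyphen_error=0.1,
        seed=seed,
    )
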