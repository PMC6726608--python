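"""Generator calibration: determinism, missingness, logistic law, submissions."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from evicalib import (
    ConfigError,
    ConsensusClass,
    GeneSpec,
    PredictorModel,
    SimConfig,
    assign_consensus,
    default_study_config,
    generate_submissions,
    generate_variant_table,
)
from conftest import single_gene_config
from helpers import exact_consensus_recovery_rate


def test_seed_determinism_byte_identical(tmp_path):
    from evicalib.tableio import write_variant_table

    cfg = default_study_config(seed=42)
    v1 = generate_variant_table(cfg)
    v2 = generate_variant_table(cfg)
    assert v1 == v2
    write_variant_table(v1, tmp_path / "a.tsv")
    write_variant_table(v2, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_different_seeds_differ():
    a = generate_variant_table(default_study_config(seed=1))
    b = generate_variant_table(default_study_config(seed=2))
    assert a != b


def test_study_cohort_shape():
    variants = generate_variant_table(default_study_config(seed=0))
    assert len(variants) == 2153
    assert len({v.gene for v in variants}) == 20


def test_missingness_rate_matches_configuration():
    """Observed SIFT missingness within 3 MC standard errors of 5.1%."""
    cfg = single_gene_config(0.0, 3.0, 20000, seed=3, predictor="sift")
    cfg = SimConfig(
        genes=cfg.genes, missingness={"sift": 0.051}, seed=3
    )
    variants = generate_variant_table(cfg)
    rate = 0.051
    observed = np.mean([v.scores.get("sift") is None for v in variants])
    se = np.sqrt(rate * (1 - rate) / len(variants))
    assert abs(observed - rate) < 3 * se


def test_anchor_score_follows_logistic_law_in_deciles():
    """Per-decile pathogenic fraction matches expit(b0 + b1 x) within 3 SE."""
    beta0, beta1 = 0.0, 2.773
    cfg = single_gene_config(beta0, beta1, 50_000, prevalence=0.5, sd=0.6, seed=4)
    variants = generate_variant_table(cfg)
    x = np.array([v.scores["metasvm"] for v in variants])
    y = np.array([v.is_plp for v in variants], dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, 11))
    for i in range(10):
        sel = (x >= edges[i]) & (x < edges[i + 1]) if i < 9 else (x >= edges[i])
        n = sel.sum()
        expected = expit(beta0 + beta1 * x[sel].mean())
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(y[sel].mean() - expected) < 3 * se + 0.01, f"decile {i}"


def test_class_balance_converges_to_prevalence():
    prev = 0.42
    cfg = single_gene_config(0.0, 3.0, 50_000, prevalence=prev, seed=5)
    variants = generate_variant_table(cfg)
    frac = np.mean([v.is_plp for v in variants])
    se = np.sqrt(prev * (1 - prev) / len(variants))
    assert abs(frac - prev) < 3 * se


def test_missingness_independent_of_class():
    """Chi-square of (missing x class) non-significant in >=18 of 20 seeds."""
    nonsig = 0
    for seed in range(20):
        cfg = single_gene_config(0.0, 3.0, 4000, seed=seed, predictor="eigen")
        cfg = SimConfig(genes=cfg.genes, missingness={"eigen": 0.1}, seed=seed)
        variants = generate_variant_table(cfg)
        missing = np.array([v.scores.get("eigen") is None for v in variants])
        plp = np.array([v.is_plp for v in variants])
        table = np.array(
            [
                [(missing & plp).sum(), (missing & ~plp).sum()],
                [(~missing & plp).sum(), (~missing & ~plp).sum()],
            ]
        )
        if chi2_contingency(table).pvalue > 0.01:
            nonsig += 1
    assert nonsig >= 18


def test_zero_noise_submissions_match_truth():
    cfg = single_gene_config(0.0, 3.0, 200, seed=6)
    cfg = SimConfig(
        genes=cfg.genes, missingness={"metasvm": 0.0}, call_noise=0.0, seed=6
    )
    variants = generate_variant_table(cfg)
    subs = generate_submissions(variants, cfg)
    truth = {v.variant_id: v.consensus for v in variants}
    for s in subs:
        expected = ("B", "LB") if truth[s.variant_id] is ConsensusClass.BLB else ("LP", "P")
        assert s.classification in expected


def test_submissions_seed_determinism():
    cfg = single_gene_config(0.0, 3.0, 50, seed=7)
    variants = generate_variant_table(cfg)
    assert generate_submissions(variants, cfg) == generate_submissions(variants, cfg)


def test_consensus_recovery_matches_exact_enumeration():
    """Noise 0.2: consensus==truth rate matches the multinomial enumeration."""
    n, noise, n_sub = 10_000, 0.2, 3
    cfg = single_gene_config(0.0, 3.0, n, seed=8)
    cfg = SimConfig(
        genes=cfg.genes,
        missingness={"metasvm": 0.0},
        n_submitters=n_sub,
        call_noise=noise,
        seed=8,
    )
    variants = generate_variant_table(cfg)
    consensus = assign_consensus(generate_submissions(variants, cfg))
    truth = {v.variant_id: v.consensus for v in variants}
    observed = np.mean(
        [consensus[vid].consensus is truth[vid] for vid in truth]
    )
    expected = exact_consensus_recovery_rate(n_sub, noise)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 3 * se


def test_substreams_isolated():
    """Changing submitter count must not perturb scores or classes."""
    cfg_a = default_study_config(seed=9)
    from dataclasses import replace

    cfg_b = replace(cfg_a, n_submitters=6)
    assert generate_variant_table(cfg_a) == generate_variant_table(cfg_b)


@pytest.mark.parametrize(
    "bad",
    [
        dict(genes=()),
        dict(call_noise=1.5),
        dict(n_submitters=0),
    ],
)
def test_config_validation(bad):
    base = default_study_config(seed=0)
    from dataclasses import replace

    with pytest.raises(ConfigError):
        replace(base, **bad)


def test_nonfinite_beta_rejected():
    with pytest.raises(ConfigError, match="non-finite"):
        PredictorModel(beta0=float("nan"), beta1=1.0, sd=1.0)


def test_missing_rate_required_for_every_predictor():
    gene = GeneSpec(
        symbol="G",
        n_variants=5,
        prevalence=0.5,
        predictors={"revel": PredictorModel(0.0, 5.0, 0.1, (0.0, 1.0))},
        anchor="revel",
    )
    with pytest.raises(ConfigError, match="revel"):
        SimConfig(genes=(gene,), missingness={})
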