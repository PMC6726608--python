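"""Threshold inversion, gene eligibility, pooling and bootstrap CIs."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from evicalib import (
    DegenerateFitError,
    FirthFit,
    GENERALIZED,
    bootstrap_threshold_ci,
    derive_thresholds,
    fit_firth_logistic,
    gene_level_thresholds,
    generalized_thresholds,
    generate_variant_table,
)
from conftest import single_gene_config


def _fit(beta0, beta1):
    return FirthFit(beta0, beta1, 0.1, 0.1, 0.0, True, 1, 10, 10)


def test_symmetric_inversion():
    pair = derive_thresholds(_fit(0.0, 1.0))
    assert pair.t_be == pytest.approx(math.log(0.25), abs=1e-12)
    assert pair.t_de == pytest.approx(-math.log(0.25), abs=1e-12)
    assert pair.orientation == "positive"


def test_unit_interval_construction():
    pair = derive_thresholds(_fit(-1.386294, 2.772589))
    assert pair.t_be == pytest.approx(0.0, abs=1e-5)
    assert pair.t_de == pytest.approx(1.0, abs=1e-5)


def test_negative_slope_flagged_not_swapped():
    """A SIFT-like fit keeps its probability-side solutions, flagged reversed."""
    pair = derive_thresholds(_fit(0.0, -1.0))
    assert pair.orientation == "negative"
    # the benign-side solution is numerically above the deleterious-side one
    assert pair.t_be == pytest.approx(-math.log(0.25), abs=1e-12)
    assert pair.t_de == pytest.approx(math.log(0.25), abs=1e-12)
    assert expit(0.0 - 1.0 * pair.t_be) == pytest.approx(0.2, abs=1e-10)


@pytest.mark.parametrize("beta0, beta1", [(0.3, 2.0), (-2.0, 0.7), (5.0, -3.0)])
def test_inversion_reproduces_probabilities_exactly(beta0, beta1):
    pair = derive_thresholds(_fit(beta0, beta1))
    assert expit(beta0 + beta1 * pair.t_be) == pytest.approx(0.2, abs=1e-10)
    assert expit(beta0 + beta1 * pair.t_de) == pytest.approx(0.8, abs=1e-10)


def test_degenerate_slope_rejected():
    with pytest.raises(DegenerateFitError, match="uninformative"):
        derive_thresholds(_fit(0.0, 0.0))


def test_invalid_probability_order_rejected():
    with pytest.raises(ValueError):
        derive_thresholds(_fit(0.0, 1.0), p_lower=0.8, p_upper=0.2)


def test_gene_eligibility_boundary():
    """A gene with 9 B/LB consensus variants is omitted; 10/10 is kept."""
    rng = np.random.default_rng(0)
    variants = []
    cfg9 = single_gene_config(0.0, 3.0, 400, prevalence=0.5, seed=1, gene="BIG")
    variants += generate_variant_table(cfg9)
    # gene with exactly 9 B/LB and 200 P/LP
    from evicalib import ConsensusClass, VariantRecord

    for i in range(209):
        cls = ConsensusClass.BLB if i < 9 else ConsensusClass.PLP
        score = rng.normal(-1.0 if cls is ConsensusClass.BLB else 1.0)
        variants.append(
            VariantRecord(f"SPARSE:v{i}", "SPARSE", cls, {"metasvm": float(score)})
        )
    result = gene_level_thresholds(variants, "metasvm")
    assert "BIG" in result and "SPARSE" not in result


def test_identical_genes_get_identical_thresholds():
    cfg = single_gene_config(0.0, 3.0, 300, seed=5, gene="G1")
    variants = generate_variant_table(cfg)
    from dataclasses import replace

    cloned = [
        replace(v, variant_id=v.variant_id.replace("G1", "G2"), gene="G2")
        for v in variants
    ]
    result = gene_level_thresholds(variants + cloned, "metasvm")
    assert result["G1"].t_be == pytest.approx(result["G2"].t_be, abs=1e-12)
    assert result["G1"].t_de == pytest.approx(result["G2"].t_de, abs=1e-12)


def test_generalized_homogeneous_limit_and_permutation_invariance():
    """Pooling genes drawn from one common law reproduces the gene-level fit."""
    cfg = single_gene_config(0.0, 3.0, 2000, seed=2)
    variants = generate_variant_table(cfg)
    pooled = generalized_thresholds(variants, "metasvm")
    per_gene = gene_level_thresholds(variants, "metasvm")["GENE1"]
    assert pooled.scope == GENERALIZED
    assert pooled.t_be == pytest.approx(per_gene.t_be, abs=1e-12)
    assert pooled.t_de == pytest.approx(per_gene.t_de, abs=1e-12)
    shuffled = list(reversed(variants))
    again = generalized_thresholds(shuffled, "metasvm")
    assert again.t_be == pytest.approx(pooled.t_be, abs=1e-12)


def test_generalized_lies_between_divergent_gene_fits():
    """Pooling two genes with shifted intercepts lands between them, and
    matches a direct pooled-fit oracle."""
    cfg_a = single_gene_config(-2.0, 3.0, 1500, seed=3, gene="GA")
    cfg_b = single_gene_config(2.0, 3.0, 1500, seed=4, gene="GB")
    va = generate_variant_table(cfg_a)
    vb = generate_variant_table(cfg_b)
    pair_a = gene_level_thresholds(va, "metasvm")["GA"]
    pair_b = gene_level_thresholds(vb, "metasvm")["GB"]
    pooled = generalized_thresholds(va + vb, "metasvm")
    lo, hi = sorted((pair_a.t_de, pair_b.t_de))
    assert lo <= pooled.t_de <= hi
    # independent oracle: fit the concatenated arrays directly
    from evicalib.records import split_scores_labels

    x, y = split_scores_labels(va + vb, "metasvm")
    fit = fit_firth_logistic(x, y)
    assert pooled.t_de == pytest.approx((logit(0.8) - fit.beta0) / fit.beta1, abs=1e-12)


def test_bootstrap_seed_determinism():
    cfg = single_gene_config(0.0, 3.0, 200, seed=6)
    variants = generate_variant_table(cfg)
    ci1 = bootstrap_threshold_ci(variants, "metasvm", "GENE1", n_boot=50, seed=9)
    ci2 = bootstrap_threshold_ci(variants, "metasvm", "GENE1", n_boot=50, seed=9)
    assert ci1 == ci2
    assert ci1.n_boot_used <= ci1.n_boot_requested


def test_bootstrap_ci_narrows_with_sample_size():
    small = generate_variant_table(single_gene_config(0.0, 3.0, 200, seed=7))
    large = generate_variant_table(single_gene_config(0.0, 3.0, 5000, seed=7))
    ci_small = bootstrap_threshold_ci(small, "metasvm", "GENE1", n_boot=100, seed=1)
    ci_large = bootstrap_threshold_ci(large, "metasvm", "GENE1", n_boot=100, seed=1)
    width = lambda ci: ci.de_upper - ci.de_lower
    assert width(ci_large) < width(ci_small)


def test_threshold_recovery_on_synthetic_gene():
    """n=5000 fit recovers the analytic (logit(p) - b0)/b1 within 0.02.

    The law is a unit-interval meta-predictor-like score (class-conditional
    sd 0.12, slope 20 per score unit).
    """
    beta1 = 20.0
    beta0 = float(logit(0.45) - beta1 * 0.5)
    variants = generate_variant_table(
        single_gene_config(beta0, beta1, 5000, prevalence=0.45, sd=0.12, seed=8)
    )
    pair = gene_level_thresholds(variants, "metasvm")["GENE1"]
    assert pair.t_be == pytest.approx((logit(0.2) - beta0) / beta1, abs=0.02)
    assert pair.t_de == pytest.approx((logit(0.8) - beta0) / beta1, abs=0.02)
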