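"""LOOCV integrity, confusion statistics, Fisher and permutation tests."""

import numpy as np
import pytest
from evicalib import (
    ConfusionCounts,
    ConsensusClass,
    Evidence,
    EvidenceCall,
    VariantRecord,
    assign_evidence,
    confusion_counts,
    derive_thresholds,
    fisher_test_metric,
    fit_firth_logistic,
    loocv_assign,
    opp_rms,
    performance,
    permutation_test_opp,
    rank_methods,
)
from conftest import single_gene_config
from evicalib import generate_variant_table


def _ev(e):
    return EvidenceCall(Evidence(e), "test")


def test_confusion_direct_tally():
    evidence = {"v1": _ev("DE"), "v2": _ev("BE"), "v3": _ev("NE")}
    classes = {
        "v1": ConsensusClass.PLP,
        "v2": ConsensusClass.BLB,
        "v3": ConsensusClass.PLP,
    }
    c = confusion_counts(evidence, classes)
    assert (c.tp, c.tn, c.fp, c.fn, c.ne) == (1, 1, 0, 0, 1)
    assert c.total == 3


def test_confusion_all_ne():
    evidence = {f"v{i}": _ev("NE") for i in range(5)}
    classes = {f"v{i}": ConsensusClass.BLB for i in range(5)}
    c = confusion_counts(evidence, classes)
    assert (c.tp, c.tn, c.fp, c.fn, c.ne) == (0, 0, 0, 0, 5)


def test_confusion_matches_recount_oracle():
    """1,000 random calls equal an independent recount."""
    rng = np.random.default_rng(0)
    evs = rng.choice(["BE", "NE", "DE"], size=1000)
    cls = rng.choice(["BLB", "PLP"], size=1000)
    evidence = {f"v{i}": _ev(e) for i, e in enumerate(evs)}
    classes = {f"v{i}": ConsensusClass(c) for i, c in enumerate(cls)}
    c = confusion_counts(evidence, classes)
    # longhand recount
    tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0, "ne": 0}
    for e, k in zip(evs, cls):
        if e == "NE":
            tally["ne"] += 1
        elif e == "DE":
            tally["tp" if k == "PLP" else "fp"] += 1
        else:
            tally["tn" if k == "BLB" else "fn"] += 1
    assert (c.tp, c.tn, c.fp, c.fn, c.ne) == tuple(tally.values())


def test_confusion_rejects_excluded_class():
    with pytest.raises(ValueError, match="excluded"):
        confusion_counts(
            {"v1": _ev("NE")}, {"v1": ConsensusClass.EXCLUDED_CONFLICT}
        )


def test_performance_perfect_classifier():
    s = performance(ConfusionCounts(10, 10, 0, 0, 0))
    assert (s.ppv, s.npv, s.yr, s.opp) == (1.0, 1.0, 1.0, 1.0)


def test_performance_undefined_statistics_raise():
    with pytest.raises(ValueError, match="PPV"):
        performance(ConfusionCounts(0, 5, 0, 2, 3))
    with pytest.raises(ValueError, match="NPV"):
        performance(ConfusionCounts(5, 0, 2, 0, 3))


def test_opp_bounded_by_components():
    rng = np.random.default_rng(1)
    for ppv, npv, yr in rng.random((200, 3)):
        o = opp_rms(ppv, npv, yr)
        assert min(ppv, npv, yr) - 1e-12 <= o <= max(ppv, npv, yr) + 1e-12


def test_fisher_identical_counts_p_one():
    c = ConfusionCounts(50, 40, 5, 4, 10)
    assert fisher_test_metric(c, c, "PPV") == pytest.approx(1.0)


def test_fisher_extreme_table_exact_value():
    """PPV table [[10,0],[0,10]]: p = 2/C(20,10) by hypergeometric enumeration."""
    a = ConfusionCounts(10, 5, 0, 5, 0)
    b = ConfusionCounts(0, 5, 10, 5, 0)
    assert fisher_test_metric(a, b, "PPV") == pytest.approx(2 / 184756, rel=1e-9)


def test_fisher_symmetric_in_methods():
    a = ConfusionCounts(50, 40, 5, 4, 10)
    b = ConfusionCounts(45, 42, 8, 3, 11)
    for metric in ("PPV", "NPV", "YR"):
        assert fisher_test_metric(a, b, metric) == pytest.approx(
            fisher_test_metric(b, a, metric)
        )


def test_fisher_degenerate_margin_warns_p_one():
    a = ConfusionCounts(0, 5, 0, 3, 10)
    b = ConfusionCounts(0, 6, 0, 2, 10)
    with pytest.warns(UserWarning, match="degenerate"):
        assert fisher_test_metric(a, b, "PPV") == 1.0


def _random_instance(n, seed):
    rng = np.random.default_rng(seed)
    classes = {
        f"v{i}": ConsensusClass(c)
        for i, c in enumerate(rng.choice(["BLB", "PLP"], size=n))
    }
    ev = {
        f"v{i}": _ev(e) for i, e in enumerate(rng.choice(["BE", "NE", "DE"], size=n))
    }
    return classes, ev


def test_permutation_identical_methods_p_one():
    classes, ev = _random_instance(100, 2)
    assert permutation_test_opp(ev, ev, classes, n_perm=200, seed=0) == 1.0


def test_permutation_seed_determinism():
    classes, ev_a = _random_instance(100, 3)
    _, ev_b = _random_instance(100, 4)
    p1 = permutation_test_opp(ev_a, ev_b, classes, n_perm=300, seed=5)
    p2 = permutation_test_opp(ev_a, ev_b, classes, n_perm=300, seed=5)
    assert p1 == p2
    assert 0.0 < p1 <= 1.0


def test_rank_methods_descending_with_ties():
    from evicalib import PerformanceStats

    mk = lambda o: PerformanceStats(ppv=o, npv=o, yr=o, opp=o)
    stats = {"A": mk(0.908), "B": mk(0.907), "C": mk(0.871)}
    ranks = rank_methods(stats)
    assert [ranks[m]["opp"].rank for m in "ABC"] == [1, 2, 3]
    tied = rank_methods({"A": mk(0.9), "B": mk(0.9)})
    assert tied["A"]["opp"].rank == tied["B"]["opp"].rank == 1
    assert tied["A"]["opp"].tied and tied["B"]["opp"].tied


# ---------------------------------------------------------------------------
# LOOCV


def test_loocv_missing_score_gets_no_evidence(study_variants):
    missing = [
        v for v in study_variants if v.scores.get("eigen") is None and v.consensus.included
    ]
    assert missing, "study cohort should contain missing eigen scores"
    out = loocv_assign(study_variants, "eigen", "GENE")
    for v in missing:
        assert out[v.variant_id].evidence is Evidence.NE


def test_loocv_duplicate_invariance():
    """With a duplicated variant present, leaving one copy out changes nothing."""
    variants = generate_variant_table(single_gene_config(0.0, 3.0, 120, seed=9))
    from dataclasses import replace

    dup = replace(variants[0], variant_id="GENE1:dup")
    cohort = variants + [dup]
    loo = loocv_assign(cohort, "metasvm", "GENE")
    # non-LOOCV assignment from the full fit
    from evicalib.records import split_scores_labels

    x, y = split_scores_labels(cohort, "metasvm")
    fit = fit_firth_logistic(x, y)
    pair = derive_thresholds(fit, predictor="metasvm", scope="GENE1")
    direct = assign_evidence(variants[0].scores["metasvm"], pair)
    assert loo[variants[0].variant_id].evidence is direct.evidence


def test_loocv_ignores_held_out_label():
    """An injected extreme variant's own call does not depend on its label."""
    variants = generate_variant_table(single_gene_config(0.0, 3.0, 150, seed=10))
    from dataclasses import replace

    probe_plp = VariantRecord(
        "GENE1:probe", "GENE1", ConsensusClass.PLP, {"metasvm": 30.0}
    )
    probe_blb = replace(probe_plp, consensus=ConsensusClass.BLB)
    call_plp = loocv_assign(variants + [probe_plp], "metasvm", "GENE")["GENE1:probe"]
    call_blb = loocv_assign(variants + [probe_blb], "metasvm", "GENE")["GENE1:probe"]
    assert call_plp.evidence is call_blb.evidence is Evidence.DE


def test_loocv_gene_mode_requires_eligibility():
    variants = generate_variant_table(
        single_gene_config(0.0, 3.0, 12, prevalence=0.5, seed=12)
    )
    with pytest.raises(ValueError, match="ineligible"):
        loocv_assign(variants, "metasvm", "GENE", min_per_class=10)


def test_loocv_combined_falls_back_to_pooled():
    """COMBINED uses the gene when eligible, else the pooled model."""
    big = generate_variant_table(single_gene_config(0.0, 3.0, 200, seed=13, gene="BIG"))
    small = generate_variant_table(
        single_gene_config(0.0, 3.0, 8, seed=14, gene="TINY")
    )
    cohort = big + small
    combined = loocv_assign(cohort, "metasvm", "COMBINED")
    pooled = loocv_assign(cohort, "metasvm", "GENERALIZED")
    gene_only = loocv_assign(big, "metasvm", "GENE")
    for v in small:
        assert combined[v.variant_id] == pooled[v.variant_id]
    # eligible-gene variants use per-gene fits, which differ from pooled rule tags
    assert combined[big[0].variant_id].rule == gene_only[big[0].variant_id].rule
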