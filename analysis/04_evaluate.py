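"""Evaluate evidence-assignment schemes by leave-one-out cross-validation.

For each of the five meta-predictors, assigns benign/deleterious/no
evidence with gene-level and with generalized thresholds, refitting the
relevant model with each variant held out; the SIFT/PolyPhen2 agreement
comparator needs no fitting.  Tallies evidence against consensus classes,
reports PPV/NPV/YR/OPP with descending ranks, and tests pairwise
differences (Fisher exact for PPV/NPV/YR; Monte Carlo permutation for
OPP, gene-level vs generalized per predictor).

Input:   results/variants_consensus.tsv
Outputs: results/performance.tsv, results/pairwise_tests.tsv
"""

import argparse
from pathlib import Path

from evicalib import (
    META_PREDICTORS,
    confusion_counts,
    loocv_assign,
    performance,
    permutation_test_opp,
    rank_methods,
    sift_polyphen_agreement,
)
from evicalib.evaluation import fisher_test_metric
from evicalib.tableio import (
    read_variant_table,
    write_performance_table,
    write_tests_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()

    variants = read_variant_table(args.outdir / "variants_consensus.tsv")
    evaluated = [v for v in variants if v.is_blb or v.is_plp]
    classes = {v.variant_id: v.consensus for v in evaluated}
    print(f"evaluating {len(evaluated)} consensus-classified variants")

    evidence = {
        "sift_polyphen2_agreement": {
            v.variant_id: sift_polyphen_agreement(v.scores.get("sift"), v.polyphen2_call)
            for v in evaluated
        }
    }
    for pred in META_PREDICTORS:
        evidence[f"{pred}:gene"] = loocv_assign(evaluated, pred, "GENE")
        evidence[f"{pred}:generalized"] = loocv_assign(evaluated, pred, "GENERALIZED")

    confusion = {m: confusion_counts(ev, classes) for m, ev in evidence.items()}
    stats = {m: performance(c) for m, c in confusion.items()}
    ranks = rank_methods(stats)

    print(f"\n{'method':<26}{'TP':>5}{'TN':>5}{'FP':>4}{'FN':>4}{'NE':>5}"
          f"{'PPV':>12}{'NPV':>12}{'YR':>12}{'OPP':>12}")
    rows = []
    for m in evidence:
        c, s = confusion[m], stats[m]
        fmt = {k: f"{getattr(s, k):.3f} ({ranks[m][k].rank})" for k in ("ppv", "npv", "yr", "opp")}
        print(f"{m:<26}{c.tp:>5}{c.tn:>5}{c.fp:>4}{c.fn:>4}{c.ne:>5}"
              f"{fmt['ppv']:>12}{fmt['npv']:>12}{fmt['yr']:>12}{fmt['opp']:>12}")
        rows.append(
            {
                "method": m,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn, "ne": c.ne,
                "ppv": round(s.ppv, 3), "npv": round(s.npv, 3),
                "yr": round(s.yr, 3), "opp": round(s.opp, 3),
            }
            | {f"rank_{k}": ranks[m][k].rank for k in ("ppv", "npv", "yr", "opp")}
        )
    write_performance_table(rows, args.outdir / "performance.tsv")

    # gene-level vs generalized thresholds, per meta-predictor
    test_rows = []
    print("\ngene-level vs generalized thresholds:")
    for i, pred in enumerate(META_PREDICTORS):
        a, b = f"{pred}:gene", f"{pred}:generalized"
        p_opp = permutation_test_opp(
            evidence[a], evidence[b], classes, args.n_perm, seed=args.seed + i
        )
        d_opp = stats[a].opp - stats[b].opp
        print(f"  {pred:<10} OPP {stats[a].opp:.3f} vs {stats[b].opp:.3f} "
              f"(diff {d_opp:+.3f}), permutation p = {p_opp:.4f}")
        test_rows.append(
            {"method_a": a, "method_b": b, "metric": "OPP", "p_value": p_opp,
             "test": f"monte_carlo_permutation_n{args.n_perm}"}
        )
        for metric in ("PPV", "NPV", "YR"):
            test_rows.append(
                {"method_a": a, "method_b": b, "metric": metric,
                 "p_value": fisher_test_metric(confusion[a], confusion[b], metric),
                 "test": "fisher_exact_two_sided"}
            )
    write_tests_table(test_rows, args.outdir / "pairwise_tests.tsv")
    print(f"\nwrote {args.outdir / 'performance.tsv'} and "
          f"{args.outdir / 'pairwise_tests.tsv'}")


if __name__ == "__main__":
    main()
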