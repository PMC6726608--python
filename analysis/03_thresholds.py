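"""Derive two-sided evidence thresholds with bootstrap confidence intervals.

For REVEL and BayesDel, fits a Firth logistic regression of consensus
pathogenicity on score within each eligible gene (>=10 B/LB and >=10 P/LP
consensus variants) and pooled over all genes, inverts each fit at
predicted probabilities 0.2 (benign side, T_BE) and 0.8 (deleterious side,
T_DE), and attaches 90% percentile CIs from a bootstrap stratified by
classification status.

Input:   results/variants_consensus.tsv
Outputs: results/thresholds.tsv
"""

import argparse
from pathlib import Path

from evicalib import (
    GENERALIZED,
    bootstrap_threshold_ci,
    gene_level_thresholds,
    generalized_thresholds,
)
from evicalib.tableio import read_variant_table, write_thresholds_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--predictors", nargs="+", default=["revel", "bayesdel"])
    ap.add_argument(
        "--n-boot", type=int, default=1000,
        help="bootstrap replicates per CI (10000 for the full analysis)",
    )
    args = ap.parse_args()

    variants = read_variant_table(args.outdir / "variants_consensus.tsv")
    evaluated = [v for v in variants if v.is_blb or v.is_plp]
    print(f"{len(evaluated)} consensus B/LB + P/LP variants of {len(variants)} read")

    pairs, cis = [], {}
    for p_idx, pred in enumerate(args.predictors):
        per_gene = gene_level_thresholds(evaluated, pred)
        pooled = generalized_thresholds(evaluated, pred)
        scoped = list(per_gene.values()) + [pooled]
        pairs.extend(scoped)
        for s_idx, pair in enumerate(scoped):
            cis[(pred, pair.scope)] = bootstrap_threshold_ci(
                evaluated, pred, pair.scope, args.n_boot,
                seed=args.seed + 1000 * p_idx + s_idx,
            )
        print(f"\n{pred}: {len(per_gene)} gene-level fits + 1 generalized")
        print(f"  {'scope':<12}{'T_BE':>8}{'T_DE':>8}   90% CI(T_BE)        90% CI(T_DE)")
        for pair in scoped:
            ci = cis[(pred, pair.scope)]
            print(
                f"  {pair.scope:<12}{pair.t_be:>8.3f}{pair.t_de:>8.3f}"
                f"   [{ci.be_lower:6.3f}, {ci.be_upper:6.3f}]"
                f"   [{ci.de_lower:6.3f}, {ci.de_upper:6.3f}]"
            )

    write_thresholds_table(pairs, args.outdir / "thresholds.tsv", cis)
    n_gene = sum(p.scope != GENERALIZED for p in pairs)
    print(f"\nwrote {n_gene} gene-level + {len(pairs) - n_gene} generalized "
          f"threshold pairs to {args.outdir / 'thresholds.tsv'}")


if __name__ == "__main__":
    main()
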