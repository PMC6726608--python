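"""Reduce submitter calls to consensus classes and annotate the cohort.

Applies the consensus rules (P/LP if N_P/LP >= max(N_VUS, 1) with no B/LB
call, symmetrically for B/LB; conflicting or VUS-majority variants
excluded) to the simulated submissions, reports how often the consensus
recovers the simulated truth, and writes a consensus-annotated variant
table for the downstream threshold and evaluation steps.

Inputs:  results/variants.tsv, results/submissions.tsv
Outputs: results/consensus.tsv, results/variants_consensus.tsv
"""

import argparse
from collections import Counter
from dataclasses import replace
from pathlib import Path

from evicalib import assign_consensus
from evicalib.tableio import (
    read_submissions,
    read_variant_table,
    write_consensus_table,
    write_variant_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    variants = read_variant_table(args.outdir / "variants.tsv")
    submissions = read_submissions(args.outdir / "submissions.tsv")
    results = assign_consensus(submissions)
    write_consensus_table(results, args.outdir / "consensus.tsv")

    tally = Counter(r.consensus.value for r in results.values())
    print(f"{len(results)} variants classified from {len(submissions)} calls")
    print(f"consensus outcome: {dict(tally)}")

    truth = {v.variant_id: v.consensus for v in variants}
    included = [vid for vid, r in results.items() if r.consensus.included]
    agree = sum(results[vid].consensus is truth[vid] for vid in included)
    print(
        f"{len(included)} included ({len(results) - len(included)} excluded); "
        f"consensus matches simulated truth for {agree}/{len(included)} "
        f"({agree / len(included):.1%}) of included variants"
    )

    annotated = [replace(v, consensus=results[v.variant_id].consensus) for v in variants]
    write_variant_table(annotated, args.outdir / "variants_consensus.tsv")
    print(f"wrote {args.outdir / 'variants_consensus.tsv'}")


if __name__ == "__main__":
    main()
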