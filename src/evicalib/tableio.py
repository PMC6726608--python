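"""TSV readers and writers for every table the pipeline exchanges.

The native exchange format is a dbNSFP-extract-style tab-separated table;
missing values are written as "." and read from any of "", ".", "NA".
All writers emit full-precision floats so that write-then-read round-trips
records exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .consensus import ClassCounts, ConsensusClass, SubmissionRecord
from .evidence import EvidenceCall
from .records import PREDICTORS, VariantRecord
from .thresholds import ThresholdCI, ThresholdPair

__all__ = [
    "FormatError",
    "read_variant_table",
    "write_variant_table",
    "read_submissions",
    "write_submissions",
    "write_consensus_table",
    "write_thresholds_table",
    "write_evidence_table",
    "write_performance_table",
    "write_tests_table",
]

MISSING_MARKERS = ("", ".", "NA")
_WRITE_MISSING = "."

VARIANT_COLUMNS = ("variant_id", "gene", "class") + PREDICTORS[:1] + (
    "polyphen2_call",
) + PREDICTORS[1:]
SUBMISSION_COLUMNS = ("variant_id", "submitter", "classification", "date")


class FormatError(ValueError):
    """Malformed or incomplete input table."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_float(raw: str, row: int, column: str) -> float | None:
    raw = raw.strip()
    if raw in MISSING_MARKERS:
        return None
    try:
        return float(raw)
    except ValueError:
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(
            f"malformed numeric cell {raw!r} in column {column!r}, line {row + 2}"
        ) from None


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a per-variant score table.

    Columns are matched case-insensitively; ``variant_id`` and ``gene`` are
    mandatory, ``class`` (BLB/PLP, or an exclusion code) and every score
    column optional.  Duplicate variant ids and malformed numeric cells are
    reported with their locations.
    """
    df = _read_tsv(path)
    for col in ("variant_id", "gene"):
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    dup = df["variant_id"][df["variant_id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate variant_id values: {dup}")

    records: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        scores: dict[str, float | None] = {}
        for pred in PREDICTORS:
            if pred in df.columns:
                scores[pred] = _parse_float(row[pred], i, pred)
        consensus = None
        if "class" in df.columns:
            raw_cls = row["class"].strip()
            if raw_cls not in MISSING_MARKERS:
                try:
                    consensus = ConsensusClass(raw_cls)
                except ValueError:
                    raise FormatError(
                        f"unknown class {raw_cls!r} on line {i + 2}"
                    ) from None
        polyphen = None
        if "polyphen2_call" in df.columns:
            raw_pp = row["polyphen2_call"].strip()
            if raw_pp not in MISSING_MARKERS:
                polyphen = raw_pp
        records.append(
            VariantRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                consensus=consensus,
                scores=scores,
                polyphen2_call=polyphen,
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return _WRITE_MISSING
    return str(value)


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.variant_id,
                    v.gene,
                    v.consensus.value if v.consensus is not None else _WRITE_MISSING,
                    _fmt(v.scores.get("sift")),
                    _fmt(v.polyphen2_call),
                ]
                + [_fmt(v.scores.get(p)) for p in PREDICTORS[1:]]
            )


def read_submissions(path: str | Path) -> list[SubmissionRecord]:
    df = _read_tsv(path)
    for col in ("variant_id", "submitter", "classification"):
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    out: list[SubmissionRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        raw_date = row.get("date", "").strip() if "date" in df.columns else ""
        try:
            out.append(
                SubmissionRecord(
                    variant_id=row["variant_id"],
                    submitter=row["submitter"],
                    classification=row["classification"].strip(),
                    date=None if raw_date in MISSING_MARKERS else raw_date,
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {i + 2}: {exc}") from None
    return out


def write_submissions(
    submissions: Sequence[SubmissionRecord], path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SUBMISSION_COLUMNS)
        for s in submissions:
            w.writerow(
                [s.variant_id, s.submitter, s.classification, _fmt(s.date)]
            )


def write_consensus_table(
    results: Mapping[str, tuple[ClassCounts, ConsensusClass]] | Mapping[str, object],
    path: str | Path,
) -> None:
    """Write per-variant tallies and consensus classes.

    Accepts the mapping returned by :func:`evicalib.consensus.assign_consensus`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "n_blb", "n_plp", "n_vus", "consensus"])
        for vid, res in results.items():
            counts, consensus = res.counts, res.consensus
            w.writerow([vid, counts.n_blb, counts.n_plp, counts.n_vus, consensus.value])


def write_thresholds_table(
    thresholds: Sequence[ThresholdPair],
    path: str | Path,
    cis: Mapping[tuple[str, str], ThresholdCI] | None = None,
    round_to: int | None = 3,
) -> None:
    """Write the derived thresholds, one row per (predictor, scope).

    ``cis`` maps (predictor, scope) to a bootstrap CI; rows without one get
    missing markers.  ``round_to=None`` writes full precision.
    """
    cis = cis or {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def r(x: float | None) -> str:
        if x is None:
            return _WRITE_MISSING
        return str(round(x, round_to)) if round_to is not None else str(x)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "predictor", "scope", "t_be", "t_de",
                "ci_be_lo", "ci_be_hi", "ci_de_lo", "ci_de_hi",
                "n_blb", "n_plp", "orientation", "converged",
            ]
        )
        for t in thresholds:
            ci = cis.get((t.predictor, t.scope))
            fit = t.fit
            w.writerow(
                [
                    t.predictor, t.scope, r(t.t_be), r(t.t_de),
                    r(ci.be_lower if ci else None), r(ci.be_upper if ci else None),
                    r(ci.de_lower if ci else None), r(ci.de_upper if ci else None),
                    fit.n_controls if fit else _WRITE_MISSING,
                    fit.n_cases if fit else _WRITE_MISSING,
                    t.orientation,
                    str(fit.converged).lower() if fit else _WRITE_MISSING,
                ]
            )


def write_evidence_table(
    evidence: Mapping[str, Mapping[str, EvidenceCall]],
    variants: Sequence[VariantRecord],
    path: str | Path,
) -> None:
    """Write per-variant evidence, one row per (method, variant).

    ``evidence`` maps method name -> (variant_id -> call).
    """
    by_id = {v.variant_id: v for v in variants}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "gene", "method", "score", "evidence", "rule"])
        for method in evidence:
            for vid, call in evidence[method].items():
                v = by_id[vid]
                score = v.scores.get(method) if method in PREDICTORS else None
                w.writerow(
                    [vid, v.gene, method, _fmt(score), call.evidence.value, call.rule]
                )


def write_performance_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write the Table-1-style performance summary (pre-built row dicts)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tests_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write pairwise-comparison test results (pre-built row dicts)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
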