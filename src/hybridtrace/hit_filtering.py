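"""Best-hit retention for tabular homology searches and compound labeling.

Mirrors the common screening step after a protein BLAST against a large
database: per query, drop hits below a query-coverage cutoff (default 80%),
then keep the best 15 by bitscore.  "Best" means highest bitscore; ties fall
back to ascending e-value, then lexicographic subject id, so the filter is
deterministic under any input permutation.

Compound labeling ("genetic dereplication") joins each tip's single best
retained hit against a reference map of characterized cluster genes (e.g.
MIBiG entries) to annotate the likely product.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

#: the 12 standard BLAST outfmt-6 columns
OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bitscore",
]

_NUMERIC = {
    "percent_identity": float,
    "alignment_length": int,
    "mismatches": int,
    "gap_opens": int,
    "query_start": int,
    "query_end": int,
    "subject_start": int,
    "subject_end": int,
    "evalue": float,
    "bitscore": float,
}


class HitParseError(ValueError):
    pass


def read_blast_tab(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Read BLAST tabular output (outfmt 6, optional 13th ``qcovs`` column).

    Query coverage is taken from the ``qcovs`` column when present;
    otherwise it is computed as ``100 * alignment_length / query_length``
    from the companion FASTA lengths (outfmt 6 lacks coverage by default).
    Malformed rows raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise HitParseError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(fields)}"
                )
            row = dict(zip(OUTFMT6_COLUMNS, fields[:12]))
            try:
                for col, cast in _NUMERIC.items():
                    row[col] = cast(row[col])
                if len(fields) == 13:
                    row["query_coverage"] = float(fields[12])
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from None
            rows.append(row)
    hits = pd.DataFrame(rows)
    if hits.empty:
        return pd.DataFrame(columns=OUTFMT6_COLUMNS + ["query_coverage"])
    if "query_coverage" not in hits.columns:
        if query_lengths is None:
            raise HitParseError(
                f"{path}: no qcovs column; supply query_lengths to compute coverage"
            )
        missing = sorted(set(hits["query_id"]) - set(query_lengths))
        if missing:
            raise HitParseError(f"{path}: no query length for {missing}")
        qlen = hits["query_id"].map(query_lengths)
        hits["query_coverage"] = 100.0 * hits["alignment_length"] / qlen
    return hits


def filter_best_hits(
    hits: pd.DataFrame, min_qcov: float = 80.0, top_n: int = 15
) -> pd.DataFrame:
    """Per query: drop hits with coverage below ``min_qcov``, then keep the
    ``top_n`` best by descending bitscore (ties: ascending e-value, then
    subject id).  Output is grouped by query in rank order."""
    if hits.empty:
        return hits.copy()
    kept = hits[hits["query_coverage"] >= min_qcov]
    kept = kept.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return kept.groupby("query_id", sort=True).head(top_n).reset_index(drop=True)


def annotate_compounds(
    meta: pd.DataFrame,
    hits: pd.DataFrame,
    reference_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Label each tip with the compound of its single best retained hit.

    ``hits`` must already be filtered; the best hit per query follows the
    same bitscore/e-value/subject ordering as :func:`filter_best_hits`.
    Tips without hits, and hits whose subject is absent from the reference
    map (warned), keep an empty compound.
    """
    out = meta.copy()
    if "compound" not in out.columns:
        out["compound"] = ""
    if hits.empty:
        return out
    ranked = hits.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.groupby("query_id", sort=True).head(1)
    for _, row in best.iterrows():
        tip = row["query_id"]
        if tip not in out.index:
            continue
        subject = row["subject_id"]
        if subject not in reference_labels:
            warnings.warn(
                f"best hit subject {subject} for {tip} has no compound label",
                stacklevel=2,
            )
            continue
        out.loc[tip, "compound"] = reference_labels[subject]
    return out


def load_reference_labels(path: str | Path) -> dict[str, str]:
    """Load a subject_id -> compound TSV map."""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["subject_id", "compound"],
                     header=None, comment="#")
    return dict(zip(df["subject_id"], df["compound"]))
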