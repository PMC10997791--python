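"""Readers and writers for summary-statistics and results tables.

All files are UTF-8 tab-separated with '.' decimal separators, matching
biobank summary-statistic conventions.  The summary-stats input contract is
one row per phenotype::

    phenotype_id  trait_kind  group_a  beta_a  se_a  n_a  group_b  beta_b  se_b  n_b

Rows that cannot form a valid paired record (non-positive or non-finite
standard error, missing group, malformed numbers) are routed to an
excluded-rows table with the offending line number and reason rather than
aborting the run.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core_stats import GroupAssociation, PhenotypeRecord

__all__ = ["SUMMARY_COLUMNS", "read_summary_stats", "records_to_frame", "write_results"]

SUMMARY_COLUMNS = [
    "phenotype_id", "trait_kind",
    "group_a", "beta_a", "se_a", "n_a",
    "group_b", "beta_b", "se_b", "n_b",
]

#: columns printed in scientific notation (p-values); everything else
#: numeric is printed at 6 significant digits.
_P_COLUMNS = ("p_mean", "p_het", "p_weighted", "p_adjusted")


def read_summary_stats(path: str | Path) -> tuple[list[PhenotypeRecord], pd.DataFrame]:
    """Read a summary-statistics TSV into validated records.

    Returns ``(records, excluded)`` where ``excluded`` has columns
    ``line``, ``phenotype_id``, ``reason``.  Missing required columns raise
    immediately, naming them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"phenotype_id": str, "group_a": str, "group_b": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    records: list[PhenotypeRecord] = []
    excluded: list[tuple[int, str, str]] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # 1-based, after the header
        pid = str(row["phenotype_id"])
        try:
            for side in ("a", "b"):
                if pd.isna(row[f"beta_{side}"]) or pd.isna(row[f"se_{side}"]):
                    raise ValueError(f"missing group {side} estimate")
            rec = PhenotypeRecord(
                phenotype_id=pid,
                trait_kind=str(row["trait_kind"]),
                assoc_a=GroupAssociation(
                    str(row["group_a"]), float(row["beta_a"]), float(row["se_a"]), int(row["n_a"])
                ),
                assoc_b=GroupAssociation(
                    str(row["group_b"]), float(row["beta_b"]), float(row["se_b"]), int(row["n_b"])
                ),
            )
        except (ValueError, TypeError) as exc:
            excluded.append((line, pid, str(exc)))
            continue
        records.append(rec)
    excluded_df = pd.DataFrame(excluded, columns=["line", "phenotype_id", "reason"])
    return records, excluded_df


def records_to_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Records back to the summary-stats table layout (round-trip inverse)."""
    return pd.DataFrame(
        [
            (
                r.phenotype_id, r.trait_kind,
                r.assoc_a.group_id, r.assoc_a.beta, r.assoc_a.se, r.assoc_a.n,
                r.assoc_b.group_id, r.assoc_b.beta, r.assoc_b.se, r.assoc_b.n,
            )
            for r in records
        ],
        columns=SUMMARY_COLUMNS,
    )


def _format_value(value, column: str) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return "NA"
        if column in _P_COLUMNS:
            return f"{value:.6e}"
        return f"{value:.6g}"
    return str(value)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with stable, byte-reproducible formatting.

    Floats at 6 significant digits; p-value columns in scientific notation;
    an empty table yields a header-only file.
    """
    path = Path(path)
    lines = ["\t".join(map(str, table.columns))]
    for _, row in table.iterrows():
        lines.append("\t".join(_format_value(row[c], c) for c in table.columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
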