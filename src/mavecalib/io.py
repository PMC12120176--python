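"""Tab-separated table input/output.

Variant tables are TSV with a header row. A ``column_map`` translates the
source file's headers onto the canonical field names, so arbitrary dialects
(supplementary tables copy-pasted from publications included) can be
ingested without editing the file. Cells may use the unicode minus sign
(``−``) and any of ``""``, ``NA``, ``NaN`` for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import Domain, FunctionalClass, ScoreTable, ValidationError, VariantRecord

__all__ = ["ParseReport", "read_variant_table", "write_results_table"]

#: Canonical (non-score) column names a variant table may carry.
RESERVED_COLUMNS = ("variant_id", "domain", "mave_score", "rsa", "functional_class")

MANDATORY_COLUMNS = ("variant_id", "mave_score")

_MISSING_TOKENS = {"", "na", "nan", "n/a", "none", "null"}


@dataclass
class ParseReport:
    """Accounting for one parsed table: nothing is ever dropped silently."""

    rows_in: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    missing_cells: dict[str, int] = field(default_factory=dict)
    rejected_ids: list[str] = field(default_factory=list)

    def note_missing(self, column: str) -> None:
        self.missing_cells[column] = self.missing_cells.get(column, 0) + 1


def _parse_float(cell: object) -> float | None:
    """Parse a numeric cell; missing tokens and unparseable text give None."""
    if cell is None:
        return None
    text = str(cell).strip().replace("−", "-")  # unicode minus
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def read_variant_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[ScoreTable, ParseReport]:
    """Read a TSV variant table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Canonical name → source header. Canonical names are the reserved
        fields (``variant_id``, ``domain``, ``mave_score``, ``rsa``,
        ``functional_class``) plus one entry per computational tool (e.g.
        ``{"AM": "alphamissense"}``). When omitted, source headers are taken
        at face value and every non-reserved column becomes a tool.

    Returns
    -------
    (ScoreTable, ParseReport)
        Rows whose mandatory ``mave_score`` cell is missing or unparseable
        are rejected (and counted); unparseable optional cells become absent
        values (and are counted per column).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if column_map is None:
        column_map = {c: c for c in frame.columns}
    for canonical in MANDATORY_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in frame.columns:
            raise ValidationError(
                f"mandatory column {canonical!r} (source header {source!r}) "
                f"not found in {path.name}; available: {list(frame.columns)}"
            )

    def src(canonical: str) -> str | None:
        source = column_map.get(canonical)
        return source if source in frame.columns else None

    tool_columns = {
        canonical: source
        for canonical, source in column_map.items()
        if canonical not in RESERVED_COLUMNS and source in frame.columns
    }

    report = ParseReport(rows_in=len(frame))
    records: list[VariantRecord] = []
    for _, row in frame.iterrows():
        vid = str(row[column_map.get("variant_id", "variant_id")]).strip()
        mave = _parse_float(row[column_map.get("mave_score", "mave_score")])
        if mave is None:
            report.rows_rejected += 1
            report.rejected_ids.append(vid)
            report.note_missing("mave_score")
            continue

        domain = Domain.OTHER
        if src("domain"):
            token = str(row[src("domain")]).strip().upper()
            domain = Domain(token) if token in Domain.__members__ else Domain.OTHER

        rsa = None
        if src("rsa"):
            rsa = _parse_float(row[src("rsa")])
            if rsa is None:
                report.note_missing("rsa")

        func_class = FunctionalClass.UNASSIGNED
        if src("functional_class"):
            token = str(row[src("functional_class")]).strip().upper()
            if token in FunctionalClass.__members__:
                func_class = FunctionalClass(token)

        scores: dict[str, float] = {}
        for tool, source in tool_columns.items():
            value = _parse_float(row[source])
            if value is None:
                report.note_missing(tool)
            else:
                scores[tool] = value

        records.append(
            VariantRecord(
                variant_id=vid,
                mave_score=mave,
                domain=domain,
                rsa=rsa,
                functional_class=func_class,
                scores=scores,
            )
        )
        report.rows_kept += 1

    table = ScoreTable(records, provenance=str(path))
    return table, report


def write_results_table(rows: list[dict[str, object]], path: str | Path) -> None:
    """Write flat mappings as a TSV with full numeric precision.

    All rows must share one key set; an empty collection is an error (a
    header-only file would silently hide an upstream failure).
    """
    if not rows:
        raise ValidationError("nothing to write: empty row collection")
    keys = list(rows[0].keys())
    for i, row in enumerate(rows[1:], start=1):
        if list(row.keys()) != keys:
            raise ValidationError(
                f"heterogeneous keys: row 0 has {keys}, row {i} has {list(row.keys())}"
            )
    frame = pd.DataFrame(rows, columns=keys)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
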