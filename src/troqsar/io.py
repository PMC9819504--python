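"""Compound-table CSV reading/writing, the packaged organophosphate
fixture, and screening-report serialization.

CSV schema
----------
Required column: ``name`` (alias ``compound``). Optional identifier
columns: ``cas``, ``abbreviation``, ``smiles``. Descriptor column:
``log_kow``. Endpoint columns, any of: ``lc50_mg_per_l`` (alias
``lc50``), ``log_lc50``, ``noec_mg_per_l`` (alias ``noec``),
``log_noec``. Headers are matched case-insensitively after trimming;
unrecognised columns are preserved verbatim in each record's ``extra``
mapping. Concentrations are mg/L; decimal separator is the dot (decimal
commas are rejected per cell with an explanatory finding); the Unicode
minus sign is normalised to ASCII before numeric parsing.

When a row supplies both a concentration and its log and they disagree,
the log value wins and a ``CONFLICTING_ENDPOINT`` finding is recorded —
log space is the working scale throughout this package.
"""

from __future__ import annotations

import csv as _csv
import io as _stdio
import json
import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    CompoundRecord,
    MOAClass,
    ToxicityEndpoints,
    LOG_CONC_AGREEMENT_TOL,
)
from .exceptions import InvalidInputError, SchemaError
from .screening import ScreeningReport

__all__ = [
    "Finding",
    "ParseReport",
    "read_compounds_csv",
    "records_from_dataframe",
    "records_to_dataframe",
    "write_compounds_csv",
    "load_table2_fixture",
    "write_report",
    "read_report",
    "round_half_up",
]

TABLE2_RESOURCE = "table2_organophosphates.csv"

_COLUMN_ALIASES = {
    "name": "name",
    "compound": "name",
    "cas": "cas",
    "abbreviation": "abbreviation",
    "abbr": "abbreviation",
    "smiles": "smiles",
    "log_kow": "log_kow",
    "logkow": "log_kow",
    "lc50_mg_per_l": "lc50",
    "lc50": "lc50",
    "log_lc50": "log_lc50",
    "noec_mg_per_l": "noec",
    "noec": "noec",
    "log_noec": "log_noec",
}

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table display."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Finding:
    """One QC/parse finding, tied to a row (1-based, header excluded)."""

    code: str
    message: str
    row: Optional[int] = None
    column: Optional[str] = None


@dataclass
class ParseReport:
    n_rows: int = 0
    findings: List[Finding] = field(default_factory=list)


def _normalise_text(text: str) -> str:
    # U+2212 MINUS SIGN appears in typeset tables
    return text.replace("−", "-").lstrip("﻿")


def _parse_float(
    raw: object, row: int, column: str, report: ParseReport
) -> Optional[float]:
    if raw is None:
        return None
    text = _normalise_text(str(raw)).strip()
    if text == "" or text.lower() in {"nan", "na", "-", "none"}:
        return None
    if _DECIMAL_COMMA.match(text):
        report.findings.append(
            Finding(
                "DECIMAL_COMMA",
                f"row {row}, column {column!r}: {text!r} uses a decimal comma; "
                "use a dot as the decimal separator",
                row,
                column,
            )
        )
        return None
    try:
        value = float(text)
    except ValueError:
        report.findings.append(
            Finding(
                "MALFORMED_NUMBER",
                f"row {row}, column {column!r}: cannot parse {text!r} as a number",
                row,
                column,
            )
        )
        return None
    if not math.isfinite(value):
        report.findings.append(
            Finding(
                "MALFORMED_NUMBER",
                f"row {row}, column {column!r}: non-finite value {text!r}",
                row,
                column,
            )
        )
        return None
    return value


def _clean_str(raw: object) -> Optional[str]:
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in {"nan", "none", "-"}:
        return None
    return text


def records_from_dataframe(df: pd.DataFrame) -> Tuple[List[CompoundRecord], ParseReport]:
    """Build CompoundRecords from a schema-shaped DataFrame.

    Malformed cells yield per-row findings, never a global failure;
    a row whose endpoints cannot be parsed still produces a record
    (it will surface as UNCLASSIFIED/MISSING_ENDPOINT downstream).
    """
    report = ParseReport()
    canonical: dict = {}
    passthrough: List[str] = []
    for col in df.columns:
        key = str(col).strip().lower()
        target = _COLUMN_ALIASES.get(key)
        if target is not None and target not in canonical:
            canonical[target] = col
        else:
            passthrough.append(col)
    if "name" not in canonical:
        raise SchemaError(
            "missing required column 'name' (or alias 'compound'); "
            f"found columns: {list(df.columns)}"
        )

    records: List[CompoundRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        report.n_rows += 1
        name = _clean_str(row[canonical["name"]])
        if name is None:
            report.findings.append(
                Finding("MISSING_NAME", f"row {i}: empty compound name; row skipped", i)
            )
            continue

        def get_float(target: str) -> Optional[float]:
            if target not in canonical:
                return None
            return _parse_float(row[canonical[target]], i, target, report)

        def get_str(target: str) -> Optional[str]:
            if target not in canonical:
                return None
            return _clean_str(row[canonical[target]])

        kwargs = dict(
            lc50=get_float("lc50"),
            log_lc50=get_float("log_lc50"),
            noec=get_float("noec"),
            log_noec=get_float("log_noec"),
        )
        # nonpositive concentrations are findings, not crashes
        for conc_key in ("lc50", "noec"):
            value = kwargs[conc_key]
            if value is not None and value <= 0:
                report.findings.append(
                    Finding(
                        "NONPOSITIVE_CONCENTRATION",
                        f"row {i}: {conc_key} = {value} is not a positive "
                        "concentration (mg/L); treated as missing",
                        i,
                        conc_key,
                    )
                )
                kwargs[conc_key] = None
        for conc_key, log_key in (("lc50", "log_lc50"), ("noec", "log_noec")):
            conc, log = kwargs[conc_key], kwargs[log_key]
            if conc is not None and log is not None:
                if abs(math.log10(conc) - log) > LOG_CONC_AGREEMENT_TOL:
                    report.findings.append(
                        Finding(
                            "CONFLICTING_ENDPOINT",
                            f"row {i}: {conc_key} = {conc} disagrees with "
                            f"{log_key} = {log}; the log value wins",
                            i,
                            log_key,
                        )
                    )

        cas = get_str("cas")
        try:
            record = CompoundRecord(
                name=name,
                endpoints=ToxicityEndpoints(**kwargs),
                cas=cas,
                abbreviation=get_str("abbreviation"),
                smiles=get_str("smiles"),
                log_kow=get_float("log_kow"),
                extra={str(c): row[c] for c in passthrough},
            )
        except InvalidInputError as exc:
            report.findings.append(Finding("INVALID_RECORD", f"row {i}: {exc}", i))
            continue
        records.append(record)
    return records, report


def read_compounds_csv(
    path, delimiter: Optional[str] = None
) -> Tuple[List[CompoundRecord], ParseReport]:
    """Read a compound table from a comma- or tab-delimited file.

    The delimiter is sniffed from the header unless given; UTF-8 with an
    optional BOM is assumed.
    """
    try:
        text = Path(path).read_text(encoding="utf-8-sig")
    except OSError as exc:
        raise InvalidInputError(f"cannot read {path}: {exc}") from exc
    text = _normalise_text(text)
    if delimiter is None:
        header = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(_stdio.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False)
    return records_from_dataframe(df)


def records_to_dataframe(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Serialise records back to the CSV schema (plus passthrough columns)."""
    rows = []
    extra_cols: List[str] = []
    for rec in records:
        for key in rec.extra:
            if key not in extra_cols:
                extra_cols.append(key)
    for rec in records:
        row = {
            "name": rec.name,
            "cas": rec.cas,
            "abbreviation": rec.abbreviation,
            "smiles": rec.smiles,
            "log_kow": rec.log_kow,
            "lc50_mg_per_l": rec.endpoints.lc50,
            "log_lc50": rec.endpoints.log_lc50,
            "noec_mg_per_l": rec.endpoints.noec,
            "log_noec": rec.endpoints.log_noec,
        }
        for key in extra_cols:
            row[key] = rec.extra.get(key)
        rows.append(row)
    return pd.DataFrame(rows)


def write_compounds_csv(records: Sequence[CompoundRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def load_table2_fixture() -> List[CompoundRecord]:
    """The packaged organophosphate worked-example table, verbatim.

    Twelve records in printed order (diethyl phthalate appears twice, as
    printed). Each record's ``extra`` carries the table's own reference
    annotations under ``printed_log_tro`` (float) and ``printed_moa``
    (MOAClass), so recomputed values can be compared against the printed
    ones — including the rows where the printed table is internally
    inconsistent with its own endpoints.
    """
    source = resources.files("troqsar.data").joinpath(TABLE2_RESOURCE)
    with resources.as_file(source) as fp:
        records, report = read_compounds_csv(fp)
    assert not report.findings, report.findings
    type_map = {"N": MOAClass.NARCOSIS, "T": MOAClass.TRANSITION, "R": MOAClass.REACTIVE}
    for rec in records:
        rec.extra["printed_log_tro"] = float(rec.extra["printed_log_tro"])
        rec.extra["printed_moa"] = type_map[str(rec.extra.pop("printed_type")).strip()]
    return records


def _report_rows(report: ScreeningReport) -> List[dict]:
    rows = []
    contributing = [
        item
        for item in report.retained
        if item.record.log_kow is not None
        and item.record.endpoints.resolved_log_lc50() is not None
    ]
    residuals = dict(
        zip((id(item) for item in contributing), report.model_screened.residuals)
    )
    for status, items in (("retained", report.retained), ("excluded", report.excluded)):
        for item in items:
            tro = item.tro
            rows.append(
                {
                    "name": item.record.name,
                    "cas": item.record.cas,
                    "log_kow": item.record.log_kow,
                    "log_lc50": item.record.endpoints.resolved_log_lc50(),
                    "log_noec": item.record.endpoints.resolved_log_noec(),
                    "log_tro_signed": tro.log_tro_signed,
                    "log_tro_abs": tro.log_tro_abs,
                    "log_tro_abs_2dp": (
                        round_half_up(tro.log_tro_abs) if tro.log_tro_abs is not None else None
                    ),
                    "moa": tro.moa.value,
                    "status": status,
                    "reason": item.reason,
                    "residual": residuals.get(id(item)),
                    "flags": ";".join(sorted(f.value for f in tro.flags)),
                }
            )
    return rows


def write_report(report: ScreeningReport, path, format: str = "json") -> None:
    """Serialise a screening report as JSON (lossless) or CSV (per-record)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2), encoding="utf-8")
    elif format == "csv":
        pd.DataFrame(_report_rows(report)).to_csv(
            path, index=False, quoting=_csv.QUOTE_MINIMAL
        )
    else:
        raise InvalidInputError(f"unknown report format {format!r}; use 'json' or 'csv'")


def read_report(path) -> dict:
    """Read back a JSON report (structural round-trip counterpart)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
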