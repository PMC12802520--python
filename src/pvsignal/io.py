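"""Reading, writing and cleaning of spontaneous-report interchange files.

Two plain-text CSV dialects are supported, mirroring the two layouts in which
FAERS-style extracts circulate:

``wide``
    One row per report.  Multi-valued cells are delimited: ``drugs`` holds
    ``name|role`` entries joined by ``;``, ``pts`` and ``outcomes`` are
    ``;``-joined lists.  Columns: ``report_id, case_id, receipt_date, drugs,
    pts, sex, age_years, country, indication, outcomes, dose_mg_per_day``.

``long``
    One row per report–drug–PT record (the cartesian product within a
    report); reports are reassembled by ``report_id``.  Columns: ``report_id,
    case_id, receipt_date, drug, role, pt, sex, age_years, country,
    indication, outcomes, dose_mg_per_day``.

Drug and PT names must not contain the reserved delimiters ``;`` and ``|``.
Missing optional values are empty cells and become explicit missing values
(``None`` / ``not_specified``) on read.  Malformed rows never abort a read:
they are collected into a reject table with a reason per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    NOT_SPECIFIED,
    OUTCOMES,
    ROLES,
    SEX_LEVELS,
    DrugEntry,
    FormatError,
    MedDRAMap,
    SafetyReport,
)

log = logging.getLogger(__name__)

WIDE_COLUMNS = [
    "report_id", "case_id", "receipt_date", "drugs", "pts", "sex",
    "age_years", "country", "indication", "outcomes", "dose_mg_per_day",
]
LONG_COLUMNS = [
    "report_id", "case_id", "receipt_date", "drug", "role", "pt", "sex",
    "age_years", "country", "indication", "outcomes", "dose_mg_per_day",
]


@dataclass
class ReadResult:
    reports: list[SafetyReport]
    rejects: pd.DataFrame  # columns: row, report_id, reason

    def __iter__(self):
        return iter((self.reports, self.rejects))


@dataclass(frozen=True)
class DedupAccounting:
    input_reports: int
    removed: int
    output_reports: int


@dataclass
class ValidationResult:
    reports: list[SafetyReport]
    rejected_terms: list[tuple[str, int]]  # (term, occurrence count)
    dropped_reports: int

    def __iter__(self):
        return iter((self.reports, self.rejected_terms))


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_date(text: str) -> date:
    return date.fromisoformat(text)


def _parse_float(text: str) -> float | None:
    if text == "":
        return None
    return float(text)


def _parse_outcomes(cell: str) -> tuple[str, ...]:
    if cell == "":
        return ()
    out = []
    for tok in cell.split(";"):
        tok = tok.strip()
        if tok not in OUTCOMES:
            raise ValueError(f"unknown outcome class: {tok!r}")
        if tok not in out:
            out.append(tok)
    return tuple(out)


def _parse_sex(cell: str) -> str:
    if cell == "":
        return NOT_SPECIFIED
    if cell not in SEX_LEVELS:
        raise ValueError(f"unknown sex level: {cell!r}")
    return cell


def _common_fields(row) -> dict:
    return dict(
        sex=_parse_sex(row["sex"]),
        age_years=_parse_float(row["age_years"]),
        country=row["country"] or None,
        indication=row["indication"] or None,
        outcomes=_parse_outcomes(row["outcomes"]),
        dose_mg_per_day=_parse_float(row["dose_mg_per_day"]),
    )


def _wide_row_to_report(row) -> SafetyReport:
    drugs = []
    for tok in row["drugs"].split(";"):
        tok = tok.strip()
        if not tok:
            continue
        name, _, role = tok.partition("|")
        if role not in ROLES:
            raise ValueError(f"unknown role code: {role!r}")
        drugs.append(DrugEntry(name, role))
    if not drugs:
        raise ValueError("report has no drugs")
    pts = []
    for tok in row["pts"].split(";"):
        tok = tok.strip()
        if tok and tok not in pts:
            pts.append(tok)
    if not pts:
        raise ValueError("report has no event terms")
    return SafetyReport(
        report_id=row["report_id"],
        case_id=row["case_id"],
        receipt_date=_parse_date(row["receipt_date"]),
        drugs=tuple(drugs),
        pts=tuple(pts),
        **_common_fields(row),
    )


def read_reports(path: str | Path, dialect: str = "wide") -> ReadResult:
    """Read an interchange CSV into validated :class:`SafetyReport` records.

    Malformed rows (missing report id, unknown role code, bad dates/numbers)
    are dropped into ``rejects`` with a reason rather than raising.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = WIDE_COLUMNS if dialect == "wide" else LONG_COLUMNS
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    rejects: list[tuple[int, str, str]] = []
    reports: list[SafetyReport] = []

    if dialect == "wide":
        for i, row in enumerate(frame.to_dict("records")):
            if not row["report_id"]:
                rejects.append((i, "", "missing report_id"))
                continue
            try:
                reports.append(_wide_row_to_report(row))
            except ValueError as exc:
                rejects.append((i, row["report_id"], str(exc)))
    else:
        groups: dict[str, list[tuple[int, dict]]] = {}
        for i, row in enumerate(frame.to_dict("records")):
            if not row["report_id"]:
                rejects.append((i, "", "missing report_id"))
                continue
            groups.setdefault(row["report_id"], []).append((i, row))
        for report_id, rows in groups.items():
            drugs: list[DrugEntry] = []
            pts: list[str] = []
            kept_rows = []
            for i, row in rows:
                if row["role"] not in ROLES:
                    rejects.append((i, report_id, f"unknown role code: {row['role']!r}"))
                    continue
                kept_rows.append((i, row))
            if not kept_rows:
                continue
            first = kept_rows[0][1]
            try:
                common = _common_fields(first)
                receipt = _parse_date(first["receipt_date"])
            except ValueError as exc:
                rejects.append((kept_rows[0][0], report_id, str(exc)))
                continue
            for _, row in kept_rows:
                entry = DrugEntry(row["drug"], row["role"])
                if entry.name and entry not in drugs:
                    drugs.append(entry)
                if row["pt"] and row["pt"] not in pts:
                    pts.append(row["pt"])
            if not drugs or not pts:
                rejects.append((kept_rows[0][0], report_id, "report has no drugs or no event terms"))
                continue
            reports.append(
                SafetyReport(
                    report_id=report_id,
                    case_id=first["case_id"],
                    receipt_date=receipt,
                    drugs=tuple(drugs),
                    pts=tuple(pts),
                    **common,
                )
            )

    reject_frame = pd.DataFrame(rejects, columns=["row", "report_id", "reason"])
    return ReadResult(reports, reject_frame)


# ---------------------------------------------------------------------------
# writing

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_reports(reports: Sequence[SafetyReport], path: str | Path,
                  dialect: str = "wide") -> None:
    """Write reports in an interchange dialect; lossless round-trip with read."""
    rows = []
    if dialect == "wide":
        for r in reports:
            rows.append({
                "report_id": r.report_id,
                "case_id": r.case_id,
                "receipt_date": r.receipt_date.isoformat(),
                "drugs": ";".join(f"{d.name}|{d.role}" for d in r.drugs),
                "pts": ";".join(r.pts),
                "sex": r.sex,
                "age_years": _fmt(r.age_years),
                "country": _fmt(r.country),
                "indication": _fmt(r.indication),
                "outcomes": ";".join(r.outcomes),
                "dose_mg_per_day": _fmt(r.dose_mg_per_day),
            })
        frame = pd.DataFrame(rows, columns=WIDE_COLUMNS)
    elif dialect == "long":
        for r in reports:
            for d in r.drugs:
                for pt in r.pts:
                    rows.append({
                        "report_id": r.report_id,
                        "case_id": r.case_id,
                        "receipt_date": r.receipt_date.isoformat(),
                        "drug": d.name,
                        "role": d.role,
                        "pt": pt,
                        "sex": r.sex,
                        "age_years": _fmt(r.age_years),
                        "country": _fmt(r.country),
                        "indication": _fmt(r.indication),
                        "outcomes": ";".join(r.outcomes),
                        "dose_mg_per_day": _fmt(r.dose_mg_per_day),
                    })
        frame = pd.DataFrame(rows, columns=LONG_COLUMNS)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cleaning

def deduplicate(reports: Iterable[SafetyReport]) -> tuple[list[SafetyReport], DedupAccounting]:
    """Keep one version per case: latest receipt date, ties to greatest report id.

    Spontaneous-reporting databases store successive versions of a case under
    one case id; analysis counts each case once.  Output preserves the input
    order of the retained reports, so the operation is deterministic and
    idempotent.
    """
    reports = list(reports)
    best: dict[str, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or (r.receipt_date, r.report_id) > (cur.receipt_date, cur.report_id):
            best[r.case_id] = r
    kept_ids = {r.report_id for r in best.values()}
    out = [r for r in reports if r.report_id in kept_ids]
    acct = DedupAccounting(len(reports), len(reports) - len(out), len(out))
    return out, acct


def filter_primary_suspect(reports: Iterable[SafetyReport], drug: str,
                           synonyms: Sequence[str] = ()) -> list[SafetyReport]:
    """Reports in which ``drug`` carries the primary-suspect role code.

    Name matching is case-insensitive; ``synonyms`` lets brand and generic
    names collapse onto one drug of interest.
    """
    syn = tuple(synonyms)
    return [r for r in reports if r.is_primary_suspect(drug, syn)]


def validate_pts(reports: Iterable[SafetyReport], meddra: MedDRAMap,
                 drop_empty: bool = True) -> ValidationResult:
    """Remove event terms absent from the MedDRA map.

    Terms not classified as a PT are stripped from each report and tallied;
    reports left with no valid PT are dropped (and counted) unless
    ``drop_empty`` is false, in which case they remain with an empty PT list
    so they can still serve as background population.
    """
    rejected: dict[str, int] = {}
    out: list[SafetyReport] = []
    dropped = 0
    for r in reports:
        kept = tuple(pt for pt in r.pts if pt in meddra)
        for pt in r.pts:
            if pt not in meddra:
                rejected[pt] = rejected.get(pt, 0) + 1
        if not kept and drop_empty:
            dropped += 1
            continue
        out.append(r if kept == r.pts else r.with_pts(kept))
    rejected_list = sorted(rejected.items(), key=lambda kv: (-kv[1], kv[0]))
    return ValidationResult(out, rejected_list, dropped)


def load_meddra_map(path: str | Path) -> MedDRAMap:
    """Load a PT→SOC map from TSV with columns ``pt, soc, soc_code`` (+ optional ``pt_code``).

    Duplicate PT rows are tolerated when they agree; conflicting SOC
    assignments are a format error (MedDRA gives every PT one primary SOC).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["pt", "soc", "soc_code"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"MedDRA map missing required column(s): {', '.join(missing)}")
    pt_to_soc: dict[str, tuple[str, str]] = {}
    pt_codes: dict[str, str] = {}
    seen_norm: dict[str, str] = {}
    for _, row in frame.iterrows():
        pt = row["pt"]
        soc = (row["soc"], row["soc_code"])
        key = pt.casefold()
        if key in seen_norm:
            prior = pt_to_soc[seen_norm[key]]
            if prior != soc:
                raise FormatError(
                    f"conflicting SOC assignment for PT {pt!r}: {prior} vs {soc}"
                )
            continue
        seen_norm[key] = pt
        pt_to_soc[pt] = soc
        if "pt_code" in frame.columns and row["pt_code"]:
            pt_codes[pt] = row["pt_code"]
    return MedDRAMap(pt_to_soc, pt_codes)


def write_meddra_map(meddra: MedDRAMap, path: str | Path) -> None:
    rows = [
        {"pt": pt, "pt_code": meddra.pt_codes.get(pt, ""), "soc": soc, "soc_code": code}
        for pt, (soc, code) in meddra.pt_to_soc.items()
    ]
    pd.DataFrame(rows, columns=["pt", "pt_code", "soc", "soc_code"]).to_csv(
        path, sep="\t", index=False
    )
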