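"""Domain model for spontaneous adverse-event reports and FAERS-style ASCII I/O.

The FDA Adverse Event Reporting System (FAERS) distributes quarterly data as
'$'-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, INDI, THER).  This module
reads those tables into :class:`RawRecordSet` objects, joins them into the
per-case :class:`SafetyReport` model, and provides a lossless JSON-lines
interchange format for the assembled reports.

Conventions follow the modern (post-2012) FAERS layout: tables join on
``primaryid`` (report version id); ``caseid`` identifies the underlying case,
of which a report is one version.  Ages are normalised to years, weights to
kilograms, reaction terms to upper-case MedDRA Preferred Terms (PTs).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("faerspv")

DELIMITER = "$"
INTERCHANGE_FORMAT = "faerspv-reports"
INTERCHANGE_VERSION = 1

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
DRUG_ROLES = ("PS", "SS", "C", "I")  # primary/secondary suspect, concomitant, interacting
SEX_CODES = ("F", "M", "UNK")

QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

# Multiplicative factors converting an age value in the given unit code to years.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
MAX_PLAUSIBLE_AGE_YEARS = 150.0

WEIGHT_UNIT_TO_KG = {
    "KG": 1.0,
    "KGS": 1.0,
    "LBS": 0.453592,
    "GMS": 0.001,
}

REPORTER_CODE_MAP = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "other_health_professional",
    "OT": "other_health_professional",
    "LW": "lawyer",
    "RN": "registered_nurse",
}

# Editable ISO-2 → display-name map; unmatched codes are kept verbatim and the
# descriptive summaries bucket them under "Others".
COUNTRY_MAP = {
    "US": "United States",
    "GB": "United Kingdom",
    "FR": "France",
    "DE": "Germany",
    "IT": "Italy",
    "CA": "Canada",
    "NL": "Netherlands",
    "ES": "Spain",
    "SG": "Singapore",
    "TR": "Turkey",
    "JP": "Japan",
    "IN": "India",
    "BE": "Belgium",
    "RU": "Russia",
    "AU": "Australia",
    "CN": "China",
}


class FaersError(Exception):
    """Base class for errors raised by this package."""


class MissingTableError(FaersError):
    """A mandatory FAERS table (DEMO, DRUG or REAC) is absent."""


class SchemaVersionError(FaersError):
    """Interchange file written with an incompatible schema version."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RawRecordSet:
    """One parsed '$'-delimited table for one quarter.

    ``rows`` preserves field values verbatim (only the trailing newline is
    stripped); ``rejects`` lists (line_number, raw_line) for rows whose field
    count does not match the header.
    """

    table_name: str
    quarter: str
    header: list[str]
    rows: list[dict[str, str]]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table_name not in TABLE_NAMES:
            raise ValueError(f"unknown table name {self.table_name!r}")
        if not QUARTER_RE.match(self.quarter):
            raise ValueError(f"quarter label {self.quarter!r} does not match YYYYQ[1-4]")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(slots=True)
class DrugEntry:
    """One drug record within a report: role, names, and its indications."""

    seq: int
    role: str  # PS | SS | C | I
    verbatim_name: str
    active_ingredient: str | None = None
    standardized_name: str | None = None
    indications: set[str] = field(default_factory=set)


@dataclass(slots=True)
class SafetyReport:
    """One (version of a) spontaneous adverse-event case report."""

    primaryid: str
    caseid: str
    case_version: int
    receipt_date: _dt.date
    age_years: float | None = None
    sex: str = "UNK"
    weight_kg: float | None = None
    reporter: str = "unknown"
    country: str | None = None
    route: str | None = None
    outcomes: set[str] = field(default_factory=set)
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = self.outcomes - OUTCOME_CODES
        if bad:
            raise ValueError(f"invalid outcome codes {sorted(bad)}")
        if self.case_version < 1:
            raise ValueError("case_version must be >= 1")


@dataclass
class MedDRADict:
    """PT → System Organ Class lookup.

    Lookup is case-insensitive after whitespace normalisation; PTs absent from
    the mapping resolve to the sentinel SOC ``"UNMAPPED"``.
    """

    pt_to_soc: dict[str, str]
    version_label: str = "unversioned"

    UNMAPPED = "UNMAPPED"

    def __post_init__(self) -> None:
        self.pt_to_soc = {_norm_term(pt): soc for pt, soc in self.pt_to_soc.items()}

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(_norm_term(pt), self.UNMAPPED)

    def __contains__(self, pt: str) -> bool:
        return _norm_term(pt) in self.pt_to_soc

    @classmethod
    def from_file(cls, path: str | Path, version_label: str | None = None) -> "MedDRADict":
        """Read a two-column delimited (pt, soc) file with a header row."""
        path = Path(path)
        lines = path.read_text().splitlines()
        if not lines:
            raise FaersError(f"empty dictionary file: {path}")
        sep = _sniff_delimiter(lines[0])
        mapping: dict[str, str] = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise FaersError(f"malformed dictionary line in {path}: {line!r}")
            mapping[parts[0]] = parts[1].strip()
        return cls(mapping, version_label or path.stem)


def _norm_term(term: str) -> str:
    return " ".join(term.upper().split())


def _sniff_delimiter(header_line: str) -> str:
    for sep in ("\t", "$", ";", ","):
        if sep in header_line:
            return sep
    raise FaersError(f"cannot determine delimiter of header {header_line!r}")


# ---------------------------------------------------------------------------
# Reading quarterly ASCII tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path, table_name: str, quarter: str) -> RawRecordSet:
    """Parse one '$'-delimited ASCII table file.

    The first line is the header.  Rows whose field count differs from the
    header's are recorded in ``rejects`` with their 1-based line number and are
    not silently dropped from the accounting.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise FaersError(f"{path}: empty file, expected a '$'-delimited header")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    n_fields = len(header)
    rows: list[dict[str, str]] = []
    rejects: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            rejects.append((lineno, line))
            continue
        rows.append(dict(zip(header, parts)))
    rs = RawRecordSet(table_name, quarter, header, rows, rejects)
    logger.info("%s %s: %d rows parsed, %d rejected", table_name, quarter, len(rows), len(rejects))
    return rs


def read_quarter(paths: Mapping[str, str | Path], quarter: str) -> dict[str, RawRecordSet]:
    """Read the per-table files of one quarter into RawRecordSets.

    ``paths`` maps table names (DEMO, DRUG, ...) to file paths.  DEMO, DRUG and
    REAC are mandatory; other tables are read when present.
    """
    if not QUARTER_RE.match(quarter):
        raise ValueError(f"quarter label {quarter!r} does not match YYYYQ[1-4]")
    missing = [t for t in MANDATORY_TABLES if t not in paths or not Path(paths[t]).exists()]
    if missing:
        raise MissingTableError(f"mandatory table(s) missing for {quarter}: {', '.join(missing)}")
    out: dict[str, RawRecordSet] = {}
    for table_name, path in paths.items():
        if table_name not in TABLE_NAMES:
            raise ValueError(f"unknown table name {table_name!r}")
        out[table_name] = read_table(path, table_name, quarter)
    return out


# ---------------------------------------------------------------------------
# Field normalisation
# ---------------------------------------------------------------------------


def normalize_age(value: str | float | None, unit_code: str | None) -> float | None:
    """Convert an (age value, unit code) pair to years.

    Unknown or blank unit codes yield missing, as do non-numeric values and
    implausible results (> 150 years).  Rounded to 2 decimals; idempotent when
    re-applied with unit 'YR'.
    """
    if value is None or value == "":
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    factor = AGE_UNIT_TO_YEARS.get((unit_code or "").strip().upper())
    if factor is None or v < 0:
        return None
    years = round(v * factor, 2)
    return years if years <= MAX_PLAUSIBLE_AGE_YEARS else None


def normalize_weight(value: str | float | None, unit_code: str | None) -> float | None:
    """Convert a (weight value, unit code) pair to kilograms (2 decimals)."""
    if value is None or value == "":
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    factor = WEIGHT_UNIT_TO_KG.get((unit_code or "").strip().upper())
    if factor is None or v < 0:
        return None
    return round(v * factor, 2)


def normalize_country(raw: str | None) -> str | None:
    if raw is None or not raw.strip():
        return None
    code = raw.strip()
    return COUNTRY_MAP.get(code.upper(), code)


def _parse_date(raw: str | None) -> _dt.date | None:
    if not raw:
        return None
    raw = raw.strip()
    for fmt in ("%Y%m%d", "%Y-%m-%d"):
        try:
            return _dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    return None


# ---------------------------------------------------------------------------
# Assembling SafetyReports
# ---------------------------------------------------------------------------


def assemble_reports(
    raw: Mapping[str, RawRecordSet],
    meddra: MedDRADict | None = None,
) -> list[SafetyReport]:
    """Join raw DEMO/DRUG/REAC/OUTC/INDI record sets into SafetyReports.

    One report is produced per DEMO row.  Child-table rows whose ``primaryid``
    matches no DEMO row are counted as orphans, logged and excluded.  Reaction
    PTs are upper-case normalised and de-duplicated per report; PTs absent from
    ``meddra`` are kept (their SOC resolves to "UNMAPPED" at analysis time).
    """
    demo = raw.get("DEMO")
    if demo is None:
        raise MissingTableError("DEMO record set required to assemble reports")

    by_pid: dict[str, SafetyReport] = {}
    for row in demo.rows:
        pid = row.get("primaryid", "").strip()
        if not pid:
            continue
        report = SafetyReport(
            primaryid=pid,
            caseid=row.get("caseid", "").strip() or pid,
            case_version=int(row.get("caseversion", "1") or 1),
            receipt_date=_parse_date(row.get("fda_dt")) or _dt.date(1900, 1, 1),
            age_years=normalize_age(row.get("age"), row.get("age_cod")),
            sex=(row.get("sex", "").strip().upper() if row.get("sex", "").strip().upper() in ("F", "M") else "UNK"),
            weight_kg=normalize_weight(row.get("wt"), row.get("wt_cod")),
            reporter=REPORTER_CODE_MAP.get(row.get("occp_cod", "").strip().upper(), "unknown"),
            country=normalize_country(row.get("reporter_country") or row.get("occr_country")),
        )
        by_pid[pid] = report

    orphans = {t: 0 for t in ("DRUG", "REAC", "OUTC", "INDI")}

    drug_by_key: dict[tuple[str, int], DrugEntry] = {}
    if "DRUG" in raw:
        for row in raw["DRUG"].rows:
            pid = row.get("primaryid", "").strip()
            report = by_pid.get(pid)
            if report is None:
                orphans["DRUG"] += 1
                continue
            seq = int(row.get("drug_seq", "0") or 0)
            role = row.get("role_cod", "").strip().upper()
            entry = DrugEntry(
                seq=seq,
                role=role if role in DRUG_ROLES else "C",
                verbatim_name=row.get("drugname", "").strip(),
                active_ingredient=(row.get("prod_ai", "").strip() or None),
            )
            report.drugs.append(entry)
            drug_by_key[(pid, seq)] = entry
            route = row.get("route", "").strip()
            if route and report.route is None:
                report.route = route

    if "REAC" in raw:
        for row in raw["REAC"].rows:
            pid = row.get("primaryid", "").strip()
            report = by_pid.get(pid)
            if report is None:
                orphans["REAC"] += 1
                continue
            pt = _norm_term(row.get("pt", ""))
            if pt:
                report.reactions.add(pt)

    if "OUTC" in raw:
        for row in raw["OUTC"].rows:
            pid = row.get("primaryid", "").strip()
            report = by_pid.get(pid)
            if report is None:
                orphans["OUTC"] += 1
                continue
            code = row.get("outc_cod", "").strip().upper()
            if code in OUTCOME_CODES:
                report.outcomes.add(code)

    if "INDI" in raw:
        for row in raw["INDI"].rows:
            pid = row.get("primaryid", "").strip()
            if pid not in by_pid:
                orphans["INDI"] += 1
                continue
            seq = int(row.get("indi_drug_seq", "0") or 0)
            entry = drug_by_key.get((pid, seq))
            if entry is None:
                orphans["INDI"] += 1
                continue
            pt = _norm_term(row.get("indi_pt", ""))
            if pt:
                entry.indications.add(pt)

    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.warning("orphan child rows excluded: %s", orphans)
    logger.info("assembled %d reports from %d DEMO rows", len(by_pid), len(demo.rows))
    return list(by_pid.values())


# ---------------------------------------------------------------------------
# Interchange format (JSON lines)
# ---------------------------------------------------------------------------


def _report_to_obj(r: SafetyReport) -> dict:
    return {
        "primaryid": r.primaryid,
        "caseid": r.caseid,
        "case_version": r.case_version,
        "receipt_date": r.receipt_date.isoformat(),
        "age_years": r.age_years,
        "sex": r.sex,
        "weight_kg": r.weight_kg,
        "reporter": r.reporter,
        "country": r.country,
        "route": r.route,
        "outcomes": sorted(r.outcomes),
        "reactions": sorted(r.reactions),
        "drugs": [
            {
                "seq": d.seq,
                "role": d.role,
                "verbatim_name": d.verbatim_name,
                "active_ingredient": d.active_ingredient,
                "standardized_name": d.standardized_name,
                "indications": sorted(d.indications),
            }
            for d in r.drugs
        ],
    }


def _report_from_obj(obj: dict) -> SafetyReport:
    return SafetyReport(
        primaryid=obj["primaryid"],
        caseid=obj["caseid"],
        case_version=obj["case_version"],
        receipt_date=_dt.date.fromisoformat(obj["receipt_date"]),
        age_years=obj["age_years"],
        sex=obj["sex"],
        weight_kg=obj["weight_kg"],
        reporter=obj["reporter"],
        country=obj["country"],
        route=obj["route"],
        outcomes=set(obj["outcomes"]),
        reactions=set(obj["reactions"]),
        drugs=[
            DrugEntry(
                seq=d["seq"],
                role=d["role"],
                verbatim_name=d["verbatim_name"],
                active_ingredient=d["active_ingredient"],
                standardized_name=d["standardized_name"],
                indications=set(d["indications"]),
            )
            for d in obj["drugs"]
        ],
    )


def write_reports(reports: Sequence[SafetyReport], path: str | Path) -> None:
    """Write reports to a JSON-lines interchange file (schema header first).

    Output bytes are stable for a fixed report ordering: keys are sorted and
    sets serialised in sorted order.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"format": INTERCHANGE_FORMAT, "version": INTERCHANGE_VERSION}, sort_keys=True))
        fh.write("\n")
        for r in reports:
            fh.write(json.dumps(_report_to_obj(r), sort_keys=True))
            fh.write("\n")


def read_reports(path: str | Path) -> list[SafetyReport]:
    """Read a JSON-lines interchange file back into SafetyReports."""
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise FaersError(f"{path}: empty interchange file")
        header = json.loads(header_line)
        if header.get("format") != INTERCHANGE_FORMAT or header.get("version") != INTERCHANGE_VERSION:
            raise SchemaVersionError(
                f"interchange schema mismatch: file has "
                f"{header.get('format')!r} v{header.get('version')!r}, "
                f"reader expects {INTERCHANGE_FORMAT!r} v{INTERCHANGE_VERSION!r}"
            )
        return [_report_from_obj(json.loads(line)) for line in fh if line.strip()]
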