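"""Spontaneous adverse-event report store.

Canonical in-memory model of a spontaneous-report database (one
:class:`SafetyReport` per case, carrying demographics, drug entries and
MedDRA-preferred-term event entries) plus readers/writers for FAERS-style
delimited files: three tables (demographics, drug, reaction) joined on a
report-ID key, with the ``$``-separated quarterly-file convention as the
default dialect.

Spontaneous-report databases have no exposure denominator; the unit of
everything downstream (pair counting, disproportionality) is the distinct
report, so within-report duplicate drug names and duplicate preferred terms
are collapsed on construction.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "SourceType",
    "Gender",
    "DrugRole",
    "PartialDate",
    "DrugEntry",
    "EventEntry",
    "SafetyReport",
    "ReportDatabase",
    "FileDialect",
    "normalize_drug_name",
    "read_reports",
    "write_reports",
    "DEFAULT_COMBO_MAP",
    "DEFAULT_SALT_SUFFIXES",
    "SchemaError",
]


class SchemaError(ValueError):
    """A source file does not carry the columns the dialect promises."""


class SourceType(str, Enum):
    SPONTANEOUS = "spontaneous"
    LITERATURE = "literature"
    STUDY = "study"


class Gender(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class DrugRole(str, Enum):
    SUSPECT = "suspect"
    CONCOMITANT = "concomitant"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date that may lack month and/or day.

    Regulatory report dates are frequently partial (year-only or
    year-month).  Stored as explicit components; ``yyyymmdd`` strings with
    zero or absent month/day parse to the corresponding partial date.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not (1850 <= self.year <= 2200):
            raise ValueError(f"implausible year {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"bad month {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day without month")
            if not (1 <= self.day <= 31):
                raise ValueError(f"bad day {self.day}")

    @classmethod
    def parse(cls, text: str) -> "PartialDate | None":
        """Parse a ``yyyymmdd`` / ``yyyymm`` / ``yyyy`` string; '' -> None.

        Zero month/day components ("20120000") count as missing.
        Raises ValueError on anything else.
        """
        text = text.strip()
        if not text:
            return None
        if not text.isdigit() or len(text) not in (4, 6, 8):
            raise ValueError(f"unparsable date {text!r}")
        year = int(text[:4])
        month = int(text[4:6]) if len(text) >= 6 else 0
        day = int(text[6:8]) if len(text) == 8 else 0
        return cls(year, month or None, (day or None) if month else None)

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def encode(self) -> str:
        """Render back to the compact ``yyyy[mm[dd]]`` form."""
        out = f"{self.year:04d}"
        if self.month is not None:
            out += f"{self.month:02d}"
            if self.day is not None:
                out += f"{self.day:02d}"
        return out

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name_raw: str
    name_canonical: str
    role: DrugRole = DrugRole.UNKNOWN
    start_date: PartialDate | None = None

    def __post_init__(self) -> None:
        if not self.name_canonical:
            raise ValueError("empty canonical drug name")


@dataclass(frozen=True)
class EventEntry:
    """One adverse-event mention, coded as a MedDRA-like preferred term.

    The PT acts as a case-insensitive key; `pt_key` is the lowercased form
    used everywhere counting or matching happens.
    """

    preferred_term: str
    onset_date: PartialDate | None = None

    def __post_init__(self) -> None:
        if not self.preferred_term.strip():
            raise ValueError("empty preferred term")

    @property
    def pt_key(self) -> str:
        return self.preferred_term.strip().lower()


def _collapse_drugs(drugs: Sequence[DrugEntry]) -> tuple[DrugEntry, ...]:
    seen: dict[str, DrugEntry] = {}
    for d in drugs:
        seen.setdefault(d.name_canonical, d)
    return tuple(seen.values())


def _collapse_events(events: Sequence[EventEntry]) -> tuple[EventEntry, ...]:
    seen: dict[str, EventEntry] = {}
    for e in events:
        seen.setdefault(e.pt_key, e)
    return tuple(seen.values())


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous report: demographics, provenance, drugs, events.

    A report mentions a given drug or preferred term at most once
    (duplicates collapse at construction); age, when present, must lie in
    [0, 150] years.
    """

    report_id: str
    source_type: SourceType = SourceType.SPONTANEOUS
    gender: Gender = Gender.UNKNOWN
    age_years: float | None = None
    death_date: PartialDate | None = None
    receipt_date: PartialDate | None = None
    manufacturer: str | None = None
    drugs: tuple[DrugEntry, ...] = ()
    events: tuple[EventEntry, ...] = ()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("empty report_id")
        if self.age_years is not None and not (0 <= self.age_years <= 150):
            raise ValueError(f"age {self.age_years} outside [0, 150]")
        object.__setattr__(self, "drugs", _collapse_drugs(tuple(self.drugs)))
        object.__setattr__(self, "events", _collapse_events(tuple(self.events)))

    @property
    def drug_names(self) -> frozenset[str]:
        """Canonical names of all drugs on the report."""
        return frozenset(d.name_canonical for d in self.drugs)

    @property
    def event_terms(self) -> frozenset[str]:
        """Lowercased preferred-term keys of all events on the report."""
        return frozenset(e.pt_key for e in self.events)

    def suspect_drug_names(self) -> frozenset[str]:
        return frozenset(
            d.name_canonical for d in self.drugs if d.role is DrugRole.SUSPECT
        )


class ReportDatabase:
    """A collection of :class:`SafetyReport` with drug and PT indices.

    The indices map canonical drug name / lowercased PT to the set of
    report IDs mentioning them and are rebuilt from report contents, so they
    are consistent by construction.  Reports with zero drugs or zero events
    are retained and counted in the report total: the expected-count
    denominator downstream is the total number of reports.
    """

    def __init__(self, reports: Iterable[SafetyReport] = ()):
        self._reports: dict[str, SafetyReport] = {}
        for r in reports:
            if r.report_id in self._reports:
                raise ValueError(f"duplicate report_id {r.report_id!r}")
            self._reports[r.report_id] = r
        self.rebuild_indices()

    def rebuild_indices(self) -> None:
        self.drug_index: dict[str, set[str]] = {}
        self.pt_index: dict[str, set[str]] = {}
        for rid, r in self._reports.items():
            for name in r.drug_names:
                self.drug_index.setdefault(name, set()).add(rid)
            for pt in r.event_terms:
                self.pt_index.setdefault(pt, set()).add(rid)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self._reports.values())

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._reports

    def __getitem__(self, report_id: str) -> SafetyReport:
        return self._reports[report_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportDatabase):
            return NotImplemented
        return self._reports == other._reports

    @property
    def report_ids(self) -> list[str]:
        return list(self._reports)

    def reports_with_drug(self, name: str) -> set[str]:
        return set(self.drug_index.get(name.lower(), set()))

    def reports_with_pt(self, pt: str) -> set[str]:
        return set(self.pt_index.get(pt.lower(), set()))

    def check_invariants(self) -> None:
        """Assert index consistency by full rebuild; raises on violation."""
        drug_index, pt_index = self.drug_index, self.pt_index
        self.rebuild_indices()
        if drug_index != self.drug_index or pt_index != self.pt_index:
            raise AssertionError("report indices inconsistent with contents")

    def to_frame(self):
        """Canonical one-row-per-report table (pandas DataFrame).

        Drug and event lists are ';'-joined; intended for TSV export.
        """
        import pandas as pd

        rows = []
        for r in self:
            rows.append(
                {
                    "report_id": r.report_id,
                    "source_type": r.source_type.value,
                    "gender": r.gender.value,
                    "age_years": r.age_years,
                    "death_date": r.death_date.isoformat() if r.death_date else "",
                    "receipt_date": r.receipt_date.isoformat() if r.receipt_date else "",
                    "manufacturer": r.manufacturer or "",
                    "drugs": ";".join(sorted(r.drug_names)),
                    "events": ";".join(sorted(r.event_terms)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "report_id",
                "source_type",
                "gender",
                "age_years",
                "death_date",
                "receipt_date",
                "manufacturer",
                "drugs",
                "events",
            ],
        )


# ---------------------------------------------------------------------------
# Drug-name normalization
# ---------------------------------------------------------------------------

#: The fixed-dose combination of efavirenz, emtricitabine and tenofovir
#: disoproxil fumarate expands to its components, so exposure to the combo
#: product counts as exposure to each active ingredient.
DEFAULT_COMBO_MAP: Mapping[str, tuple[str, ...]] = {
    "efavirenz/emtricitabine/tenofovir disoproxil fumarate": (
        "efavirenz",
        "emtricitabine",
        "tenofovir disoproxil fumarate",
    ),
    "atripla": (
        "efavirenz",
        "emtricitabine",
        "tenofovir disoproxil fumarate",
    ),
}

#: Salt/ester suffixes that may be stripped when a salt-stripping rule is
#: configured.  Deliberately excludes "fumarate"-type esters that are part
#: of distinct active-moiety names (tenofovir disoproxil fumarate).
DEFAULT_SALT_SUFFIXES: tuple[str, ...] = (
    "sulfate",
    "sulphate",
    "hydrochloride",
    "hcl",
    "sodium",
    "potassium",
    "calcium",
    "mesylate",
    "maleate",
    "tartrate",
    "besylate",
)

_WS = re.compile(r"\s+")


def normalize_drug_name(
    name_raw: str,
    combo_map: Mapping[str, Sequence[str]] | None = None,
    salt_suffixes: Sequence[str] = (),
) -> list[str]:
    """Canonicalize a reported drug name; combo products expand to components.

    Lowercases, trims surrounding whitespace/punctuation, collapses internal
    whitespace, optionally strips a configured trailing salt suffix, then
    looks the result up in ``combo_map`` (keys canonicalized the same way).

    Returns the list of canonical component names (length 1 for a
    non-combination product).  Raises ValueError for names empty after
    normalization.
    """
    if combo_map is None:
        combo_map = DEFAULT_COMBO_MAP
    name = _WS.sub(" ", name_raw.strip().lower()).strip(" .,;:*()[]\"'")
    if not name:
        raise ValueError(f"drug name empty after normalization: {name_raw!r}")
    for suffix in salt_suffixes:
        s = " " + suffix.lower()
        if name.endswith(s) and len(name) > len(s):
            name = name[: -len(s)].rstrip()
            break
    canonical_combo = {
        _WS.sub(" ", k.strip().lower()): tuple(v) for k, v in combo_map.items()
    }
    if name in canonical_combo:
        return list(canonical_combo[name])
    return [name]


# ---------------------------------------------------------------------------
# File dialect + readers/writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FileDialect:
    """Layout of the three delimited report tables.

    Defaults follow the FAERS quarterly ASCII convention: ``$`` delimiter,
    header row, compact ``yyyymmdd`` dates with year-only/year-month partial
    dates allowed.  Column names are configurable; each mapping goes from a
    logical field to the column header in the file.
    """

    delimiter: str = "$"
    has_header: bool = True
    demo_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "report_id": "primaryid",
            "source_type": "source",
            "gender": "sex",
            "age_years": "age",
            "death_date": "death_dt",
            "receipt_date": "receipt_dt",
            "manufacturer": "mfr_sndr",
        }
    )
    drug_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "report_id": "primaryid",
            "name": "drugname",
            "role": "role_cod",
            "start_date": "start_dt",
        }
    )
    reac_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "report_id": "primaryid",
            "preferred_term": "pt",
            "onset_date": "onset_dt",
        }
    )


_GENDER_CODES = {"f": Gender.F, "female": Gender.F, "m": Gender.M, "male": Gender.M}
_SOURCE_CODES = {
    "spontaneous": SourceType.SPONTANEOUS,
    "spn": SourceType.SPONTANEOUS,
    "literature": SourceType.LITERATURE,
    "lit": SourceType.LITERATURE,
    "study": SourceType.STUDY,
    "clinical study": SourceType.STUDY,
}
_ROLE_CODES = {
    "ps": DrugRole.SUSPECT,
    "ss": DrugRole.SUSPECT,
    "suspect": DrugRole.SUSPECT,
    "c": DrugRole.CONCOMITANT,
    "concomitant": DrugRole.CONCOMITANT,
}


def _read_table(
    source, columns: Mapping[str, str], dialect: FileDialect, label: str
) -> tuple[list[dict[str, str]], int]:
    """Read one delimited table into row dicts keyed by logical field.

    Returns (rows, n_skipped).  Rows with the wrong field count or an empty
    report-ID cell are skipped and counted, never silently dropped.
    """
    path = Path(source)
    try:
        fh = path.open("r", newline="", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read {label} file {path}: {exc}") from exc
    with fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{label} file {path} is empty")
        if dialect.has_header:
            positions = {name: i for i, name in enumerate(header)}
        else:
            # headerless: dialect column names are taken as an ordered layout
            positions = {name: i for i, name in enumerate(columns.values())}
            fh.seek(0)
            reader = csv.reader(fh, delimiter=dialect.delimiter)
        idx: dict[str, int] = {}
        for logical, colname in columns.items():
            if colname in positions:
                idx[logical] = positions[colname]
        if "report_id" not in idx:
            raise SchemaError(
                f"{label} file {path} lacks report-ID column "
                f"{columns['report_id']!r}"
            )
        width = max(idx.values()) + 1
        rows: list[dict[str, str]] = []
        skipped = 0
        for raw in reader:
            if len(raw) < width or not raw[idx["report_id"]].strip():
                skipped += 1
                continue
            rows.append(
                {logical: raw[i].strip() for logical, i in idx.items()}
            )
    return rows, skipped


def _parse_date(text: str, where: str) -> PartialDate | None:
    try:
        return PartialDate.parse(text)
    except ValueError:
        log.debug("unparsable date %r in %s treated as missing", text, where)
        return None


def read_reports(
    demo_source,
    drug_source,
    reac_source,
    dialect: FileDialect | None = None,
    combo_map: Mapping[str, Sequence[str]] | None = None,
    salt_suffixes: Sequence[str] = (),
) -> ReportDatabase:
    """Assemble a :class:`ReportDatabase` from three delimited tables.

    One SafetyReport per distinct report ID across all three files; drug or
    reaction rows whose ID has no demographics row become reports with
    missing demographics.  Malformed rows are skipped and their count logged
    per file.  Drug names are canonicalized (and combo products expanded)
    via :func:`normalize_drug_name`.
    """
    if dialect is None:
        dialect = FileDialect()

    demo_rows, demo_skipped = _read_table(
        demo_source, dialect.demo_columns, dialect, "demographics"
    )
    drug_rows, drug_skipped = _read_table(
        drug_source, dialect.drug_columns, dialect, "drug"
    )
    reac_rows, reac_skipped = _read_table(
        reac_source, dialect.reac_columns, dialect, "reaction"
    )
    log.info(
        "read %d demo, %d drug, %d reaction rows (skipped malformed: %d/%d/%d)",
        len(demo_rows),
        len(drug_rows),
        len(reac_rows),
        demo_skipped,
        drug_skipped,
        reac_skipped,
    )

    demo: dict[str, dict[str, str]] = {}
    for row in demo_rows:
        demo.setdefault(row["report_id"], row)

    drugs: dict[str, list[DrugEntry]] = {}
    n_bad_drug = 0
    for row in drug_rows:
        rid = row["report_id"]
        raw = row.get("name", "")
        try:
            names = normalize_drug_name(raw, combo_map, salt_suffixes)
        except ValueError:
            n_bad_drug += 1
            continue
        role = _ROLE_CODES.get(row.get("role", "").lower(), DrugRole.UNKNOWN)
        start = _parse_date(row.get("start_date", ""), "drug start")
        for name in names:
            drugs.setdefault(rid, []).append(
                DrugEntry(name_raw=raw, name_canonical=name, role=role, start_date=start)
            )
    if n_bad_drug:
        log.info("skipped %d drug rows with empty drug names", n_bad_drug)

    events: dict[str, list[EventEntry]] = {}
    n_bad_reac = 0
    for row in reac_rows:
        rid = row["report_id"]
        pt = row.get("preferred_term", "")
        if not pt.strip():
            n_bad_reac += 1
            continue
        onset = _parse_date(row.get("onset_date", ""), "event onset")
        events.setdefault(rid, []).append(EventEntry(preferred_term=pt, onset_date=onset))
    if n_bad_reac:
        log.info("skipped %d reaction rows with empty preferred terms", n_bad_reac)

    all_ids = list(
        dict.fromkeys([*demo.keys(), *drugs.keys(), *events.keys()])
    )
    reports = []
    for rid in all_ids:
        row = demo.get(rid, {})
        age: float | None = None
        age_text = row.get("age_years", "")
        if age_text:
            try:
                age = float(age_text)
            except ValueError:
                log.debug("unparsable age %r for %s treated as missing", age_text, rid)
            else:
                if not (0 <= age <= 150):
                    log.debug("age %s for %s out of range, treated as missing", age, rid)
                    age = None
        reports.append(
            SafetyReport(
                report_id=rid,
                source_type=_SOURCE_CODES.get(
                    row.get("source_type", "").lower(), SourceType.SPONTANEOUS
                ),
                gender=_GENDER_CODES.get(row.get("gender", "").lower(), Gender.UNKNOWN),
                age_years=age,
                death_date=_parse_date(row.get("death_date", ""), "death date"),
                receipt_date=_parse_date(row.get("receipt_date", ""), "receipt date"),
                manufacturer=row.get("manufacturer") or None,
                drugs=drugs.get(rid, []),
                events=events.get(rid, []),
            )
        )
    return ReportDatabase(reports)


def _fmt_date(d: PartialDate | None) -> str:
    return d.encode() if d is not None else ""


def write_reports(
    db: ReportDatabase,
    demo_target,
    drug_target,
    reac_target,
    dialect: FileDialect | None = None,
) -> None:
    """Write the three delimited tables; inverse of :func:`read_reports`.

    Missing fields encode as empty cells and round-trip to missing; an
    empty database yields three header-only files.
    """
    if dialect is None:
        dialect = FileDialect()
    dc, gc, rc = dialect.demo_columns, dialect.drug_columns, dialect.reac_columns

    def _open(target, label):
        try:
            return Path(target).open("w", newline="", encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot write {label} file {target}: {exc}") from exc

    with _open(demo_target, "demographics") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow(list(dc.values()))
        for r in db:
            w.writerow(
                [
                    r.report_id,
                    r.source_type.value,
                    r.gender.value if r.gender is not Gender.UNKNOWN else "",
                    "" if r.age_years is None else repr(r.age_years),
                    _fmt_date(r.death_date),
                    _fmt_date(r.receipt_date),
                    r.manufacturer or "",
                ]
            )
    with _open(drug_target, "drug") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow(list(gc.values()))
        for r in db:
            for d in r.drugs:
                w.writerow(
                    [
                        r.report_id,
                        d.name_canonical,
                        {
                            DrugRole.SUSPECT: "PS",
                            DrugRole.CONCOMITANT: "C",
                            DrugRole.UNKNOWN: "",
                        }[d.role],
                        _fmt_date(d.start_date),
                    ]
                )
    with _open(reac_target, "reaction") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow(list(rc.values()))
        for r in db:
            for e in r.events:
                w.writerow([r.report_id, e.pt_key, _fmt_date(e.onset_date)])
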