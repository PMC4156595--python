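"""Multi-stage duplicate-report detection and removal.

Spontaneous-report systems receive the same case from several routes
(consumer, manufacturer, investigator), so duplicate reports are common and
inflate disproportionality scores.  Detection here is deterministic staged
matching: an ordered ladder of :class:`MatchStage` rules, strict to loose.
Within a stage two reports match when every required demographic field
agrees (ages within a tolerance; a death date is compared only when present
on both reports) and every required record field — manufacturer, the drug
set, the event set, drug/event start dates — is equal.  Duplicate groups
are the connected components of the stage's match relation among reports
not already claimed by an earlier stage, and the stage a report is eligible
for can depend on its source (spontaneous versus literature/study).

Missing values never satisfy a required match: a report lacking a required
field (including an empty drug or event set) is simply ineligible for that
stage.  The single exception is the death date, which passes when absent
from both reports and fails when present on exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

from .report_store import (
    Gender,
    ReportDatabase,
    SafetyReport,
    SourceType,
)

__all__ = [
    "MatchStage",
    "DuplicateGroup",
    "default_stage_ladder",
    "find_duplicates",
    "remove_duplicates",
]

_DEMO_FIELDS = frozenset({"gender", "age", "death_date"})
_RECORD_FIELDS = frozenset(
    {"manufacturer", "drug_set", "event_set", "drug_start_dates", "event_start_dates"}
)
_ALL_SOURCES = frozenset(SourceType)


@dataclass(frozen=True)
class MatchStage:
    """One rung of the duplicate-matching ladder."""

    stage_name: str
    required_demographic_fields: frozenset[str] = frozenset()
    age_tolerance_years: float = 1.0
    required_record_fields: frozenset[str] = frozenset()
    applies_to_sources: frozenset[SourceType] = _ALL_SOURCES

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "required_demographic_fields", frozenset(self.required_demographic_fields)
        )
        object.__setattr__(
            self, "required_record_fields", frozenset(self.required_record_fields)
        )
        object.__setattr__(
            self,
            "applies_to_sources",
            frozenset(SourceType(s) for s in self.applies_to_sources),
        )
        bad = self.required_demographic_fields - _DEMO_FIELDS
        if bad:
            raise ValueError(f"unknown demographic fields {sorted(bad)}")
        bad = self.required_record_fields - _RECORD_FIELDS
        if bad:
            raise ValueError(f"unknown record fields {sorted(bad)}")
        if not (self.required_demographic_fields or self.required_record_fields):
            raise ValueError(f"stage {self.stage_name!r} requires no fields at all")
        if self.age_tolerance_years < 0:
            raise ValueError("age tolerance must be nonnegative")


@dataclass(frozen=True)
class DuplicateGroup:
    """Reports judged to describe one case; one representative survives."""

    member_ids: frozenset[str]
    stage_name: str
    representative_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))
        if len(self.member_ids) < 2:
            raise ValueError("a duplicate group needs at least 2 members")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a group member")


def default_stage_ladder(
    age_tolerance_years: float = 1.0, include_event_only_stage: bool = False
) -> list[MatchStage]:
    """Strict-to-loose default ladder.

    Stage 1 anchors on full demographics plus manufacturer, the drug and
    event sets and drug start dates; for literature/study reports the
    manufacturer requirement is dropped (those reports often arrive without
    a meaningful sender).  Stage 2 relaxes manufacturer and death date.
    Start dates are part of every default stage: demographic fields and
    term sets alone are too coarse to separate distinct cases in a large
    database, and essentially every report carries drug information.

    ``include_event_only_stage`` appends a loose fallback (gender + age +
    event set + event onset dates) for databases where drug records may be
    missing entirely; with complete drug records it only merges distinct
    cases that happen to share one event and demography, so it is off by
    default.

    The age tolerance ("nearby age values") defaults to ±1 year and is a
    configuration knob.
    """
    spont = frozenset({SourceType.SPONTANEOUS})
    litstudy = frozenset({SourceType.LITERATURE, SourceType.STUDY})
    ladder = [
        MatchStage(
            "demo+mfr+drugs+events+drug_dates",
            frozenset({"gender", "age", "death_date"}),
            age_tolerance_years,
            frozenset({"manufacturer", "drug_set", "event_set", "drug_start_dates"}),
            spont,
        ),
        MatchStage(
            "demo+drugs+events+drug_dates (lit/study)",
            frozenset({"gender", "age", "death_date"}),
            age_tolerance_years,
            frozenset({"drug_set", "event_set", "drug_start_dates"}),
            litstudy,
        ),
        MatchStage(
            "demo+drugs+events",
            frozenset({"gender", "age"}),
            age_tolerance_years,
            frozenset({"drug_set", "event_set", "drug_start_dates"}),
            _ALL_SOURCES,
        ),
    ]
    if include_event_only_stage:
        ladder.append(
            MatchStage(
                "demo+events+event_dates",
                frozenset({"gender", "age"}),
                age_tolerance_years,
                frozenset({"event_set", "event_start_dates"}),
                _ALL_SOURCES,
            )
        )
    return ladder


def _stage_key(report: SafetyReport, stage: MatchStage) -> tuple[Hashable, ...] | None:
    """Exact-equality blocking key for a stage, or None if ineligible.

    Age is excluded from the key (it matches within a tolerance, handled
    separately); everything else must be equal outright.
    """
    if report.source_type not in stage.applies_to_sources:
        return None
    key: list[Hashable] = []
    if "gender" in stage.required_demographic_fields:
        if report.gender is Gender.UNKNOWN:
            return None
        key.append(report.gender)
    if "age" in stage.required_demographic_fields and report.age_years is None:
        return None
    if "death_date" in stage.required_demographic_fields:
        # absent-in-both passes, so None is a legitimate key value
        key.append(report.death_date)
    for fname in sorted(stage.required_record_fields):
        if fname == "manufacturer":
            if not report.manufacturer:
                return None
            key.append(report.manufacturer)
        elif fname == "drug_set":
            names = report.drug_names
            if not names:
                return None
            key.append(names)
        elif fname == "event_set":
            terms = report.event_terms
            if not terms:
                return None
            key.append(terms)
        elif fname == "drug_start_dates":
            if not report.drugs or any(d.start_date is None for d in report.drugs):
                return None
            key.append(frozenset((d.name_canonical, d.start_date) for d in report.drugs))
        elif fname == "event_start_dates":
            if not report.events or any(e.onset_date is None for e in report.events):
                return None
            key.append(frozenset((e.pt_key, e.onset_date) for e in report.events))
    return tuple(key)


def _keep_representative(
    members: Iterable[str], db: ReportDatabase, keep_rule: str
) -> str:
    ids = list(members)
    if keep_rule == "lexicographic_id":
        return min(ids)
    if keep_rule == "latest_receipt":
        def key(rid: str):
            r = db[rid]
            rd = r.receipt_date.sort_key() if r.receipt_date else (0, 0, 0)
            return (rd, rid)

        return max(ids, key=key)
    raise ValueError(f"unknown keep_rule {keep_rule!r}")


def find_duplicates(
    db: ReportDatabase,
    stages: Sequence[MatchStage] | None = None,
    keep_rule: str = "latest_receipt",
) -> list[DuplicateGroup]:
    """Evaluate the stage ladder in order and return disjoint duplicate groups.

    Groups are connected components of each stage's pairwise match relation,
    restricted to reports not grouped by an earlier stage, so each report
    belongs to at most one group.  Within a block of reports agreeing on all
    exact fields, the age-tolerance relation links a sorted run of ages
    whenever consecutive ages differ by at most the tolerance — exactly the
    connected components of the pairwise |Δage| ≤ tol graph.
    """
    if stages is None:
        stages = default_stage_ladder()
    if not stages:
        raise ValueError("stage ladder is empty")
    grouped: set[str] = set()
    groups: list[DuplicateGroup] = []
    for stage in stages:
        blocks: dict[tuple[Hashable, ...], list[str]] = {}
        for report in db:
            if report.report_id in grouped:
                continue
            key = _stage_key(report, stage)
            if key is not None:
                blocks.setdefault(key, []).append(report.report_id)

        use_age = "age" in stage.required_demographic_fields
        for members in blocks.values():
            if len(members) < 2:
                continue
            if use_age:
                members = sorted(
                    members, key=lambda rid: (db[rid].age_years, rid)
                )
                runs: list[list[str]] = [[members[0]]]
                for rid in members[1:]:
                    prev = runs[-1][-1]
                    if db[rid].age_years - db[prev].age_years <= stage.age_tolerance_years:
                        runs[-1].append(rid)
                    else:
                        runs.append([rid])
            else:
                runs = [members]
            for run in runs:
                if len(run) >= 2:
                    rep = _keep_representative(run, db, keep_rule)
                    groups.append(
                        DuplicateGroup(frozenset(run), stage.stage_name, rep)
                    )
                    grouped.update(run)
    return groups


def remove_duplicates(
    db: ReportDatabase,
    groups: Sequence[DuplicateGroup],
    keep_rule: str = "latest_receipt",
) -> ReportDatabase:
    """Drop all but one representative per duplicate group.

    Groups must be disjoint.  The returned database has
    ``len(db) - sum(len(g) - 1 for g in groups)`` reports and freshly built
    indices.
    """
    claimed: set[str] = set()
    drop: set[str] = set()
    for g in groups:
        if g.member_ids & claimed:
            raise ValueError("duplicate groups overlap")
        claimed |= g.member_ids
        rep = _keep_representative(g.member_ids, db, keep_rule)
        drop |= g.member_ids - {rep}
    return ReportDatabase(r for r in db if r.report_id not in drop)
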