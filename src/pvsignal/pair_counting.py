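"""Drug × event-term contingency counting for disproportionality analysis.

Counts are counts of distinct reports.  An event term is either a single
MedDRA-like preferred term or a composite pooling several PTs (e.g. a
"suicidality" endpoint combining suicidal ideation, suicide attempt and
completed suicide); a report carrying two member PTs of a composite still
contributes one unique report to the composite cell, while contributing to
each member PT's own cell.

The expected count under independence of drug and event reporting is

    E = (reports with event X) x (reports with drug Y) / (total reports)

and the relative reporting ratio is RRR = N / E — the raw
disproportionality measure that the gamma-Poisson shrinkage model
stabilizes downstream.  The denominator is the total number of reports in
the analyzed (deduplicated) database, including reports that mention none
of the studied drugs or terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

from .report_store import ReportDatabase, SafetyReport

log = logging.getLogger(__name__)

__all__ = [
    "EventTerm",
    "PairCountTable",
    "ContingencyCell",
    "UndefinedCellError",
    "DEFAULT_TERMS",
    "count_pairs",
    "expected_count",
    "make_cells",
    "term_level_totals",
    "stratified_expected_counts",
]


class UndefinedCellError(ValueError):
    """Expected count undefined because a margin is zero."""


@dataclass(frozen=True)
class EventTerm:
    """A named endpoint: one PT, or a composite set of PTs."""

    name: str
    member_pts: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "member_pts", frozenset(pt.strip().lower() for pt in self.member_pts)
        )
        if not self.member_pts:
            raise ValueError(f"term {self.name!r} has no member PTs")

    @classmethod
    def single(cls, pt: str) -> "EventTerm":
        return cls(name=pt.strip().lower(), member_pts=frozenset({pt}))

    @classmethod
    def composite(cls, name: str, pts: Iterable[str]) -> "EventTerm":
        return cls(name=name, member_pts=frozenset(pts))


#: The shipped example term set: three suicidality PTs plus their composite.
DEFAULT_TERMS: tuple[EventTerm, ...] = (
    EventTerm.single("suicidal ideation"),
    EventTerm.single("suicide attempt"),
    EventTerm.single("completed suicide"),
    EventTerm.composite(
        "suicidality",
        ["suicidal ideation", "suicide attempt", "completed suicide"],
    ),
)


@dataclass
class PairCountTable:
    """Report-level (drug, term) counts with margins and grand total."""

    cells: dict[tuple[str, str], int]
    drug_margins: dict[str, int]
    term_margins: dict[str, int]
    total_reports: int

    def __post_init__(self) -> None:
        if self.total_reports <= 0:
            raise ValueError("total_reports must be positive")
        for (drug, term), n in self.cells.items():
            if n < 0:
                raise ValueError(f"negative count in cell ({drug}, {term})")
            if n > min(
                self.drug_margins.get(drug, 0), self.term_margins.get(term, 0)
            ):
                raise ValueError(
                    f"cell ({drug}, {term}) exceeds a margin: "
                    f"N={n}, drug={self.drug_margins.get(drug)}, "
                    f"term={self.term_margins.get(term)}"
                )
        for name, m in {**self.drug_margins, **self.term_margins}.items():
            if m > self.total_reports:
                raise ValueError(f"margin for {name!r} exceeds total reports")

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "drug": drug,
                "term": term,
                "N": n,
                "drug_margin": self.drug_margins[drug],
                "term_margin": self.term_margins[term],
                "total_reports": self.total_reports,
            }
            for (drug, term), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["drug", "term", "N", "drug_margin", "term_margin", "total_reports"]
        )


@dataclass(frozen=True)
class ContingencyCell:
    """One (drug, term) pair: observed N, expected E, RRR = N/E."""

    drug: str
    term: str
    observed_n: int
    expected_e: float
    rrr: float

    def __post_init__(self) -> None:
        if self.expected_e <= 0:
            raise ValueError("expected count must be positive")
        if self.observed_n < 0:
            raise ValueError("observed count must be nonnegative")
        if abs(self.rrr - self.observed_n / self.expected_e) > 1e-9 * max(
            1.0, self.rrr
        ):
            raise ValueError("rrr inconsistent with N/E")


def count_pairs(
    db: ReportDatabase,
    terms: Sequence[EventTerm],
    drugs: Sequence[str] | None = None,
    suspect_only: bool = False,
) -> PairCountTable:
    """Count distinct reports per (drug, term) cell, with margins.

    drug margin = number of reports mentioning the drug; term margin =
    number of reports mentioning at least one member PT; a report counts at
    most once per cell regardless of how many member PTs it carries.
    ``drugs`` restricts (and orders) the drug universe; by default every
    drug in the database is counted.  ``suspect_only`` counts exposure only
    through suspect-role drug entries.
    """
    if not terms:
        raise ValueError("term set is empty")
    if drugs is None:
        drug_names = sorted(db.drug_index)
    else:
        drug_names = [d.strip().lower() for d in drugs]

    if suspect_only:
        drug_ids: dict[str, set[str]] = {d: set() for d in drug_names}
        for r in db:
            for name in r.suspect_drug_names():
                if name in drug_ids:
                    drug_ids[name].add(r.report_id)
    else:
        drug_ids = {d: db.reports_with_drug(d) for d in drug_names}

    term_ids: dict[str, set[str]] = {}
    for t in terms:
        ids: set[str] = set()
        for pt in t.member_pts:
            ids |= db.reports_with_pt(pt)
        term_ids[t.name] = ids

    cells = {
        (d, t.name): len(drug_ids[d] & term_ids[t.name])
        for d in drug_names
        for t in terms
    }
    return PairCountTable(
        cells=cells,
        drug_margins={d: len(ids) for d, ids in drug_ids.items()},
        term_margins={t: len(ids) for t, ids in term_ids.items()},
        total_reports=len(db),
    )


def expected_count(table: PairCountTable, drug: str, term: str) -> float:
    """Independence-model expected count E = term_margin * drug_margin / total."""
    dm = table.drug_margins.get(drug, 0)
    tm = table.term_margins.get(term, 0)
    if dm == 0 or tm == 0:
        raise UndefinedCellError(
            f"cell ({drug}, {term}) has a zero margin (drug={dm}, term={tm})"
        )
    return tm * dm / table.total_reports


def make_cells(
    table: PairCountTable,
    expected: Mapping[tuple[str, str], float] | None = None,
) -> list[ContingencyCell]:
    """One :class:`ContingencyCell` per pair with both margins positive.

    Cells with N = 0 are retained — the shrinkage model is defined at zero
    and excluding them biases the hyperparameter fit.  Pairs with a zero
    margin are excluded (E undefined) and logged.  ``expected`` optionally
    overrides E per cell (e.g. stratified expected counts).  Ordering is
    deterministic: lexicographic by drug then term.
    """
    out: list[ContingencyCell] = []
    n_undefined = 0
    for (drug, term), n in sorted(table.cells.items()):
        try:
            e = expected_count(table, drug, term)
        except UndefinedCellError:
            n_undefined += 1
            continue
        if expected is not None:
            e = expected[(drug, term)]
        out.append(
            ContingencyCell(drug=drug, term=term, observed_n=n, expected_e=e, rrr=n / e)
        )
    if n_undefined:
        log.info("excluded %d cells with zero margins from scoring", n_undefined)
    return out


def term_level_totals(
    table: PairCountTable,
    terms: Sequence[str] | None = None,
    drugs: Sequence[str] | None = None,
) -> tuple[dict[str, int], int]:
    """Per-term report counts summed over the drug set, plus the grand total.

    Summing the per-drug cells of each term gives the total number of
    events of that term reported across the studied drugs (a report with
    two studied drugs contributes to each); the grand total sums the
    per-term sums.
    """
    if terms is None:
        terms = sorted(table.term_margins)
    if drugs is None:
        drugs = sorted(table.drug_margins)
    per_term = {
        t: sum(table.cells.get((d, t), 0) for d in drugs) for t in terms
    }
    return per_term, sum(per_term.values())


def stratified_expected_counts(
    db: ReportDatabase,
    terms: Sequence[EventTerm],
    drugs: Sequence[str] | None = None,
    stratum_of: Callable[[SafetyReport], Hashable] | None = None,
) -> dict[tuple[str, str], float]:
    """Expected counts summed over strata: E = sum_s E_s.

    ``stratum_of`` maps a report to a stratum key (for instance an age band
    x gender pair).  Within each stratum the independence formula applies
    with that stratum's margins and total; strata where either margin is
    zero contribute nothing.  With a constant stratum function this reduces
    to the unstratified expected count.
    """
    if stratum_of is None:
        stratum_of = lambda r: 0  # noqa: E731 - single default stratum
    strata: dict[Hashable, list[SafetyReport]] = {}
    for r in db:
        strata.setdefault(stratum_of(r), []).append(r)
    if drugs is None:
        drug_names = sorted(db.drug_index)
    else:
        drug_names = [d.strip().lower() for d in drugs]
    out: dict[tuple[str, str], float] = {
        (d, t.name): 0.0 for d in drug_names for t in terms
    }
    for members in strata.values():
        total = len(members)
        dm = {d: 0 for d in drug_names}
        tm = {t.name: 0 for t in terms}
        for r in members:
            names = r.drug_names
            for d in drug_names:
                if d in names:
                    dm[d] += 1
            for t in terms:
                if r.event_terms & t.member_pts:
                    tm[t.name] += 1
        for d in drug_names:
            for t in terms:
                if dm[d] and tm[t.name]:
                    out[(d, t.name)] += tm[t.name] * dm[d] / total
    return out
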