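import numpy as np
import pytest

from pvsignal import (
    DrugEntry,
    DrugRole,
    EventEntry,
    Gender,
    PartialDate,
    ReportDatabase,
    SafetyReport,
    SourceType,
)


def make_report(
    rid,
    gender=Gender.F,
    age=40.0,
    drugs=(),
    events=(),
    source=SourceType.SPONTANEOUS,
    death_date=None,
    receipt_date=None,
    manufacturer="MFR_A",
):
    """Terse report builder: drugs/events as names or (name, PartialDate)."""

    def _drug(d):
        if isinstance(d, DrugEntry):
            return d
        if isinstance(d, tuple):
            name, date = d
            return DrugEntry(name, name, DrugRole.SUSPECT, date)
        return DrugEntry(d, d, DrugRole.SUSPECT, PartialDate(2010, 1, 1))

    def _event(e):
        if isinstance(e, EventEntry):
            return e
        if isinstance(e, tuple):
            pt, date = e
            return EventEntry(pt, date)
        return EventEntry(e, PartialDate(2010, 2, 1))

    return SafetyReport(
        report_id=rid,
        source_type=source,
        gender=gender,
        age_years=age,
        death_date=death_date,
        receipt_date=receipt_date,
        manufacturer=manufacturer,
        drugs=[_drug(d) for d in drugs],
        events=[_event(e) for e in events],
    )


@pytest.fixture
def small_db():
    """10 reports: drug a on 4, PT x on 5, both on 3."""
    reports = []
    for i in range(10):
        drugs = ["a"] if i in (0, 1, 2, 3) else ["b"]
        events = ["x"] if i in (0, 1, 2, 8, 9) else ["y"]
        reports.append(make_report(f"r{i}", age=30 + i, drugs=drugs, events=events))
    return ReportDatabase(reports)


def random_small_db(rng: np.random.Generator, n_reports: int) -> ReportDatabase:
    """Messy little database for brute-force oracle comparisons."""
    drugs = ["a", "b", "c", "d"]
    pts = ["x", "y", "z"]
    reports = []
    for i in range(n_reports):
        nd = rng.integers(0, 3)
        ne = rng.integers(0, 3)
        reports.append(
            make_report(
                f"r{i}",
                gender=Gender.F if rng.random() < 0.5 else Gender.M,
                age=float(rng.integers(20, 60)),
                drugs=list(rng.choice(drugs, size=nd, replace=False)),
                events=list(rng.choice(pts, size=ne, replace=False)),
            )
        )
    return ReportDatabase(reports)
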