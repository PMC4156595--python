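"""Signal screening and results rendering.

A drug-event pair is a potential signal when its EB05 — the lower bound of
the 90% posterior interval on the reporting ratio — is at least the
threshold (default 2.0, i.e. reported at least twice as often as expected
with 95% posterior confidence).  The boundary is inclusive: EB05 exactly at
the threshold flags.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

from .gps import PosteriorScore
from .pair_counting import ContingencyCell

__all__ = ["SignalVerdict", "screen", "render_results"]

DEFAULT_THRESHOLD = 2.0


@dataclass(frozen=True)
class SignalVerdict:
    drug: str
    term: str
    eb05: float
    threshold: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.flagged != (self.eb05 >= self.threshold):
            raise ValueError("flag inconsistent with eb05 and threshold")


def screen(
    scores: Sequence[tuple[ContingencyCell, PosteriorScore]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SignalVerdict]:
    """One verdict per scored cell, flagged first then by descending EB05.

    Ties break lexicographically on (drug, term).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    verdicts = [
        SignalVerdict(
            drug=c.drug,
            term=c.term,
            eb05=s.eb05,
            threshold=threshold,
            flagged=s.eb05 >= threshold,
        )
        for c, s in scores
    ]
    verdicts.sort(key=lambda v: (not v.flagged, -v.eb05, v.drug, v.term))
    return verdicts


def render_results(
    verdicts: Sequence[SignalVerdict],
    scores: Sequence[tuple[ContingencyCell, PosteriorScore]],
    style: str = "tsv",
) -> str:
    """Results table: one row per pair with n, EBGM, EB05, EB95 and flag.

    Rows follow the verdict ordering; scores print at 3 decimals.  ``tsv``
    parses back to the same numbers at printed precision; ``markdown``
    renders a pipe table.
    """
    if style not in ("tsv", "markdown"):
        raise ValueError(f"unknown style {style!r}")
    by_pair = {(c.drug, c.term): (c, s) for c, s in scores}
    header = ["drug", "term", "n", "EBGM", "EB05", "EB95", "flagged"]
    rows = []
    for v in verdicts:
        c, s = by_pair[(v.drug, v.term)]
        rows.append(
            [
                v.drug,
                v.term,
                str(c.observed_n),
                f"{s.ebgm:.3f}",
                f"{s.eb05:.3f}",
                f"{s.eb95:.3f}",
                "yes" if v.flagged else "no",
            ]
        )
    buf = io.StringIO()
    if style == "tsv":
        buf.write("\t".join(header) + "\n")
        for row in rows:
            buf.write("\t".join(row) + "\n")
    else:
        buf.write("| " + " | ".join(header) + " |\n")
        buf.write("|" + "|".join("---" for _ in header) + "|\n")
        for row in rows:
            buf.write("| " + " | ".join(row) + " |\n")
    return buf.getvalue()
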