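"""Per-(variant, submitter) classification histories and event detection.

A reclassification is tracked *within* a submitter: the same laboratory
changing its asserted term for the same variant.  Histories are the
date-ordered assertions of one (variant, submitter) pair; an event is the
first-versus-last term change of an in-window history.  Chained intermediate
states (VUS -> LP -> P) collapse to a single first-to-last event, matching
the one-current-record-per-submitter structure of the public archive.

Inclusion rule: a history contributes (to event counts and to the per-term
denominators) only if its *first* assessment date falls inside the analysis
window — restricting to variants first assessed under the 2015 ACMG/AMP
guidelines.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import IO, Iterable, Sequence

from .ingest import PipelineConfig, SubmissionRecord, classify_consequence
from .terms import ClassificationTerm

log = logging.getLogger(__name__)


@dataclass(slots=True)
class ClassificationHistory:
    """Date-ordered classification assertions of one (variant, submitter)."""

    variant_id: str
    submitter_id: str
    entries: list[tuple[date, ClassificationTerm]]
    gene: str = ""
    consequence: str = ""

    @property
    def first(self) -> tuple[date, ClassificationTerm]:
        return self.entries[0]

    @property
    def last(self) -> tuple[date, ClassificationTerm]:
        return self.entries[-1]


@dataclass(slots=True)
class ReclassificationEvent:
    """A detected change of term by one submitter for one variant."""

    variant_id: str
    submitter_id: str
    from_term: ClassificationTerm
    to_term: ClassificationTerm
    from_date: date
    to_date: date
    gene: str = ""
    consequence_class: str = "other"

    def __post_init__(self) -> None:
        if self.from_term is self.to_term:
            raise ValueError("a reclassification requires from_term != to_term")
        if self.from_date > self.to_date:
            raise ValueError("from_date must not postdate to_date")


def build_histories(records: Sequence[SubmissionRecord]) -> list[ClassificationHistory]:
    """Group records into one history per distinct (variant, submitter).

    Entries sort by (date, axis position); the axis tie-break makes two
    same-day assertions with different terms order deterministically (benign
    side first), with a logged warning since such duplicates are ambiguous.
    The result is independent of input order.
    """
    grouped: dict[tuple[str, str], list[tuple[date, ClassificationTerm]]] = defaultdict(list)
    meta: dict[tuple[str, str], tuple[str, str]] = {}
    for rec in records:
        key = (rec.variant_id, rec.submitter_id)
        grouped[key].append((rec.date_evaluated, rec.term))
        if key not in meta or not meta[key][0]:
            meta[key] = (rec.gene, rec.consequence)
    histories: list[ClassificationHistory] = []
    for key in sorted(grouped):
        entries = sorted(grouped[key], key=lambda e: (e[0], e[1].axis_position))
        for (d1, t1), (d2, t2) in zip(entries, entries[1:]):
            if d1 == d2 and t1 is not t2:
                log.warning(
                    "variant %s / submitter %s: conflicting terms %s and %s on %s; "
                    "ordered by pathogenicity axis", key[0], key[1], t1, t2, d1,
                )
        gene, consequence = meta[key]
        histories.append(
            ClassificationHistory(
                variant_id=key[0], submitter_id=key[1], entries=entries,
                gene=gene, consequence=consequence,
            )
        )
    return histories


def detect_events(
    histories: Iterable[ClassificationHistory], config: PipelineConfig | None = None
) -> tuple[list[ReclassificationEvent], Counter]:
    """Detect first-versus-last reclassification events inside the window.

    For each history whose first assessment date lies in
    [window_start, window_end): the first term increments the per-term
    denominator of initial classifications, and if the last term differs
    from the first, exactly one event (first -> last) is emitted.  Histories
    first assessed before the window contribute nothing.  A history that
    oscillated back to its starting term (LP -> VUS -> LP) yields no event.

    Returns ``(events, denominators)`` with ``denominators`` a Counter over
    :class:`ClassificationTerm`.
    """
    config = config or PipelineConfig()
    events: list[ReclassificationEvent] = []
    denominators: Counter = Counter()
    n_oscillated = 0
    for h in histories:
        first_date, first_term = h.first
        if not (config.window_start <= first_date < config.window_end):
            continue
        denominators[first_term] += 1
        last_date, last_term = h.last
        if last_term is first_term:
            if any(t is not first_term for _, t in h.entries):
                n_oscillated += 1  # e.g. LP -> VUS -> LP: collapses to no event
            continue
        events.append(
            ReclassificationEvent(
                variant_id=h.variant_id,
                submitter_id=h.submitter_id,
                from_term=first_term,
                to_term=last_term,
                from_date=first_date,
                to_date=last_date,
                gene=h.gene,
                consequence_class=classify_consequence(
                    SubmissionRecord(h.variant_id, h.submitter_id, first_term,
                                     first_date, h.gene, h.consequence),
                    config,
                ),
            )
        )
    if n_oscillated:
        log.info("%d histories oscillated back to their starting term (no event)", n_oscillated)
    return events, denominators


EVENT_COLUMNS = (
    "VariationID", "Submitter", "FromTerm", "ToTerm",
    "FromDate", "ToDate", "GeneSymbol", "ConsequenceClass",
)


def write_events(events: Iterable[ReclassificationEvent], dest: str | Path | IO[str]) -> None:
    """Emit events as a TSV for downstream or external use."""
    fh = open(dest, "w", encoding="utf-8", newline="") if isinstance(dest, (str, Path)) else dest
    try:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow([e.variant_id, e.submitter_id, e.from_term, e.to_term,
                        e.from_date.isoformat(), e.to_date.isoformat(),
                        e.gene, e.consequence_class])
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


def read_events(source: str | Path | IO[str]) -> list[ReclassificationEvent]:
    """Read an events TSV written by :func:`write_events`."""
    fh = open(source, encoding="utf-8", newline="") if isinstance(source, (str, Path)) else source
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        out = []
        for row in reader:
            out.append(
                ReclassificationEvent(
                    variant_id=row["VariationID"],
                    submitter_id=row["Submitter"],
                    from_term=ClassificationTerm[row["FromTerm"]],
                    to_term=ClassificationTerm[row["ToTerm"]],
                    from_date=date.fromisoformat(row["FromDate"]),
                    to_date=date.fromisoformat(row["ToDate"]),
                    gene=row.get("GeneSymbol", ""),
                    consequence_class=row.get("ConsequenceClass", "other"),
                )
            )
        return out
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
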