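"""The 5x5 reclassification transition matrix and its summaries.

Two summaries matter clinically.  The *certainty direction* of a transition
uses the signed pathogenicity axis (B=-2 ... P=+2): a move is *opposing* if
source and destination sit on opposite nonzero sides of the axis (crossing
the pathogenic/benign divide), *more certain* if it increases distance from
VUS, and *less certain* otherwise.  The *rate table* reports, per starting
term, the fraction of initial classifications that were reclassified and,
per ordered pair, each transition's share of its starting group and of all
reclassifications — the standard presentation for longitudinal archive
audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Counter, Iterable, Mapping

import numpy as np
import pandas as pd

from .events import ReclassificationEvent
from .terms import TERM_INDEX, TERM_ORDER, ClassificationTerm

DIRECTIONS = ("more_certain", "less_certain", "opposing")


def classify_direction(
    from_term: ClassificationTerm, to_term: ClassificationTerm
) -> str:
    """Categorise one transition as more_certain, less_certain, or opposing.

    Opposing means both terms are non-VUS with opposite axis signs (a swap
    across the pathogenic/benign divide, e.g. LP -> LB).  Otherwise the move
    is more_certain when the destination is further from VUS than the
    source (VUS -> LP/P, LP -> P, VUS -> LB/B, LB -> B), else less_certain.
    """
    if from_term is to_term:
        raise ValueError("not a reclassification: from_term == to_term")
    a, b = from_term.axis_position, to_term.axis_position
    if a * b < 0:
        return "opposing"
    if to_term.certainty > from_term.certainty:
        return "more_certain"
    return "less_certain"


@dataclass
class TransitionMatrix:
    """Event counts per ordered (from, to) term pair, plus denominators.

    ``counts`` is indexed [from, to] in the order P, LP, VUS, LB, B with a
    structurally zero diagonal.  ``start_totals`` holds, per term, the count
    of *all* in-window initial classifications (reclassified or not) — the
    denominators for reclassification rates.
    """

    counts: np.ndarray
    start_totals: dict[ClassificationTerm, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("counts must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal (no-change) cells must be zero")
        for t in TERM_ORDER:
            self.start_totals.setdefault(t, 0)
            if self.row_total(t) > self.start_totals[t]:
                raise ValueError(
                    f"{t}: more events ({self.row_total(t)}) than initial "
                    f"classifications ({self.start_totals[t]})"
                )

    def count(self, from_term: ClassificationTerm, to_term: ClassificationTerm) -> int:
        return int(self.counts[TERM_INDEX[from_term], TERM_INDEX[to_term]])

    def row(self, from_term: ClassificationTerm) -> dict[ClassificationTerm, int]:
        i = TERM_INDEX[from_term]
        return {t: int(self.counts[i, TERM_INDEX[t]]) for t in TERM_ORDER if t is not from_term}

    def row_total(self, from_term: ClassificationTerm) -> int:
        return int(self.counts[TERM_INDEX[from_term]].sum())

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    @property
    def total_classifications(self) -> int:
        return sum(self.start_totals.values())

    def to_frame(self) -> pd.DataFrame:
        labels = [t.label for t in TERM_ORDER]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def build_transition_matrix(
    events: Iterable[ReclassificationEvent],
    denominators: Mapping[ClassificationTerm, int] | Counter,
) -> TransitionMatrix:
    """Accumulate detected events into a :class:`TransitionMatrix`."""
    counts = np.zeros((5, 5), dtype=np.int64)
    for e in events:
        counts[TERM_INDEX[e.from_term], TERM_INDEX[e.to_term]] += 1
    return TransitionMatrix(counts=counts, start_totals={t: int(denominators.get(t, 0)) for t in TERM_ORDER})


@dataclass(frozen=True)
class DirectionSummary:
    """Partition of all events by certainty direction."""

    more_certain: int
    less_certain: int
    opposing: int

    @property
    def total(self) -> int:
        return self.more_certain + self.less_certain + self.opposing

    def fraction(self, direction: str) -> float:
        if self.total == 0:
            return 0.0
        return getattr(self, direction) / self.total


def summarize_directions(matrix: TransitionMatrix) -> DirectionSummary:
    """Accumulate each cell into its certainty-direction category."""
    tally = {d: 0 for d in DIRECTIONS}
    for f in TERM_ORDER:
        for t in TERM_ORDER:
            if f is t:
                continue
            n = matrix.count(f, t)
            if n:
                tally[classify_direction(f, t)] += n
    return DirectionSummary(**tally)


@dataclass(frozen=True)
class RateCell:
    """One ordered transition with its shares of group and of all events."""

    from_term: ClassificationTerm
    to_term: ClassificationTerm
    count: int
    frac_of_group: float   # share of this starting term's reclassifications
    frac_of_all: float     # share of all reclassifications


@dataclass(frozen=True)
class RateRow:
    """One starting term's reclassification summary."""

    term: ClassificationTerm
    start_total: int
    n_reclassified: int
    frac_reclassified: float
    cells: tuple[RateCell, ...]


@dataclass(frozen=True)
class RateTable:
    """Per-starting-term reclassification rates over the analysis window."""

    rows: tuple[RateRow, ...]
    total_classifications: int
    total_events: int

    @property
    def overall_rate(self) -> float:
        if self.total_classifications == 0:
            return 0.0
        return self.total_events / self.total_classifications

    def row(self, term: ClassificationTerm) -> RateRow:
        return next(r for r in self.rows if r.term is term)


def summarize_rates(matrix: TransitionMatrix) -> RateTable:
    """Build the per-term rate table from a transition matrix.

    Fractions are kept at full precision; rounding happens only at render
    time (:mod:`varreclass.report`).  A starting term with events but a zero
    start total is an inconsistency and raises.
    """
    total_events = matrix.total_events
    rows = []
    for term in TERM_ORDER:
        row_events = matrix.row_total(term)
        start = matrix.start_totals.get(term, 0)
        if start == 0 and row_events > 0:
            raise ValueError(f"{term}: events present but start total is zero")
        cells = []
        if row_events:
            for to_term in TERM_ORDER:
                if to_term is term:
                    continue
                n = matrix.count(term, to_term)
                cells.append(
                    RateCell(
                        from_term=term, to_term=to_term, count=n,
                        frac_of_group=n / row_events,
                        frac_of_all=n / total_events,
                    )
                )
        rows.append(
            RateRow(
                term=term, start_total=start, n_reclassified=row_events,
                frac_reclassified=(row_events / start) if start else 0.0,
                cells=tuple(cells),
            )
        )
    return RateTable(
        rows=tuple(rows),
        total_classifications=matrix.total_classifications,
        total_events=total_events,
    )
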