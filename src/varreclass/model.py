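"""Model/Results interface over the reclassification pipeline.

:class:`ReclassificationModel` is constructed from submission records (or a
file, or a DataFrame) plus a :class:`~varreclass.ingest.PipelineConfig`;
``fit()`` runs history assembly, event detection and transition analysis,
returning a :class:`ReclassificationResults` that carries the transition
matrix, the certainty-direction partition, the rate table, the LP
confidence estimators, and methods for stratified comparisons and a
``summary()`` report.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from . import report
from .events import (
    ClassificationHistory,
    ReclassificationEvent,
    build_histories,
    detect_events,
)
from .ingest import (
    GenePanel,
    PipelineConfig,
    SubmissionRecord,
    read_gene_panel,
    read_submission_history,
)
from .lp import LPConfidenceEstimate, extrapolated_lp_rate
from .strata import StratumComparison, compare_strata, consequence_predicate, panel_predicate
from .terms import ClassificationTerm, parse_term
from .transitions import (
    DirectionSummary,
    RateTable,
    TransitionMatrix,
    build_transition_matrix,
    summarize_directions,
    summarize_rates,
)


class ReclassificationModel:
    """Per-submitter reclassification analysis of classification histories."""

    def __init__(
        self,
        records: Sequence[SubmissionRecord],
        config: PipelineConfig | None = None,
        skips: Counter | None = None,
    ) -> None:
        self.records = list(records)
        self.config = config or PipelineConfig()
        self.skips = skips if skips is not None else Counter()

    @classmethod
    def from_file(
        cls, source: str | Path | IO[str], config: PipelineConfig | None = None
    ) -> "ReclassificationModel":
        """Build from a submission TSV (ClinVar submission-summary dialect)."""
        config = config or PipelineConfig()
        records, skips = read_submission_history(source, config)
        return cls(records, config, skips)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: PipelineConfig | None = None
    ) -> "ReclassificationModel":
        """Build from a DataFrame with the same columns as the TSV dialect."""
        config = config or PipelineConfig()
        records: list[SubmissionRecord] = []
        skips: Counter = Counter()
        for row in df.itertuples(index=False):
            term = parse_term(str(row.ClinicalSignificance), config.term_aliases)
            if term is None:
                skips["unmappable_term"] += 1
                continue
            records.append(
                SubmissionRecord(
                    variant_id=str(row.VariationID),
                    submitter_id=str(row.Submitter),
                    term=term,
                    date_evaluated=pd.Timestamp(row.DateLastEvaluated).date(),
                    gene=str(getattr(row, "GeneSymbol", "") or ""),
                    consequence=str(getattr(row, "Consequence", "") or ""),
                )
            )
        return cls(records, config, skips)

    def fit(self) -> "ReclassificationResults":
        histories = build_histories(self.records)
        events, denominators = detect_events(histories, self.config)
        matrix = build_transition_matrix(events, denominators)
        return ReclassificationResults(self, histories, events, matrix)


class ReclassificationResults:
    """Fitted transition structure with estimators and reports."""

    def __init__(
        self,
        model: ReclassificationModel,
        histories: list[ClassificationHistory],
        events: list[ReclassificationEvent],
        matrix: TransitionMatrix,
    ) -> None:
        self.model = model
        self.histories = histories
        self.events = events
        self.matrix = matrix

    @property
    def direction_summary(self) -> DirectionSummary:
        return summarize_directions(self.matrix)

    @property
    def rate_table(self) -> RateTable:
        return summarize_rates(self.matrix)

    def lp_confidence(self) -> LPConfidenceEstimate:
        """The three LP -> P confidence rates (raises if no LP events)."""
        return extrapolated_lp_rate(self.matrix)

    def compare_panels(self, panel_a: GenePanel, panel_b: GenePanel) -> StratumComparison:
        overlap = panel_a.genes & panel_b.genes
        if overlap:
            raise ValueError(f"panels overlap on {sorted(overlap)}; strata must be disjoint")
        return compare_strata(
            self.events,
            panel_a.name, panel_predicate(panel_a),
            panel_b.name, panel_predicate(panel_b),
        )

    def compare_consequences(
        self, class_a: str = "pLoF", class_b: str = "missense"
    ) -> StratumComparison:
        return compare_strata(
            self.events,
            class_a, consequence_predicate(class_a),
            class_b, consequence_predicate(class_b),
        )

    def default_comparisons(self) -> list[StratumComparison]:
        """Configured panel pair (if exactly two panels) plus pLoF vs missense."""
        out = [self.compare_consequences()]
        panels = [read_gene_panel(p) for p in self.model.config.panels]
        if len(panels) == 2:
            out.append(self.compare_panels(panels[0], panels[1]))
        return out

    def summary(self) -> str:
        """Plain-text report: rate table, direction partition, LP rates."""
        try:
            lp = self.lp_confidence()
        except ValueError:
            lp = None
        return report.render_run_report(
            self.rate_table, self.direction_summary, lp, [],
        )

    def to_summary_dict(self) -> dict:
        """JSON-serializable run summary (full-precision fractions)."""
        try:
            lp: dict | None = self.lp_confidence().as_dict()
        except ValueError:
            lp = None
        return {
            "n_records": len(self.model.records),
            "skips": dict(self.model.skips),
            "n_histories": len(self.histories),
            "n_events": len(self.events),
            "directions": report.direction_dict(self.direction_summary),
            "rate_table": report.rate_table_dict(self.rate_table),
            "lp_confidence": lp,
        }
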