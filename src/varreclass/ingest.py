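"""Reading and validating submission histories, gene panels, and run config.

The input dialect mirrors ClinVar's ``submission_summary.txt``: a UTF-8,
tab-separated table with one header row and one row per (variant, submitter,
date) classification assertion.  Required columns are ``VariationID``,
``Submitter``, ``ClinicalSignificance`` and ``DateLastEvaluated``;
``GeneSymbol`` and ``Consequence`` are optional.  Real ClinVar exports need
only column renames to be readable here.

Rows whose classification string does not map to one of the five ACMG/AMP
terms (aggregate assertions such as "Pathogenic/Likely pathogenic",
"Conflicting interpretations", or non-Mendelian categories such as "drug
response") are dropped and tallied — the analysis is defined over
single-submitter assertions in the standard five terms only.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

import yaml

from .terms import DEFAULT_TERM_ALIASES, ClassificationTerm, parse_term

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("VariationID", "Submitter", "ClinicalSignificance", "DateLastEvaluated")
OPTIONAL_COLUMNS = ("GeneSymbol", "Consequence")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

#: Default predicted loss-of-function consequence labels.  The pLoF
#: vocabulary is configurable because usage varies between pipelines.
DEFAULT_PLOF_CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "splice donor", "splice acceptor", "start lost", "stop gained"}
)
DEFAULT_MISSENSE_CONSEQUENCES = frozenset({"missense"})

DEFAULT_WINDOW_START = date(2016, 1, 1)
DEFAULT_WINDOW_END = date(2019, 7, 1)


@dataclass(slots=True)
class SubmissionRecord:
    """One classification assertion by one submitter for one variant."""

    variant_id: str
    submitter_id: str
    term: ClassificationTerm
    date_evaluated: date
    gene: str = ""
    consequence: str = ""

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not self.submitter_id:
            raise ValueError("submitter_id must be non-empty")


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols used for disease-area stratification."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene panel {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass
class PipelineConfig:
    """Analysis window, panel paths, consequence classes, and term aliases.

    The analysis window is [window_start, window_end): a classification
    history enters the analysis only if its first assessment date falls in
    the window.  Defaults cover 1 January 2016 (adoption of the 2015
    ACMG/AMP guidelines) through 1 July 2019.
    """

    window_start: date = DEFAULT_WINDOW_START
    window_end: date = DEFAULT_WINDOW_END
    panels: list[Path] = field(default_factory=list)
    plof_consequences: frozenset[str] = DEFAULT_PLOF_CONSEQUENCES
    missense_consequences: frozenset[str] = DEFAULT_MISSENSE_CONSEQUENCES
    term_aliases: dict[str, ClassificationTerm] = field(
        default_factory=lambda: dict(DEFAULT_TERM_ALIASES)
    )

    def __post_init__(self) -> None:
        if isinstance(self.window_start, str):
            self.window_start = date.fromisoformat(self.window_start)
        if isinstance(self.window_end, str):
            self.window_end = date.fromisoformat(self.window_end)
        if not self.window_start < self.window_end:
            raise ValueError(
                f"window_start {self.window_start} must precede window_end {self.window_end}"
            )
        self.plof_consequences = frozenset(s.lower() for s in self.plof_consequences)
        self.missense_consequences = frozenset(s.lower() for s in self.missense_consequences)
        overlap = self.plof_consequences & self.missense_consequences
        if overlap:
            raise ValueError(f"pLoF and missense consequence sets overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; panel paths resolve relative to the file."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "window_start" in raw:
            kwargs["window_start"] = _coerce_date(raw["window_start"])
        if "window_end" in raw:
            kwargs["window_end"] = _coerce_date(raw["window_end"])
        if "panels" in raw:
            kwargs["panels"] = [
                (path.parent / p if not Path(p).is_absolute() else Path(p))
                for p in raw["panels"]
            ]
        if "plof_consequences" in raw:
            kwargs["plof_consequences"] = frozenset(raw["plof_consequences"])
        if "missense_consequences" in raw:
            kwargs["missense_consequences"] = frozenset(raw["missense_consequences"])
        if "term_aliases" in raw:
            aliases = dict(DEFAULT_TERM_ALIASES)
            for k, v in raw["term_aliases"].items():
                aliases[k.strip().lower()] = ClassificationTerm[v]
            kwargs["term_aliases"] = aliases
        return cls(**kwargs)

    def load_panels(self) -> list[GenePanel]:
        return [read_gene_panel(p) for p in self.panels]


def _coerce_date(value) -> date:
    if isinstance(value, date):
        return value
    return _parse_date(str(value))


def _parse_date(raw: str) -> date:
    """ISO-8601 primary; 'Mon DD, YYYY' (ClinVar display format) fallback."""
    raw = raw.strip()
    try:
        return date.fromisoformat(raw)
    except ValueError:
        pass
    try:
        return datetime.strptime(raw, "%b %d, %Y").date()
    except ValueError as exc:
        raise ValueError(f"unparseable date: {raw!r}") from exc


def _open_maybe(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8", newline=""), True
    return source, False


def read_submission_history(
    source: str | Path | IO[str], config: PipelineConfig | None = None
) -> tuple[list[SubmissionRecord], Counter]:
    """Read a submission table into records, tallying skipped rows.

    Returns ``(records, skips)`` where ``skips`` counts dropped rows by
    reason (``unmappable_term``, ``bad_date``, ``missing_field``).  Output
    order preserves file order; ``len(records) + sum(skips.values())``
    equals the input row count.

    Raises ``ValueError`` if a required column is absent from the header.
    """
    config = config or PipelineConfig()
    fh, owned = _open_maybe(source)
    skips: Counter = Counter()
    records: list[SubmissionRecord] = []
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ValueError(f"missing required column: {col}")
        for i, row in enumerate(reader, start=2):
            term = parse_term(row["ClinicalSignificance"] or "", config.term_aliases)
            if term is None:
                skips["unmappable_term"] += 1
                continue
            try:
                when = _parse_date(row["DateLastEvaluated"] or "")
            except ValueError:
                log.warning("line %d: unparseable date %r; row dropped", i, row["DateLastEvaluated"])
                skips["bad_date"] += 1
                continue
            try:
                rec = SubmissionRecord(
                    variant_id=(row["VariationID"] or "").strip(),
                    submitter_id=(row["Submitter"] or "").strip(),
                    term=term,
                    date_evaluated=when,
                    gene=(row.get("GeneSymbol") or "").strip(),
                    consequence=(row.get("Consequence") or "").strip(),
                )
            except ValueError:
                log.warning("line %d: missing variant or submitter id; row dropped", i)
                skips["missing_field"] += 1
                continue
            records.append(rec)
    finally:
        if owned:
            fh.close()
    return records, skips


def write_submission_history(
    records: Iterable[SubmissionRecord], dest: str | Path | IO[str]
) -> None:
    """Write records back to the tab-separated dialect (round-trip safe)."""
    fh, owned = _open_maybe_write(dest)
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ALL_COLUMNS)
        for r in records:
            writer.writerow(
                [r.variant_id, r.submitter_id, _CANONICAL_SPELLING[r.term],
                 r.date_evaluated.isoformat(), r.gene, r.consequence]
            )
    finally:
        if owned:
            fh.close()


_CANONICAL_SPELLING = {
    ClassificationTerm.P: "Pathogenic",
    ClassificationTerm.LP: "Likely pathogenic",
    ClassificationTerm.VUS: "Uncertain significance",
    ClassificationTerm.LB: "Likely benign",
    ClassificationTerm.B: "Benign",
}


def _open_maybe_write(dest: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(dest, (str, Path)):
        return open(dest, "w", encoding="utf-8", newline=""), True
    return dest, False


def read_gene_panel(source: str | Path | IO[str], name: str | None = None) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` lines are comments.

    Symbols are upper-cased and deduplicated.  An empty panel (after
    stripping comments and blanks) is a hard error.
    """
    if name is None:
        name = Path(source).stem if isinstance(source, (str, Path)) else "panel"
    fh, owned = _open_maybe(source)
    try:
        genes = frozenset(
            line.strip().upper()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        )
    finally:
        if owned:
            fh.close()
    if not genes:
        raise ValueError(f"gene panel {name!r} is empty")
    return GenePanel(name=name, genes=genes)


def builtin_panel(name: str) -> GenePanel:
    """Load a panel shipped with the package (``acmg_sf_cancer``, ``acmg_sf_cardio``)."""
    ref = resources.files("varreclass") / "data" / "panels" / f"{name}.txt"
    return read_gene_panel(io.StringIO(ref.read_text(encoding="utf-8")), name=name)


def classify_consequence(record: SubmissionRecord, config: PipelineConfig | None = None) -> str:
    """Assign one of ``pLoF``, ``missense``, ``other`` by exact membership
    of the record's lower-cased consequence label in the config sets."""
    config = config or PipelineConfig()
    c = record.consequence.strip().lower()
    if c in config.plof_consequences:
        return "pLoF"
    if c in config.missense_consequences:
        return "missense"
    return "other"
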