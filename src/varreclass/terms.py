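"""The five-tier ACMG/AMP classification vocabulary.

Sequence variants in Mendelian disease genes are classified on a five-term
ordinal scale: benign (B), likely benign (LB), uncertain significance (VUS),
likely pathogenic (LP), and pathogenic (P).  The scale has a natural signed
axis: benign terms sit on the negative side, pathogenic terms on the positive
side, and VUS at the origin.  The *certainty* of a term is its distance from
VUS — definitive terms (B, P) have certainty 2, "likely" terms certainty 1,
and VUS certainty 0.  This signed-axis view is what lets a reclassification
be categorised as moving toward certainty, away from it, or across the
pathogenic/benign divide (see :mod:`varreclass.transitions`).
"""

from __future__ import annotations

import enum


class ClassificationTerm(enum.Enum):
    """One of the five ACMG/AMP classification terms.

    The enum value is the term's signed position on the pathogenicity axis:
    B=-2, LB=-1, VUS=0, LP=+1, P=+2.
    """

    B = -2
    LB = -1
    VUS = 0
    LP = 1
    P = 2

    @property
    def label(self) -> str:
        return self.name

    @property
    def axis_position(self) -> int:
        """Signed position on the benign(-)/pathogenic(+) axis."""
        return self.value

    @property
    def certainty(self) -> int:
        """Distance from VUS: 0 for VUS, 1 for LP/LB, 2 for P/B."""
        return abs(self.value)

    def __str__(self) -> str:  # compact rendering in tables and TSVs
        return self.name


#: Display order used throughout reports: most pathogenic first.
TERM_ORDER: tuple[ClassificationTerm, ...] = (
    ClassificationTerm.P,
    ClassificationTerm.LP,
    ClassificationTerm.VUS,
    ClassificationTerm.LB,
    ClassificationTerm.B,
)

TERM_INDEX: dict[ClassificationTerm, int] = {t: i for i, t in enumerate(TERM_ORDER)}

#: Raw classification strings (lower-cased) accepted by default.  Covers the
#: canonical spellings plus the short codes; aggregate or non-Mendelian
#: assertion strings ("drug response", "conflicting interpretations", ...)
#: are deliberately absent and are skipped at ingest.
DEFAULT_TERM_ALIASES: dict[str, ClassificationTerm] = {
    "pathogenic": ClassificationTerm.P,
    "likely pathogenic": ClassificationTerm.LP,
    "uncertain significance": ClassificationTerm.VUS,
    "variant of uncertain significance": ClassificationTerm.VUS,
    "likely benign": ClassificationTerm.LB,
    "benign": ClassificationTerm.B,
    "p": ClassificationTerm.P,
    "lp": ClassificationTerm.LP,
    "vus": ClassificationTerm.VUS,
    "lb": ClassificationTerm.LB,
    "b": ClassificationTerm.B,
}


def parse_term(raw: str, aliases: dict[str, ClassificationTerm] | None = None) -> ClassificationTerm | None:
    """Map a raw classification string to a term, or ``None`` if unmappable.

    Matching is case-insensitive and whitespace-stripped.  ``aliases``
    defaults to :data:`DEFAULT_TERM_ALIASES`.
    """
    table = DEFAULT_TERM_ALIASES if aliases is None else aliases
    return table.get(raw.strip().lower())
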