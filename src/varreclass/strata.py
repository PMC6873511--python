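"""Stratified comparison of LP upgrade fractions with Fisher's exact test.

Strata are defined by predicates over reclassification events that started
at LP — by molecular-consequence class (pLoF vs missense) or by gene-panel
membership (e.g. cancer vs cardiovascular genes).  For each pair of
disjoint strata, the 2x2 table (upgraded to P, not upgraded) x (stratum A,
stratum B) is tested with a two-sided Fisher exact test.

The test is implemented here rather than delegated: the two-sided p-value
is the point-probability ("minimum-likelihood") definition used by standard
statistical software — the sum of hypergeometric probabilities of all
tables sharing the observed margins whose point probability does not exceed
the observed table's (within a small relative tolerance to absorb floating-
point ties).  Probabilities are formed in log-space via log-gamma for
stability at large counts.

Conditioning on both margins, the count ``a`` in the top-left cell follows
the hypergeometric law

    P(a) = C(r1, a) C(r2, c1 - a) / C(n, c1)

with row sums r1, r2, column sum c1 = a + c, and total n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .events import ReclassificationEvent
from .ingest import GenePanel
from .terms import ClassificationTerm

log = logging.getLogger(__name__)

#: tables whose point probability exceeds the observed one by at most this
#: relative amount still count as "no more probable" (floating-point ties)
_REL_TOL = 1e-7


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Exact conditional test on the hypergeometric distribution; two-sided by
    the point-probability rule.  A zero margin leaves no free cell, so p = 1
    by convention (with a warning).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        log.warning("degenerate 2x2 table (zero margin): p = 1 by convention")
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = (
        _log_binom(r1, support)
        + _log_binom(r2, c1 - support)
        - _log_binom(n, c1)
    )
    log_obs = logp[support == a][0]
    mask = logp <= log_obs + np.log1p(_REL_TOL)
    p = float(np.exp(logp[mask]).sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class StratumComparison:
    """Upgrade fractions in two disjoint strata of LP events, with a p-value."""

    stratum_a: str
    stratum_b: str
    upgraded_a: int
    total_a: int
    upgraded_b: int
    total_b: int
    p_value: float | None
    computable: bool = True
    reason: str | None = None

    @property
    def fraction_a(self) -> float | None:
        return self.upgraded_a / self.total_a if self.total_a else None

    @property
    def fraction_b(self) -> float | None:
        return self.upgraded_b / self.total_b if self.total_b else None

    def as_dict(self) -> dict:
        return {
            "stratum_a": self.stratum_a,
            "stratum_b": self.stratum_b,
            "upgraded_a": self.upgraded_a,
            "total_a": self.total_a,
            "upgraded_b": self.upgraded_b,
            "total_b": self.total_b,
            "fraction_a": self.fraction_a,
            "fraction_b": self.fraction_b,
            "p_value": self.p_value,
            "computable": self.computable,
            "reason": self.reason,
        }


Predicate = Callable[[ReclassificationEvent], bool]


def panel_predicate(panel: GenePanel) -> Predicate:
    """Stratum membership by gene-panel membership of the event's gene."""
    return lambda e: e.gene.upper() in panel.genes


def consequence_predicate(consequence_class: str) -> Predicate:
    """Stratum membership by consequence class (pLoF / missense / other)."""
    return lambda e: e.consequence_class == consequence_class


def upgrade_table(
    events: Iterable[ReclassificationEvent],
    predicate_a: Predicate,
    predicate_b: Predicate,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 table of (upgraded to P, not upgraded) for two strata of LP events.

    Only events with ``from_term == LP`` are considered.  An event matching
    both predicates is a hard error: strata must be disjoint (silent
    double-counting would bias both rows).
    """
    a = b = c = d = 0
    for e in events:
        if e.from_term is not ClassificationTerm.LP:
            continue
        in_a, in_b = predicate_a(e), predicate_b(e)
        if in_a and in_b:
            raise ValueError(
                f"event {e.variant_id}/{e.submitter_id} matches both strata; "
                "strata must be disjoint"
            )
        if not (in_a or in_b):
            continue
        upgraded = e.to_term is ClassificationTerm.P
        if in_a:
            a += upgraded
            b += not upgraded
        else:
            c += upgraded
            d += not upgraded
    return ((a, b), (c, d))


def compare_strata(
    events: Sequence[ReclassificationEvent],
    name_a: str,
    predicate_a: Predicate,
    name_b: str,
    predicate_b: Predicate,
) -> StratumComparison:
    """Assemble the upgrade table, fractions, and Fisher p for two strata."""
    (a, b), (c, d) = upgrade_table(events, predicate_a, predicate_b)
    if a + b == 0 or c + d == 0:
        empty = name_a if a + b == 0 else name_b
        return StratumComparison(
            stratum_a=name_a, stratum_b=name_b,
            upgraded_a=a, total_a=a + b, upgraded_b=c, total_b=c + d,
            p_value=None, computable=False,
            reason=f"no LP reclassifications in stratum {empty!r}",
        )
    return StratumComparison(
        stratum_a=name_a, stratum_b=name_b,
        upgraded_a=a, total_a=a + b, upgraded_b=c, total_b=c + d,
        p_value=fisher_exact_two_sided(a, b, c, d),
    )
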