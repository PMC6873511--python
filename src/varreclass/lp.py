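"""Confidence estimators for the 'likely pathogenic' (LP) category.

The 2015 ACMG/AMP guidelines define LP to mean greater than 90% certainty of
pathogenicity.  Reclassification outcomes of LP variants give an empirical
handle on that threshold, via three estimators of increasing inclusiveness:

* **definitive rate** — among LP reclassifications that reached a definitive
  state (P or B), the fraction that reached P.  The most conservative view:
  LP -> VUS and LP -> LB moves carry no final verdict and are excluded.
* **definitive rate, LB-inclusive** — pools LB with B in the denominator, on
  the argument that LB variants essentially never become pathogenic.
* **extrapolated rate** — assigns the LP -> VUS mass an eventual fate in
  proportion to the observed VUS reclassification split (VUS -> LP/P upward
  versus VUS -> LB/B downward), then reports (upgrades, observed plus
  extrapolated) over *all* LP reclassifications.  Because variants that
  started at LP plausibly return upward more often than generic VUS, this
  is a worst-case (downward-biased) estimate, and is flagged as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .terms import ClassificationTerm
from .transitions import TransitionMatrix

log = logging.getLogger(__name__)

P, LP, VUS, LB, B = (
    ClassificationTerm.P,
    ClassificationTerm.LP,
    ClassificationTerm.VUS,
    ClassificationTerm.LB,
    ClassificationTerm.B,
)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (41.95 -> 42)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DefinitiveRate:
    """An LP confidence rate restricted to definitive outcomes."""

    numerator: int      # LP -> P events
    denominator: int    # LP -> P plus LP -> B (plus LP -> LB if inclusive)
    include_lb: bool

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class VusFateRates:
    """The observed up/down split of VUS reclassifications."""

    n_up: int      # VUS -> LP or P
    n_down: int    # VUS -> LB or B
    r_up: float
    r_down: float

    @property
    def total(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class LPConfidenceEstimate:
    """All three LP -> P confidence rates with their component counts."""

    n_lp_events: int
    n_to_p: int
    n_to_vus: int
    n_to_lb: int
    n_to_b: int
    rate_definitive: float
    rate_definitive_lb: float
    vus_up_rate: float
    vus_down_rate: float
    extrap_up: int
    extrap_down: int
    rate_extrapolated: float
    rate_extrapolated_raw: float
    #: the extrapolation assumes LP->VUS variants share generic VUS fates,
    #: which plausibly overstates eventual downgrades — a worst-case bound.
    worst_case: bool = True

    def as_dict(self) -> dict:
        return {
            "n_lp_events": self.n_lp_events,
            "n_to_p": self.n_to_p,
            "n_to_vus": self.n_to_vus,
            "n_to_lb": self.n_to_lb,
            "n_to_b": self.n_to_b,
            "rate_definitive": self.rate_definitive,
            "rate_definitive_lb": self.rate_definitive_lb,
            "vus_up_rate": self.vus_up_rate,
            "vus_down_rate": self.vus_down_rate,
            "extrap_up": self.extrap_up,
            "extrap_down": self.extrap_down,
            "rate_extrapolated": self.rate_extrapolated,
            "rate_extrapolated_raw": self.rate_extrapolated_raw,
            "worst_case": self.worst_case,
        }


def definitive_rate(matrix: TransitionMatrix, include_lb: bool = False) -> DefinitiveRate:
    """LP -> P share among LP reclassifications reaching a definitive state.

    With ``include_lb`` the LB outcomes are pooled with B in the
    denominator.  Raises ``ValueError`` when no definitive outcomes exist.
    """
    n_p = matrix.count(LP, P)
    den = n_p + matrix.count(LP, B)
    if include_lb:
        den += matrix.count(LP, LB)
    if den == 0:
        raise ValueError("no LP reclassifications reached a definitive state")
    return DefinitiveRate(numerator=n_p, denominator=den, include_lb=include_lb)


def vus_fate_rates(matrix: TransitionMatrix) -> VusFateRates:
    """Observed split of VUS reclassifications into upward vs downward moves.

    ``r_up + r_down == 1`` exactly (complementary counts over the VUS row).
    Raises ``ValueError`` on an empty VUS row.
    """
    n_up = matrix.count(VUS, LP) + matrix.count(VUS, P)
    n_down = matrix.count(VUS, LB) + matrix.count(VUS, B)
    total = n_up + n_down
    if total == 0:
        raise ValueError("no VUS reclassifications observed; fate rates undefined")
    return VusFateRates(n_up=n_up, n_down=n_down, r_up=n_up / total, r_down=n_down / total)


def extrapolated_lp_rate(matrix: TransitionMatrix) -> LPConfidenceEstimate:
    """Full LP confidence estimate, extrapolating LP -> VUS fates.

    The LP -> VUS count is split into eventual upgrades and downgrades in
    proportion to the observed VUS fate rates, each rounded to an integer
    (half away from zero) before forming the adjusted rate
    ``(n_to_p + extrap_up) / n_lp_events``.  ``rate_extrapolated_raw``
    carries the unrounded version.  If the VUS row is empty the upward rate
    is taken as 0 with a warning.
    """
    n_lp = matrix.row_total(LP)
    if n_lp == 0:
        raise ValueError("no LP reclassifications observed")
    n_to_p = matrix.count(LP, P)
    n_to_vus = matrix.count(LP, VUS)
    n_to_lb = matrix.count(LP, LB)
    n_to_b = matrix.count(LP, B)
    try:
        fates = vus_fate_rates(matrix)
        r_up, r_down = fates.r_up, fates.r_down
    except ValueError:
        log.warning("empty VUS row: extrapolating with r_up = 0")
        r_up, r_down = 0.0, 1.0
    extrap_up = _round_half_away(r_up * n_to_vus)
    extrap_down = _round_half_away(r_down * n_to_vus)
    # a rate with an empty denominator is undefined, not zero
    try:
        rate_def = definitive_rate(matrix, include_lb=False).rate
    except ValueError:
        rate_def = float("nan")
    try:
        rate_def_lb = definitive_rate(matrix, include_lb=True).rate
    except ValueError:
        rate_def_lb = float("nan")
    return LPConfidenceEstimate(
        n_lp_events=n_lp,
        n_to_p=n_to_p,
        n_to_vus=n_to_vus,
        n_to_lb=n_to_lb,
        n_to_b=n_to_b,
        rate_definitive=rate_def,
        rate_definitive_lb=rate_def_lb,
        vus_up_rate=r_up,
        vus_down_rate=r_down,
        extrap_up=extrap_up,
        extrap_down=extrap_down,
        rate_extrapolated=(n_to_p + extrap_up) / n_lp,
        rate_extrapolated_raw=(n_to_p + r_up * n_to_vus) / n_lp,
    )
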