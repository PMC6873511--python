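"""Synthetic submission histories with known ground truth.

Two generators live here.

:func:`make_reference_fixture` builds a *deterministic* dataset whose
detected events reproduce, cell for cell, the published summary of ClinVar
reclassifications over the January 2016 – July 2019 window (571,850 initial
classifications, 4501 reclassification events), including the cancer /
cardiovascular gene tagging of the LP events.  Because that public summary
prints every transition count and start total, the entire quantitative
surface of the analysis is reconstructible from it; the fixture is the
package's end-to-end regression anchor.

:func:`generate_dataset` draws histories at random under a configurable
generative model — initial term, per-term reassessment probability, and a
row-stochastic destination law — and returns both the records and the exact
ground-truth events they imply, enabling oracle-equivalence and
parameter-recovery testing of the full pipeline.  Defaults are calibrated
to the same published summary, so the generator's default regime matches
the archive's observed dynamics.

The generator intentionally emits at most one reassessment per variant,
matching the pipeline's one-event-per-history model; multi-step histories
(for the first-versus-last collapse rule) are exercised by dedicated
hand-built fixtures in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .events import ReclassificationEvent
from .ingest import (
    DEFAULT_WINDOW_END,
    DEFAULT_WINDOW_START,
    PipelineConfig,
    SubmissionRecord,
    builtin_panel,
)
from .terms import TERM_INDEX, TERM_ORDER, ClassificationTerm

P, LP, VUS, LB, B = (
    ClassificationTerm.P,
    ClassificationTerm.LP,
    ClassificationTerm.VUS,
    ClassificationTerm.LB,
    ClassificationTerm.B,
)

#: Initial-classification totals per term, ClinVar Jan 2016 – July 2019.
REFERENCE_START_TOTALS: dict[ClassificationTerm, int] = {
    P: 63_658, LP: 36_808, VUS: 272_581, LB: 140_779, B: 58_024,
}

#: Reclassification event counts per ordered term pair, same window.
REFERENCE_TRANSITIONS: dict[ClassificationTerm, dict[ClassificationTerm, int]] = {
    P: {LP: 64, VUS: 41, LB: 1, B: 4},
    LP: {P: 625, VUS: 165, LB: 4, B: 2},
    VUS: {P: 171, LP: 486, LB: 1586, B: 341},
    LB: {P: 2, LP: 2, VUS: 66, B: 926},
    B: {P: 1, LP: 3, VUS: 1, LB: 10},
}

#: Cancer/cardiovascular split of the LP events: (upgraded to P, not upgraded).
REFERENCE_PANEL_SPLIT = {"acmg_sf_cancer": (151, 17), "acmg_sf_cardio": (82, 27)}

_NEUTRAL_GENES = ("TTN", "OBSCN", "SYNE1", "NEB", "AHNAK2")

#: Representative raw consequence labels per class (as written to records).
_CONSEQUENCE_LABEL = {"pLoF": "frameshift", "missense": "missense", "other": "intron"}


def reference_counts() -> tuple[dict, dict]:
    """Copies of the reference start totals and transition counts."""
    return dict(REFERENCE_START_TOTALS), {f: dict(row) for f, row in REFERENCE_TRANSITIONS.items()}


def make_reference_fixture() -> list[SubmissionRecord]:
    """Deterministic records reproducing the reference summary exactly.

    One submitter; one variant per initial classification; reclassified
    variants get a second record two years after the first.  LP events are
    gene-tagged so the cancer-panel events split 151 upgraded / 17 not, and
    the cardiovascular-panel events 82 / 27, with all remaining variants on
    neutral genes.  No randomness is involved.
    """
    cancer = sorted(builtin_panel("acmg_sf_cancer").genes)
    cardio = sorted(builtin_panel("acmg_sf_cardio").genes)
    d0, d1 = date(2016, 4, 1), date(2018, 4, 1)
    records: list[SubmissionRecord] = []
    vid = 0

    def lp_gene(to_term: ClassificationTerm, i: int) -> str:
        n_ca_up, n_ca_no = REFERENCE_PANEL_SPLIT["acmg_sf_cancer"]
        n_cv_up, n_cv_no = REFERENCE_PANEL_SPLIT["acmg_sf_cardio"]
        if to_term is P:
            if i < n_ca_up:
                return cancer[i % len(cancer)]
            if i < n_ca_up + n_cv_up:
                return cardio[i % len(cardio)]
        elif to_term is VUS:  # the non-upgraded panel events sit in LP -> VUS
            if i < n_ca_no:
                return cancer[i % len(cancer)]
            if i < n_ca_no + n_cv_no:
                return cardio[i % len(cardio)]
        return _NEUTRAL_GENES[i % len(_NEUTRAL_GENES)]

    for term in TERM_ORDER:
        transitions = REFERENCE_TRANSITIONS[term]
        for to_term in TERM_ORDER:
            for i in range(transitions.get(to_term, 0)):
                vid += 1
                v = f"V{vid:07d}"
                gene = lp_gene(to_term, i) if term is LP else _NEUTRAL_GENES[i % len(_NEUTRAL_GENES)]
                records.append(SubmissionRecord(v, "LAB001", term, d0, gene, ""))
                records.append(SubmissionRecord(v, "LAB001", to_term, d1, gene, ""))
        for i in range(REFERENCE_START_TOTALS[term] - sum(transitions.values())):
            vid += 1
            records.append(
                SubmissionRecord(f"V{vid:07d}", "LAB001", term, d0,
                                 _NEUTRAL_GENES[i % len(_NEUTRAL_GENES)], "")
            )
    return records


def _reference_start_distribution() -> dict[ClassificationTerm, float]:
    total = sum(REFERENCE_START_TOTALS.values())
    return {t: n / total for t, n in REFERENCE_START_TOTALS.items()}


def _reference_reassess_prob() -> dict[ClassificationTerm, float]:
    return {
        t: sum(REFERENCE_TRANSITIONS[t].values()) / REFERENCE_START_TOTALS[t]
        for t in TERM_ORDER
    }


def _reference_transition_probs() -> dict[ClassificationTerm, dict[ClassificationTerm, float]]:
    out = {}
    for t in TERM_ORDER:
        row = REFERENCE_TRANSITIONS[t]
        total = sum(row.values())
        out[t] = {d: n / total for d, n in row.items()}
    return out


def _default_gene_pools() -> dict[str, tuple[str, ...]]:
    return {
        "acmg_sf_cancer": tuple(sorted(builtin_panel("acmg_sf_cancer").genes)),
        "acmg_sf_cardio": tuple(sorted(builtin_panel("acmg_sf_cardio").genes)),
        "neutral": _NEUTRAL_GENES,
    }


@dataclass
class SyntheticConfig:
    """Generative model for synthetic submission histories.

    Defaults reproduce the reference regime: start distribution,
    reassessment probabilities and destination laws taken from the
    published 2016–2019 summary; dates uniform over the window; genes drawn
    from cancer / cardiovascular / neutral pools; consequence classes mixed
    pLoF 20% / missense 50% / other 30%.
    """

    n_variants: int = sum(REFERENCE_START_TOTALS.values())
    start_distribution: dict[ClassificationTerm, float] = field(
        default_factory=_reference_start_distribution)
    reassess_prob: dict[ClassificationTerm, float] = field(
        default_factory=_reference_reassess_prob)
    transition_probs: dict[ClassificationTerm, dict[ClassificationTerm, float]] = field(
        default_factory=_reference_transition_probs)
    #: per-stratum override of P(LP -> P | reassessed); keys are consequence
    #: classes (pLoF/missense/other) or gene-pool names
    upgrade_prob_by_stratum: dict[str, float] = field(default_factory=dict)
    date_window: tuple[date, date] = (DEFAULT_WINDOW_START, DEFAULT_WINDOW_END)
    panel_gene_pools: dict[str, tuple[str, ...]] = field(default_factory=_default_gene_pools)
    pool_weights: dict[str, float] = field(
        default_factory=lambda: {"acmg_sf_cancer": 0.05, "acmg_sf_cardio": 0.05, "neutral": 0.90})
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {"pLoF": 0.20, "missense": 0.50, "other": 0.30})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        _check_prob_vector("start_distribution", self.start_distribution.values())
        _check_prob_vector("consequence_mix", self.consequence_mix.values())
        _check_prob_vector("pool_weights", self.pool_weights.values())
        for t, p in self.reassess_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reassess_prob[{t}] = {p} outside [0, 1]")
        for t, row in self.transition_probs.items():
            if t in row:
                raise ValueError(f"transition_probs[{t}] may not include {t} itself")
            _check_prob_vector(f"transition_probs[{t}]", row.values())
        for u in self.upgrade_prob_by_stratum.values():
            if not 0.0 <= u <= 1.0:
                raise ValueError("upgrade probabilities must lie in [0, 1]")


def _check_prob_vector(name: str, values) -> None:
    values = list(values)
    if any(v < 0 for v in values):
        raise ValueError(f"{name}: negative probability")
    if abs(sum(values) - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities sum to {sum(values)}, not 1")


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[SubmissionRecord], list[ReclassificationEvent]]:
    """Draw a synthetic dataset and its exact ground-truth event list.

    Per variant: a gene (pool then symbol), a consequence class, an initial
    term, and an initial date uniform over the window; with probability
    ``reassess_prob[term]`` a destination term is drawn from
    ``transition_probs[term]`` (optionally overridden per stratum for LP)
    and a strictly later in-window date, yielding a second record.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    start_d, end_d = config.date_window
    span = (end_d - start_d).days  # dates occupy day offsets [0, span - 1]
    if span < 2:
        raise ValueError("date window must span at least two days")

    pool_names = list(config.panel_gene_pools)
    pool_p = np.array([config.pool_weights.get(p, 0.0) for p in pool_names])
    pool_idx = rng.choice(len(pool_names), size=n, p=pool_p / pool_p.sum())
    genes = np.empty(n, dtype=object)
    for k, pname in enumerate(pool_names):
        mask = pool_idx == k
        pool = config.panel_gene_pools[pname]
        genes[mask] = np.asarray(pool, dtype=object)[rng.integers(0, len(pool), mask.sum())]

    cons_classes = list(config.consequence_mix)
    cons_idx = rng.choice(len(cons_classes), size=n,
                          p=[config.consequence_mix[c] for c in cons_classes])

    start_p = np.array([config.start_distribution.get(t, 0.0) for t in TERM_ORDER])
    term_idx = rng.choice(5, size=n, p=start_p)

    init_day = rng.integers(0, span - 1, size=n)  # leave room for a later date
    reassess_p = np.array([config.reassess_prob.get(t, 0.0) for t in TERM_ORDER])
    reassessed = rng.random(n) < reassess_p[term_idx]

    dest_idx = np.full(n, -1, dtype=np.int64)
    for i, t in enumerate(TERM_ORDER):
        sel = np.flatnonzero(reassessed & (term_idx == i))
        if sel.size == 0:
            continue
        dests = [d for d in TERM_ORDER if d is not t]
        row = config.transition_probs.get(t, {})
        p_row = np.array([row.get(d, 0.0) for d in dests])
        if p_row.sum() <= 0:
            reassessed[sel] = False
            continue
        draw = rng.choice(4, size=sel.size, p=p_row / p_row.sum())
        dest_idx[sel] = np.array([TERM_INDEX[d] for d in dests])[draw]

    if config.upgrade_prob_by_stratum:
        _apply_lp_overrides(config, rng, genes, cons_idx, cons_classes,
                            term_idx, reassessed, dest_idx, pool_idx, pool_names)

    # reassessment date strictly after the initial one, still in-window
    gap = np.zeros(n, dtype=np.int64)
    sel = np.flatnonzero(reassessed)
    if sel.size:
        gap[sel] = 1 + rng.integers(0, span - 1 - init_day[sel])

    records: list[SubmissionRecord] = []
    truth: list[ReclassificationEvent] = []
    for i in range(n):
        v = f"S{i + 1:07d}"
        gene = genes[i]
        cons_class = cons_classes[cons_idx[i]]
        cons_label = _CONSEQUENCE_LABEL[cons_class]
        t0 = TERM_ORDER[term_idx[i]]
        day0 = start_d + timedelta(days=int(init_day[i]))
        records.append(SubmissionRecord(v, "SIMLAB", t0, day0, gene, cons_label))
        if reassessed[i]:
            t1 = TERM_ORDER[dest_idx[i]]
            day1 = day0 + timedelta(days=int(gap[i]))
            records.append(SubmissionRecord(v, "SIMLAB", t1, day1, gene, cons_label))
            truth.append(
                ReclassificationEvent(
                    variant_id=v, submitter_id="SIMLAB",
                    from_term=t0, to_term=t1, from_date=day0, to_date=day1,
                    gene=gene, consequence_class=cons_class,
                )
            )
    return records, truth


def _apply_lp_overrides(config, rng, genes, cons_idx, cons_classes,
                        term_idx, reassessed, dest_idx, pool_idx, pool_names) -> None:
    """Re-draw LP destinations where a stratum upgrade override applies.

    Consequence-class keys take precedence over gene-pool keys.  With
    override u, the destination is P with probability u, else one of
    VUS/LB/B in proportion to the base law.
    """
    lp_i = TERM_INDEX[LP]
    sel = np.flatnonzero(reassessed & (term_idx == lp_i))
    if sel.size == 0:
        return
    base = config.transition_probs.get(LP, {})
    downs = [VUS, LB, B]
    p_down = np.array([base.get(d, 0.0) for d in downs])
    p_down = p_down / p_down.sum() if p_down.sum() > 0 else np.array([1.0, 0.0, 0.0])
    down_choices = np.array([TERM_INDEX[d] for d in downs])
    for j in sel:
        key = cons_classes[cons_idx[j]]
        if key not in config.upgrade_prob_by_stratum:
            key = pool_names[pool_idx[j]]
            if key not in config.upgrade_prob_by_stratum:
                continue
        u = config.upgrade_prob_by_stratum[key]
        if rng.random() < u:
            dest_idx[j] = TERM_INDEX[P]
        else:
            dest_idx[j] = down_choices[rng.choice(3, p=p_down)]


def recover_parameters(
    records: list[SubmissionRecord], config: PipelineConfig | None = None
) -> dict:
    """Run the real pipeline on generated records and return empirical rates.

    Returns ``{"reassess_prob": {term: rate}, "transition_probs": {term:
    {dest: prob}}, "n_initial": {term: count}}`` — the validation harness
    for parameter-recovery tests.
    """
    from .events import build_histories, detect_events
    from .transitions import build_transition_matrix

    histories = build_histories(records)
    events, denominators = detect_events(histories, config)
    matrix = build_transition_matrix(events, denominators)
    reassess = {}
    trans: dict = {}
    for t in TERM_ORDER:
        start = matrix.start_totals.get(t, 0)
        row_total = matrix.row_total(t)
        reassess[t] = row_total / start if start else 0.0
        trans[t] = (
            {d: matrix.count(t, d) / row_total for d in TERM_ORDER if d is not t}
            if row_total else {}
        )
    return {
        "reassess_prob": reassess,
        "transition_probs": trans,
        "n_initial": dict(matrix.start_totals),
    }
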