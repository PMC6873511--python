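# Methods

## Data model and event definition

The unit of observation is a classification assertion: one (variant,
submitter, date) row carrying one of the five ACMG/AMP terms. Assertions
with aggregate or non-Mendelian significance strings ("Pathogenic/Likely
pathogenic", "Conflicting interpretations", "drug response", …) are dropped
at ingest and tallied; the analysis is defined over single-submitter
assertions in the standard five terms only.

Assertions group into per-(variant, submitter) histories, date-sorted.
Same-day assertions with different terms sort by pathogenicity axis
(benign side first) with a logged warning; because the secondary key is the
term itself, detection is provably independent of input row order.

A history enters the analysis only if its **first** assessment date falls
in the window `[window_start, window_end)`, default 2016-01-01 to
2019-07-01 — restricting to variants plausibly classified under the 2015
guidelines. An in-window history contributes one count to its first term's
denominator, and one **event** (first term → last term) iff the last term
differs. Chained intermediate states collapse; a history that oscillates
back to its first term yields no event. This one-event-per-record rule
mirrors the fact that a public archive keeps a single current record per
submitter, under which "was reclassified" is a first-versus-current
comparison; multi-step counting would be an equally defensible but
different estimand.

## Certainty direction

Each term has a signed axis position (B=−2, LB=−1, VUS=0, LP=+1, P=+2) and
certainty = |position|. A transition is

- **opposing** if source and destination are both nonzero with opposite
  signs (8 of the 20 ordered pairs),
- **more certain** if destination certainty exceeds source certainty
  (6 pairs: VUS→{LP,P,LB,B}, LP→P, LB→B),
- **less certain** otherwise (6 pairs).

This sign/magnitude rule is a formalization chosen so that the three
categories partition all events exactly (property-tested on arbitrary
matrices).

## LP confidence estimators

With `n_f→t` the event count from term f to t and `N_LP` the LP row sum:

- definitive rate: `n_LP→P / (n_LP→P + n_LP→B)` — only events that reached
  a definitive state carry a verdict;
- LB-inclusive: `n_LP→P / (n_LP→P + n_LP→LB + n_LP→B)` — LB variants
  essentially never become pathogenic, so LB may be pooled with B;
- extrapolated: VUS fate rates `r_up = (n_VUS→LP + n_VUS→P) / N_VUS` and
  `r_down = 1 − r_up` split the LP→VUS mass into `round(r_up · n_LP→VUS)`
  eventual upgrades and `round(r_down · n_LP→VUS)` downgrades, giving
  `(n_LP→P + extrap_up) / N_LP`.

Extrapolated counts round half away from zero **before** forming the rate
(0.254… × 165 = 41.95 → 42; 0.746… × 165 = 123.05 → 123); the unrounded
rate is exposed as `rate_extrapolated_raw`. Because independent rounding
can shift the up/down split by one unit, the invariant is
`extrap_up + extrap_down ∈ {n_LP→VUS − 1, n_LP→VUS, n_LP→VUS + 1}`.
Variants that started at LP plausibly resolve upward more often than
generic VUS, so the extrapolated rate is a worst-case lower bound; the
estimate object carries `worst_case = True` and no numeric correction is
invented for it. Empty denominators raise (an undefined rate is not zero);
an empty VUS row extrapolates with `r_up = 0` under a warning.

On the reference counts the three estimators give 625/627 = 99.68%,
625/631 = 99.05%, and (625+42)/796 = 83.79%. Note 625/631 renders as
99.0% at one decimal.

## Stratified comparison and the exact Fisher test

Strata are predicates over LP-start events — consequence class (pLoF =
{nonsense, frameshift, splice donor, splice acceptor, start lost, stop
gained} by default; missense = {missense}; both configurable because no
single pLoF vocabulary is universal) or gene-panel membership. Events
labelled "other" are excluded from the consequence comparison, not pooled;
an event matching both strata raises rather than double-counting. The
comparison tests the 2×2 table (upgraded to P, not upgraded) × stratum.

The two-sided Fisher p-value is computed in-package: conditioning on both
margins, the top-left count is hypergeometric,
`P(a) = C(r1,a) C(r2,c1−a) / C(n,c1)`; the two-sided p is the sum of
probabilities of all tables with the observed margins whose point
probability does not exceed the observed one — the point-probability
convention of standard statistical software. Probabilities are formed in
log-space via log-gamma; a relative gate of 1e−7 absorbs floating-point
ties in the ≤ comparison. A zero margin leaves no free cell: p = 1 by
convention, with a warning. The implementation is verified against exact
integer-combinatorics enumeration on every 2×2 table with n ≤ 40 (to
1e−9) and against an independent library implementation on assorted
larger tables. Under an equal-proportion null simulation the rejection
rate at α = 0.05 stays below α, as expected for a conservative exact test.

## Synthetic data

`generate_dataset` draws, per variant: a gene (cancer-panel /
cardiovascular-panel / neutral pools, weights 0.05/0.05/0.90), a
consequence class (pLoF 0.20 / missense 0.50 / other 0.30 — a realistic
clinical-lab mix of reportable variants), an initial term, and an initial
date uniform over the window; with a per-term reassessment probability it
draws a destination from a row-stochastic law and a strictly later
in-window date. Defaults for the start distribution, reassessment
probabilities, and destination laws are the published 2016–2019 archive
summary, so the default regime matches observed dynamics. The generator
returns the exact ground-truth event list alongside the records and is
byte-reproducible from its seed.

What the generator does *not* emulate: multiple submitters per variant,
more than one reassessment per record (exercised instead by hand-built
multi-step fixtures), non-uniform temporal patterns (evidence arrives in
bursts with database releases), and correlation between gene, consequence
and fate beyond the explicit per-stratum upgrade overrides. Passing
recovery tests therefore validate the pipeline's bookkeeping and
estimators, not any mechanistic claim about why laboratories reclassify.

`make_reference_fixture` is the deterministic counterpart: one submitter,
571,850 variants with fixed dates, whose detected events reproduce the
published summary exactly — including gene tags making the cancer-panel LP
events split 151 upgraded / 17 not and the cardiovascular 82 / 27. The
non-upgraded panel events are placed in the LP→VUS cell; the published
counts constrain only their totals, not which non-P cell they occupy.

## Numerical and rendering conventions

Rates are computed at full precision and rounded only at render time: the
"percentage reclassified" column always shows two decimals; share columns
show one decimal at ≥1% and two below 1%. Percentages in `summary.json`
are stored as full-precision fractions. Problem sizes in the test suite —
the full 571,850-record reference fixture, 200,000-variant recovery runs,
a 2,000-replicate null simulation, and the exhaustive n ≤ 40 Fisher sweep
— keep the whole suite under half a minute on one CPU.

## Known limitations

- The TSV dialect is a reconstruction of the public archive's
  submission-summary format; real exports may need column renames.
- Reclassification is tracked within, not across, submitters; cross-lab
  conflict resolution is out of scope.
- The extrapolated LP rate inherits the stationarity assumption of the VUS
  fate split over a 3.5-year window; it is a bound, not an estimate of the
  eventual rate.
- The pLoF-vs-missense contrast is exercised on synthetic data only, as no
  public per-consequence event counts exist to pin a deterministic fixture.
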