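"""Stratified LP upgrade comparisons and the exact Fisher test."""

from datetime import date
from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

import varreclass as v
from varreclass.terms import ClassificationTerm as T


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive integer-combinatorics enumeration.

    Works entirely in exact integer arithmetic: for fixed margins the
    probability of top-left count k is proportional to C(r1,k)*C(r2,c1-k),
    so the point-probability rule reduces to comparing integer weights.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in support}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / comb(n, c1)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [((1, 1, 1, 1), 1.0),
         ((5, 0, 0, 5), 2 / 252)],
    )
    def test_closed_form_examples(self, table, expected):
        assert v.fisher_exact_two_sided(*table) == pytest.approx(expected, abs=1e-12)

    def test_cancer_vs_cardio_table(self):
        p = v.fisher_exact_two_sided(151, 17, 82, 27)
        assert round(p, 3) == 0.001

    def test_matches_scipy_on_assorted_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher
        tables = [(151, 17, 82, 27), (3, 9, 12, 2), (40, 60, 55, 45),
                  (1, 0, 0, 30), (7, 7, 7, 7), (0, 10, 10, 0), (2, 3, 5, 8)]
        for t in tables:
            expected = scipy_fisher([[t[0], t[1]], [t[2], t[3]]]).pvalue
            assert v.fisher_exact_two_sided(*t) == pytest.approx(expected, abs=1e-9)

    def test_zero_margin_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert v.fisher_exact_two_sided(0, 0, 3, 4) == 1.0
        assert any("zero margin" in m for m in caplog.messages)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            v.fisher_exact_two_sided(-1, 2, 3, 4)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_symmetries_and_range(self, a, b, c, d):
        """Invariant under row swap and column swap; p in (0, 1]."""
        p = v.fisher_exact_two_sided(a, b, c, d)
        assert 0 < p <= 1
        assert v.fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, abs=1e-12)
        assert v.fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-12)

    def test_matches_exact_enumeration_up_to_n25(self):
        """Exhaustive check against the integer oracle on all margins n <= 25
        (the full n <= 40 sweep runs in the acceptance suite)."""
        for n in range(1, 26):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    r2 = n - r1
                    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
                        assert abs(
                            v.fisher_exact_two_sided(a, b, c, d)
                            - exact_fisher_oracle(a, b, c, d)
                        ) <= 1e-9


def lp_event(variant, to_term, gene="", consequence_class="other"):
    return v.ReclassificationEvent(variant, "lab", T.LP, to_term,
                                   date(2016, 2, 1), date(2018, 2, 1),
                                   gene, consequence_class)


class TestUpgradeTable:
    def test_reference_panel_split(self, reference_results):
        cancer = v.builtin_panel("acmg_sf_cancer")
        cardio = v.builtin_panel("acmg_sf_cardio")
        table = v.upgrade_table(reference_results.events,
                                v.panel_predicate(cancer), v.panel_predicate(cardio))
        assert table == ((151, 17), (82, 27))

    def test_non_lp_events_are_ignored(self):
        events = [
            lp_event("a", T.P, gene="BRCA1"),
            v.ReclassificationEvent("b", "lab", T.VUS, T.P,
                                    date(2016, 2, 1), date(2018, 2, 1), "BRCA1", "other"),
        ]
        panel = v.GenePanel("cancer", frozenset({"BRCA1"}))
        table = v.upgrade_table(events, v.panel_predicate(panel),
                                lambda e: e.gene == "MYH7")
        assert table == ((1, 0), (0, 0))

    def test_overlapping_strata_is_a_hard_error(self):
        events = [lp_event("a", T.P, gene="BRCA1", consequence_class="pLoF")]
        with pytest.raises(ValueError, match="disjoint"):
            v.upgrade_table(events, v.consequence_predicate("pLoF"),
                            lambda e: e.gene == "BRCA1")


class TestCompareStrata:
    def test_reference_cancer_vs_cardio(self, reference_results):
        comp = reference_results.compare_panels(
            v.builtin_panel("acmg_sf_cancer"), v.builtin_panel("acmg_sf_cardio"))
        assert (comp.upgraded_a, comp.total_a) == (151, 168)
        assert (comp.upgraded_b, comp.total_b) == (82, 109)
        assert 100 * comp.fraction_a == pytest.approx(89.9, abs=0.05)
        assert 100 * comp.fraction_b == pytest.approx(75.2, abs=0.05)
        assert round(comp.p_value, 3) == 0.001

    def test_empty_stratum_flagged_not_computable(self):
        events = [lp_event("a", T.P, consequence_class="pLoF")]
        comp = v.compare_strata(events, "pLoF", v.consequence_predicate("pLoF"),
                                "missense", v.consequence_predicate("missense"))
        assert not comp.computable
        assert "missense" in comp.reason
        assert comp.p_value is None

    def test_other_consequences_are_excluded_not_pooled(self):
        events = [lp_event("a", T.P, consequence_class="pLoF"),
                  lp_event("b", T.VUS, consequence_class="other")]
        table = v.upgrade_table(events, v.consequence_predicate("pLoF"),
                                v.consequence_predicate("missense"))
        assert table == ((1, 0), (0, 0))

    def test_null_simulation_fractions_agree(self):
        """pLoF and missense strata generated with identical upgrade
        probabilities differ by less than three binomial standard errors."""
        cfg = v.SyntheticConfig(
            n_variants=60_000, seed=3,
            start_distribution={T.LP: 1.0, T.P: 0.0, T.VUS: 0.0, T.LB: 0.0, T.B: 0.0},
            reassess_prob={t: (0.5 if t is T.LP else 0.0) for t in T},
            transition_probs={T.LP: {T.P: 0.75, T.VUS: 0.20, T.LB: 0.03, T.B: 0.02}},
        )
        _, truth = v.generate_dataset(cfg)
        comp = v.compare_strata(truth, "pLoF", v.consequence_predicate("pLoF"),
                                "missense", v.consequence_predicate("missense"))
        assert comp.computable
        p_pool = (comp.upgraded_a + comp.upgraded_b) / (comp.total_a + comp.total_b)
        se = (p_pool * (1 - p_pool) * (1 / comp.total_a + 1 / comp.total_b)) ** 0.5
        assert abs(comp.fraction_a - comp.fraction_b) < 3 * se
        assert comp.p_value > 0.01
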