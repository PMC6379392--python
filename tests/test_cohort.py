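"""Cohort table parsing, published tallies, association and survival ops."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import alkdeep as ad
from alkdeep import cohort as coh
from alkdeep.errors import UndefinedTestError


def _hypergeom_pmf(a, r1, c1, n):
    """P(top-left cell = a) at fixed margins, from binomial coefficients."""
    return (
        math.comb(c1, a) * math.comb(n - c1, r1 - a) / math.comb(n, r1)
    )


def _fisher_by_enumeration(a, b, c, d):
    """Two-sided exact p: sum over tables no more probable than observed."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = _hypergeom_pmf(a, r1, c1, n)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = _hypergeom_pmf(x, r1, c1, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestDeepSeqParsing:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("F1174L (24,7%)", (("F1174L", 24.7),)),
            ("F1245I (53%)", (("F1245I", 53.0),)),
            ("2nd F1174S (58,7%) and F1174I (7,7%)",
             (("F1174S", 58.7), ("F1174I", 7.7))),
            ("D1160D", (("D1160D", None),)),
        ],
    )
    def test_mutation_entries(self, raw, expected):
        assert coh.parse_deep_seq(raw).mutations == expected

    def test_negative_and_amplified(self):
        assert coh.parse_deep_seq("Neg").negative
        assert coh.parse_deep_seq("Amp.").amplified

    def test_out_of_range_vaf_rejected(self):
        with pytest.raises(ValueError):
            coh.parse_deep_seq("F1174L (120%)")


class TestFixture:
    def test_fixture_loads_and_validates(self, cohort_table):
        assert len(cohort_table) == 105
        assert list(cohort_table.columns) == coh.COHORT_COLUMNS

    def test_round_trip_preserves_summary(self, cohort_table, tmp_path):
        path = tmp_path / "cohort.tsv"
        coh.write_cohort_tsv(cohort_table, path)
        back = ad.load_cohort(path)
        assert ad.summarize_mutations(back) == ad.summarize_mutations(cohort_table)

    def test_unknown_vocabulary_rejected(self, cohort_table, tmp_path):
        bad = cohort_table.copy()
        bad.loc[0, "outcome"] = "UNKNOWN"
        path = tmp_path / "bad.tsv"
        coh.write_cohort_tsv(bad, path)
        with pytest.raises(ValueError, match="outcome"):
            ad.load_cohort(path)


class TestSummary:
    def test_published_tallies(self, cohort_table):
        s = ad.summarize_mutations(cohort_table)
        assert s["n_cases"] == 105
        assert s["point_mutation_positive"] == 16
        assert s["pct_point_mutation_positive"] == pytest.approx(15.2)
        assert s["samples_by_residue"][1174] == 11
        assert s["samples_by_residue"][1245] == 3
        assert s["samples_by_residue"][1171] == 1
        assert s["samples_by_residue"][1240] == 1
        assert s["primary_substitution_counts"]["F1174L"] == 7
        assert s["subclonal"] == 6 and s["clonal"] == 10
        assert s["sanger_missed"] == 4
        assert s["amplification_cases"] == 4
        assert s["alk_altered"] == 20
        assert s["synonymous_cases"] == 1
        assert s["min_vaf_pct"] == pytest.approx(2.7)

    def test_empty_table_all_zero(self, cohort_table):
        s = ad.summarize_mutations(cohort_table.head(0))
        assert s["point_mutation_positive"] == 0
        assert s["alk_altered"] == 0
        assert s["samples_by_residue"] == {}


class TestCrosstab:
    def test_11q_deletion_excludes_mutations(self, cohort_table):
        ct = ad.crosstab(cohort_table, "11q_del", "mutation_positive")
        assert int(ct.loc[True].sum()) == 27
        assert int(ct.loc[True, True]) == 0
        assert int(ct.to_numpy().sum()) == 105

    def test_mycn_amplified_mutations_mostly_subclonal(self, cohort_table):
        ct = ad.crosstab(cohort_table, "mycn_amplified", "subclonal")
        # restricted to the 16 mutated cases (subclonal undefined elsewhere)
        assert int(ct.to_numpy().sum()) == 16
        assert int(ct.loc[True].sum()) == 6
        assert int(ct.loc[True, True]) == 4
        assert int(ct.loc[False, False]) == 8  # clonal non-MYCN-amplified

    def test_single_row_single_cell(self, cohort_table):
        ct = ad.crosstab(cohort_table.head(1), "11q_del", "mutation_positive")
        assert int(ct.to_numpy().sum()) == 1

    def test_unknown_factor_raises(self, cohort_table):
        with pytest.raises(KeyError):
            ad.crosstab(cohort_table, "11q_del", "nonexistent")


class TestFisherExact:
    def test_exhaustive_agreement_with_enumeration_small_margins(self):
        for r1 in range(0, 13):
            for c in range(0, 13):
                for a in range(0, r1 + 1):
                    b = r1 - a
                    for x in range(0, c + 1):
                        d = c - x
                        if a + b + x + d == 0:
                            continue
                        assert ad.fisher_exact(a, b, x, d) == pytest.approx(
                            _fisher_by_enumeration(a, b, x, d), abs=1e-9
                        ), (a, b, x, d)

    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)))
    def test_random_tables_up_to_margin_30(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert ad.fisher_exact(a, b, c, d) == pytest.approx(
            _fisher_by_enumeration(a, b, c, d), abs=1e-9
        )

    def test_symmetric_table_p_is_one(self):
        assert ad.fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    def test_cohort_association_table(self, cohort_table):
        ct = ad.crosstab(cohort_table, "11q_del", "mutation_positive")
        p = ad.fisher_exact(
            int(ct.loc[True, True]), int(ct.loc[True, False]),
            int(ct.loc[False, True]), int(ct.loc[False, False]),
        )
        assert 0 < p < 0.05  # depletion of mutations among 11q-deleted cases

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ad.fisher_exact(0, 0, 0, 0)
        with pytest.raises(ValueError):
            ad.fisher_exact(-1, 2, 3, 4)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        records = [ad.SurvivalRecord(t, 0) for t in range(1, 11)]
        curve = ad.km_estimate(records)
        assert curve(0) == 1.0 and curve(100) == 1.0

    def test_two_uncensored_events_closed_form(self):
        records = [ad.SurvivalRecord(1, 1), ad.SurvivalRecord(2, 1)]
        curve = ad.km_estimate(records)
        assert curve(0.5) == 1.0
        assert curve(1) == pytest.approx(0.5)
        assert curve(2) == pytest.approx(0.0)

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(30, size=80)
        records = [ad.SurvivalRecord(float(t), 1) for t in times]
        curve = ad.km_estimate(records)
        for t in [0.0, 5.0, 20.0, 50.0, 120.0]:
            empirical = np.mean(times > t)
            assert curve(t) == pytest.approx(empirical, abs=1e-12)

    def test_median_recovery_from_exponential(self):
        records = coh.simulate_exponential_survival(
            500, median_months=36.0, seed=9
        )
        curve = ad.km_estimate(records)
        below = curve.survival <= 0.5
        median = curve.times[below.argmax()]
        assert median == pytest.approx(36.0, rel=0.10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ad.SurvivalRecord(-1, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        group = [ad.SurvivalRecord(t, 1) for t in (3, 6, 9, 12)]
        stat, p = ad.logrank(group, list(group))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        a = coh.simulate_exponential_survival(60, 20.0, seed=1)
        b = coh.simulate_exponential_survival(60, 45.0, seed=2)
        stat_ab, p_ab = ad.logrank(a, b)
        stat_ba, p_ba = ad.logrank(b, a)
        assert stat_ab == pytest.approx(stat_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_power_under_hazard_ratio_three(self):
        significant = 0
        n_seeds = 20
        for seed in range(n_seeds):
            a = coh.simulate_exponential_survival(200, 12.0, seed=1000 + seed)
            b = coh.simulate_exponential_survival(200, 36.0, seed=2000 + seed)
            _, p = ad.logrank(a, b)
            significant += p < 0.01
        assert significant >= 0.9 * n_seeds

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ad.logrank([], [ad.SurvivalRecord(1, 1)])

    def test_no_events_anywhere_is_undefined(self):
        a = [ad.SurvivalRecord(5, 0)] * 3
        b = [ad.SurvivalRecord(7, 0)] * 3
        with pytest.raises(UndefinedTestError):
            ad.logrank(a, b)
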