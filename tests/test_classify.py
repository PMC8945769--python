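"""Factor thresholds, categories, matching rates and prioritization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutamatch import (
    CATEGORIES,
    FactorThresholds,
    GeneRecord,
    classify_cohort,
    classify_gene,
    prioritize,
    summarize_cohort,
)


def make_gene(symbol="G", proximity=10.0, at=50.0, **kw):
    return GeneRecord(symbol=symbol, chromosome=1, proximity=proximity, a_plus_t=at, **kw)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "proximity, at, category",
        [
            (9, 60, "BOTH"),      # KCNJ6
            (71, 34, "NONE"),     # KCNK4
            (76, 64, "FII_ONLY"), # CACNA2D1
            (1.9, 48, "FI_ONLY"), # CACNA1C
            (50, 59, "NONE"),     # both cutoffs fail strict comparison
        ],
    )
    def test_strict_default_categories(self, proximity, at, category):
        assert classify_gene(make_gene(proximity=proximity, at=at)).category == category

    def test_non_strict_includes_boundary(self):
        t = FactorThresholds(strict_fi=False, strict_fii=False)
        call = classify_gene(make_gene(proximity=50, at=59), t)
        assert call.category == "BOTH"

    def test_missing_fields_name_the_gene(self):
        rec = GeneRecord(symbol="ORPHAN", chromosome=1, a_plus_t=50)
        with pytest.raises(ValueError, match="ORPHAN"):
            classify_gene(rec)

    def test_category_consistent_with_flags(self):
        for prox in (10, 90):
            for at in (40, 70):
                call = classify_gene(make_gene(proximity=prox, at=at))
                expected = {
                    (True, True): "BOTH", (True, False): "FI_ONLY",
                    (False, True): "FII_ONLY", (False, False): "NONE",
                }[(call.meets_fi, call.meets_fii)]
                assert call.category == expected


cohort_strategy = st.lists(
    st.tuples(
        st.floats(0, 250, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    ),
    min_size=1,
    max_size=25,
)


class TestSummarize:
    def test_table1_rates(self, table1):
        s = summarize_cohort(classify_cohort(table1))
        assert (s.n, s.either_count, s.matching_pct) == (11, 9, 82)
        assert s.fi_count == 7

    def test_table2_rates(self, table2):
        s = summarize_cohort(classify_cohort(table2))
        assert (s.n, s.either_count, s.counts["NONE"]) == (20, 15, 5)

    def test_all_none_cohort_rate_zero(self):
        calls = classify_cohort([make_gene(str(i), 100, 30) for i in range(4)])
        assert summarize_cohort(calls).matching_rate == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    @given(cohort_strategy)
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_brute_force(self, rows):
        """Summary counts match an independent gene-by-gene recount."""
        records = [make_gene(f"G{i}", p, a) for i, (p, a) in enumerate(rows)]
        calls = classify_cohort(records)
        s = summarize_cohort(calls)
        # brute force from raw values, not from FactorCall
        brute = {"BOTH": 0, "FI_ONLY": 0, "FII_ONLY": 0, "NONE": 0}
        for rec in records:
            fi, fii = rec.proximity < 50, rec.a_plus_t > 59
            brute[
                "BOTH" if fi and fii else "FI_ONLY" if fi else "FII_ONLY" if fii else "NONE"
            ] += 1
        assert s.counts == brute
        assert sum(s.counts.values()) == s.n == len(records)
        assert s.either_count == s.n - brute["NONE"]
        assert s.matching_rate == pytest.approx(s.either_count / s.n)

    @given(
        cohort_strategy,
        st.floats(1, 99, allow_nan=False),
        st.floats(1, 99, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotonicity(self, rows, at_cut, at_cut2):
        """Lowering the A+T cutoff never loses F(ii) genes; raising the
        proximity cutoff never loses F(i) genes."""
        records = [make_gene(f"G{i}", p, a) for i, (p, a) in enumerate(rows)]
        lo, hi = sorted((at_cut, at_cut2))
        fii_lo = sum(
            classify_gene(r, FactorThresholds(at_cutoff=lo)).meets_fii for r in records
        )
        fii_hi = sum(
            classify_gene(r, FactorThresholds(at_cutoff=hi)).meets_fii for r in records
        )
        assert fii_lo >= fii_hi
        fi_narrow = sum(
            classify_gene(r, FactorThresholds(proximity_cutoff=lo)).meets_fi for r in records
        )
        fi_wide = sum(
            classify_gene(r, FactorThresholds(proximity_cutoff=hi)).meets_fi for r in records
        )
        assert fi_wide >= fi_narrow


class TestFixtureNoneSets:
    def test_table1_none_genes(self, table1):
        calls = classify_cohort(table1)
        none = {c.symbol for c in calls if c.category == "NONE"}
        assert none == {"KCNK4", "GABRB3"}

    def test_table2_none_genes(self, table2):
        calls = classify_cohort(table2)
        none = {c.symbol for c in calls if c.category == "NONE"}
        assert none == {"S1PR1", "TACR1", "HCRTR2", "CASR", "DRD3"}

    def test_gabrb3_at_exactly_59_fails_strict_fii(self, table1):
        gabrb3 = next(r for r in table1 if r.symbol == "GABRB3")
        assert gabrb3.a_plus_t == 59
        assert not classify_gene(gabrb3).meets_fii


class TestPrioritize:
    def test_table1_none_group_membership(self, table1):
        calls = classify_cohort(table1)
        top = prioritize(table1, calls, "NONE", 5)
        assert set(top) == {"KCNK4", "GABRB3"}

    def test_k_zero_empty(self, table1):
        calls = classify_cohort(table1)
        assert prioritize(table1, calls, "BOTH", 0) == []

    def test_single_both_gene_ranks_first(self):
        records = [
            make_gene("A", 80, 40), make_gene("B", 10, 70), make_gene("C", 10, 40),
            make_gene("D", 80, 70), make_gene("E", 80, 45),
        ]
        calls = classify_cohort(records)
        assert prioritize(records, calls, "BOTH", 5) == ["B"]

    def test_both_ranked_by_at_desc_then_proximity_asc(self):
        records = [
            make_gene("A", 20, 65), make_gene("B", 5, 70),
            make_gene("C", 10, 70), make_gene("D", 5, 65),
        ]
        calls = classify_cohort(records)
        assert prioritize(records, calls, "BOTH", 4) == ["B", "C", "D", "A"]

    def test_unknown_group_rejected(self, table1):
        calls = classify_cohort(table1)
        with pytest.raises(ValueError):
            prioritize(table1, calls, "FI_ONLY", 3)
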