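"""Fisher exact test, BH adjustment, per-gene screen, gene-set enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hst

from pocketprior.enrichment_stats import (
    ContingencyTable2x2,
    GeneSet,
    bh_adjust,
    build_contingency,
    fisher_exact,
    gene_set_enrichment,
    odds_ratio,
    run_per_gene_screen,
    select_top_cancer_types,
)

from conftest import make_mset


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Exact-rational hypergeometric enumeration, independent of the implementation."""
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, col1 - (n_total - row1)), min(row1, col1)
    weights = {x: comb(row1, x) * comb(n_total - row1, col1 - x) for x in range(lo, hi + 1)}
    total = comb(n_total, col1)
    if alternative == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    else:  # two-sided, R-style relative tolerance mirrored in exact integers
        wa = weights[a]
        num = sum(w for w in weights.values() if w * 10**7 <= wa * (10**7 + 1))
    return float(Fraction(num, total))


class TestFisherExact:
    def test_two_by_two_example(self):
        p, _ = fisher_exact((2, 0, 0, 2), "greater")
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_zero_pocket_count_gives_p_one(self):
        for b, c, d in [(3, 1, 9), (10, 5, 2), (1, 7, 0)]:
            p, _ = fisher_exact((0, b, c, d), "greater")
            assert p == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_matches_rational_oracle_on_random_tables(self, alternative):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                continue
            mine, _ = fisher_exact((int(a), int(b), int(c), int(d)), alternative)
            ref = fisher_oracle(int(a), int(b), int(c), int(d), alternative)
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_matches_scipy_on_large_cells(self):
        # log-space evaluation must survive cells far beyond factorial range
        table = (120, 480, 1500, 60000)
        mine, _ = fisher_exact(table, "greater")
        ref = st.fisher_exact([[120, 480], [1500, 60000]], alternative="greater")[1]
        assert mine == pytest.approx(ref, rel=1e-9)
        assert 0.0 <= mine <= 1.0

    def test_haldane_odds_ratio_on_zero_cell(self):
        assert odds_ratio(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(25.0)
        assert odds_ratio(ContingencyTable2x2(4, 2, 1, 8)) == pytest.approx(16.0)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact((1, 1, 1, 1), "less")


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook step-up rule: q_i = min_{j>=i} (m p_(j) / j), mapped back."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_step_up_formula(self, pvals):
        result = bh_adjust(pvals)
        expected = bh_oracle(np.array(pvals))
        assert np.allclose(result, expected, atol=1e-12)
        assert ((result >= 0) & (result <= 1)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


SCREEN_ROWS = (
    [("G", "PG", "skin", "missense", True)] * 5
    + [("G", "PG", "skin", "missense", False)] * 1
    + [("H", "PH", "skin", "missense", True)] * 10
    + [("H", "PH", "skin", "missense", False)] * 60
    + [("K", "PK", "colon", "missense", False)] * 40
)


class TestBuildContingency:
    def test_fixture_counts(self):
        table = build_contingency("PG", make_mset(SCREEN_ROWS))
        assert table.as_tuple() == (5, 1, 10, 100)

    def test_scope_restricts_counts(self):
        table = build_contingency("PG", make_mset(SCREEN_ROWS), scope="skin")
        assert table.as_tuple() == (5, 1, 10, 60)

    def test_zero_pocket_gene(self):
        table = build_contingency("PK", make_mset(SCREEN_ROWS))
        assert table.a == 0 and table.b == 40

    def test_absent_gene_raises_with_scope(self):
        with pytest.raises(KeyError, match="colon"):
            build_contingency("PG", make_mset(SCREEN_ROWS), scope="colon")


class TestScreen:
    def test_single_gene_fdr_equals_p(self):
        rows = [("G", "PG", "skin", "missense", True)] * 3 + [
            ("G", "PG", "skin", "missense", False)
        ] * 2
        out = run_per_gene_screen(make_mset(rows))
        assert len(out) == 1
        assert out["fdr"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_only_pocket_missense_proteins_tested(self):
        out = run_per_gene_screen(make_mset(SCREEN_ROWS))
        assert set(out["accession"]) == {"PG", "PH"}

    def test_row_order_invariance(self):
        mset_a = make_mset(SCREEN_ROWS)
        shuffled = mset_a.records.sample(frac=1.0, random_state=5).reset_index(drop=True)
        mset_b = type(mset_a)(shuffled)
        a = run_per_gene_screen(mset_a)
        b = run_per_gene_screen(mset_b)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_scope_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = run_per_gene_screen(make_mset(SCREEN_ROWS), scope="brain")
        assert out.empty

    def test_p_values_match_direct_fisher(self):
        mset = make_mset(SCREEN_ROWS)
        out = run_per_gene_screen(mset).set_index("accession")
        for acc in ("PG", "PH"):
            table = build_contingency(acc, mset)
            assert out.loc[acc, "p"] == pytest.approx(fisher_exact(table)[0], rel=1e-12)


class TestTopCancerTypes:
    ROWS = (
        [("G", "P1", "skin", "missense", True)] * 5
        + [("G", "P1", "colon", "silent", True)] * 3
        + [("G", "P1", "lung", "missense", True)] * 1
        + [("G", "P1", "brain", "missense", False)] * 50
    )

    def test_ranked_by_pocket_occurrences(self):
        assert select_top_cancer_types(make_mset(self.ROWS), 2) == ["skin", "colon"]

    def test_tie_break_lexicographic(self):
        rows = [("G", "P1", "b", "missense", True)] * 5 + [("G", "P1", "a", "missense", True)] * 5
        assert select_top_cancer_types(make_mset(rows), 1) == ["a"]

    def test_k_beyond_types_returns_all(self):
        assert len(select_top_cancer_types(make_mset(self.ROWS), 10)) == 3


class TestGeneSetEnrichment:
    def test_perfect_overlap_example(self):
        table, p, _ = gene_set_enrichment({"A", "B"}, {"C", "D"}, GeneSet("s", frozenset({"A", "B"})))
        assert table.as_tuple() == (2, 0, 0, 2)
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_disjoint_set_gives_p_one(self):
        _, p, _ = gene_set_enrichment({"A"}, {"B"}, GeneSet("s", frozenset({"Z"})))
        assert p == pytest.approx(1.0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            gene_set_enrichment({"A"}, {"A", "B"}, GeneSet("s", frozenset({"A"})))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment(set(), {"B"}, GeneSet("s", frozenset({"A"})))
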