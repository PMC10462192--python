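"""Fisher exact test, odds ratios, and the enrichment operations built on them."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from misplice import (
    ContingencyTable2x2,
    concordance,
    fisher_exact_2x2,
    gene_set_enrichment,
    microexon_enrichment,
    odds_ratio_ci,
    overlap_test,
)
from misplice.calibration import fisher_p_rational

cells = st.integers(0, 25)


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(20, 10, 10, 20), (0, 10, 10, 0), (5, 0, 3, 7)])
    def test_matches_rational_enumeration(self, table):
        p = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert p == pytest.approx(fisher_p_rational(*table), abs=1e-12)

    @given(cells, cells, cells, cells)
    def test_agrees_with_scipy_cross_check(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]]).pvalue, abs=1e-9)

    @given(st.integers(1, 25), st.integers(1, 25), st.integers(1, 25), st.integers(1, 25))
    def test_row_swap_preserves_p(self, a, b, c, d):
        p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        p2 = fisher_exact_2x2(ContingencyTable2x2(c, d, a, b))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        or_, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_cross_product(self):
        or_, _ = odds_ratio_ci(ContingencyTable2x2(20, 10, 10, 20))
        assert or_ == pytest.approx(4.0)

    def test_haldane_anscombe_on_zero_cell(self):
        or_, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(5, 0, 3, 7))
        assert or_ == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))  # 23.571...
        assert np.isfinite(lo) and np.isfinite(hi) and lo <= or_ <= hi

    def test_correction_policies(self):
        t = ContingencyTable2x2(5, 0, 3, 7)
        assert np.isinf(odds_ratio_ci(t, correction="never")[0])
        always, _ = odds_ratio_ci(ContingencyTable2x2(2, 2, 2, 2), correction="always")
        assert always == pytest.approx(1.0)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    def test_inversion_identity(self, a, b, c, d):
        or1, _ = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
        or2, _ = odds_ratio_ci(ContingencyTable2x2(b, a, d, c))
        assert or1 * or2 == pytest.approx(1.0)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    def test_row_swap_inverts_or(self, a, b, c, d):
        or1, _ = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
        or2, _ = odds_ratio_ci(ContingencyTable2x2(c, d, a, b))
        assert or1 * or2 == pytest.approx(1.0)


class TestGeneSetEnrichment:
    def test_hand_tabulated_example(self):
        universe = [f"G{i}" for i in range(100)]
        gene_set = universe[:20]
        mis = universe[:6] + universe[50:54]  # 6 in set, 4 outside
        out = gene_set_enrichment(mis, universe, {"S": gene_set}.items())
        row = out.loc["S"]
        assert (row.a, row.b, row.c, row.d) == (6, 4, 14, 76)
        assert row.odds_ratio == pytest.approx((6 * 76) / (4 * 14))

    def test_set_equal_to_universe_is_degenerate_not_dropped(self):
        universe = [f"G{i}" for i in range(20)]
        out = gene_set_enrichment(universe[:5], universe, {"ALL": universe}.items())
        assert bool(out.loc["ALL", "degenerate"])
        assert np.isfinite(out.loc["ALL", "odds_ratio"])

    def test_validation(self):
        with pytest.raises(ValueError, match="universe"):
            gene_set_enrichment([], [], {"S": ["A"]}.items())
        with pytest.raises(ValueError, match="subset"):
            gene_set_enrichment(["X"], ["A", "B"], {"S": ["A"]}.items())

    def test_null_foreground_centers_or_near_one(self, rng):
        universe = [f"G{i}" for i in range(400)]
        medians = []
        for _ in range(30):
            fg = rng.choice(universe, size=40, replace=False)
            sets = {f"S{k}": rng.choice(universe, size=30, replace=False) for k in range(10)}
            out = gene_set_enrichment(set(fg), universe, sets.items())
            medians.append(out["odds_ratio"].median())
        assert 0.7 <= float(np.median(medians)) <= 1.4


class TestMicroexonEnrichment:
    def _results(self, n_bg=1000, n_bg_mie=40, n_fg=100, n_fg_mie=10):
        # foreground (mis-spliced) events are a subset of the background
        mie = [True] * n_fg_mie + [False] * (n_fg - n_fg_mie)
        mie += [True] * (n_bg_mie - n_fg_mie) + [False] * ((n_bg - n_fg) - (n_bg_mie - n_fg_mie))
        mis = [True] * n_fg + [False] * (n_bg - n_fg)
        return pd.DataFrame(
            {
                "event_type": "SE",
                "gene_symbol": "G",
                "is_microexon": mie,
                "is_mis_spliced": mis,
                "fdr": 0.01,
            },
            index=[f"E{i}" for i in range(n_bg)],
        )

    def test_hand_tabulated_example(self):
        r = microexon_enrichment(self._results())
        assert r.table.as_tuple() == (10, 90, 40, 960)
        assert r.odds_ratio == pytest.approx((10 * 960) / (90 * 40))

    def test_equal_proportions_give_or_one(self):
        r = microexon_enrichment(self._results(n_bg=1000, n_bg_mie=100, n_fg=100, n_fg_mie=10))
        assert r.odds_ratio == pytest.approx(1.0)

    def test_no_misspliced_se_is_degenerate(self):
        res = self._results()
        res["is_mis_spliced"] = False
        r = microexon_enrichment(res)
        assert r.degenerate


class TestOverlap:
    def test_hand_tabulated_example(self):
        universe = [f"G{i}" for i in range(1000)]
        A = universe[:100]
        B = universe[70:150]  # |A&B| = 30
        r = overlap_test(A, B, universe)
        assert r.table.as_tuple() == (30, 70, 50, 850)
        assert r.odds_ratio == pytest.approx((30 * 850) / (70 * 50))

    def test_disjoint_and_identical_sets(self):
        universe = [f"G{i}" for i in range(100)]
        disjoint = overlap_test(universe[:10], universe[10:20], universe)
        assert disjoint.table.a == 0 and disjoint.odds_ratio < 1
        same = overlap_test(universe[:10], universe[:10], universe)
        assert same.odds_ratio > 100

    def test_universe_must_cover_items(self):
        with pytest.raises(ValueError, match="subsets"):
            overlap_test(["X"], ["Y"], ["Y"])


class TestConcordance:
    def test_mixed_signs(self):
        r = concordance({"e1": -0.2, "e2": 0.2}, {"e1": -0.3, "e2": -0.1})
        assert r.n_shared == 2
        assert r.frac_concordant == pytest.approx(0.5)
        assert r.frac_concordant_negative == pytest.approx(1.0)

    def test_all_same_sign(self):
        r = concordance({"a": 0.3, "b": 0.1}, {"a": 0.2, "b": 0.4})
        assert r.frac_concordant == pytest.approx(1.0)
        assert r.frac_concordant_negative == pytest.approx(0.0)

    def test_zero_dpsi_excluded_from_denominator(self):
        r = concordance({"a": 0.0, "b": -0.2}, {"a": 0.5, "b": -0.4})
        assert r.n_classified == 1
        assert r.frac_concordant == pytest.approx(1.0)

    def test_empty_intersection(self):
        r = concordance({"a": 0.1}, {"b": 0.2})
        assert r.n_shared == 0 and np.isnan(r.frac_concordant)
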