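"""Se/Sp/OR/AUC estimators and the Wald interval on the odds ratio."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watertaste import ContingencyTable2x2, ZeroCellError, estimate, wald_ci
from watertaste._round import round_half_away

positive_tables = st.builds(
    ContingencyTable2x2,
    st.integers(1, 200),
    st.integers(1, 200),
    st.integers(1, 200),
    st.integers(1, 200),
)


class TestEstimate:
    @pytest.mark.parametrize(
        "cells,se,sp,or_,auc",
        [
            ((106, 33, 110, 29), 0.76, 0.21, 0.85, 0.49),  # the published study
            ((50, 50, 50, 50), 0.50, 0.50, 1.00, 0.50),  # perfect symmetry
            ((25, 21, 30, 13), 0.54, 0.30, 0.52, 0.42),  # a reconstructed subgroup
        ],
    )
    def test_point_estimates_round_to_printed_values(self, cells, se, sp, or_, auc):
        est = estimate(ContingencyTable2x2(*cells), correction="none")
        assert round_half_away(est.se) == se
        assert round_half_away(est.sp) == sp
        assert round_half_away(est.odds_ratio) == or_
        assert round_half_away(est.auc) == auc

    def test_log_or_standard_error_is_woolf_form(self, paper_table):
        est = estimate(paper_table, correction="none")
        assert est.log_or_se == pytest.approx(
            math.sqrt(1 / 106 + 1 / 33 + 1 / 110 + 1 / 29)
        )
        assert round_half_away(est.log_or_se, 4) == 0.2886

    def test_zero_cell_without_correction_is_explicit_error(self):
        with pytest.raises(ZeroCellError):
            estimate(ContingencyTable2x2(10, 0, 5, 5), correction="none")

    def test_haldane_adds_half_to_all_cells_only_on_zero(self):
        est = estimate(ContingencyTable2x2(10, 0, 5, 5), correction="haldane")
        assert est.correction_applied
        assert est.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))
        assert est.se == 1.0  # Se/Sp stay on raw counts
        untouched = estimate(ContingencyTable2x2(10, 1, 5, 5), correction="haldane")
        assert not untouched.correction_applied
        assert untouched.odds_ratio == pytest.approx(50 / 5)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            estimate(ContingencyTable2x2(0, 0, 5, 5))

    @settings(derandomize=True, max_examples=200)
    @given(positive_tables)
    def test_cross_product_equals_se_sp_odds_form(self, t):
        est = estimate(t, correction="none")
        se, sp = t.a / t.n1, t.d / t.n2
        assert est.odds_ratio == pytest.approx(
            se / (1 - se) * sp / (1 - sp), rel=1e-12
        )
        assert est.odds_ratio == pytest.approx((t.a * t.d) / (t.b * t.c), rel=1e-12)
        assert est.auc == (se + sp) / 2

    @settings(derandomize=True, max_examples=200)
    @given(positive_tables)
    def test_or_and_auc_agree_on_side_of_null(self, t):
        est = estimate(t, correction="none")
        if est.odds_ratio > 1:
            assert est.auc > 0.5
        elif est.odds_ratio < 1:
            assert est.auc < 0.5
        else:
            assert est.auc == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=200)
    @given(positive_tables)
    def test_swapping_arms_and_responses_preserves_or_and_auc(self, t):
        est = estimate(t, correction="none")
        swapped = estimate(
            ContingencyTable2x2(t.d, t.c, t.b, t.a), correction="none"
        )
        assert swapped.odds_ratio == pytest.approx(est.odds_ratio)
        assert swapped.auc == pytest.approx(est.auc)
        assert (swapped.se, swapped.sp) == (est.sp, est.se)

    @settings(derandomize=True, max_examples=100)
    @given(positive_tables.filter(lambda t: t.b >= 2))
    def test_moving_a_tap_guess_from_wrong_to_right_raises_everything(self, t):
        lo = estimate(t, correction="none")
        hi = estimate(
            ContingencyTable2x2(t.a + 1, t.b - 1, t.c, t.d), correction="none"
        )
        assert hi.se > lo.se
        assert hi.odds_ratio > lo.odds_ratio
        assert hi.auc > lo.auc


class TestWaldCI:
    def test_published_interval(self, paper_table):
        lo, hi = wald_ci(paper_table, level=0.95, correction="none")
        assert (round_half_away(lo), round_half_away(hi)) == (0.48, 1.49)

    def test_interval_contains_point_estimate_and_orders(self, paper_table):
        est = estimate(paper_table)
        lo, hi = wald_ci(paper_table)
        assert lo < est.odds_ratio < hi

    def test_level_to_zero_collapses_to_point_estimate(self, paper_table):
        est = estimate(paper_table)
        lo, hi = wald_ci(paper_table, level=1e-12)
        assert lo == pytest.approx(est.odds_ratio, rel=1e-6)
        assert hi == pytest.approx(est.odds_ratio, rel=1e-6)

    def test_balanced_table_interval_symmetric_about_one_on_log_scale(self):
        lo, hi = wald_ci(ContingencyTable2x2(50, 50, 50, 50), level=0.95)
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_invalid_level_rejected(self, paper_table):
        with pytest.raises(ValueError):
            wald_ci(paper_table, level=1.0)
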