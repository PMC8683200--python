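import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snvnet.univariate import (
    AssociationResult,
    ContingencyTable2x2,
    build_contingency,
    chi_square_test,
    fisher_exact_test,
    odds_ratio_ci,
    table1_report,
    two_group_continuous,
)

cells = st.integers(min_value=1, max_value=60)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exhaustive two-sided Fisher over all admissible tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = stats.hypergeom.pmf(x, n, r1, c1)
        if pr <= obs * (1 + 1e-9):
            total += pr
    return min(1.0, total)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, or_expected, ci_expected",
        [
            # published marijuana row: exact Woolf reproduction
            ((61, 78, 9, 43), 3.7365, (1.69, 8.26)),
            # published cocaine row: point OR to 3 s.f. (CI upper not Woolf-consistent)
            ((35, 104, 1, 51), 17.163, None),
            ((72, 68, 24, 28), 1.2353, (0.65, 2.34)),
        ],
    )
    def test_published_count_examples(self, table, or_expected, ci_expected):
        res = odds_ratio_ci(ContingencyTable2x2(*table))
        assert res.or_point == pytest.approx(or_expected, abs=5e-4)
        if ci_expected:
            assert res.ci_low == pytest.approx(ci_expected[0], abs=5e-3)
            assert res.ci_high == pytest.approx(ci_expected[1], abs=5e-3)

    @given(k=st.integers(min_value=1, max_value=500))
    def test_symmetric_table_gives_unity(self, k):
        res = odds_ratio_ci(ContingencyTable2x2(k, k, k, k))
        assert res.or_point == 1.0

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=50, deadline=None)
    def test_or_equivariance(self, a, b, c, d):
        r1 = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
        r2 = odds_ratio_ci(ContingencyTable2x2(b, a, d, c))
        assert r1.or_point * r2.or_point == pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=50, deadline=None)
    def test_outcome_swap_inverts_or_keeps_pvalues(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        s = t.swap_outcome()
        assert odds_ratio_ci(s).or_point == pytest.approx(1 / odds_ratio_ci(t).or_point)
        assert chi_square_test(s) == pytest.approx(chi_square_test(t))
        assert fisher_exact_test(s) == pytest.approx(fisher_exact_test(t))

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=40, deadline=None)
    def test_woolf_ci_contains_point_and_narrows_with_counts(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        res = odds_ratio_ci(t)
        assert res.ci_low <= res.or_point <= res.ci_high
        big = odds_ratio_ci(ContingencyTable2x2(3 * a, 3 * b, 3 * c, 3 * d))
        assert (big.ci_high / big.ci_low) < (res.ci_high / res.ci_low)

    def test_zero_cell_flags(self):
        both = odds_ratio_ci(ContingencyTable2x2(2, 0, 0, 3))
        assert math.isnan(both.or_point) and both.flag == "undefined_or"
        one = odds_ratio_ci(ContingencyTable2x2(2, 0, 1, 3))
        assert math.isinf(one.or_point) and one.flag == "infinite_or"

    def test_continuity_correction_behind_flag(self):
        res = odds_ratio_ci(ContingencyTable2x2(2, 0, 1, 3), continuity=True)
        assert math.isfinite(res.or_point)
        assert res.or_point == pytest.approx((2.5 * 3.5) / (0.5 * 1.5))


class TestChiSquare:
    def test_proportional_rows_give_p_one(self):
        assert chi_square_test(ContingencyTable2x2(20, 10, 40, 20)) == pytest.approx(1.0)

    def test_published_marijuana_row_significant(self):
        assert chi_square_test(ContingencyTable2x2(61, 78, 9, 43)) < 0.05

    def test_closed_form_identity_on_random_tables(self, rng):
        # statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df
        for _ in range(10):
            a, b, c, d = rng.integers(1, 50, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            n = t.n
            stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi_square_test(t) == pytest.approx(stats.chi2.sf(stat, 1))

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square_test(ContingencyTable2x2(0, 5, 0, 5))


class TestFisherExact:
    def test_unit_margins(self):
        assert fisher_exact_test(ContingencyTable2x2(1, 0, 0, 1)) == 1.0

    def test_zero_margin_gives_one(self):
        assert fisher_exact_test(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_exact_test(t) == pytest.approx(
                fisher_enumeration(a, b, c, d), abs=1e-9
            )


class TestContinuous:
    def test_identical_groups_t(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["smoker"] * 3 + ["ex_smoker"] * 3
        p, s1, s0, test = two_group_continuous(vals, groups, method="t_test")
        assert p == pytest.approx(1.0)
        assert s1 == s0

    def test_identical_groups_mann_whitney(self, rng):
        x = rng.normal(size=15)
        vals = np.concatenate([x, x])
        groups = ["smoker"] * 15 + ["ex_smoker"] * 15
        p, *_ = two_group_continuous(vals, groups, method="mann_whitney")
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_mann_whitney_matches_pairwise_count_oracle(self, rng):
        # U = #(x_i > y_j) + 0.5 #(ties); p from tie-corrected normal approximation
        x = np.round(rng.normal(size=14), 1)
        y = np.round(rng.normal(size=12), 1)
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        n1, n2 = len(x), len(y)
        allv = np.concatenate([x, y])
        _, counts = np.unique(allv, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1))
        sd = math.sqrt(n1 * n2 / 12 * (n1 + n2 + 1 - tie_term))
        z = (u - n1 * n2 / 2) / sd
        p_expected = 2 * stats.norm.sf(abs(z))
        vals = np.concatenate([x, y])
        groups = ["smoker"] * n1 + ["ex_smoker"] * n2
        p, *_ = two_group_continuous(vals, groups, method="mann_whitney")
        assert p == pytest.approx(p_expected, rel=1e-6)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            two_group_continuous([1.0, 2.0, 3.0], ["smoker", "smoker", "ex_smoker"])


class TestBuildContingency:
    def test_audit_boundary(self, mirror):
        _, pheno = mirror
        df = pheno.df
        # scores of exactly 8 are hazardous; 7 is not
        hz = pheno.hazardous_alcohol()
        assert bool((df["audit_score"] == 8).any())
        assert (hz[df["audit_score"] == 8] == True).all()  # noqa: E712
        assert (hz[df["audit_score"] == 7] == False).all()  # noqa: E712

    def test_mirror_marijuana_counts(self, mirror):
        _, pheno = mirror
        t = build_contingency(pheno, "marijuana_30d")
        assert (t.a, t.b, t.c, t.d) == (61, 78, 9, 43)

    def test_all_missing_errors(self, mirror):
        _, pheno = mirror
        df = pheno.df.copy()
        df["marijuana_30d"] = None
        df["marijuana_30d"] = df["marijuana_30d"].astype("boolean")
        from snvnet.io import PhenotypeTable

        with pytest.raises(ValueError, match="empty contingency"):
            build_contingency(PhenotypeTable(df), "marijuana_30d")

    def test_non_boolean_without_rule_errors(self, mirror):
        _, pheno = mirror
        with pytest.raises(ValueError):
            build_contingency(pheno, "age")


class TestTable1Report:
    def test_mirror_report_rows(self, mirror):
        _, pheno = mirror
        rows = {r.variable: r for r in table1_report(pheno)}
        assert len(rows) == 10
        assert rows["marijuana_30d"].or_point == pytest.approx(3.73, abs=0.01)
        assert rows["male_gender"].or_point == pytest.approx(1.24, abs=0.01)
        assert rows["cocaine_30d"].or_point == pytest.approx(17.2, abs=0.05)
        assert rows["hazardous_alcohol"].n_smokers == 131
        assert rows["hazardous_alcohol"].n_exsmokers == 48
        # race row restricted to declared White/Black, zero cell -> Fisher
        assert rows["race_white"].test_used == "fisher_exact"
        assert rows["race_white"].n_smokers == 118
        assert rows["race_white"].n_exsmokers == 38
        for r in rows.values():
            assert 0.0 <= r.p_value <= 1.0

    def test_empty_table_errors(self, mirror):
        import pandas as pd

        from snvnet.io import PhenotypeTable

        _, pheno = mirror
        empty = PhenotypeTable(pheno.df.iloc[:0])
        with pytest.raises(ValueError):
            table1_report(empty)
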