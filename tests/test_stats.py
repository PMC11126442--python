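"""Unit and property tests for the nonparametric statistics layer.

The rank tests are checked against independently coded brute-force
enumeration oracles (all sign assignments for the signed-rank test, all
group assignments for the U test) and against scipy on tie-free inputs.
"""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from periomri.phantom import ClinicalSimConfig, generate_site_table
from periomri.stats import (
    build_table2,
    build_table3,
    categorize,
    chi_square,
    mann_whitney,
    median_iqr,
    wilcoxon_paired,
)

# ---------------------------------------------------------------------------
# independent enumeration oracles


def brute_wilcoxon_p(d):
    """Two-sided exact p by explicit enumeration of all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    obs = abs(ranks[d > 0].sum() - mu)
    hits = total = 0
    for signs in product([0, 1], repeat=len(d)):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if abs(t - mu) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def brute_mannwhitney_p(a, b):
    """Two-sided exact p by enumeration of all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na = len(a)
    ranks = sps.rankdata(np.concatenate([a, b]))
    mu = na * len(b) / 2.0
    obs = abs(ranks[:na].sum() - na * (na + 1) / 2.0 - mu)
    hits = total = 0
    for idx in combinations(range(len(ranks)), na):
        u = sum(ranks[i] for i in idx) - na * (na + 1) / 2.0
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------


class TestCategorize:
    @pytest.mark.parametrize(
        "ppd,bop,expected",
        [
            (3, False, "PPD<=3_noBOP"),
            (3, True, "PPD<=3_BOP"),
            (1, False, "PPD<=3_noBOP"),
            (4, True, "PPD4-5"),  # BOP ignored above 3 mm
            (5, False, "PPD4-5"),
            (6, False, "PPD>=6"),
            (9, True, "PPD>=6"),
        ],
    )
    def test_stratum_assignment(self, ppd, bop, expected):
        assert categorize(ppd, bop) == expected

    def test_negative_ppd_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1, False)


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([3]) == (3, 3, 3)

    def test_linear_interpolation_convention(self):
        assert median_iqr([1, 2, 3, 4]) == (2.5, 1.75, 3.25)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert median_iqr(shuffled) == median_iqr(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.degenerate
        assert res.p == 1.0

    def test_exact_matches_enumeration_n8(self):
        x0 = [1, 2, 3, 4, 5, 6, 7, 8]
        x1 = [2.5, 1, 5, 3, 9, 4, 10.5, 6]
        res = wilcoxon_paired(x0, x1)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_wilcoxon_p(np.array(x1) - np.array(x0)))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(size=10)
            res = wilcoxon_paired(np.zeros(10), d)
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1, size=60)
        res = wilcoxon_paired(np.zeros(60), d)
        assert res.method == "normal-tie-corrected"
        ref = sps.wilcoxon(d, correction=False, method="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=5, max_size=10).filter(
            lambda d: any(x != 0 for x in d)
        )
    )
    def test_exact_agrees_with_enumeration_under_ties(self, d):
        res = wilcoxon_paired(np.zeros(len(d)), np.array(d, float))
        assert res.p == pytest.approx(brute_wilcoxon_p(d))


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=7)
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.statistic + r2.statistic == pytest.approx(6 * 7)
        assert r1.p == pytest.approx(r2.p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=5),
        st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    def test_exact_agrees_with_enumeration(self, a, b):
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_mannwhitney_p(a, b))

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 8, 40).astype(float)
        b = rng.integers(1, 9, 35).astype(float)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestChiSquare:
    def test_published_2x3_reproduces(self):
        chi2, df, p = chi_square([[591, 379, 170], [631, 347, 132]])
        assert df == 2
        assert round(p, 3) == 0.029

    def test_identical_rows_null(self):
        chi2, df, p = chi_square([[50, 30, 20], [50, 30, 20]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            tab = rng.integers(1, 60, size=(2, 2))
            cy, _, _ = chi_square(tab, yates="always")
            cu, _, _ = chi_square(tab, yates="never")
            assert cy <= cu + 1e-12

    def test_pearson_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tab = rng.integers(1, 50, size=(3, 4)).astype(float)
            chi2, df, p = chi_square(tab)
            exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            direct = ((tab - exp) ** 2 / exp).sum()
            assert chi2 == pytest.approx(direct)
            assert p == pytest.approx(sps.chi2.sf(direct, df))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [3, 4]])


@pytest.fixture(scope="module")
def records():
    return generate_site_table(ClinicalSimConfig(n_sites=600, seed=21))


class TestTableBuilders:
    def test_table2_percentages_and_denominators(self, records):
        t2 = build_table2(records)
        n = 600
        for row in t2.rows:
            if row["block"] == "category_counts":
                assert row["denom_t0"] == n and row["denom_t1"] == n
                assert row["pct_t0"] == int(np.floor(100 * row["count_t0"] / n + 0.5))
        counts = [r for r in t2.rows if r["block"] == "category_counts"]
        assert sum(r["count_t0"] for r in counts if r["stratum"] != "with_BOP") == n

    def test_table3_no_edema_flagged_empty(self):
        df = generate_site_table(ClinicalSimConfig(n_sites=200, seed=22))
        df = df.copy()
        df["ed_mm"] = 0.0
        df["edema_present"] = 0
        t3 = build_table3(df)
        aff = t3.row("all_sites")
        assert aff["count_t0"] == 0 and aff["count_t1"] == 0
        assert all(r["empty"] for r in t3.rows if r["block"] == "ed")

    def test_doubling_records_preserves_percentages(self, records):
        t_one = build_table2(records)
        doubled = records.copy()
        doubled["patient_id"] = doubled["patient_id"] + 10_000
        t_two = build_table2(pd.concat([records, doubled], ignore_index=True))
        for r1, r2 in zip(t_one.rows, t_two.rows):
            if r1["block"] == "category_counts":
                assert r2["pct_t0"] == r1["pct_t0"]
                assert r2["pct_t1"] == r1["pct_t1"]
                assert r2["count_t0"] == 2 * r1["count_t0"]

    def test_orphan_sites_rejected(self, records):
        broken = records.drop(index=records.index[0])  # remove one t0 row
        with pytest.raises(ValueError, match="pair"):
            build_table2(broken)

    def test_category_partition(self, records):
        t0 = records[records.timepoint == "t0"]
        cats = [categorize(p, bool(b)) for p, b in zip(t0.ppd_mm, t0.bop)]
        assert len(cats) == len(t0)  # total function: every record categorized
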