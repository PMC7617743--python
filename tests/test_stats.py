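import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from circumnaut.errors import InvalidArgumentError
from circumnaut.stats import (
    describe,
    holm_adjust,
    kruskal_wallis,
    kruskal_wallis_exact_p,
    posthoc_pairwise,
    run_group_analysis,
    shapiro_wilk,
)

WORKED_GROUPS = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]


class TestShapiroWilk:
    def test_exact_normal_scores_give_w_near_one(self):
        # sample constructed from exact normal quantiles
        n = 500
        q = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        w, _ = shapiro_wilk(q)
        assert w > 1 - 1e-3

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(0)
        _, p = shapiro_wilk(rng.exponential(size=200))
        assert p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestKruskalWallis:
    def test_worked_rank_example(self):
        res = kruskal_wallis(WORKED_GROUPS)
        assert np.isclose(res.H, 7.2)
        assert res.df == 2
        assert not res.tie_corrected

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        groups = [np.round(rng.normal(loc, 1, 15), 1) for loc in (0, 0.5, 1)]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert np.isclose(ours.H, ref.statistic)
        assert np.isclose(ours.p, ref.pvalue)

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3]] * 3)
        assert res.H == 0.0 and res.p == 1.0

    def test_all_tied_input(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.H == 0.0 and res.p == 1.0 and res.tie_corrected

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(-50, 50), min_size=3, max_size=8),
            min_size=2,
            max_size=4,
        )
    )
    def test_rank_invariance_under_monotone_transform(self, groups):
        # integer values keep ties exact under the strictly increasing map
        base = kruskal_wallis(groups)
        transformed = [[np.exp(x / 50.0) for x in g] for g in groups]
        res = kruskal_wallis(transformed)
        assert np.isclose(res.H, base.H, atol=1e-9)
        assert np.isclose(res.p, base.p, atol=1e-9)

    def test_h_upper_bound_untied(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.permutation(15).astype(float)
            groups = [vals[:5], vals[5:10], vals[10:]]
            N = 15
            assert kruskal_wallis(groups).H <= N - 1 + 1e-9

    def test_exact_permutation_oracle_agreement(self):
        # the chi-square approximation is known to be loose for three groups
        # of three; its error against the exact permutation distribution
        # stays within 0.10 at this size (the documented envelope), and H
        # must rank the cases exactly as the exact p does
        cases = [
            WORKED_GROUPS,
            [[1, 5, 9], [2, 6, 7], [3, 4, 8]],
            [[1, 2, 8], [3, 5, 9], [4, 6, 7]],
        ]
        rows = []
        for groups in cases:
            res = kruskal_wallis(groups)
            p_exact = kruskal_wallis_exact_p(groups)
            assert abs(res.p - p_exact) < 0.10  # documented envelope at N = 9
            rows.append((res.H, p_exact))
        hs = [r[0] for r in rows]
        ps = [r[1] for r in rows]
        # larger H => smaller (or equal) exact p
        order = np.argsort(hs)
        assert all(ps[order[i]] >= ps[order[i + 1]] - 1e-12 for i in range(len(ps) - 1))

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(2024)
        rejections = sum(
            kruskal_wallis([rng.normal(size=20) for _ in range(3)]).p < 0.05
            for _ in range(2000)
        )
        assert abs(rejections / 2000 - 0.05) <= 0.01


class TestPosthoc:
    def test_identical_groups_all_adjusted_p_one(self):
        table = posthoc_pairwise([[1, 2, 3]] * 3, "dunn_holm")
        assert np.allclose(table["p_adj"], 1.0)

    def test_extreme_pair_has_smallest_adjusted_p(self):
        table = posthoc_pairwise(WORKED_GROUPS, "dunn_holm", labels=["a", "b", "c"])
        extreme = table[(table.group1 == "a") & (table.group2 == "c")]
        assert extreme["p_adj"].iloc[0] == table["p_adj"].min()

    def test_tukey_on_ranks_available(self):
        table = posthoc_pairwise(WORKED_GROUPS, "tukey_on_ranks")
        assert len(table) == 3
        assert (table["p_adj"] <= 1).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            posthoc_pairwise(WORKED_GROUPS, "bonferroni")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_holm_adjustment_monotone(self, p_raw):
        adj = holm_adjust(np.array(p_raw))
        assert np.all(adj >= np.array(p_raw) - 1e-15)
        assert np.all(adj <= 1.0)


class TestDescribe:
    def test_linear_interpolation_convention(self):
        d = describe([1, 2, 3, 4, 5])
        assert d.median == 3 and d.p25 == 2 and d.p75 == 4
        assert d.iqr == 2 and d.range == (1, 5)

    def test_single_value(self):
        d = describe([7])
        assert d.p25 == d.p50 == d.p75 == 7 and d.iqr == 0

    def test_median_robust_to_outlier(self):
        d = describe([1, 1, 1, 100])
        assert d.median == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            describe([])


class TestRunGroupAnalysis:
    @staticmethod
    def _table(rng, n=12, shift=(0.0, 1.0, 2.0)):
        rows = []
        for g, s in zip(("a", "b", "c"), shift):
            for _ in range(n):
                rows.append(
                    {"genotype": g, "m1": rng.normal(s), "m2": rng.normal()}
                )
        return pd.DataFrame(rows)

    def test_report_structure_and_detection(self):
        rng = np.random.default_rng(3)
        report = run_group_analysis(
            self._table(rng), measures=("m1", "m2"), unit="per_plant"
        )
        assert set(report.measures) == {"m1", "m2"}
        assert report.measures["m1"]["kruskal_wallis"].p < 0.05
        assert len(report.measures["m1"]["posthoc"]) == 3
        txt = report.render_text()
        assert "H(2)" in txt and "per_plant" in txt

    def test_missing_column_named(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InvalidArgumentError, match="nope"):
            run_group_analysis(self._table(rng), measures=("nope",))

    def test_two_groups_give_df_one(self):
        rng = np.random.default_rng(5)
        table = self._table(rng)
        table = table[table.genotype != "c"]
        report = run_group_analysis(table, measures=("m1",), unit="per_plant")
        assert report.measures["m1"]["kruskal_wallis"].df == 1

    def test_label_shuffle_calibration(self):
        # with shuffled labels the rejection fraction stays near alpha
        rng = np.random.default_rng(6)
        table = self._table(rng, n=20)
        hits = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            shuffled = table.copy()
            shuffled["genotype"] = rng.permutation(shuffled["genotype"].to_numpy())
            rep = run_group_analysis(shuffled, measures=("m1",), unit="per_plant")
            hits += rep.measures["m1"]["kruskal_wallis"].p < 0.05
        assert abs(hits / n_shuffles - 0.05) <= 0.05
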