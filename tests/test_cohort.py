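"""Tests of the rank-based case/control statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import mannwhitneyu

from retfdc.cohort import (
    _mwu_cdf,
    cohort_report,
    kruskal_wallis,
    mann_whitney_ci,
)
from retfdc.errors import ParameterError

from ._oracles import kw_h_direct, kw_permutation_p


class TestKruskalWallis:
    def test_textbook_example(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.H == pytest.approx(3.857, abs=5e-4)
        assert res.groups["a"].avg_rank == 2.0
        assert res.groups["b"].avg_rank == 5.0

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.groups["a"].z == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.random(8), rng.random(9)
        r1 = kruskal_wallis({"case": a, "control": b})
        r2 = kruskal_wallis({"case": b, "control": a})
        assert r1.H == pytest.approx(r2.H, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.groups["case"].z == pytest.approx(-r2.groups["case"].z, abs=1e-12)

    def test_two_group_z_values_sum_to_zero(self, rng):
        res = kruskal_wallis({"a": rng.random(7), "b": rng.random(11)})
        assert res.groups["a"].z + res.groups["b"].z == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            a = np.round(rng.random(9), 1)
            b = np.round(rng.random(12), 1)
            ours = kruskal_wallis({"a": a, "b": b})
            ref = scipy_kruskal(a, b)
            assert ours.H == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_h_on_all_small_splits(self):
        """H matches an independent transcription on every 2-group split of
        small pooled sets (n <= 5 per group), including tied values."""
        pools = [
            [1, 2, 3, 4, 5, 6],
            [1.5, 2.5, 2.5, 3.0, 7.0, 9.0],
            [1, 1, 2, 2, 3, 3, 4, 4],
        ]
        for pool in pools:
            n = len(pool)
            for na in range(2, min(5, n - 2) + 1):
                for idx in itertools.combinations(range(n), na):
                    sel = set(idx)
                    a = [pool[i] for i in idx]
                    b = [pool[i] for i in range(n) if i not in sel]
                    ours = kruskal_wallis({"a": a, "b": b}).H
                    assert ours == pytest.approx(kw_h_direct([a, b]), abs=1e-12)

    def test_asymptotic_p_close_to_permutation(self):
        a, b = [1, 2, 5, 8], [3, 9, 11, 12]
        p_perm = kw_permutation_p(a, b)
        p_chi2 = kruskal_wallis({"a": a, "b": b}).p
        assert abs(p_perm - p_chi2) < 0.08  # documented exact-vs-asymptotic gap

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.random(8), rng.random(10)
        r1 = kruskal_wallis({"a": a, "b": b})
        r2 = kruskal_wallis({"a": np.exp(5 * a), "b": np.exp(5 * b)})
        assert r1.H == pytest.approx(r2.H, abs=1e-10)

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="identical"):
            res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert (res.H, res.p) == (0.0, 1.0)

    def test_group_size_validation(self):
        with pytest.raises(ParameterError):
            kruskal_wallis({"a": [1.0], "b": [2.0, 3.0]})


class TestMannWhitneyCI:
    def test_exhaustive_tiny_example(self):
        res = mann_whitney_ci([1.0, 2.0], [3.0, 4.0], confidence=0.8)
        # pairwise differences {-3, -2, -2, -1}
        assert res.point_estimate == -2.0
        assert res.ci_low == -3.0 and res.ci_high == -1.0

    def test_pure_shift_recovers_delta(self, rng):
        x = rng.random(15)
        delta = 0.37
        res = mann_whitney_ci(x, x - delta)
        assert res.point_estimate == pytest.approx(delta, abs=1e-12)

    def test_antisymmetry_under_sample_swap(self, rng):
        a, b = rng.random(10), rng.random(12) + 0.2
        r1 = mann_whitney_ci(a, b)
        r2 = mann_whitney_ci(b, a)
        assert r1.point_estimate == pytest.approx(-r2.point_estimate, abs=1e-12)
        assert r1.ci_low == pytest.approx(-r2.ci_high, abs=1e-12)
        assert r1.ci_high == pytest.approx(-r2.ci_low, abs=1e-12)

    def test_interval_brackets_point(self, rng):
        a, b = rng.random(9), rng.random(11)
        res = mann_whitney_ci(a, b)
        assert res.ci_low <= res.point_estimate <= res.ci_high

    def test_all_tied_zero_width(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney_ci([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.ci_low == res.ci_high == 0.0

    def test_exact_u_cdf_matches_scipy(self, rng):
        """The DP null distribution agrees with scipy's exact one-sided p."""
        for m, n in [(4, 5), (6, 6), (8, 5)]:
            cdf = _mwu_cdf(m, n)
            a = rng.random(m)
            b = rng.random(n)
            u = sum((x > y) for x in a for y in b)
            p_scipy = mannwhitneyu(a, b, alternative="less", method="exact").pvalue
            assert cdf[u] == pytest.approx(p_scipy, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 28)
        exact = mann_whitney_ci(a, b)
        approx = mann_whitney_ci(a, b, exact_max=1)
        assert exact.ci_low == pytest.approx(approx.ci_low, abs=0.25)
        assert exact.ci_high == pytest.approx(approx.ci_high, abs=0.25)


class TestCohortReport:
    @staticmethod
    def _table(rng, methods=("fdc",), zones=("ABC",), n=8, shift=0.0):
        rows = []
        for method in methods:
            for zone in zones:
                for i in range(n):
                    rows.append(("c%d" % i, "case", method, zone, rng.normal(1.98 - shift, 0.01)))
                for i in range(n):
                    rows.append(("k%d" % i, "control", method, zone, rng.normal(1.98, 0.01)))
        return pd.DataFrame(rows, columns=["subject_id", "group", "method", "zone", "fd_value"])

    def test_single_cell_single_row(self, rng):
        rep = cohort_report(self._table(rng))
        assert len(rep) == 1
        assert set(["median_case", "median_control", "H", "p", "ci_low", "ci_high"]).issubset(rep.columns)

    def test_zone_ordering_deterministic(self, rng):
        t = self._table(rng, zones=("BC", "A", "ABC", "C", "AB", "B", "AC"))
        rep = cohort_report(t)
        assert list(rep["zone"]) == ["A", "B", "C", "AB", "AC", "BC", "ABC"]

    def test_incomplete_cell_skipped(self, rng):
        t = self._table(rng)
        t = t[~((t["group"] == "case") & (t["subject_id"] != "c0"))]
        rep = cohort_report(t)
        assert len(rep) == 0

    def test_duplicate_rows_rejected(self, rng):
        t = self._table(rng)
        with pytest.raises(ParameterError):
            cohort_report(pd.concat([t, t.iloc[[0]]]))

    def test_detects_true_shift(self, rng):
        rep = cohort_report(self._table(rng, n=20, shift=0.02))
        row = rep.iloc[0]
        assert row["median_case"] < row["median_control"]
        assert row["p"] < 0.05
        assert row["ci_high"] < 0.0  # CI for case - control excludes zero

    def test_holm_adjustment_monotone(self, rng):
        t = self._table(rng, zones=("A", "B", "C"), n=10, shift=0.01)
        rep = cohort_report(t, holm=True)
        assert np.all(rep["p_holm"] >= rep["p"] - 1e-15)
        assert np.all(rep["p_holm"] <= 1.0)
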