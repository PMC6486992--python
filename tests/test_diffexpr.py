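import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oracles import bh_step_up_by_hand, ranksum_two_sided_enumeration

from cucirc.diffexpr import (
    bh_adjust,
    call_de,
    de_report,
    de_test,
    estimate_dispersion,
    global_shift,
)


def _frames(counts_t, counts_c, lib=1_000_000, read_len=100):
    """Two-sample-per-group raw/srpbm frames with equal library sizes."""
    raw = pd.DataFrame(
        {
            "t1": counts_t, "t2": counts_t,
            "c1": counts_c, "c2": counts_c,
        }
    )
    libs = {s: lib for s in raw.columns}
    srpbm = raw / (lib / 1e9) / read_len
    return raw, srpbm, libs


class TestDeTest:
    def test_identical_pooled_proportions_are_null(self):
        raw, srpbm, libs = _frames([10], [10])
        res = de_test(raw, srpbm, libs, ["t1", "t2"], ["c1", "c2"], dispersion=0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_strong_count_imbalance_is_significant(self):
        raw, srpbm, libs = _frames([10], [0])
        res = de_test(raw, srpbm, libs, ["t1", "t2"], ["c1", "c2"], dispersion=0.0)
        # pooled 20 vs 0 at equal library sizes: p = 2 * 0.5^20
        assert res["p_value"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-6)
        assert res["p_value"].iloc[0] < 0.01
        assert res["log2fc"].iloc[0] > 5

    @pytest.mark.parametrize("dispersion", [0.0, 0.2])
    def test_swapping_groups_negates_lfc_and_keeps_p(self, dispersion):
        raw, srpbm, libs = _frames([12, 3, 7], [4, 9, 7])
        a = de_test(raw, srpbm, libs, ["t1", "t2"], ["c1", "c2"], dispersion=dispersion)
        b = de_test(raw, srpbm, libs, ["c1", "c2"], ["t1", "t2"], dispersion=dispersion)
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_value"], b["p_value"], rtol=1e-9)

    def test_zero_library_size_is_an_error(self):
        raw, srpbm, libs = _frames([1], [1])
        libs["t1"] = 0
        libs["t2"] = 0
        with pytest.raises(ValueError, match="library"):
            de_test(raw, srpbm, libs, ["t1", "t2"], ["c1", "c2"])

    def test_exact_p_values_super_uniform_under_own_null(self):
        # binomial sampling model (no biological overdispersion)
        rng = np.random.default_rng(2024)
        lib = 1_000_000
        mu = rng.lognormal(np.log(20), 0.5, size=1000)
        raw = pd.DataFrame(
            {s: rng.poisson(mu) for s in ("t1", "t2", "c1", "c2")}
        )
        libs = {s: lib for s in raw.columns}
        srpbm = raw / (lib / 1e9) / 100
        res = de_test(raw, srpbm, libs, ["t1", "t2"], ["c1", "c2"], dispersion=0.0)
        p = np.sort(res["p_value"].to_numpy())
        ecdf = np.arange(1, len(p) + 1) / len(p)
        # super-uniformity: P(p <= x) <= x, small slack for the ECDF
        assert np.all(ecdf - p <= 0.03)

    def test_dispersion_estimator_recovers_truth(self, de_benchmark_sim):
        from cucirc.quantify import build_matrix

        mat = build_matrix(de_benchmark_sim.tables, de_benchmark_sim.stats)
        libs = {s.sample_id: s.mapped_reads for s in de_benchmark_sim.stats}
        treated = [s for s in mat.sample_ids if s.startswith("Na")]
        ctrl = [s for s in mat.sample_ids if s.startswith("CK")]
        theta = estimate_dispersion(mat.raw, libs, [treated, ctrl])
        assert 0.1 <= theta <= 0.3  # true value 0.2

    def test_dispersion_is_zero_without_replication(self):
        raw, srpbm, libs = _frames([5, 8], [3, 2])
        assert estimate_dispersion(raw, libs, [["t1"], ["c1"]]) == 0.0


class TestBhAdjust:
    def test_hand_step_up_example(self):
        got = bh_adjust([0.01, 0.03, 0.04, 0.05])
        assert np.allclose(got, [0.04, 0.05, 0.05, 0.05])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.73])[0] == pytest.approx(0.73)

    def test_all_equal_p_stay_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_literal_step_up_and_never_decreases(self, pvals):
        got = bh_adjust(pvals)
        assert np.allclose(got, bh_step_up_by_hand(pvals))
        assert np.all(got >= np.asarray(pvals) - 1e-12)
        assert np.all(got <= 1.0)


class TestCallDe:
    def test_cutoffs_applied_strictly_as_printed(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.5, 1.0, -1.5, 0.2],
                "p_value": [0.001, 0.001, 0.001, 0.9],
            },
            index=["a", "b", "c", "d"],
        )
        out = call_de(res)
        # |log2FC| > 1 is strict: exactly 1.0 is not called
        assert list(out["call"]) == ["up", "ns", "down", "ns"]

    def test_fdr_boundary_is_non_strict(self):
        res = pd.DataFrame({"log2fc": [2.0], "p_value": [0.05]}, index=["a"])
        assert call_de(res)["call"].iloc[0] == "up"


class TestGlobalShift:
    def test_fully_separated_triples(self):
        u, p = global_shift([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.10)

    def test_identical_groups_are_null(self):
        _, p = global_shift([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_matches_enumeration_oracle_at_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            x = list(np.round(rng.normal(0, 1, 4), 6))
            y = list(np.round(rng.normal(0.5, 1, 5), 6))
            _, p = global_shift(x, y)
            assert p == pytest.approx(ranksum_two_sided_enumeration(x, y), abs=1e-9)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.8, 1, 10)
            _, p_exact = global_shift(x, y)  # n = 20: exact branch
            res = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert abs(p_exact - res.pvalue) < 0.01

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            global_shift([], [1.0])


class TestDeReport:
    def test_published_per_tissue_totals(self):
        def table(up, down, n):
            calls = ["up"] * up + ["down"] * down + ["ns"] * (n - up - down)
            return pd.DataFrame({"call": calls}, index=[f"c{i}" for i in range(n)])

        report = de_report({"root": table(991, 943, 2420), "leaf": table(19, 25, 827)})
        root = report[report["tissue"] == "root"].iloc[0]
        leaf = report[report["tissue"] == "leaf"].iloc[0]
        assert (root["up"], root["down"], root["total"]) == (991, 943, 1934)
        assert (leaf["up"], leaf["down"], leaf["total"]) == (19, 25, 44)

    def test_union_counts_shared_circs_once(self):
        a = pd.DataFrame({"call": ["up", "ns"]}, index=["c1", "c2"])
        b = pd.DataFrame({"call": ["down", "up"]}, index=["c1", "c3"])
        report = de_report({"t1": a, "t2": b})
        assert report[report["tissue"] == "union"]["total"].iloc[0] == 2

    def test_empty_results_report_zeros(self):
        empty = pd.DataFrame({"call": []})
        report = de_report({"t": empty})
        row = report[report["tissue"] == "t"].iloc[0]
        assert (row["up"], row["down"], row["total"]) == (0, 0, 0)
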