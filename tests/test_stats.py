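"""Paired tests with normality gating, BH FDR, and the top-10 summary."""

import numpy as np
import pandas as pd
import pytest

import safconn as sc

from conftest import bh_stepup_oracle


class TestPairedCompare:
    def test_identical_conditions_degenerate(self):
        x = np.full(10, 0.5)
        c = sc.paired_compare(x, x)
        assert c.test_used == "degenerate"
        assert c.p_two_sided == 1.0
        assert c.mean_relative_difference_pct == 0.0

    def test_normal_shift_selects_t_branch(self):
        rng = np.random.default_rng(123)
        d = rng.normal(0.05, 0.01, 20)
        y = rng.uniform(0.4, 0.6, 20)
        c = sc.paired_compare(y + d, y)
        assert c.test_used == "paired_t"
        assert c.p_two_sided < 0.001

    def test_heavy_tailed_selects_wilcoxon(self):
        # seed chosen so the Cauchy sample visibly rejects normality
        rng = np.random.default_rng(2024)
        d = rng.standard_cauchy(20)
        y = np.full(20, 1.0)
        c = sc.paired_compare(y + d, y)
        assert c.test_used == "wilcoxon"

    def test_constant_nonzero_difference_routes_to_wilcoxon(self):
        y = np.full(10, 0.5)
        c = sc.paired_compare(y + 0.05, y)
        assert c.test_used == "wilcoxon"
        assert np.isnan(c.normality_p)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            sc.paired_compare([1.0, 2.0], [1.0, 2.0])

    def test_undefined_pairs_dropped(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([0.9, 2.0, 2.8, 3.9, 4.7])
        c = sc.paired_compare(x, y)
        assert c.n_pairs == 4


class TestBhFdr:
    def test_hand_worked_example(self):
        assert np.allclose(sc.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert sc.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert np.allclose(sc.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(sc.bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_order_and_idempotent(self):
        rng = np.random.default_rng(9)
        p = rng.random(25)
        q = sc.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            sc.bh_fdr([0.5, 1.2])


class TestCompareGscf:
    def test_three_conditions_give_three_comparisons(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(
            {c: rng.uniform(0.4, 0.6, 12) for c in ("hi", "mid", "lo")}
        )
        comps = sc.compare_gscf(table, ["hi", "mid", "lo"])
        assert len(comps) == 3
        assert {c.label for c in comps} == {"mid_vs_hi", "lo_vs_hi", "lo_vs_mid"}

    def test_attenuated_ensemble_detected_with_negative_sign(self):
        spec = sc.CohortSpec(seed=21)
        ens, truth = sc.make_connectome_ensemble(spec)
        table = pd.DataFrame(
            {r: [sc.gscf(ens[(s, r)], truth.true_adjacency) for s in range(spec.n_subjects)]
             for r in spec.resolutions}
        )
        (c,) = sc.compare_gscf(table, list(spec.resolutions))
        assert c.significant
        assert c.mean_relative_difference_pct < 0


class TestCompareRscf:
    def test_constructed_decrease_regions_flagged(self):
        rng = np.random.default_rng(11)
        regions = pd.DataFrame(
            {"id": [1, 2, 3, 4], "name": ["a", "b", "a", "b"],
             "hemisphere": ["L", "L", "R", "R"]}
        )
        base = rng.uniform(0.7, 0.9, (20, 4))
        high = pd.DataFrame(base, columns=[1, 2, 3, 4])
        low = high.copy()
        low[1] -= 0.2  # only region 1 attenuated
        low += rng.normal(0, 0.005, (20, 4))
        comps, report = sc.compare_rscf(high, low, regions)
        directions = dict(zip(report["region"], report["direction"]))
        assert directions[1] == "decrease"
        assert directions[2] == "none" and directions[3] == "none"

    def test_region_undefined_everywhere_excluded(self):
        regions = pd.DataFrame(
            {"id": [1, 2], "name": ["a", "b"], "hemisphere": ["L", "L"]}
        )
        rng = np.random.default_rng(12)
        high = pd.DataFrame({1: rng.uniform(0.5, 0.9, 10), 2: np.nan})
        low = pd.DataFrame({1: rng.uniform(0.5, 0.9, 10), 2: np.nan})
        comps, report = sc.compare_rscf(high, low, regions)
        assert len(comps) == 1
        row = report[report["region"] == 2].iloc[0]
        assert row["direction"] == "excluded"


class TestTop10Frequency:
    @pytest.fixture
    def regions(self):
        names = [f"r{k}" for k in range(12)]
        return pd.DataFrame(
            {"id": list(range(1, 25)),
             "name": names + names,
             "hemisphere": ["L"] * 12 + ["R"] * 12}
        )

    def test_membership_matches_sort_oracle_with_tie(self, regions):
        rng = np.random.default_rng(13)
        diffs = pd.DataFrame(
            rng.uniform(-10, 2, (3, 24)), index=["m1", "m2", "m3"],
            columns=regions["id"],
        )
        # force a tie at rank 10 in m1: one extra region equals the 10th value
        tenth = np.sort(diffs.loc["m1"].to_numpy())[9]
        outside = diffs.loc["m1"][diffs.loc["m1"] > tenth].index[0]
        diffs.loc["m1", outside] = tenth
        assert (diffs.loc["m1"] <= tenth).sum() == 11
        table, _ = sc.top10_frequency(diffs, regions, min_frequency=0.0)
        freq_got = dict(zip(table["region"], table["frequency"]))
        counts = {r: 0 for r in diffs.columns}
        for method in diffs.index:
            vals = diffs.loc[method]
            thr = np.sort(vals.to_numpy())[9]
            for r in vals.index[vals <= thr]:
                counts[r] += 1
        for r, cnt in counts.items():
            assert freq_got.get(r, 0.0) == pytest.approx(cnt / 3)

    def test_frequency_filter(self, regions):
        # distinct positive baseline ranks; region 1 always among the worst,
        # region 2 only under method m1
        base = np.arange(1.0, 25.0)
        diffs = pd.DataFrame(
            [base] * 4, index=["m1", "m2", "m3", "m4"], columns=regions["id"]
        )
        diffs.loc[:, 1] = -100.0
        diffs.loc["m1", 2] = -50.0
        diffs.loc[["m2", "m3", "m4"], 2] = 200.0
        table, _ = sc.top10_frequency(diffs, regions)
        freqs = dict(zip(table["region"], table["frequency"]))
        assert freqs[1] == 1.0
        assert 2 not in freqs  # 25% < 50%

    def test_homologous_pairs_matched_by_name(self, regions):
        diffs = pd.DataFrame(0.0, index=["m1", "m2"], columns=regions["id"])
        diffs.loc[:, [1, 13]] = -9.0  # name r0 on both hemispheres
        table, homologous = sc.top10_frequency(diffs, regions)
        assert {"r0"} <= set(homologous["name"])
        pair = homologous[homologous["name"] == "r0"].iloc[0]
        assert pair["left_id"] == 1 and pair["right_id"] == 13

    def test_fewer_than_ten_regions_all_members(self):
        regions = pd.DataFrame(
            {"id": [1, 2, 3], "name": ["a", "b", "c"], "hemisphere": ["L"] * 3}
        )
        diffs = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["m"], columns=[1, 2, 3])
        table, _ = sc.top10_frequency(diffs, regions)
        assert set(table["region"]) == {1, 2, 3}
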