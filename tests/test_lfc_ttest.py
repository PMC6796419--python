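"""Welch comparison of fold changes, t-ranking, and the early/late partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosscontrast.lfc_ttest import (partition_early_late, rank_by_t, se_to_sd,
                                     welch_compare, welch_satterthwaite_df)
from conftest import make_de_table


class TestSeToSd:
    @pytest.mark.parametrize("se,n,expected", [
        (1.0, 1, 1.0),
        (0.5, 4, 1.0),
        (0.3, 192, 0.3 * np.sqrt(192)),
    ])
    def test_examples(self, se, n, expected):
        assert se_to_sd(se, n) == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="sample count"):
            se_to_sd(1.0, 0)
        with pytest.raises(ValueError, match="standard error"):
            se_to_sd(-0.1, 4)


class TestWelchCompare:
    def test_hand_arithmetic_example(self):
        # X1=2, X2=0, s1=s2=1 (se=0.5 at n=4), n1=n2=4
        a = make_de_table(["g"], [2.0], [0.5], 4)
        b = make_de_table(["g"], [0.0], [0.5], 4)
        w = welch_compare(a, b)
        assert w.loc["g", "s_delta"] == pytest.approx(np.sqrt(0.5))
        assert w.loc["g", "t"] == pytest.approx(2 * np.sqrt(2))
        assert w.loc["g", "df"] == pytest.approx(6.0)  # 2(n-1) with n=4

    def test_equal_estimates_give_zero_t(self):
        a = make_de_table(["g"], [1.3], [0.2], 10)
        b = make_de_table(["g"], [1.3], [0.4], 7)
        w = welch_compare(a, b)
        assert w.loc["g", "t"] == 0.0
        assert w.loc["g", "pvalue"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 5, 20])
    def test_symmetric_welch_df_closed_form(self, n):
        a = make_de_table(["g"], [1.0], [0.7], n)
        b = make_de_table(["g"], [0.0], [0.7], n)
        assert welch_compare(a, b).loc["g", "df"] == pytest.approx(2 * (n - 1))

    def test_antisymmetry(self, rng):
        genes = [f"g{i}" for i in range(40)]
        a = make_de_table(genes, rng.normal(0, 2, 40), rng.uniform(0.1, 1, 40), 26)
        b = make_de_table(genes, rng.normal(0, 2, 40), rng.uniform(0.1, 1, 40), 192)
        ab, ba = welch_compare(a, b), welch_compare(b, a)
        assert np.allclose(ab["t"], -ba["t"])
        assert np.allclose(ab["delta_l2fc"], -ba["delta_l2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])
        assert np.all(np.sign(ab["t"]) == np.sign(ab["delta_l2fc"]))

    def test_df_bounded_by_pooled(self, rng):
        genes = [f"g{i}" for i in range(30)]
        n1, n2 = 5, 192
        a = make_de_table(genes, rng.normal(size=30), rng.uniform(0.1, 1, 30), n1)
        b = make_de_table(genes, rng.normal(size=30), rng.uniform(0.1, 1, 30), n2)
        w = welch_compare(a, b)
        assert (w["df"] <= n1 + n2 - 2 + 1e-9).all()
        assert (w["df"] >= min(n1, n2) - 1 - 1e-9).all()

    def test_large_n_matches_normal_approximation(self):
        n = 10_000
        a = make_de_table(["g"], [0.3], [0.05], n)
        b = make_de_table(["g"], [0.1], [0.05], n)
        w = welch_compare(a, b)
        z = (0.3 - 0.1) / np.sqrt(0.05**2 + 0.05**2)
        assert w.loc["g", "pvalue"] == pytest.approx(2 * stats.norm.sf(z), abs=1e-3)

    def test_zero_spread_is_flagged(self):
        a = make_de_table(["g1", "g2"], [1.0, 2.0], [0.0, 0.3], 5, [0.5, 0.5])
        b = make_de_table(["g1", "g2"], [0.5, 0.0], [0.0, 0.2], 5, [0.5, 0.5])
        w = welch_compare(a, b)
        assert np.isnan(w.loc["g1", "t"]) and np.isnan(w.loc["g1", "pvalue"])
        assert np.isfinite(w.loc["g2", "t"])

    def test_empty_intersection_rejected(self):
        a = make_de_table(["g1"], [1.0], [0.1], 5)
        b = make_de_table(["g2"], [1.0], [0.1], 5)
        with pytest.raises(ValueError, match="shared"):
            welch_compare(a, b)

    def test_printed_component_estimates_reproduce_deltas(self):
        """ΔL2FC arithmetic on the published caudate-vs-cortex examples."""
        genes = ["CFAP157", "SPAG6", "CAPSL", "TVP23C-CDRT4", "MMP8"]
        x3 = [-0.13, -2.20, -2.59, 2.55, 4.70]
        x5 = [4.30, 2.64, 3.65, -0.02, 0.13]
        a = make_de_table(genes, x3, [0.5] * 5, 5)
        b = make_de_table(genes, x5, [0.1] * 5, 192)
        w = welch_compare(a, b)
        expected = {"CFAP157": -4.43, "SPAG6": -4.84, "CAPSL": -6.24,
                    "TVP23C-CDRT4": 2.57, "MMP8": 4.57}
        for gene, delta in expected.items():
            assert w.loc[gene, "delta_l2fc"] == pytest.approx(delta, abs=1e-9)


class TestRankByT:
    def test_orders_by_t_descending(self):
        w = pd.DataFrame({"t": [3.0, -1.0, 5.0]}, index=["g1", "g2", "g3"])
        assert rank_by_t(w).index.tolist() == ["g3", "g1", "g2"]

    def test_ties_break_lexicographically(self):
        w = pd.DataFrame({"t": [2.0, 2.0, -1.0]}, index=["zeta", "alpha", "mid"])
        assert rank_by_t(w).index.tolist() == ["alpha", "zeta", "mid"]

    def test_invariant_to_input_order(self, rng):
        w = pd.DataFrame({"t": rng.normal(size=30)},
                         index=[f"g{i}" for i in range(30)])
        shuffled = w.sample(frac=1.0, random_state=1)
        assert rank_by_t(w).index.tolist() == rank_by_t(shuffled).index.tolist()

    def test_excludes_flagged_records(self):
        w = pd.DataFrame({"t": [1.0, np.nan]}, index=["g1", "g2"])
        assert rank_by_t(w).index.tolist() == ["g1"]


class TestPartition:
    def _tables(self):
        genes = ["NPAS4", "up_up", "down_down", "up_down", "null"]
        l2fc1 = [-1.27, 2.0, -2.0, 2.0, 0.1]
        l2fc2 = [7.64, 3.5, -3.5, -2.0, 0.1]
        # NPAS4-like: not DE in (1), strongly DE in (2), significant between
        p1 = [0.5, 1e-4, 1e-4, 1e-4, 0.9]
        p2 = [1e-6, 1e-5, 1e-5, 1e-5, 0.9]
        de1 = make_de_table(genes, l2fc1, [0.4] * 5, 82, p1)
        de2 = make_de_table(genes, l2fc2, [0.4] * 5, 59, p2)
        welch = welch_compare(de1, de2)
        return de1, de2, welch

    def test_quadrants(self):
        de1, de2, welch = self._tables()
        part = partition_early_late(de1, de2, welch)
        genes = part["genes"]
        assert genes.loc["NPAS4", "quadrant"] == "II"
        assert genes.loc["up_up", "quadrant"] == "I"
        assert genes.loc["down_down", "quadrant"] == "III"
        assert genes.loc["up_down", "quadrant"] == "IV"
        assert genes.loc["null", "quadrant"] == ""

    def test_null_gene_lands_in_null_cell(self):
        de1, de2, welch = self._tables()
        part = partition_early_late(de1, de2, welch)
        row = part["genes"].loc["null"]
        assert not row["de1"] and not row["de2"] and not row["sig_between"]
        assert part["table"].loc[(False, False, False)] == 1

    def test_cells_partition_all_common_genes(self):
        de1, de2, welch = self._tables()
        part = partition_early_late(de1, de2, welch)
        assert part["table"].sum() == len(de1.index.intersection(de2.index))

    def test_side_tables_hold_filtered_genes(self):
        de1, de2, welch = self._tables()
        extra = make_de_table(["only1"], [1.0], [0.2], 82, [1e-5])
        de1x = pd.concat([de1, extra])
        part = partition_early_late(de1x, de2, welch)
        assert part["only_in_1"].index.tolist() == ["only1"]
        assert bool(part["only_in_1"].loc["only1", "de"])
        assert part["table"].sum() == 5  # side genes not double-counted
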