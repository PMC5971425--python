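"""Expressed sets, maintenance chains, Venn accounting, proportion test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import commitpoint as cp


@pytest.fixture()
def toy_matrix():
    df = pd.DataFrame(
        {
            "LSK": [1.0, 0.99, 5.0, 0.0, 2.0],
            "CMP": [2.0, 3.0, 0.5, 0.0, 2.0],
            "ERY": [0.0, 4.0, 6.0, 0.0, 2.0],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return cp.ExpressionMatrix(df)


class TestExpressedSet:
    def test_threshold_boundary_inclusive(self, toy_matrix):
        s = cp.expressed_set(toy_matrix, "LSK")
        assert "g0" in s  # exactly 1.0 TPM counts as expressed
        assert "g1" not in s  # 0.99 does not

    def test_all_zero_matrix_empty(self):
        m = cp.ExpressionMatrix(pd.DataFrame({"A": [0.0, 0.0]}, index=["g0", "g1"]))
        assert cp.expressed_set(m, "A") == set()

    def test_unknown_cell_raises(self, toy_matrix):
        with pytest.raises(KeyError):
            cp.expressed_set(toy_matrix, "NEU")

    def test_threshold_monotonicity(self, toy_matrix):
        lo = cp.expressed_set(toy_matrix, "LSK", threshold=0.5)
        hi = cp.expressed_set(toy_matrix, "LSK", threshold=2.0)
        assert hi <= lo
        assert cp.expressed_set(toy_matrix, "LSK", threshold=0.0) == set(toy_matrix.genes)


class TestMaintenanceChain:
    def test_two_stage_intersection(self):
        df = pd.DataFrame(
            {"s1": [2, 2, 2, 0], "s2": [0, 2, 2, 2]},
            index=["a", "b", "c", "d"],
            dtype=float,
        )
        m = cp.ExpressionMatrix(df)
        lin = cp.Lineage("toy", ("s1", "s2"))
        assert cp.maintenance_chain(m, lin) == [3, 2]

    def test_identical_stages_constant(self, toy_matrix):
        df = toy_matrix.tpm.copy()
        df["CMP"] = df["LSK"]
        df["ERY"] = df["LSK"]
        m = cp.ExpressionMatrix(df)
        counts = cp.maintenance_chain(m, cp.Lineage("l", ("LSK", "CMP", "ERY")))
        assert counts == [counts[0]] * 3

    def test_matches_set_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        stages = ["s1", "s2", "s3", "s4"]
        tpm = pd.DataFrame(
            rng.choice([0.0, 5.0], p=[0.35, 0.65], size=(400, 4)),
            index=[f"g{i}" for i in range(400)],
            columns=stages,
        )
        m = cp.ExpressionMatrix(tpm)
        lin = cp.Lineage("l", tuple(stages))
        counts = cp.maintenance_chain(m, lin)
        acc = None
        for k, s in enumerate(stages):
            sk = {g for g in m.genes if tpm.loc[g, s] >= 1.0}
            acc = sk if acc is None else acc & sk
            assert counts[k] == len(acc)
        assert all(x >= y for x, y in zip(counts, counts[1:]))  # non-increasing


class TestRoundedPercent:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (8239, 13066, 0, 63.0),
            (789, 6386, 1, 12.4),
            (0, 50, 0, 0.0),
            (1, 8, 0, 13.0),  # 12.5 rounds half-up
            (1, 800, 1, 0.1),  # 0.125 rounds half-up at one decimal
        ],
    )
    def test_examples(self, num, den, decimals, expected):
        assert cp.rounded_percent(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            cp.rounded_percent(1, 0)


class TestExclusiveOverlap:
    def test_identical_sets_center_only(self):
        s = {"a", "b", "c", "d", "e"}
        counts = cp.exclusive_overlap({"X": set(s), "Y": set(s), "Z": set(s)})
        assert counts[("X", "Y", "Z")] == 5
        assert sum(counts.values()) == 5

    def test_pairwise_disjoint(self):
        counts = cp.exclusive_overlap({"X": {1}, "Y": {2, 3}, "Z": {4, 5, 6}})
        assert counts[("X",)] == 1 and counts[("Y",)] == 2 and counts[("Z",)] == 3
        assert all(v == 0 for k, v in counts.items() if len(k) > 1)

    def test_matches_membership_oracle_and_sums_to_union(self, rng):
        sets = {
            name: set(rng.choice(200, size=int(rng.integers(20, 120)), replace=False))
            for name in ("X", "Y", "Z")
        }
        counts = cp.exclusive_overlap(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        for element in union:
            members = tuple(sorted(n for n in sets if element in sets[n]))
            # count the region this element belongs to via direct tally
        for key, val in counts.items():
            tally = sum(
                1
                for e in union
                if tuple(sorted(n for n in sets if e in sets[n])) == key
            )
            assert val == tally


class TestTwoProportionTest:
    def test_equal_proportions_give_z_zero_p_one(self):
        assert cp.two_proportion_test(5, 10, 50, 100) == (0.0, 1.0)
        assert cp.two_proportion_test(0, 10, 0, 20) == (0.0, 1.0)
        assert cp.two_proportion_test(10, 10, 20, 20) == (0.0, 1.0)

    def test_maintained_fraction_contrast_is_significant(self):
        # 63% vs 81% of the same 13,066-transcript root set
        z, p = cp.two_proportion_test(8239, 13066, 10522, 13066)
        assert p < 0.001
        assert z < 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            cp.two_proportion_test(3, 0, 1, 2)
        with pytest.raises(ValueError):
            cp.two_proportion_test(5, 4, 1, 2)

    def test_against_monte_carlo_binomial_null(self):
        # two-sided p for 3/10 vs 7/10 within ±0.02 of a pooled-null simulation
        k1, n1, k2, n2 = 3, 10, 7, 10
        z, p = cp.two_proportion_test(k1, n1, k2, n2)
        rng = np.random.default_rng(2024)
        pooled = (k1 + k2) / (n1 + n2)
        draws = 200_000
        s1 = rng.binomial(n1, pooled, size=draws) / n1
        s2 = rng.binomial(n2, pooled, size=draws) / n2
        observed = abs(k1 / n1 - k2 / n2)
        diff = np.abs(s1 - s2)
        # mid-p convention: the continuous z-test approximates the discrete
        # null with half the probability mass at the observed difference
        mc_p = float((diff > observed + 1e-12).mean() + 0.5 * (np.isclose(diff, observed)).mean())
        assert abs(p - mc_p) <= 0.02
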