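"""Spearman, Bonferroni, exact Mann-Whitney and r x c Fisher tests."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats as sps

from honeyforage.composition import proportions
from honeyforage.formats_io import ChecklistRow, RegionalChecklist
from honeyforage.stats import (
    StatResult,
    bonferroni,
    fisher_exact,
    hive_concordance,
    mann_whitney_u,
    spearman_rho,
    status_association,
)


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.6, 5.3, 5.8, 9.7]
        assert spearman_rho(x, x).statistic == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0, 13.0, 20.0, 21.0, 22.0]
        assert spearman_rho(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_tied_data_equals_pearson_on_average_ranks(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(9, 40))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
                continue
            rho = spearman_rho(x, y).statistic
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_rho(x, y).statistic
        assert spearman_rho(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman_rho(x, 3 * y + 7).statistic == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_p_value_matches_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        result = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert result.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert result.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_small_n_exact_permutation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 5.0, 4.0]
        result = spearman_rho(x, y)
        assert result.method == "exact"
        # enumeration oracle over all 120 permutations
        rho_obs = result.statistic
        rx = sps.rankdata(x)
        count = 0
        from itertools import permutations

        for perm in permutations(sps.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        assert result.p_value == pytest.approx(count / 120)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01]) == [0.01]
        assert bonferroni([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.06, 0.09])
        assert bonferroni([0.5, 0.9]) == [1.0, 1.0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.0, 0.5])


def mwu_exact_oracle(g1, g2):
    """Two-sided exact Mann-Whitney p by direct labeling enumeration."""
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    u1_obs = n1 * n2 + n1 * (n1 + 1) / 2 - ranks[:n1].sum()
    le = ge = total = 0
    for idx in combinations(range(n), n1):
        u1 = n1 * n2 + n1 * (n1 + 1) / 2 - ranks[list(idx)].sum()
        le += u1 <= u1_obs + 1e-9
        ge += u1 >= u1_obs - 1e-9
        total += 1
    return min(1.0, 2 * min(le, ge) / total)


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(4.5)  # n1*n2/2
        assert r.extras["z"] == pytest.approx(0.0)
        assert r.p_value == 1.0

    def test_separated_groups_exact_p(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)  # 2/20 labelings

    def test_u1_plus_u2_is_n1n2(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.integers(0, 10, 5).astype(float), rng.integers(0, 10, 7).astype(float)
        r = mann_whitney_u(g1, g2)
        assert r.extras["u1"] + r.extras["u2"] == pytest.approx(35)

    def test_invariant_under_group_swap(self):
        rng = np.random.default_rng(7)
        g1, g2 = rng.normal(size=4), rng.normal(size=5)
        assert mann_whitney_u(g1, g2).p_value == pytest.approx(
            mann_whitney_u(g2, g1).p_value
        )

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            g1 = rng.integers(0, 6, n1).astype(float)  # ties likely
            g2 = rng.integers(0, 6, n2).astype(float)
            r = mann_whitney_u(g1, g2)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(mwu_exact_oracle(g1, g2))

    def test_tie_corrected_z_matches_scipy(self):
        g1 = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 8.0]
        g2 = [2.0, 3.0, 3.0, 4.0, 7.0, 7.0, 9.0, 10.0]
        r = mann_whitney_u(g1, g2)
        ref = sps.mannwhitneyu(
            g1, g2, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert abs(r.extras["p_normal"] - ref.pvalue) < 1e-9


class TestFisherExact:
    def test_classic_2x2(self):
        r = fisher_exact([[1, 9], [11, 3]])
        assert r.p_value == pytest.approx(0.0027594561852, rel=1e-9)

    def test_zero_row_degenerate(self):
        assert fisher_exact([[0, 0], [5, 7]]).p_value == 1.0

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = fisher_exact(table.tolist()).p_value
            ref = sps.fisher_exact(table).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_3x2_column_swap_invariance(self):
        table = [[5, 4], [5, 7], [0, 18]]
        p = fisher_exact(table).p_value
        swapped = [[4, 5], [7, 5], [18, 0]]
        assert fisher_exact(swapped).p_value == pytest.approx(p)
        assert 0 < p <= 1

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="enumeration bound"):
            fisher_exact([[400, 200], [100, 50]])


class TestHiveConcordance:
    def test_identical_compositions_give_rho_1(self):
        a = proportions({"X": 50, "Y": 30, "Z": 20}, "A", "April")
        b = proportions({"X": 50, "Y": 30, "Z": 20}, "B", "April")
        results = hive_concordance([a, b])
        assert len(results) == 1
        assert results[0].statistic == pytest.approx(1.0)

    def test_three_hives_give_three_pairs(self):
        comps = [
            proportions({"X": 50, "Y": 30, "Z": 20}, h, "April") for h in "ABC"
        ]
        results = hive_concordance(comps, month="April")
        assert len(results) == 3
        assert all(r.p_adjusted == pytest.approx(min(1, 3 * r.p_value))
                   for r in results)

    def test_absent_taxa_filled_with_zero(self):
        a = proportions({"X": 90, "Y": 10}, "A", "April")
        b = proportions({"X": 80, "Z": 20}, "B", "April")
        results = hive_concordance([a, b])
        assert results[0].n == 3  # union of taxa


class TestStatusAssociation:
    CHECKLIST = RegionalChecklist(
        {
            "salix": ChecklistRow("native", "W", "W", frozenset("NP")),
            "crataegus": ChecklistRow("both", "W", "W", frozenset("NP")),
            "tulipa": ChecklistRow("horticulture", "H", "B", frozenset("P")),
        }
    )

    def test_single_status_gives_p_1(self):
        mm = {"Salix alba": "major", "Salix caprea": "minor"}
        assert status_association(self.CHECKLIST, mm).p_value == 1.0

    def test_contingency_table_built_from_classes(self):
        mm = {
            "Salix alba": "major",
            "Crataegus monogyna": "major",
            "Tulipa gesneriana": "minor",
        }
        r = status_association(self.CHECKLIST, mm)
        assert r.extras["table"] == [[1, 0], [1, 0], [0, 1]]
        assert 0 < r.p_value <= 1

    def test_reconstructed_major_minor_table(self):
        """Status x class table for 10 major / 29 minor taxa, computed by
        full r x c enumeration (frozen oracle value from R fisher.test)."""
        r = fisher_exact([[5, 4], [5, 7], [0, 18]])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.000914696360617, rel=1e-9)


def test_stat_result_validates_p():
    with pytest.raises(ValueError):
        StatResult("t", 0.0, 0.0, n=3, method="exact")
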