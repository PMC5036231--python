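"""Contribution statistic and the Monte-Carlo permutation machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbertail import (
    RiskModelParams,
    contribution_statistic,
    exhaustive_null,
    generate_cohort,
    generate_pedigree,
    permutation_test,
    simulate_case_status,
)


def pedigree_from_counts(sire_counts, dam_per_dog=None):
    """Pedigree where sire i contributes sire_counts[i] dogs."""
    sires = [f"S{i}" for i, c in enumerate(sire_counts) for _ in range(c)]
    n = len(sires)
    return pd.DataFrame(
        {
            "dog_id": [f"D{i}" for i in range(n)],
            "sire_id": sires,
            "dam_id": dam_per_dog or [f"M{i}" for i in range(n)],
        }
    )


class TestContributionStatistic:
    def test_published_illustrative_counts(self):
        # one sire with three offspring, two with two, 31 with one
        ped = pedigree_from_counts([3, 2, 2] + [1] * 31)
        s = contribution_statistic(ped["dog_id"], ped, "sire")
        assert s.n_dogs == 38 and s.n_parents == 34
        assert s.counts[:3] == (3, 2, 2)
        assert s.statistic == pytest.approx((9 + 4 + 4 + 31) / 38)
        plain = contribution_statistic(ped["dog_id"], ped, "sire", "plain_mean")
        assert plain.statistic == pytest.approx(38 / 34)

    def test_all_distinct_parents_gives_one(self):
        ped = pedigree_from_counts([1] * 12)
        for w in ("offspring_weighted", "plain_mean"):
            assert contribution_statistic(ped["dog_id"], ped, "sire", w).statistic == 1.0

    def test_single_parent_gives_n(self):
        ped = pedigree_from_counts([9])
        for w in ("offspring_weighted", "plain_mean"):
            assert contribution_statistic(ped["dog_id"], ped, "sire", w).statistic == 9.0

    def test_unknown_parent_excluded_with_count(self):
        ped = pedigree_from_counts([2, 2])
        ped.loc[0, "sire_id"] = ""
        s = contribution_statistic(ped["dog_id"], ped, "sire")
        assert s.n_excluded == 1 and s.n_dogs == 3

    def test_dam_axis_independent_of_sires(self):
        ped = pedigree_from_counts([4], dam_per_dog=["M1", "M1", "M2", "M2"])
        assert contribution_statistic(ped["dog_id"], ped, "dam").statistic == 2.0
        assert contribution_statistic(ped["dog_id"], ped, "sire").statistic == 4.0

    @given(
        counts=st.lists(st.integers(1, 6), min_size=1, max_size=12),
        frac=st.floats(0.2, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_statistic_bounded_by_one_and_sample_size(self, counts, frac):
        ped = pedigree_from_counts(counts)
        m = max(1, int(frac * len(ped)))
        sample = ped["dog_id"].iloc[:m]
        for w in ("offspring_weighted", "plain_mean"):
            s = contribution_statistic(sample, ped, "sire", w)
            assert 1.0 <= s.statistic <= s.n_dogs
            if all(c == 1 for c in s.counts):
                assert s.statistic == 1.0
            if s.n_parents == 1:
                assert s.statistic == s.n_dogs


class TestPermutationTest:
    def test_degenerate_full_cohort_sample(self):
        ped = pedigree_from_counts([3, 3])
        res = permutation_test(ped["dog_id"], ped["dog_id"], ped, n_perm=50, seed=0)
        assert res.p_value == 1.0
        assert np.all(res.null_values == res.observed.statistic)

    def test_seed_determinism(self):
        ped = pedigree_from_counts([4, 3, 2, 1, 1, 1])
        cases = ped["dog_id"].iloc[:4]
        a = permutation_test(cases, ped["dog_id"], ped, n_perm=200, seed=5)
        b = permutation_test(cases, ped["dog_id"], ped, n_perm=200, seed=5)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_values, b.null_values)

    def test_relabelling_invariance(self):
        ped = pedigree_from_counts([4, 3, 2, 1, 1, 1])
        cases = list(ped["dog_id"].iloc[:4])
        renamed = ped.assign(
            dog_id="X" + ped["dog_id"], sire_id="Y" + ped["sire_id"]
        )
        a = permutation_test(cases, ped["dog_id"], ped, n_perm=300, seed=6)
        b = permutation_test(["X" + c for c in cases], renamed["dog_id"],
                             renamed, n_perm=300, seed=6)
        assert a.observed.statistic == b.observed.statistic
        assert a.p_value == b.p_value

    def test_case_set_must_be_subset(self):
        ped = pedigree_from_counts([2, 2])
        with pytest.raises(ValueError, match="subset"):
            permutation_test(["ghost"], ped["dog_id"], ped, n_perm=10, seed=0)

    def test_percentile_band_brackets_observed_flag(self):
        ped = pedigree_from_counts([6, 1, 1, 1, 1, 1, 1])
        clustered = ped[ped["sire_id"] == "S0"]["dog_id"]
        res = permutation_test(clustered, ped["dog_id"], ped, n_perm=500, seed=7)
        assert res.pct_2_5 <= res.pct_97_5
        assert res.significant_clustering == (res.observed.statistic > res.pct_97_5)

    def test_add_one_rule_floor(self):
        ped = pedigree_from_counts([5] + [1] * 20)
        clustered = ped[ped["sire_id"] == "S0"]["dog_id"]
        res = permutation_test(clustered, ped["dog_id"], ped, n_perm=99, seed=8)
        assert res.p_value >= 1 / 100


class TestExhaustiveOracle:
    def test_subset_counts(self):
        ped = pedigree_from_counts([2, 2, 1])
        null = exhaustive_null(2, ped["dog_id"], ped)
        assert null.n_subsets == math.comb(5, 2) == 10
        single = exhaustive_null(4, ped["dog_id"].iloc[:4], ped)
        assert single.n_subsets == 1 and single.tail_p(single.values[0]) == 1.0

    def test_enumeration_bound_enforced(self):
        ped = pedigree_from_counts([1] * 40)
        with pytest.raises(ValueError, match="exceeds"):
            exhaustive_null(20, ped["dog_id"], ped, max_subsets=1000)

    def test_monte_carlo_converges_to_exhaustive(self):
        # 6-dog cohort, two sires with 3 offspring each; the case set is
        # one full sibship, so the exact tail probability is 2/20
        ped = pedigree_from_counts([3, 3])
        cases = ped[ped["sire_id"] == "S0"]["dog_id"]
        exact = exhaustive_null(3, ped["dog_id"], ped)
        obs = contribution_statistic(cases, ped, "sire").statistic
        t = exact.tail_p(obs)
        assert t == pytest.approx(2 / 20)
        res = permutation_test(cases, ped["dog_id"], ped, n_perm=10_000, seed=9)
        se = math.sqrt(t * (1 - t) / 10_000)
        assert abs(res.p_value - t) < 3 * se + 1 / 10_001


class TestPower:
    def test_rejection_rate_increases_with_sire_effect(self):
        # familial clustering raises the statistic; the test's power at
        # the 5% level should rise monotonically with sire_sd
        rates = []
        for sd in (0.5, 1.0, 1.5):
            hits = 0
            reps = 120
            for i in range(reps):
                ped = generate_pedigree(400, 40, 50, seed=900 + i)
                cohort = generate_cohort(ped, seed=1900 + i)
                sim = simulate_case_status(
                    cohort, RiskModelParams(sire_sd=sd), seed=2900 + i
                )
                cases = sim.affected[sim.affected].index
                if len(cases) < 2:
                    continue
                res = permutation_test(cases, cohort["dog_id"], ped,
                                       n_perm=99, seed=3900 + i)
                hits += res.p_value <= 0.05
            rates.append(hits / reps)
        assert rates[0] > 0.05  # above the nominal level already
        assert rates[0] < rates[1] < rates[2]
        assert rates[-1] > 0.5  # strong clustering is reliably detected
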