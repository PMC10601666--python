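import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, rankdata

from tracequant.fixtures import CohortSpec, make_synthetic_atlas, simulate_cohort
from tracequant.quantify import HemisphereSample
from tracequant.stats import (
    bh_fdr,
    compare_cohort,
    rank_sum_exact,
    sign_imbalance,
)


def brute_force_rank_sum_p(x, y):
    """Oracle: enumerate every assignment of the pooled mid-ranks."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, n1)]
    n = len(sums)
    lower = sum(s <= observed + 1e-9 for s in sums)
    upper = sum(s >= observed - 1e-9 for s in sums)
    return min(1.0, 2.0 * min(lower, upper) / n)


def brute_force_bh(p_values, level):
    """O(m^2) step-up oracle: scan all candidate thresholds."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank * level / m:
            k_star = rank
    rejected = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            rejected[i] = True
    return rejected


class TestRankSumExact:
    def test_complete_separation_4v4(self):
        p = rank_sum_exact([10, 11, 12, 13], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 70)
        assert round(p, 3) == 0.029

    def test_u4_7v7(self):
        x = [10, 20, 30, 40, 50, 60, 70]
        y = [1, 2, 3, 4, 5, 6, 45]
        assert sum(a > b for a in y for b in x) == 4  # U = 4
        p = rank_sum_exact(x, y)
        assert p == pytest.approx(24 / 3432)
        assert round(p, 3) == 0.007

    def test_identical_groups_p_one(self):
        assert rank_sum_exact([1, 2, 3], [1, 2, 3]) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_sum_exact([], [1, 2])

    def test_matches_bruteforce_500_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n1 = int(rng.integers(1, 8))
            n2 = int(rng.integers(1, 8))
            x = rng.integers(0, 12, n1).tolist()  # integer data: plenty of ties
            y = rng.integers(0, 12, n2).tolist()
            assert rank_sum_exact(x, y) == pytest.approx(
                brute_force_rank_sum_p(x, y), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 8)).tolist()
            y = rng.normal(size=rng.integers(2, 8)).tolist()
            assert rank_sum_exact(x, y) == pytest.approx(rank_sum_exact(y, x))

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=7),
        st.lists(st.integers(0, 20), min_size=1, max_size=7),
    )
    @settings(max_examples=60, deadline=None)
    def test_p_in_unit_interval(self, x, y):
        p = rank_sum_exact(x, y)
        assert 0.0 < p <= 1.0

    def test_large_groups_use_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40).tolist()
        y = rng.normal(1.0, 1, 40).tolist()
        p = rank_sum_exact(x, y)
        assert 0 < p < 0.01


class TestBH:
    def test_single_test(self):
        q, rej = bh_fdr([0.04])
        assert q == [pytest.approx(0.04)]
        assert rej == [True]

    def test_uniform_strong_signal(self):
        q, rej = bh_fdr([0.001] * 10)
        assert all(r for r in rej)
        assert q == pytest.approx([0.001] * 10)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    def test_matches_oracle_200_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            # mixture of nulls and signals so rejection sets vary
            p = np.concatenate(
                [rng.uniform(1e-6, 1, m), rng.uniform(1e-6, 0.01, rng.integers(0, 5))]
            ).tolist()
            _, rejected = bh_fdr(p, level=0.05)
            assert rejected == brute_force_bh(p, 0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 30).tolist()
        _, rej = bh_fdr(p)
        perm = rng.permutation(30)
        _, rej_perm = bh_fdr([p[i] for i in perm])
        assert [rej[i] for i in perm] == rej_perm

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        p = sorted(rng.uniform(1e-6, 1, 25).tolist())
        q, _ = bh_fdr(p)
        assert all(a <= b + 1e-12 for a, b in zip(q, q[1:]))


class TestSignImbalance:
    def test_balanced_is_one(self):
        assert sign_imbalance(25, 50) == pytest.approx(1.0)

    def test_extreme_closed_form(self):
        assert sign_imbalance(50, 50) == pytest.approx(min(1.0, 2 * 0.5**50))

    def test_46_of_50_matches_pmf_summation(self):
        # oracle: direct two-tailed summation of binomial pmf terms
        pmf = binom.pmf(np.arange(51), 50, 0.5)
        expected = pmf[pmf <= pmf[46] * (1 + 1e-12)].sum()
        assert sign_imbalance(46, 50) == pytest.approx(expected, rel=1e-9)

    def test_fisher_mode_runs(self):
        p = sign_imbalance(46, 50, mode="fisher")
        assert 0 < p < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            sign_imbalance(1, 0)
        with pytest.raises(ValueError):
            sign_imbalance(5, 4)
        with pytest.raises(ValueError):
            sign_imbalance(1, 2, mode="bogus")


def _sample(sid, sex, presynaptic):
    return HemisphereSample(
        sample_id=sid, sex=sex, target="amygdala", side="left",
        starters={1: 50}, presynaptic=presynaptic,
    )


class TestCompareCohort:
    def _cohort(self, seed=0, flip=False):
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(4):
            for sex, rate in (("male", 40), ("female", 10)):
                if flip:
                    sex = "female" if sex == "male" else "male"
                samples.append(
                    _sample(
                        f"{sex[0]}{i}{rng.integers(1000)}",
                        sex,
                        {2: int(rng.poisson(rate)), 3: int(rng.poisson(20))},
                    )
                )
        return samples

    def test_detects_planted_effect(self):
        res = compare_cohort(self._cohort(), metric="pps", included_regions={2, 3})
        by_region = {c.region_id: c for c in res.comparisons}
        assert by_region[2].direction == "male_higher"
        assert by_region[2].p_value < 0.05

    def test_label_swap_symmetry(self):
        a = compare_cohort(self._cohort(seed=1), included_regions={2, 3})
        b = compare_cohort(self._cohort(seed=1, flip=True), included_regions={2, 3})
        for ca, cb in zip(a.comparisons, b.comparisons):
            assert ca.p_value == pytest.approx(cb.p_value)
            flipmap = {"male_higher": "female_higher", "female_higher": "male_higher", "tie": "tie"}
            assert cb.direction == flipmap[ca.direction]

    def test_deterministic(self):
        cohort = self._cohort(seed=2)
        a = compare_cohort(cohort, included_regions={2, 3})
        b = compare_cohort(cohort, included_regions={2, 3})
        assert a == b

    def test_requires_two_per_sex(self):
        with pytest.raises(ValueError, match="2 samples per sex"):
            compare_cohort(
                [_sample("m1", "male", {2: 5}), _sample("f1", "female", {2: 5})],
                included_regions={2},
            )

    def test_requires_regions(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_cohort(self._cohort(), included_regions=set())

    def test_sign_counts(self):
        res = compare_cohort(self._cohort(seed=3), included_regions={2, 3})
        n_higher, n_total = res.sign_counts
        assert n_total == 2
        assert 0 <= n_higher <= 2
        assert 0 < res.sign_imbalance_p() <= 1.0


class TestCalibrationSmoke:
    """Scaled-down versions of the simulation calibration checks (full-size
    runs live in the acceptance suite)."""

    def test_null_cohort_fdr_controlled(self):
        atlas = make_synthetic_atlas(1, 21, (64, 64), seed=0)
        fracs = []
        for seed in range(15):
            spec = CohortSpec(
                regions=tuple((rid, 5.0, 1.0) for rid in range(1, 21)),
                n_male=7, n_female=7, starter_mean=50.0,
                starter_target_region=21 - 1, seed=seed,
            )
            samples, _ = simulate_cohort(spec, atlas)
            res = compare_cohort(samples, included_regions=set(range(1, 21)))
            fracs.append(res.n_significant / 20)
        assert np.mean(fracs) <= 0.10

    def test_dimorphic_cohort_power(self):
        atlas = make_synthetic_atlas(1, 21, (64, 64), seed=0)
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            regions = tuple(
                (rid, 5.0, 5.0 if rid <= 10 else 1.0) for rid in range(1, 21)
            )
            spec = CohortSpec(
                regions=regions, n_male=7, n_female=7, starter_mean=50.0,
                starter_target_region=20, seed=seed,
            )
            samples, _ = simulate_cohort(spec, atlas)
            res = compare_cohort(samples, included_regions=set(range(1, 21)))
            flagged = {c.region_id for c in res.comparisons if c.significant}
            if len(flagged & set(range(1, 11))) >= 8:
                hits += 1
        assert hits / n_seeds >= 0.8
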