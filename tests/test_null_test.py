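import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from mcadet.null_test import (
    NullSpec,
    bh_select,
    count_distinct_ratios,
    count_rank_pairs,
    joint_minmax_pmf,
    mc_null_sample,
    pvalues,
    v_pmf,
)


def binned_tv(values, probs, samples, n_bins=20):
    """Total variation between an exact pmf and a sample, on equal-probability
    bins of the exact law.

    Atom-level TV of an empirical measure is dominated by per-atom sampling
    noise when the support is large; binning keeps the noise floor well below
    the tolerances asserted here while still detecting any real mismatch.
    """
    cdf = np.cumsum(probs)
    cuts = np.linspace(1 / n_bins, 1 - 1 / n_bins, n_bins - 1)
    edges = values[np.searchsorted(cdf, cuts)]
    exact = np.diff(np.concatenate([[0.0], cdf[np.searchsorted(cdf, cuts)], [1.0]]))
    emp, _ = np.histogram(samples, bins=np.concatenate([[-np.inf], edges + 1e-12, [np.inf]]))
    return np.abs(emp / len(samples) - exact).sum()


def _enumerate_minmax(p, d):
    """Brute-force joint law of (min, max) over all p^d rank tuples."""
    counts = {}
    for tup in itertools.product(range(1, p + 1), repeat=d):
        key = (min(tup), max(tup))
        counts[key] = counts.get(key, 0) + 1
    total = p**d
    return {k: v / total for k, v in counts.items()}


class TestJointMinMaxPmf:
    @pytest.mark.parametrize("p,d", [(2, 2), (3, 2), (4, 3), (5, 3)])
    def test_matches_enumeration(self, p, d):
        oracle = _enumerate_minmax(p, d)
        for k1 in range(1, p + 1):
            for k2 in range(k1, p + 1):
                assert joint_minmax_pmf(p, d, k1, k2) == pytest.approx(
                    oracle.get((k1, k2), 0.0), abs=1e-12
                )

    def test_diagonal_is_single_atom(self):
        # all d draws equal: (1/p)^d, not the k1<k2 expression
        assert joint_minmax_pmf(2, 2, 1, 1) == pytest.approx(0.25)
        assert joint_minmax_pmf(2, 2, 1, 2) == pytest.approx(0.5)

    def test_normalization(self):
        total = sum(
            joint_minmax_pmf(5, 3, k1, k2)
            for k1 in range(1, 6)
            for k2 in range(k1, 6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_minmax_pmf(5, 2, 3, 2)
        with pytest.raises(ValueError):
            joint_minmax_pmf(5, 2, 0, 3)


class TestVPmf:
    def test_two_by_two_exact(self):
        values, probs = v_pmf(2, 2)
        assert np.allclose(values, [0.0, math.log(2)])
        assert np.allclose(probs, [0.5, 0.5])

    @pytest.mark.parametrize("p,d", [(5, 3), (20, 4), (60, 5)])
    def test_mass_sums_to_one(self, p, d):
        _, probs = v_pmf(p, d)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_support_size_equals_distinct_ratio_count(self):
        values, _ = v_pmf(5, 3)
        assert len(values) == count_distinct_ratios(5)
        assert np.all(np.diff(values) > 0)

    def test_matches_sampling_oracle(self):
        p, d = 20, 3
        values, probs = v_pmf(p, d)
        rng = np.random.default_rng(42)
        draws = rng.integers(1, p + 1, size=(200_000, d))
        v = np.log(draws.max(1) / draws.min(1))
        assert binned_tv(values, probs, v) < 0.01

    def test_cap_directs_to_monte_carlo(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            v_pmf(10_000, 3, max_pairs=1000)


class TestCombinatorialCounts:
    def test_pair_count_small_cases(self):
        assert count_rank_pairs(1) == 1
        assert count_rank_pairs(4) == 10

    def test_distinct_ratios_by_enumeration(self):
        # p=4: {1, 4/3, 3/2, 2, 3, 4}
        assert count_distinct_ratios(1) == 1
        assert count_distinct_ratios(4) == 6
        from fractions import Fraction

        for p in (2, 3, 5, 8, 12):
            exact = {
                Fraction(k2, k1) for k1 in range(1, p + 1) for k2 in range(k1, p + 1)
            }
            assert count_distinct_ratios(p) == len(exact)


class TestMonteCarloNull:
    def test_support_for_two_ranks(self):
        samples = mc_null_sample(NullSpec(p=2, ds=[2], T=500, seed=3))
        assert set(np.round(samples, 12)) <= {0.0, round(math.log(2), 12)}

    def test_seed_reproducibility(self):
        spec = NullSpec(p=100, ds=[3, 5], T=1000, seed=11)
        assert np.array_equal(mc_null_sample(spec), mc_null_sample(spec))

    def test_single_run_matches_exact_pmf(self):
        p, d = 50, 5
        values, probs = v_pmf(p, d)
        samples = mc_null_sample(NullSpec(p=p, ds=[d], T=200_000, seed=8))
        assert binned_tv(values, probs, samples) < 0.01

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NullSpec(p=1, ds=[2])
        with pytest.raises(ValueError):
            NullSpec(p=10, ds=[1])
        with pytest.raises(ValueError):
            NullSpec(p=10, ds=[2], T=0)


class TestPvalues:
    def test_extreme_observation_attains_lower_bound(self):
        samples = np.arange(100, dtype=float)
        assert pvalues(np.array([1e9]), samples)[0] == pytest.approx(1 / 101)

    def test_smallest_observation_gives_one(self):
        samples = np.arange(1, 101, dtype=float)
        assert pvalues(np.array([-1.0]), samples)[0] == 1.0

    def test_null_pvalues_are_uniform(self):
        p, ds = 500, [4, 6]
        rng = np.random.default_rng(0)
        v_obs = np.zeros(1000)
        for d in ds:
            draws = rng.integers(1, p + 1, size=(1000, d))
            v_obs += np.log(draws.max(1) / draws.min(1))
        samples = mc_null_sample(NullSpec(p=p, ds=ds, T=20_000, seed=123))
        pv = pvalues(v_obs, samples)
        assert np.all((pv > 0) & (pv <= 1))
        assert kstest(pv, "uniform").pvalue > 0.01


class TestBhSelect:
    def test_all_ones_select_nothing(self):
        res = bh_select(np.ones(5))
        assert not res.selected.any()
        assert np.all(np.isnan(res.q_values))  # all filtered at 0.9

    def test_hand_computed_example(self):
        # filter removes the 1.0; BH on {0.001, 0.002, 0.9}:
        # q = {0.003, 0.003, 0.9} -> two selected at alpha 0.05
        res = bh_select(np.array([0.001, 0.002, 0.9, 1.0]), alpha=0.05)
        assert list(res.selected) == [True, True, False, False]
        assert res.q_values[0] == pytest.approx(0.003)
        assert res.q_values[1] == pytest.approx(0.003)
        assert res.q_values[2] == pytest.approx(0.9)
        assert np.isnan(res.q_values[3])

    def test_identical_small_pvalues_all_selected(self):
        res = bh_select(np.full(20, 0.01), alpha=0.05)
        assert res.selected.all()

    def test_qvalues_monotone_in_pvalues(self, rng):
        pv = rng.uniform(0.001, 0.89, size=50)
        res = bh_select(pv)
        order = np.argsort(pv)
        q = res.q_values[order]
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_select(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_select(np.array([0.5, 1.5]))
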