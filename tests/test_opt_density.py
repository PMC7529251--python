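"""Mass allocation, OPT likelihood recursion and the pair-density estimator."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import beta as beta_fn

from censnet import (
    CNEConfig,
    Region,
    allocate_mass,
    density_covariance_diagnostic,
    estimate_bivariate_density,
    marginalize,
    opt_log_likelihood,
    region_mass,
)
from censnet.opt_density import MassAllocation, _PairTables


def make_alloc(x1, d1, x2, d2, hi1=None, hi2=None):
    hi1 = hi1 or 1.5 * max(x1)
    hi2 = hi2 or 1.5 * max(x2)
    return MassAllocation(
        allocate_mass(np.asarray(x1, float), np.asarray(d1), hi1),
        allocate_mass(np.asarray(x2, float), np.asarray(d2), hi2),
    )


class TestAllocateMass:
    def test_uncensored_are_point_masses(self):
        a = allocate_mass(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]), 4.5)
        assert a.weights.sum() == 3.0
        assert np.all(a.tail_weight == 0)
        np.testing.assert_array_equal(a.weights, np.eye(3))

    def test_censored_mass_follows_km_increments(self):
        # times (1,2,3,4), censored at 2: events at 1,3,4 with survival
        # 3/4, 3/8, 0; increments beyond 2 are 3/8 and 3/8, each 1/2 of S(2)=3/4
        a = allocate_mass(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 1]), 6.0)
        np.testing.assert_allclose(a.weights[1], [0.0, 0.5, 0.5])
        assert a.tail_weight[1] == 0.0

    def test_every_allocation_sums_to_one(self, rng):
        t = rng.exponential(1.0, 60)
        s = rng.integers(0, 2, 60)
        a = allocate_mass(t, s, 1.5 * t.max())
        np.testing.assert_allclose(a.totals(), 1.0, atol=1e-10)

    def test_residual_tail_mass_when_largest_observation_censored(self):
        a = allocate_mass(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]), 4.5)
        # S never reaches 0: the sample censored at 3 keeps all mass in the tail
        assert a.tail_weight[2] == pytest.approx(1.0)
        assert a.tail_lo[2] == 3.0
        np.testing.assert_allclose(a.totals(), 1.0)

    def test_censored_samples_always_have_positive_survival(self, rng):
        # under the events-before-censorings tie convention a censored sample
        # is in the risk set at its own time, so S(x) > 0 and the zero-survival
        # fallback is purely defensive; allocations stay well defined even
        # with heavy ties
        t = rng.integers(1, 6, 80).astype(float)  # many exact ties
        s = rng.integers(0, 2, 80)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            a = allocate_mass(t, s, 1.5 * t.max())
        np.testing.assert_allclose(a.totals(), 1.0, atol=1e-10)


class TestRegionMass:
    def test_root_mass_is_one(self, rng):
        t1, t2 = rng.exponential(1, 40), rng.exponential(1, 40)
        s1, s2 = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        alloc = make_alloc(t1, s1, t2, s2)
        assert region_mass(alloc, alloc.root) == pytest.approx(1.0, abs=1e-10)

    def test_two_point_count(self):
        alloc = make_alloc([1.0, 3.0], [1, 1], [1.0, 3.0], [1, 1], 4.0, 4.0)
        assert region_mass(alloc, Region(0, 2, 0, 2)) == pytest.approx(0.5)

    def test_outside_root_raises(self):
        alloc = make_alloc([1.0, 2.0], [1, 1], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="outside"):
            region_mass(alloc, Region(0, 100.0, 0, 1.0))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_additivity_under_halving(self, seed):
        r = np.random.default_rng(seed)
        t1, t2 = r.exponential(1, 30), r.exponential(1, 30)
        s1, s2 = r.integers(0, 2, 30), r.integers(0, 2, 30)
        alloc = make_alloc(t1, s1, t2, s2)
        region = Region(0.0, alloc.axis1.root_hi, 0.0, alloc.axis2.root_hi)
        for axis in (1, 2):
            c1, c2 = region.children(axis)
            total = region_mass(alloc, c1) + region_mass(alloc, c2)
            assert total == pytest.approx(region_mass(alloc, region), abs=1e-12)


def _phi_bruteforce(region, alloc, max_depth):
    """Explicit enumeration over all stop/split partition trees (linear space)."""
    n = alloc.n_samples
    n_a = n * region_mass(alloc, region)
    phi0 = region.area ** (-n_a)
    if region.depth >= max_depth:
        return phi0
    total = 0.5 * phi0
    for axis in (1, 2):
        c1, c2 = region.children(axis)
        w = (
            beta_fn(n * region_mass(alloc, c1) + 0.5, n * region_mass(alloc, c2) + 0.5)
            / beta_fn(0.5, 0.5)
        )
        total += 0.25 * w * _phi_bruteforce(c1, alloc, max_depth) * _phi_bruteforce(
            c2, alloc, max_depth
        )
    return total


class TestOPTLikelihood:
    def test_empty_region_has_unit_likelihood(self):
        alloc = make_alloc([1.0, 1.1], [1, 1], [1.0, 1.1], [1, 1], 4.0, 4.0)
        assert opt_log_likelihood(Region(3.0, 4.0, 3.0, 4.0), alloc, 3) == pytest.approx(0.0)

    def test_depth_limit_gives_uniform_likelihood(self):
        alloc = make_alloc([1.0, 2.0], [1, 1], [1.0, 2.0], [1, 1], 4.0, 4.0)
        root = Region(0, 4.0, 0, 4.0)
        assert opt_log_likelihood(root, alloc, 0) == pytest.approx(-2 * math.log(16.0))

    @pytest.mark.parametrize("max_depth", [1, 2])
    def test_matches_bruteforce_tree_enumeration(self, max_depth):
        alloc = make_alloc(
            [0.5, 1.2, 2.0, 2.8], [1, 1, 1, 1], [0.4, 1.5, 2.2, 2.9], [1, 1, 1, 1],
            4.2, 4.35,
        )
        root = Region(0, 4.2, 0, 4.35)
        expected = math.log(_phi_bruteforce(root, alloc, max_depth))
        assert opt_log_likelihood(root, alloc, max_depth) == pytest.approx(expected, rel=1e-10)

    def test_bruteforce_agrees_with_censoring(self):
        alloc = make_alloc(
            [0.5, 1.2, 2.0, 2.8], [1, 0, 1, 1], [0.4, 1.5, 2.2, 2.9], [1, 1, 0, 1],
            4.2, 4.35,
        )
        root = Region(0, 4.2, 0, 4.35)
        expected = math.log(_phi_bruteforce(root, alloc, 2))
        assert opt_log_likelihood(root, alloc, 2) == pytest.approx(expected, rel=1e-10)

    def test_fast_tables_equal_region_recursion(self, rng):
        t1, t2 = rng.exponential(1, 25), rng.exponential(1, 25)
        s1, s2 = rng.integers(0, 2, 25), rng.integers(0, 2, 25)
        alloc = make_alloc(t1, s1, t2, s2)
        tables = _PairTables(alloc.axis1, alloc.axis2, 4)
        root = Region(0.0, alloc.axis1.root_hi, 0.0, alloc.axis2.root_hi)
        slow = opt_log_likelihood(root, alloc, 4)
        assert tables.log_phi[(0, 0)][0, 0] == pytest.approx(slow, rel=1e-10)

    def test_no_overflow_at_large_n(self, rng):
        t1, t2 = rng.exponential(1, 10_000), rng.exponential(1, 10_000)
        s1, s2 = rng.integers(0, 2, 10_000), rng.integers(0, 2, 10_000)
        alloc = make_alloc(t1, s1, t2, s2)
        tables = _PairTables(alloc.axis1, alloc.axis2, 6)
        for arr in tables.log_phi.values():
            assert np.all(np.isfinite(arr))


class TestDensityEstimate:
    def test_integrates_to_one(self, small_dataset):
        d = estimate_bivariate_density(
            *small_dataset.sm.column(0), *small_dataset.sm.column(1)
        )
        assert d.integral() == pytest.approx(1.0, abs=1e-8)
        assert all(v >= 0 for _, v in d.leaves)

    def test_leaves_tile_root(self, small_dataset):
        d = estimate_bivariate_density(
            *small_dataset.sm.column(0), *small_dataset.sm.column(1)
        )
        total_area = sum(r.area for r, _ in d.leaves)
        assert total_area == pytest.approx(d.root.area, rel=1e-10)

    def test_uniform_data_recovers_flat_density(self):
        r = np.random.default_rng(21)
        n = 500
        x1, x2 = r.uniform(0, 1, n), r.uniform(0, 1, n)
        cfg = CNEConfig(tail_factor=1.0 / max(x1.max(), x2.max()))
        d = estimate_bivariate_density(x1, np.ones(n, int), x2, np.ones(n, int), cfg)
        # at least 90% of the mass should sit in leaves within 20% of flat
        flat = 1.0 / d.root.area
        good = sum(v * reg.area for reg, v in d.leaves if abs(v - flat) <= 0.2 * flat)
        assert good >= 0.9

    def test_independent_margins_give_near_zero_correlation(self):
        r = np.random.default_rng(22)
        n = 1000
        x1, x2 = r.lognormal(0, 0.5, n), r.lognormal(0, 0.5, n)
        d = estimate_bivariate_density(x1, np.ones(n, int), x2, np.ones(n, int))
        cov = density_covariance_diagnostic(d)
        m1, m2 = marginalize(d, 1), marginalize(d, 2)
        v1 = _marginal_var(m1)
        v2 = _marginal_var(m2)
        assert abs(cov / math.sqrt(v1 * v2)) < 0.1

    def test_status_is_read_not_mutated(self, rng):
        t1, t2 = rng.exponential(1, 50), rng.exponential(1, 50)
        ones = np.ones(50, int)
        before = ones.copy()
        d1 = estimate_bivariate_density(t1, ones, t2, ones)
        np.testing.assert_array_equal(ones, before)
        d2 = estimate_bivariate_density(t1, ones.copy(), t2, ones.copy())
        assert [(r, v) for r, v in d1.leaves] == [(r, v) for r, v in d2.leaves]

    def test_degenerate_input_yields_single_leaf(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = estimate_bivariate_density(
                np.full(12, 2.0), np.ones(12, int),
                np.arange(1.0, 13.0), np.ones(12, int),
            )
        assert len(d.leaves) == 1

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_bivariate_density([1.0] * 3, [1] * 3, [1.0] * 3, [1] * 3)


def _marginal_var(m):
    a, b = m.breakpoints[:-1], m.breakpoints[1:]
    ex = float(np.sum(m.values * (b ** 2 - a ** 2) / 2))
    ex2 = float(np.sum(m.values * (b ** 3 - a ** 3) / 3))
    return ex2 - ex ** 2


class TestMarginalize:
    def test_integrates_to_one(self, small_dataset):
        d = estimate_bivariate_density(
            *small_dataset.sm.column(0), *small_dataset.sm.column(1)
        )
        for axis in (1, 2):
            assert marginalize(d, axis).integral() == pytest.approx(1.0, abs=1e-8)

    def test_uniform_density_gives_uniform_marginal(self):
        from censnet import DensityEstimate

        root = Region(0, 2.0, 0, 4.0)
        d = DensityEstimate(leaves=[(root, 1 / 8.0)], root=root)
        m = marginalize(d, 1)
        np.testing.assert_allclose(m.values, 0.5)

    def test_matches_strip_quadrature(self):
        from censnet import DensityEstimate

        # hand-built 3-leaf density on [0,2]x[0,2]
        leaves = [
            (Region(0, 1, 0, 2), 0.15),
            (Region(1, 2, 0, 1), 0.5),
            (Region(1, 2, 1, 2), 0.2),
        ]
        root = Region(0, 2, 0, 2)
        d = DensityEstimate(leaves=leaves, root=root)
        m = marginalize(d, 1)

        def f(t1, t2):
            return d.evaluate(t1, t2)

        for probe in (0.3, 1.2, 1.9):
            expected = quad(lambda t2: f(probe, t2), 0, 2)[0]
            assert m.evaluate(probe) == pytest.approx(expected, abs=1e-10)

    def test_exactness_against_leaf_quadrature(self, small_dataset):
        d = estimate_bivariate_density(
            *small_dataset.sm.column(0), *small_dataset.sm.column(1)
        )
        m = marginalize(d, 2)
        probes = 0.5 * (m.breakpoints[:-1] + m.breakpoints[1:])[::7]
        for probe in probes:
            direct = sum(
                v * (r.hi1 - r.lo1)
                for r, v in d.leaves
                if r.lo2 <= probe < r.hi2
            )
            assert m.evaluate(float(probe)) == pytest.approx(direct, abs=1e-10)
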