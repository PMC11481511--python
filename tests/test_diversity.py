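"""Accumulation curves, singleton statistics, KS test, clustering comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paraphage.cluster import SpeciesPartition
from paraphage.diversity import (
    accumulation_exact,
    accumulation_montecarlo,
    build_incidence,
    compare_clusterings,
    ks_statistic,
    ks_two_sample,
    singleton_stats,
)
from paraphage.errors import ParameterError


def _random_incidence(t, s, seed, p=0.3):
    rng = np.random.default_rng(seed)
    inc = rng.random((t, s)) < p
    # every species present somewhere, every site non-empty
    for j in range(s):
        if not inc[:, j].any():
            inc[rng.integers(0, t), j] = True
    return inc.astype(int)


class TestAccumulationExact:
    def test_one_species_everywhere_is_flat(self):
        inc = np.ones((6, 1), dtype=int)
        curve = accumulation_exact(inc)
        np.testing.assert_allclose(curve.richness, 1.0)
        np.testing.assert_allclose(curve.sd, 0.0, atol=1e-12)

    def test_endpoint_equals_total_richness(self):
        inc = _random_incidence(12, 8, seed=1)
        curve = accumulation_exact(inc)
        assert curve.richness[-1] == pytest.approx(inc.shape[1], abs=1e-9)
        assert curve.sd[-1] == pytest.approx(0.0, abs=1e-9)

    def test_first_point_is_mean_per_site_richness(self):
        inc = _random_incidence(15, 10, seed=2)
        curve = accumulation_exact(inc)
        assert curve.richness[0] == pytest.approx(inc.sum(axis=1).mean(), abs=1e-9)

    def test_monotone_and_concave(self):
        inc = _random_incidence(20, 12, seed=3)
        e = accumulation_exact(inc).richness
        diffs = np.diff(e)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_exact_curve_within_monte_carlo_band(self):
        """Exact expectation vs 10,000 random orderings of a 20x15 incidence
        matrix: inside the 99% band of the Monte-Carlo mean at every n."""
        inc = _random_incidence(20, 15, seed=4)
        curve = accumulation_exact(inc)
        mc = accumulation_montecarlo(inc, n_draws=10_000, seed=5)
        lo = mc["mean_richness"] - 2.576 * mc["se"]
        hi = mc["mean_richness"] + 2.576 * mc["se"]
        inside = (curve.richness >= lo - 1e-9) & (curve.richness <= hi + 1e-9)
        assert inside.all()

    def test_individual_mode_endpoint(self):
        inc = _random_incidence(10, 6, seed=6)
        curve = accumulation_exact(inc, mode="individual")
        assert curve.richness[-1] == pytest.approx(6.0, abs=1e-9)
        assert (np.diff(curve.richness) >= -1e-9).all()

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ParameterError):
            accumulation_exact(np.empty((0, 3), dtype=int))
        with pytest.raises(ParameterError):
            accumulation_exact(np.ones((3, 3)), mode="bogus")

    def test_large_site_count_is_stable(self):
        # log-gamma evaluation must not overflow with thousands of sites
        rng = np.random.default_rng(7)
        ti = rng.integers(1, 2000, size=30)
        inc = np.zeros((2000, 30), dtype=int)
        for j, t in enumerate(ti):
            inc[rng.choice(2000, size=t, replace=False), j] = 1
        curve = accumulation_exact(inc)
        assert np.isfinite(curve.richness).all()
        assert curve.richness[-1] == pytest.approx(30.0, abs=1e-6)


class TestSingletonStats:
    def test_all_singletons(self):
        part = SpeciesPartition(species={f"s{i}": [f"p{i}"] for i in range(4)})
        st = singleton_stats(part)
        assert st.singleton_fraction == 1.0

    def test_one_big_cluster(self):
        part = SpeciesPartition(species={"s1": [f"p{i}" for i in range(5)]})
        assert singleton_stats(part).singleton_fraction == 0.0

    def test_mixed_sizes(self):
        species = {
            "a": ["p1"], "b": ["p2"], "c": ["p3"],
            "d": ["p4", "p5"], "e": [f"q{i}" for i in range(5)],
        }
        st = singleton_stats(SpeciesPartition(species=species))
        assert st.n_species == 5
        assert st.singleton_fraction == pytest.approx(0.6)
        assert dict(st.size_histogram) == {1: 3, 2: 1, 5: 1}


def _brute_force_d(x, y):
    """Oracle: evaluate |F_x - F_y| at every pooled point by counting."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2], [10, 11, 12])
        assert d == 1.0

    def test_exhaustive_cdf_example(self):
        # x={1,2,3}, y={1,2,4}: sup over the 6 pooled points is 1/3
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 4])
        assert d == pytest.approx(1 / 3, abs=1e-12)
        assert d == pytest.approx(_brute_force_d([1, 2, 3], [1, 2, 4]), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_statistic_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=4).tolist()
        y = rng.integers(0, 5, size=4).tolist()
        assert ks_statistic(x, y) == pytest.approx(_brute_force_d(x, y), abs=1e-10)

    def test_exact_permutation_p_on_tiny_samples(self):
        """Total size <= 8: exact permutation p equals a from-scratch
        enumeration over all label assignments."""
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0, 8.0]
        d, p = ks_two_sample(x, y, method="exact")
        pooled = x + y
        count = total = 0
        for comb in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(8) if i not in comb]
            total += 1
            if _brute_force_d(xs, ys) >= d - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-10)

    def test_invariance_under_monotone_transform(self):
        x = [0.5, 1.5, 2.0, 4.0]
        y = [1.0, 2.5, 3.0]
        d1 = ks_statistic(x, y)
        d2 = ks_statistic([v ** 3 for v in x], [v ** 3 for v in y])
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_statistic_matches_scipy_and_p_is_calibrated(self):
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        d, p = ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert 0.0 < p < 1.0
        # a same-distribution comparison must not look significant
        _, p_null = ks_two_sample(rng.normal(size=50), rng.normal(size=50))
        assert p_null > 0.05


class TestBuildIncidence:
    def test_binary_and_count_modes(self):
        part = SpeciesPartition(species={"s1": ["p1", "p2"], "s2": ["p3"]})
        pg = {"p1": "g1", "p2": "g2", "p3": "g1"}
        inc = build_incidence(part, pg)
        assert inc.loc["g1"].tolist() == [1, 1]
        assert inc.loc["g2"].tolist() == [1, 0]
        counts = build_incidence(part, pg, binary=False)
        assert counts.values.sum() == 3

    def test_explicit_site_set_includes_empty_genomes(self):
        part = SpeciesPartition(species={"s1": ["p1"]})
        inc = build_incidence(part, {"p1": "g1"}, genomes=["g1", "g2"])
        assert inc.loc["g2"].sum() == 0


class TestCompareClusterings:
    def test_identical_partitions(self):
        part = SpeciesPartition(species={"s1": ["a", "b"], "s2": ["c"]})
        cmp = compare_clusterings(part, part)
        assert cmp.ks_D == 0.0
        assert cmp.refinement_holds
        assert cmp.mapping == {"s1": "s1", "s2": "s2"}

    def test_strict_singletons_into_one_lenient_cluster(self):
        strict = SpeciesPartition(species={f"s{i}": [f"p{i}"] for i in range(4)})
        lenient = SpeciesPartition(species={"L": [f"p{i}" for i in range(4)]})
        cmp = compare_clusterings(strict, lenient)
        assert cmp.refinement_holds
        assert set(cmp.mapping.values()) == {"L"}

    def test_split_cluster_is_violation(self):
        strict = SpeciesPartition(species={"s1": ["a", "b"]})
        lenient = SpeciesPartition(species={"x": ["a"], "y": ["b"]})
        cmp = compare_clusterings(strict, lenient)
        assert cmp.refinement_violations == ["s1"]

    def test_id_mismatch_rejected(self):
        a = SpeciesPartition(species={"s1": ["a"]})
        b = SpeciesPartition(species={"s1": ["b"]})
        with pytest.raises(ParameterError):
            compare_clusterings(a, b)
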