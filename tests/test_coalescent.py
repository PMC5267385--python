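import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from zeascan.coalescent import (
    DemographicModel,
    SimConfig,
    critical_values,
    mutate,
    percentile_of,
    replicate_seeds,
    simulate_genealogy,
    simulate_null,
    simulate_replicate,
)


class TestDemographicModel:
    def test_bottleneck_epochs_and_severity(self):
        m = DemographicModel.bottleneck(0.01, 0.0204, 0.05, 1.0)
        assert [e[1] for e in m.epochs] == [1.0, 0.05, 1.0]
        assert [e[0] for e in m.epochs] == pytest.approx([0.0, 0.01, 0.0304])
        assert m.severity == pytest.approx(2.45, abs=0.01)
        assert m.size_at(0.005) == 1.0
        assert m.size_at(0.02) == 0.05
        assert m.size_at(0.5) == 1.0

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(epochs=((0.1, 1.0),))
        with pytest.raises(ValueError):
            DemographicModel(epochs=((0.0, 1.0), (0.0, 0.5)))
        with pytest.raises(ValueError):
            DemographicModel(epochs=((0.0, -1.0),))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n=3, theta=5)
        with pytest.raises(ValueError):
            SimConfig(n=10, theta=-1)


class TestSimulator:
    def test_pairwise_expectation_n2(self):
        """E[pairwise differences] = theta for a sample of two."""
        rng = np.random.default_rng(8)
        model = DemographicModel.constant()
        diffs = []
        for _ in range(6000):
            gen = simulate_genealogy(["p", "p"], {"p": model}, rng=rng)
            m = mutate(gen, 4.0, rng)
            diffs.append(m.num_sites)
        assert np.mean(diffs) == pytest.approx(4.0, rel=0.05)

    def test_tiny_theta_yields_no_sites(self):
        model = DemographicModel.constant()
        for child in replicate_seeds(4, 30):
            rng = np.random.default_rng(child)
            m = simulate_replicate(SimConfig(n=6, theta=1e-9), model, rng)
            assert m.num_sites == 0

    def test_fixed_s_mode(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(n=6, theta=1.0, fixed_s=7)
        m = simulate_replicate(cfg, DemographicModel.constant(), rng)
        assert m.num_sites == 7

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(n=10, theta=4, reps=50, seed=99)
        model = DemographicModel.bottleneck(0.01, 0.02, 0.1)
        a = simulate_null(cfg, model, ["tajima_d", "S"])
        b = simulate_null(cfg, model, ["tajima_d", "S"])
        for k in a:
            assert np.array_equal(a[k].values, b[k].values)
            assert a[k].na_count == b[k].na_count

    def test_single_replicate_distribution(self):
        cfg = SimConfig(n=6, theta=5, reps=1, seed=2)
        out = simulate_null(cfg, DemographicModel.constant(), ["S"])
        assert out["S"].size <= 1

    def test_all_na_raises_theta_too_small(self):
        cfg = SimConfig(n=6, theta=1e-9, reps=20, seed=1)
        with pytest.raises(ValueError, match="theta too small"):
            simulate_null(cfg, DemographicModel.constant(), ["tajima_d"])

    def test_na_accounting(self):
        cfg = SimConfig(n=6, theta=0.3, reps=300, seed=5)
        out = simulate_null(cfg, DemographicModel.constant(), ["tajima_d", "S"])
        assert out["tajima_d"].size + out["tajima_d"].na_count == 300
        assert out["S"].na_count == 0  # S = 0 is a value, not an NA

    def test_bottleneck_shifts_tajimas_d_distribution(self):
        """A severity-2.45 bottleneck visibly distorts the D null."""
        bottleneck = DemographicModel.bottleneck(0.01, 0.0204, 0.05)
        a = simulate_null(SimConfig(n=20, theta=5, reps=3000, seed=31),
                          bottleneck, ["tajima_d"])["tajima_d"]
        b = simulate_null(SimConfig(n=20, theta=5, reps=3000, seed=32),
                          DemographicModel.constant(), ["tajima_d"])["tajima_d"]
        assert ks_2samp(a.values, b.values).pvalue < 0.01

    def test_segregating_sites_match_msprime_oracle(self):
        """Cross-validation of the S null against an independent simulator."""
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 12, 6.0, 10000
        model = DemographicModel.bottleneck(0.01, 0.0204, 0.05)
        mine = simulate_null(SimConfig(n=n, theta=theta, reps=reps, seed=21),
                             model, ["S"])["S"].values
        demog = msprime.Demography()
        demog.add_population(name="p", initial_size=0.5)
        for t, x in model.epochs[1:]:
            demog.add_population_parameters_change(
                time=t, initial_size=0.5 * x, population="p"
            )
        rng = np.random.default_rng(123)
        s_ref = []
        for _ in range(reps):
            ts = msprime.sim_ancestry(
                samples={"p": n}, demography=demog, ploidy=1,
                sequence_length=1,
                random_seed=int(rng.integers(1, 2**31)),
            )
            mts = msprime.sim_mutations(
                ts, rate=theta, discrete_genome=False,
                random_seed=int(rng.integers(1, 2**31)),
            )
            s_ref.append(mts.num_sites)
        assert ks_2samp(mine, np.array(s_ref)).pvalue > 0.01


class TestStructuredGenealogy:
    def test_two_demes_cannot_coalesce_before_merge(self):
        rng = np.random.default_rng(6)
        model = DemographicModel.constant()
        for _ in range(50):
            gen = simulate_genealogy(
                ["a", "a", "b", "b"], {"a": model, "b": model},
                merges=[(1.5, "a", "b")], rng=rng,
            )
            # any node joining lineages across demes must postdate the merge
            cross = [
                t for t, mask in zip(gen.node_times, gen.leaf_masks)
                if (mask & 0b0011) and (mask & 0b1100) and mask != 0
            ]
            assert min(cross) >= 1.5

    def test_unmergeable_populations_raise(self):
        rng = np.random.default_rng(1)
        with pytest.raises(RuntimeError, match="stranded"):
            simulate_genealogy(
                ["a", "a", "b", "b"],
                {"a": DemographicModel.constant(),
                 "b": DemographicModel.constant()},
                merges=[], rng=rng,
            )


class TestPercentiles:
    def test_below_minimum_is_zero(self):
        assert percentile_of(-10.0, np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == 0.0

    def test_median_of_odd_distribution_is_fifty(self):
        assert percentile_of(0.0, np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == 50.0

    def test_mid_rank_between_values(self):
        # -1.75 sits above one of five values and ties none
        assert percentile_of(-1.75, np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == 20.0

    def test_ties_take_middle_rank(self):
        assert percentile_of(1.0, np.array([0.0, 1.0, 1.0, 2.0])) == 50.0

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            percentile_of(0.0, np.array([]))

    @settings(derandomize=True, max_examples=60)
    @given(
        values=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=1, max_size=40
        ),
        a=st.floats(-60, 60, allow_nan=False),
        b=st.floats(-60, 60, allow_nan=False),
    )
    def test_percentile_bounded_and_monotone(self, values, a, b):
        dist = np.sort(np.asarray(values))
        pa, pb = percentile_of(a, dist), percentile_of(b, dist)
        assert 0.0 <= pa <= 100.0
        if a <= b:
            assert pa <= pb
        else:
            assert pa >= pb


class TestCriticalValues:
    def test_interpolated_tails(self):
        values = np.arange(10001) / 100.0  # 0.00 .. 100.00
        lo, hi = critical_values(values, alpha=0.05)
        assert lo == pytest.approx(2.5, abs=0.01)
        assert hi == pytest.approx(97.5, abs=0.01)

    def test_symmetric_distribution_has_mirrored_tails(self):
        rng = np.random.default_rng(12)
        values = rng.standard_normal(20000)
        lo, hi = critical_values(values)
        assert lo == pytest.approx(-hi, abs=0.1)

    def test_small_distribution_rejected(self):
        with pytest.raises(ValueError):
            critical_values(np.arange(10))

    def test_alpha_one_degenerates_to_range(self):
        values = np.arange(100.0)
        lo, hi = critical_values(values, alpha=1.0)
        assert (lo, hi) == (0.0, 99.0)
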