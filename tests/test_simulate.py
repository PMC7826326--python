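"""Unit and property tests for the erasure-process simulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forgetsim as fs
from _oracles import (
    brute_force_full_erasure,
    brute_force_single_erasure,
    is_linear_extension,
)


class TestFullErasure:
    def test_direct_rule_application(self):
        """A stronger item erases all weaker stored items, retroactively only."""
        res = fs.present_in_order([0.3, 0.7, 0.5])
        assert res.erasure_time.tolist() == [2, fs.SURVIVED, fs.SURVIVED]
        assert res.stored_at(3).tolist() == [1, 2]
        assert res.store_size.tolist() == [1, 1, 2]

    def test_new_item_never_erased_on_own_step(self):
        res = fs.present_in_order([0.5, 0.5, 0.5])  # ties: nobody dominates
        assert (res.erasure_time == fs.SURVIVED).all()

    @pytest.mark.parametrize("n_dims,seed", [(1, 0), (1, 1), (2, 2), (3, 3)])
    def test_matches_brute_force_oracle(self, n_dims, seed):
        """Optimised engines agree with literal O(T^2) rule application."""
        cfg = fs.SimulationConfig("full_erasure", T=300, n_dims=n_dims, seed=seed)
        res = fs.simulate_full_erasure(cfg)
        expected = brute_force_full_erasure(res.valences)
        np.testing.assert_array_equal(res.erasure_time, expected)

    def test_fast_path_matches_generic_engine(self):
        """The scalar monotone-stack path equals the general engine."""
        cfg = fs.SimulationConfig("full_erasure", T=5000, n_dims=1, seed=11)
        res = fs.simulate_full_erasure(cfg)
        generic = fs.present_in_order(res.valences)
        np.testing.assert_array_equal(res.erasure_time, generic.erasure_time)
        np.testing.assert_array_equal(res.store_size, generic.store_size)

    def test_retained_valences_increase_with_age(self):
        """Scalar model: the store always orders valence by item age."""
        cfg = fs.SimulationConfig("full_erasure", T=20_000, seed=5)
        res = fs.simulate_full_erasure(cfg)
        for step in (100, 5000, 20_000):
            stored = res.stored_at(step)  # acquisition order: oldest first
            vals = res.valences[stored, 0]
            assert (np.diff(vals) < 0).all()

    @pytest.mark.parametrize("n_dims", [2, 3])
    def test_no_stored_item_dominated_by_later_one(self, n_dims):
        """Erasure is retroactive: nothing in the store is dominated by a
        later-acquired stored item (the n-D analogue of the scalar
        valence-increases-with-age chain)."""
        cfg = fs.SimulationConfig("full_erasure", T=3000, n_dims=n_dims, seed=7)
        res = fs.simulate_full_erasure(cfg)
        for step in (50, 500, 3000):
            v = res.valences[res.stored_at(step)]  # acquisition order
            later_dominates = (v[None, :, :] > v[:, None, :]).all(axis=2)
            # only the upper triangle (j acquired after i) must be empty
            assert not np.triu(later_dominates, k=1).any()

    def test_store_size_bookkeeping(self):
        """Store size changes by +1 minus erasures and stays >= 1."""
        cfg = fs.SimulationConfig("full_erasure", T=1000, n_dims=2, seed=9)
        res = fs.simulate_full_erasure(cfg)
        assert (res.store_size >= 1).all()
        erased_per_step = np.bincount(
            res.erasure_time[~res.survived], minlength=1001
        )[1:]
        deltas = np.diff(np.concatenate([[0], res.store_size]))
        np.testing.assert_array_equal(deltas, 1 - erased_per_step)

    def test_retention_matches_inverse_law(self):
        """Scalar-model survival tracks 1/(t+1) within Monte-Carlo error."""
        cfg = fs.SimulationConfig("full_erasure", T=20_000, seed=100)
        lags = np.array([1, 10, 100])
        est = fs.replicate_retention(cfg, n_replicates=50, lags=lags)
        expected = 1.0 / (lags + 1)
        z = (est["mean_survival"] - expected) / est["se"]
        assert (np.abs(z) < 3).all()

    def test_two_dimensional_survival_at_lag_one(self):
        """P(survive one follower) with two dimensions is 3/4."""
        rng = np.random.default_rng(42)
        v = rng.random((20_000, 2, 2))
        survived = np.array(
            [fs.present_in_order(pair).erasure_time[0] == fs.SURVIVED for pair in v]
        )
        p = survived.mean()
        se = np.sqrt(p * (1 - p) / survived.size)
        assert abs(p - 0.75) < 3 * se

    def test_distribution_invariance(self):
        """Retention is distribution-free: uniform and exponential agree."""
        lags = np.array([1, 10, 50])
        a = fs.replicate_retention(
            fs.SimulationConfig("full_erasure", T=10_000, seed=0),
            n_replicates=25,
            lags=lags,
        )
        b = fs.replicate_retention(
            fs.SimulationConfig(
                "full_erasure",
                T=10_000,
                valence_distribution=fs.DistributionSpec("expon"),
                seed=500,
            ),
            n_replicates=25,
            lags=lags,
        )
        z = (a["mean_survival"] - b["mean_survival"]) / np.sqrt(
            a["se"] ** 2 + b["se"] ** 2
        )
        assert (np.abs(z) < 3).all()

    def test_rejects_distribution_with_atoms(self):
        with pytest.raises(ValueError, match="continuous"):
            fs.SimulationConfig(
                "full_erasure",
                T=10,
                valence_distribution=fs.DistributionSpec("bernoulli", {"p": 0.5}),
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_erasure_is_next_dominating_item(self, seed):
        """Scalar full erasure: erasure step is the first later, larger item."""
        rng = np.random.default_rng(seed)
        v = rng.random(60)
        res = fs.present_in_order(v)
        for i in range(60):
            later = np.nonzero(v[i + 1 :] > v[i])[0]
            expected = fs.SURVIVED if later.size == 0 else i + 2 + later[0]
            assert res.erasure_time[i] == expected


class TestSingleErasure:
    def test_direct_rule_application(self):
        """Only the stored minimum dies, and only to a larger newcomer."""
        from forgetsim.simulate import _single_erasure_engine

        v = np.array([0.5, 0.2, 0.9])
        erasure, store_size = _single_erasure_engine(v)
        # step 2: 0.2 is itself the minimum -> nothing erased;
        # step 3: 0.9 > min(0.2) -> item 2 erased; final store {0.5, 0.9}
        assert erasure.tolist() == [fs.SURVIVED, 3, fs.SURVIVED]
        assert store_size.tolist() == [1, 2, 2]
        np.testing.assert_array_equal(erasure, brute_force_single_erasure(v))

    def test_single_step_horizon(self):
        res = fs.simulate_single_erasure(fs.SimulationConfig("single_erasure", T=1))
        assert res.store_size.tolist() == [1]
        assert res.erasure_time.tolist() == [fs.SURVIVED]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cfg = fs.SimulationConfig("single_erasure", T=400, seed=seed)
        res = fs.simulate_single_erasure(cfg)
        np.testing.assert_array_equal(
            res.erasure_time, brute_force_single_erasure(res.valences)
        )

    def test_store_size_never_decreases(self):
        cfg = fs.SimulationConfig("single_erasure", T=5000, seed=3)
        res = fs.simulate_single_erasure(cfg)
        assert (np.diff(res.store_size) >= 0).all()

    def test_store_grows_at_rate_one_over_e(self):
        """N(T)/T approaches 1/e; the late-time growth slope does too."""
        T = 20_000
        ratios, slopes = [], []
        for seed in range(10):
            res = fs.simulate_single_erasure(
                fs.SimulationConfig("single_erasure", T=T, seed=seed)
            )
            ratios.append(res.store_size[-1] / T)
            steps = np.arange(T // 2, T)
            slopes.append(np.polyfit(steps, res.store_size[T // 2 :], 1)[0])
        for sample in (ratios, slopes):
            sample = np.asarray(sample)
            se = sample.std(ddof=1) / np.sqrt(sample.size)
            assert abs(sample.mean() - 1 / np.e) < 3 * se


class TestLinearDecay:
    def test_deterministic_strength_crossing(self):
        """Strength 1 - 0.25 * age hits zero at age 4."""
        cfg = fs.SimulationConfig(
            "linear_decay",
            T=10,
            strength_distribution=fs.DistributionSpec("constant", {"value": 1.0}),
            decay_distribution=fs.DistributionSpec("constant", {"value": 0.25}),
        )
        res = fs.simulate_linear_decay(cfg)
        expected = np.where(
            res.acquisition_time + 4 <= 10, res.acquisition_time + 4, fs.SURVIVED
        )
        np.testing.assert_array_equal(res.erasure_time, expected)

    def test_zero_decay_rate_never_forgets(self):
        cfg = fs.SimulationConfig(
            "linear_decay",
            T=50,
            decay_distribution=fs.DistributionSpec("constant", {"value": 0.0}),
        )
        res = fs.simulate_linear_decay(cfg)
        assert (res.erasure_time == fs.SURVIVED).all()
        assert res.store_size.tolist() == list(range(1, 51))

    def test_rejects_negative_support(self):
        with pytest.raises(ValueError, match="non-negative"):
            fs.SimulationConfig(
                "linear_decay",
                T=10,
                decay_distribution=fs.DistributionSpec("norm"),
            )

    def test_survival_scales_inversely_with_lag(self):
        """Uniform a, b: survival at lag tau is 1/(2 tau) for tau >= 1."""
        cfg = fs.SimulationConfig("linear_decay", T=200_000, seed=8)
        res = fs.simulate_linear_decay(cfg)
        curve = fs.empirical_retention(res, 100)
        for tau in (10, 100):
            row = curve.iloc[tau]
            p = row["survival_fraction"]
            se = np.sqrt(p * (1 - p) / row["n_at_risk"])
            assert abs(p - 1 / (2 * tau)) < 3 * se


class TestEmpiricalRetention:
    def test_no_erasures_gives_unit_curve(self):
        # descending valences: no newcomer ever dominates, nothing is erased
        res = fs.present_in_order([0.9, 0.7, 0.5, 0.3, 0.1])
        curve = fs.empirical_retention(res, 3)
        assert (curve["survival_fraction"] == 1.0).all()

    def test_single_item_erased_at_age_three(self):
        res = fs.present_in_order([0.2, 0.1, 0.15, 0.9])
        # item 1 (0.2) erased by 0.9 at step 4 -> age 3
        curve = fs.empirical_retention(res, 3)
        assert curve["survival_fraction"].tolist() == [1.0, 1.0, 1.0, 0.0]

    def test_monotone_and_bounded(self):
        cfg = fs.SimulationConfig("full_erasure", T=5000, seed=2)
        curve = fs.empirical_retention(fs.simulate(cfg), 200)
        frac = curve["survival_fraction"].to_numpy()
        assert frac[0] == 1.0
        assert (np.diff(frac) <= 0).all()
        assert (
            (curve["ci_low"] <= frac) & (frac <= curve["ci_high"])
        ).all()

    def test_window_must_fit_horizon(self):
        res = fs.present_in_order([0.1, 0.9])
        with pytest.raises(ValueError, match="max_lag"):
            fs.empirical_retention(res, 2)


class TestPresentationOrder:
    def test_dominators_first_explicit(self):
        res = fs.present_in_order([(0.9, 0.9), (0.5, 0.5), (0.1, 0.8)])
        assert (res.erasure_time == fs.SURVIVED).all()

    def test_dominated_first_is_erased(self):
        res = fs.present_in_order([(0.5, 0.5), (0.9, 0.9), (0.1, 0.8)])
        assert res.erasure_time.tolist() == [2, fs.SURVIVED, fs.SURVIVED]

    def test_sorted_presentation_prevents_all_erasure(self):
        """Any dominators-first order of random items yields zero erasures."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            items = rng.random((100, 2))
            order = fs.dominators_first_order(items)
            assert is_linear_extension(order, items)
            res = fs.present_in_order(items[order])
            assert (res.erasure_time == fs.SURVIVED).all()


class TestConfigValidation:
    def test_variant_dimensionality_constraints(self):
        with pytest.raises(ValueError, match="n_dims"):
            fs.SimulationConfig("single_erasure", T=10, n_dims=2)
        with pytest.raises(ValueError, match="variant"):
            fs.SimulationConfig("total_recall", T=10)
        with pytest.raises(ValueError, match="T"):
            fs.SimulationConfig("full_erasure", T=0)

    def test_replicates_are_reproducible(self):
        cfg = fs.SimulationConfig("full_erasure", T=500, n_dims=2, seed=77)
        a = fs.simulate(cfg)
        b = fs.simulate(cfg)
        np.testing.assert_array_equal(a.erasure_time, b.erasure_time)
        np.testing.assert_array_equal(a.valences, b.valences)
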