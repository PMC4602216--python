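"""Branching-process amplification models: kernels, driver, error model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, ks_2samp

from umisim.pcr_models import (
    ModelConfig,
    amplify,
    cycle_model1,
    cycle_model2,
    cycle_model3,
    cycle_model4,
    cycle_model5,
    cycle_model6,
    expected_final_copies,
    make_lineages,
    mutate_copy,
    truncated_normal_mean,
)
from umisim.barcode_pool import make_pool

KS_ALPHA = 0.01


class TestModelConfig:
    def test_rejects_bad_model_id(self):
        with pytest.raises(ValueError):
            ModelConfig(model=7)

    @pytest.mark.parametrize(
        "kw",
        [
            {"efficiency": 1.5},
            {"degradation": -0.1},
            {"resource": 0.0},
            {"resource_decay": -1.0},
            {"eff_sd": -0.5},
            {"cycles": 0},
            {"error_rate": 2.0},
        ],
    )
    def test_rejects_out_of_range_parameters(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)


class TestCycleKernels:
    def test_certain_and_impossible_replication(self, rng):
        assert cycle_model1(np.array([5]), 1.0, rng)[0] == 10
        assert cycle_model1(np.array([5]), 0.0, rng)[0] == 5

    def test_constant_efficiency_law_of_large_numbers(self, rng):
        out = cycle_model1(np.array([10**6]), 0.5, rng)
        assert out[0] / 10**6 == pytest.approx(1.5, abs=0.002)

    def test_degradation_expectation(self, rng):
        """E[growth] = 1 + e - (1-e)d for the target-degradation model."""
        out = cycle_model2(np.array([10**6]), 0.5, 0.5, rng)
        assert out[0] / 10**6 == pytest.approx(1.25, abs=0.002)

    def test_full_degradation_of_failures_empties_population(self, rng):
        assert cycle_model2(np.array([1000]), 0.0, 1.0, rng)[0] == 0

    def test_excess_resource_means_certain_replication(self, rng):
        copies = np.array([10, 20])
        out = cycle_model3(copies, resource_abs=1e9, rng=rng)
        np.testing.assert_array_equal(out, 2 * copies)

    def test_resource_limited_expected_increment(self, rng):
        """Once M >> R, each cycle adds about R molecules."""
        out = cycle_model3(np.array([10**6]), resource_abs=10**4, rng=rng)
        assert out[0] - 10**6 == pytest.approx(10**4, rel=0.05)

    def test_consumed_resource_is_decremented_by_successes(self, rng):
        copies, left = cycle_model4(np.array([100]), 1e6, 2.0, rng)
        gained = int(copies.sum()) - 100
        assert gained == 100  # p_t = 1
        assert left == 1e6 - 2.0 * gained

    def test_exhausted_resource_stops_growth(self, rng):
        copies, left = cycle_model4(np.array([100]), 0.0, 1.0, rng)
        assert copies[0] == 100 and left == 0.0

    def test_variable_efficiency_rejects_negative_sd(self, rng):
        with pytest.raises(ValueError):
            cycle_model5(np.array([5]), 0.5, -1.0, rng)

    def test_wide_truncation_symmetric_about_half(self):
        """mu=0.5 with huge sd: truncation to [0,1] is symmetric, mean 0.5."""
        assert truncated_normal_mean(0.5, 10.0) == pytest.approx(0.5, abs=1e-9)

    def test_inherited_efficiency_requires_valid_values(self, rng):
        with pytest.raises(ValueError):
            cycle_model6(np.array([5]), np.array([np.nan]), rng)
        with pytest.raises(ValueError):
            cycle_model6(np.array([5]), np.array([1.2]), rng)


class TestAmplify:
    def test_perfect_efficiency_doubles_every_cycle(self):
        pool = amplify(
            make_lineages(n=1), ModelConfig(model=1, cycles=3, efficiency=1.0),
            seed=0,
        )
        assert pool.copies[0] == 8
        np.testing.assert_array_equal(
            pool.per_cycle_population, [1, 2, 4, 8]
        )

    def test_zero_efficiency_never_amplifies(self):
        pool = amplify(
            make_lineages(n=5), ModelConfig(model=1, cycles=9, efficiency=0.0),
            seed=0,
        )
        assert pool.total_molecules == 5

    def test_branching_expectation_within_one_percent(self):
        """Mean copies tracks (1+e)^c (Galton-Watson expectation)."""
        e, c = 0.9, 25
        pool = amplify(
            make_lineages(n=10**4),
            ModelConfig(model=1, cycles=c, efficiency=e, population_cap=10**12),
            seed=1,
        )
        assert pool.copies.mean() == pytest.approx(
            expected_final_copies(e, c), rel=0.01
        )

    def test_first_cycle_failures_form_shoulder_at_half_the_mode(self):
        """Lineages missing cycle 1 end near (1+e)^(c-1): mass ~ (1-e)."""
        e, c = 0.9, 25
        pool = amplify(
            make_lineages(n=10**4),
            ModelConfig(model=1, cycles=c, efficiency=e, population_cap=10**12),
            seed=2,
        )
        rel = pool.copies / expected_final_copies(e, c)
        shoulder = np.mean((rel > 0.4) & (rel < 0.7))
        assert 0.5 * (1 - e) < shoulder < 2.0 * (1 - e)

    def test_trajectory_non_decreasing_except_model2(self):
        for model, kw in [
            (1, {"efficiency": 0.7}),
            (3, {"resource": 3.0}),
            (4, {"resource": 3.0, "resource_decay": 0.5}),
            (5, {"eff_mean": 0.6, "eff_sd": 0.2}),
            (6, {"eff_mean": 0.6, "eff_sd": 0.2}),
        ]:
            pool = amplify(
                make_lineages(n=500), ModelConfig(model=model, cycles=8, **kw),
                seed=3,
            )
            assert np.all(np.diff(pool.per_cycle_population) >= 0), model
            assert len(pool.per_cycle_population) == 9
            assert pool.total_molecules == pool.per_cycle_population[-1]

    def test_model2_copies_never_negative_and_can_shrink(self):
        pool = amplify(
            make_lineages(n=2000),
            ModelConfig(model=2, cycles=10, efficiency=0.1, degradation=0.9),
            seed=4,
        )
        assert np.all(pool.copies >= 0)
        assert pool.total_molecules < 2000  # heavy degradation shrinks

    def test_resource_conservation_bound(self):
        """delta=1, R0=k*M0: lifetime successes cannot exceed k*M0."""
        k, n0 = 3.0, 1000
        pool = amplify(
            make_lineages(n=n0),
            ModelConfig(model=4, cycles=30, resource=k, resource_decay=1.0),
            seed=5,
        )
        assert pool.total_molecules - n0 <= k * n0

    def test_model3_long_run_increment_equals_resource(self):
        pool = amplify(
            make_lineages(n=1000), ModelConfig(model=3, cycles=20, resource=2.0),
            seed=6,
        )
        late = np.diff(pool.per_cycle_population)[-5:]
        assert np.mean(late) == pytest.approx(2000, rel=0.05)

    def test_model6_extreme_efficiencies(self):
        lineages = make_lineages(n=2)
        cfg = ModelConfig(model=6, cycles=10, eff_mean=0.5, eff_sd=0.0)
        pool = amplify(lineages, cfg, seed=7)
        # sigma=0 gives every lineage the same inherited efficiency
        assert all(
            lin.inherited_efficiency == pytest.approx(0.5)
            for lin in pool.lineages
        )

    def test_population_cap_aborts_with_clear_error(self):
        with pytest.raises(RuntimeError, match="cap"):
            amplify(
                make_lineages(n=1000),
                ModelConfig(
                    model=1, cycles=20, efficiency=1.0, population_cap=10**5
                ),
                seed=8,
            )

    def test_seed_contract_bit_identical(self):
        cfg = ModelConfig(model=2, cycles=12, efficiency=0.7, degradation=0.2)
        a = amplify(make_lineages(n=300), cfg, seed=9)
        b = amplify(make_lineages(n=300), cfg, seed=9)
        np.testing.assert_array_equal(a.copies, b.copies)

    def test_mean_copies_monotone_in_efficiency_and_mu(self):
        means_1 = [
            amplify(
                make_lineages(n=3000),
                ModelConfig(model=1, cycles=8, efficiency=e),
                seed=10,
            ).copies.mean()
            for e in (0.2, 0.5, 0.8)
        ]
        assert means_1 == sorted(means_1)
        means_6 = [
            amplify(
                make_lineages(n=3000),
                ModelConfig(model=6, cycles=8, eff_mean=mu, eff_sd=0.2),
                seed=11,
            ).copies.mean()
            for mu in (0.3, 0.5, 0.7)
        ]
        assert means_6 == sorted(means_6)


class TestExactPmfOracle:
    """Exact final-copy pmf by dynamic programming over binomial outcomes."""

    @staticmethod
    def exact_pmf(e: float, cycles: int) -> dict[int, float]:
        pmf = {1: 1.0}
        for _ in range(cycles):
            nxt: dict[int, float] = {}
            for m, p in pmf.items():
                for s in range(m + 1):
                    nxt[m + s] = nxt.get(m + s, 0.0) + p * binom.pmf(s, m, e)
            pmf = nxt
        return pmf

    @pytest.mark.parametrize("e", [0.25, 0.5])
    @pytest.mark.parametrize("cycles", [1, 2, 3])
    def test_simulation_matches_enumeration(self, e, cycles):
        n = 10**5
        sim = amplify(
            make_lineages(n=n), ModelConfig(model=1, cycles=cycles, efficiency=e),
            seed=12,
        ).copies
        ks, cs = np.unique(sim, return_counts=True)
        freq = dict(zip(ks.tolist(), (cs / n).tolist()))
        for m, p in self.exact_pmf(e, cycles).items():
            se = max(np.sqrt(p * (1 - p) / n), 1e-9)
            assert abs(freq.get(m, 0.0) - p) < 3 * se, (m, p)


class TestModelEquivalences:
    """Degenerate-parameter models collapse onto the basic branching process."""

    def _copies(self, cfg: ModelConfig, seed: int, n=10**4):
        return amplify(make_lineages(n=n), cfg, seed=seed).copies

    def test_model2_without_degradation_is_model1(self):
        a = self._copies(ModelConfig(model=1, cycles=10, efficiency=0.8), 20)
        b = self._copies(
            ModelConfig(model=2, cycles=10, efficiency=0.8, degradation=0.0), 21
        )
        assert ks_2samp(a, b).pvalue > KS_ALPHA

    def test_model4_without_decay_is_model3(self):
        a = self._copies(ModelConfig(model=3, cycles=10, resource=5.0), 22)
        b = self._copies(
            ModelConfig(model=4, cycles=10, resource=5.0, resource_decay=0.0),
            23,
        )
        assert ks_2samp(a, b).pvalue > KS_ALPHA

    def test_model5_without_spread_is_model1(self):
        a = self._copies(ModelConfig(model=1, cycles=10, efficiency=0.6), 24)
        b = self._copies(
            ModelConfig(model=5, cycles=10, eff_mean=0.6, eff_sd=0.0), 25
        )
        assert ks_2samp(a, b).pvalue > KS_ALPHA

    def test_model6_without_spread_is_model1(self):
        a = self._copies(ModelConfig(model=1, cycles=10, efficiency=0.7), 26)
        b = self._copies(
            ModelConfig(model=6, cycles=10, eff_mean=0.7, eff_sd=0.0), 27
        )
        assert ks_2samp(a, b).pvalue > KS_ALPHA

    def test_model5_marginalises_to_model1_at_truncated_mean(self):
        """Fresh iid draws per molecule-cycle average out exactly."""
        mu, sd, c = 0.5, 0.3, 8
        a = self._copies(ModelConfig(model=5, cycles=c, eff_mean=mu, eff_sd=sd), 28)
        b = self._copies(
            ModelConfig(
                model=1, cycles=c, efficiency=truncated_normal_mean(mu, sd)
            ),
            29,
        )
        assert ks_2samp(a, b).pvalue > KS_ALPHA

    def test_inherited_efficiency_inflates_cross_lineage_cv(self):
        """Heritable efficiency produces far more lineage-to-lineage spread
        than the matched constant-efficiency process."""
        mu, sd, c = 0.5, 0.5, 25
        m6 = self._copies(
            ModelConfig(
                model=6, cycles=c, eff_mean=mu, eff_sd=sd,
                population_cap=10**12,
            ),
            30,
        )
        m1 = self._copies(
            ModelConfig(
                model=1, cycles=c, efficiency=truncated_normal_mean(mu, sd),
                population_cap=10**12,
            ),
            31,
        )
        cv6 = m6.std() / m6.mean()
        cv1 = m1.std() / m1.mean()
        assert cv6 / cv1 > 3.0

    def test_count_and_sequence_paths_agree(self):
        """Forcing the molecule-explicit path at zero error rate leaves the
        final copy distribution unchanged (models 1 and 6)."""
        pool = make_pool("uniform", 6, seed=0)
        for cfg, s1, s2 in [
            (ModelConfig(model=1, cycles=6, efficiency=0.8), 32, 33),
            (ModelConfig(model=6, cycles=6, eff_mean=0.5, eff_sd=0.3), 34, 35),
        ]:
            seq = amplify(
                make_lineages(n=10**3, pool=pool, with_sequences=True),
                cfg, seed=s1, force_sequence_path=True,
            ).copies
            cnt = amplify(make_lineages(n=10**3), cfg, seed=s2).copies
            assert ks_2samp(seq, cnt).pvalue > KS_ALPHA, cfg.model


class TestMutateCopy:
    def test_zero_rate_is_identity(self, rng):
        assert mutate_copy("ACGTACGT", 0.0, rng) == "ACGTACGT"

    def test_rate_one_changes_every_base(self, rng):
        parent = "ACGT" * 25
        child = mutate_copy(parent, 1.0, rng)
        assert all(a != b for a, b in zip(parent, child))

    def test_rejects_non_nucleotide_input(self, rng):
        with pytest.raises(ValueError):
            mutate_copy("ACGN", 0.1, rng)

    def test_substitution_count_matches_binomial_expectation(self, rng):
        """1e-2 on 1e4 bases, 100 repeats: mean hits within 3 SE of 100."""
        parent = "".join(np.random.default_rng(0).choice(list("ACGT"), 10**4))
        hits = []
        for _ in range(100):
            child = mutate_copy(parent, 1e-2, rng)
            hits.append(sum(a != b for a, b in zip(parent, child)))
        se = np.std(hits, ddof=1) / 10
        assert abs(np.mean(hits) - 100) < 3 * se

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=50)
    def test_length_and_alphabet_preserved(self, seq, rate):
        child = mutate_copy(seq, rate, np.random.default_rng(1))
        assert len(child) == len(seq)
        assert set(child) <= set("ACGT")


class TestExpectedFinalCopies:
    @pytest.mark.parametrize(
        "e,c,expected",
        [(1.0, 10, 1024.0), (0.0, 7, 1.0), (0.8, 15, 1.8**15)],
    )
    def test_closed_form(self, e, c, expected):
        assert expected_final_copies(e, c) == pytest.approx(expected)

    def test_fifteen_cycles_at_point_eight(self):
        # 1.8**15 computed directly
        assert expected_final_copies(0.8, 15) == pytest.approx(6746.64, rel=1e-4)
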