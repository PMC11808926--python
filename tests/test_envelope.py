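import numpy as np
import pandas as pd
import pytest

from skerryadapt.core_model import DemographicParams, generation_schedule
from skerryadapt.envelope import (
    ExpectedRange,
    classify_locus,
    envelope_calibration,
    expected_range_for_locus,
    fit_selection_coefficient,
    migrant_origin_fraction,
    simulate_neutral_trajectory,
)
from skerryadapt.envelope import _simulate_counts
from skerryadapt.core_model import population_size_trajectory
from skerryadapt.likelihood import LikelihoodSurface, SampleSeries


def _degenerate_surface(n0=40, r=0.3, k=150, m=3.0, f=2.0):
    return LikelihoodSurface(table=pd.DataFrame(
        [{"n0": n0, "r": r, "k": k, "m": m, "f": f, "negloglik": 0.0}]
    ))


class TestNeutralTrajectory:
    def test_loss_is_absorbing_without_source_allele(self):
        p = DemographicParams(n0=60, r=0.3, k=300, m=3, f=2)
        freqs = simulate_neutral_trajectory(p, 0, p_wave=0.0, seed=1)
        np.testing.assert_array_equal(freqs, 0.0)

    def test_fixation_is_absorbing_without_migration(self):
        p = DemographicParams(n0=60, r=0.3, k=300, m=0, f=2)
        freqs = simulate_neutral_trajectory(p, 60, p_wave=1.0, seed=1)
        np.testing.assert_array_equal(freqs, 1.0)

    def test_heterozygosity_decays_at_drift_rate(self):
        # closed population of constant size N: E[2p(1-p)] decays by (1-1/N)
        # per generation
        p = DemographicParams(n0=100, r=0.0, k=100, m=0, f=2)
        sched = generation_schedule(2)
        sizes = population_size_trajectory(p, sched.total_generations)
        rng = np.random.default_rng(11)
        start = np.full(2000, 30)
        counts = _simulate_counts(p, start, 0.0, sizes,
                                  sched.sampling_generations, rng)
        t = sched.sampling_generations[0]
        freq = counts[:, 0] / 100
        het = 2 * freq * (1 - freq)
        expected = 2 * 0.3 * 0.7 * (1 - 1 / 100) ** t
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - expected) < 3 * se

    def test_one_generation_distribution_matches_transition_matrix(self):
        # the simulator and the likelihood's transition matrices describe the
        # same process: chi-square goodness of fit on one generation
        from scipy import stats
        from skerryadapt.core_model import transition_matrix

        n, m, p_wave, start = 50, 4, 0.8, 10
        mat = transition_matrix(n, n, m, p_wave)
        rng = np.random.default_rng(5)
        from skerryadapt.envelope import _step_success_probability
        draws = rng.binomial(
            n, _step_success_probability(np.full(10_000, start), n, m, p_wave)
        )
        observed = np.bincount(draws, minlength=n + 1)
        expected = mat[start] * 10_000
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001

    def test_invalid_start_count_rejected(self):
        p = DemographicParams(n0=60, r=0.3, k=300, m=3, f=2)
        with pytest.raises(ValueError):
            simulate_neutral_trajectory(p, 61, 0.5)


class TestExpectedRange:
    def test_absent_allele_without_migration_gives_null_range(self):
        surf = _degenerate_surface(m=0.0)
        series = SampleSeries("L", (60, 60, 60, 60), (0, 0, 0, 0), 0.0)
        er = expected_range_for_locus(series, surf, n_reps=200, seed=0)
        assert (er.q025, er.median, er.q975) == (0.0, 0.0, 0.0)

    def test_equilibrium_locus_has_centred_range(self):
        # start frequency equals the source frequency: no directional pull
        surf = _degenerate_surface(m=6.0, n0=100, k=100, r=0.0)
        series = SampleSeries("L", (100, 60, 60, 100), (50, 30, 30, 50), 0.5)
        er = expected_range_for_locus(series, surf, n_reps=600, seed=3)
        assert abs(er.median) < 0.06

    def test_small_replicate_count_warns(self):
        surf = _degenerate_surface()
        series = SampleSeries("L", (10, 10, 10, 10), (5, 5, 5, 5), 0.5)
        with pytest.warns(UserWarning, match="unstable"):
            expected_range_for_locus(series, surf, n_reps=50, seed=0)


class TestClassification:
    def test_excess_change_toward_source_is_flagged(self):
        er = ExpectedRange("L", q025=-0.1, median=0.05, q975=0.2,
                           observed_change=0.3, n_replicates=500)
        cls = classify_locus(er, p_wave=0.9, p_1992=0.2)
        assert cls.outside_range and cls.toward_wave and cls.above_median

    def test_change_at_median_is_not_above_it(self):
        er = ExpectedRange("L", -0.1, 0.05, 0.2, observed_change=0.05,
                           n_replicates=500)
        cls = classify_locus(er, p_wave=0.9, p_1992=0.2)
        assert not cls.above_median

    def test_no_source_divergence_cannot_be_toward_wave(self):
        er = ExpectedRange("L", -0.1, 0.0, 0.1, observed_change=0.05,
                           n_replicates=500)
        assert not classify_locus(er, p_wave=0.3, p_1992=0.3).toward_wave


class TestSelectionCoefficient:
    S_GRID = np.linspace(-0.3, 0.3, 13)

    def test_neutral_data_recovers_null(self, small_params):
        rng = np.random.default_rng(2)
        sched = generation_schedule(small_params.f)
        sizes = population_size_trajectory(small_params, sched.total_generations)
        hats = []
        for i in range(8):
            counts = _simulate_counts(
                small_params, np.array([16]), 0.5, sizes,
                sched.sampling_generations, rng,
            )[0]
            obs = tuple(rng.binomial(60, c / s) for c, s in
                        zip([16] + list(counts), [40] + [sizes[g] for g in sched.sampling_generations]))
            series = SampleSeries(f"L{i}", (60, 60, 60, 60), obs, 0.5)
            hats.append(fit_selection_coefficient(series, small_params, self.S_GRID).s_hat)
        assert abs(np.median(hats)) <= 0.1

    def test_positive_selection_recovered(self, small_params):
        rng = np.random.default_rng(7)
        sched = generation_schedule(small_params.f)
        sizes = population_size_trajectory(small_params, sched.total_generations)
        hats = []
        for i in range(12):
            counts = _simulate_counts(
                small_params, np.array([8]), 0.9, sizes,
                sched.sampling_generations, rng, s=0.15,
            )[0]
            obs = tuple(rng.binomial(60, c / s) for c, s in
                        zip([8] + list(counts), [40] + [sizes[g] for g in sched.sampling_generations]))
            series = SampleSeries(f"L{i}", (60, 60, 60, 60), obs, 0.9)
            hats.append(fit_selection_coefficient(series, small_params, self.S_GRID).s_hat)
        assert 0.05 <= np.median(hats) <= 0.25

    def test_allele_relabeling_mirrors_profile(self, small_params):
        # swapping allele labels swaps relative fitnesses (1+s):1 -> 1:(1+s),
        # i.e. maps s to -s/(1+s); the profile is mirrored on that scale
        series = SampleSeries("L", (40, 40, 40, 40), (10, 18, 25, 30), 0.85)
        fit = fit_selection_coefficient(series, small_params, self.S_GRID)
        mirrored_grid = -self.S_GRID / (1.0 + self.S_GRID)
        mirrored = fit_selection_coefficient(
            series.relabeled(), small_params, mirrored_grid
        )
        np.testing.assert_allclose(
            fit.profile["loglik"].to_numpy(),
            mirrored.profile["loglik"].to_numpy(),
            rtol=1e-8,
        )

    def test_out_of_range_grid_rejected(self, small_params):
        series = SampleSeries("L", (10, 10, 10, 10), (5, 5, 5, 5), 0.5)
        with pytest.raises(ValueError):
            fit_selection_coefficient(series, small_params, np.array([0.0, 1.0]))


class TestMigrantOrigin:
    def test_no_migration_means_no_migrant_ancestry(self):
        p = DemographicParams(n0=100, r=0.2, k=200, m=0, f=2)
        res = migrant_origin_fraction(p, 0.5, 0.2, n_reps=200, seed=0)
        assert res.mean == 0.0

    def test_absent_standing_variation_means_pure_migrant_ancestry(self):
        p = DemographicParams(n0=100, r=0.2, k=200, m=4, f=2)
        res = migrant_origin_fraction(p, 0.9, 0.0, n_reps=200, seed=0)
        assert res.mean == 1.0 and res.n_retained > 0

    def test_matches_deterministic_label_expectations(self):
        # neutral case: iterate the expected founder-origin and migrant-origin
        # copy numbers deterministically and compare the simulated mean
        p = DemographicParams(n0=500, r=0.0, k=500, m=2, f=2)
        sched = generation_schedule(p.f)
        founder, migrant = 0.1 * 500, 0.0
        for _ in range(sched.total_generations):
            keep = (500 - p.m) / 500
            founder, migrant = founder * keep, migrant * keep + 0.9 * p.m
        expected = migrant / (founder + migrant)
        res = migrant_origin_fraction(p, 0.9, 0.1, n_reps=1500, seed=9)
        assert res.n_excluded == 0
        # the copy-weighted fraction estimates the ratio of expected copy
        # numbers, which is what the deterministic iteration computes
        assert abs(res.pooled - expected) < 3 * res.mc_se

    def test_too_few_replicates_rejected(self):
        p = DemographicParams(n0=100, r=0.2, k=200, m=0, f=2)
        with pytest.raises(ValueError):
            migrant_origin_fraction(p, 0.5, 0.2, n_reps=50)


class TestEnvelopeCalibration:
    def test_neutral_data_fall_inside_their_own_envelope(self):
        # quick, scaled-down version of the calibration experiment
        p = DemographicParams(n0=40, r=0.3, k=150, m=3, f=2)
        df = envelope_calibration(p, n_loci=100, n_reps=300, seed=5)
        outside = df["outside_range"].mean()
        above = df["above_median"].mean()
        assert outside < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)
        assert abs(above - 0.5) < 3 * np.sqrt(0.25 / 100) + 0.05
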