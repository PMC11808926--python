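import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skerryadapt.popgen import (
    SignedFstRecord,
    allele_count_fisher_test,
    allele_frequency_table,
    fraction_shifted_toward_wave,
    fst,
    multilocus_fst,
    signed_temporal_fst,
    space_time_correlation,
)


class TestFst:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.3, 0.3, 0.0),
        (0.0, 1.0, 1.0),
        (0.2, 0.8, 0.36),  # H_T = 0.5, H_S = 0.32
    ])
    def test_heterozygosity_formula(self, p1, p2, expected):
        assert fst(p1, p2) == pytest.approx(expected)

    def test_undefined_when_both_fixed_same_allele(self):
        assert np.isnan(fst(0.0, 0.0))

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            fst(1.2, 0.5)

    @settings(max_examples=60, derandomize=True)
    @given(
        p1=st.floats(0, 1, allow_nan=False),
        p2=st.floats(0, 1, allow_nan=False),
    )
    def test_symmetric_and_relabel_invariant(self, p1, p2):
        a, b = fst(p1, p2), fst(p2, p1)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
        c = fst(1 - p1, 1 - p2)
        if not np.isnan(a) and not np.isnan(c):
            assert a == pytest.approx(c, abs=1e-12)


class TestSignedTemporalFst:
    def test_no_change_is_zero(self):
        assert signed_temporal_fst(0.4, 0.4, 0.1, 0.9) == 0.0

    def test_wave_major_allele_rising_is_positive(self):
        assert signed_temporal_fst(0.1, 0.6, 0.1, 0.9) > 0

    def test_time_reversal_flips_sign_not_magnitude(self):
        up = signed_temporal_fst(0.1, 0.6, 0.1, 0.9)
        down = signed_temporal_fst(0.6, 0.1, 0.1, 0.9)
        assert down == pytest.approx(-up)

    def test_undefined_without_spatial_divergence(self):
        assert np.isnan(signed_temporal_fst(0.1, 0.6, 0.5, 0.5))


class TestMultilocusFst:
    @staticmethod
    def _table(freqs_a, freqs_b):
        rows = []
        for i, (fa, fb) in enumerate(zip(freqs_a, freqs_b)):
            rows.append({"locus": f"L{i}", "population": "a", "year": 2021,
                         "frequency": fa, "n_individuals": 30})
            rows.append({"locus": f"L{i}", "population": "b", "year": 2021,
                         "frequency": fb, "n_individuals": 30})
        return pd.DataFrame(rows)

    def test_identical_populations_give_zero(self):
        t = self._table([0.2, 0.7], [0.2, 0.7])
        assert multilocus_fst(t, ("a", 2021), ("b", 2021)) == 0.0

    def test_single_locus_reduces_to_fst(self):
        t = self._table([0.2], [0.8])
        assert multilocus_fst(t, ("a", 2021), ("b", 2021)) == pytest.approx(0.36)

    def test_ratio_of_sums_combination(self):
        # (0.18 + 0) / (0.5 + 0.5)
        t = self._table([0.2, 0.5], [0.8, 0.5])
        assert multilocus_fst(t, ("a", 2021), ("b", 2021)) == pytest.approx(0.18)

    def test_bounded_by_per_locus_values(self):
        t = self._table([0.2, 0.4, 0.1], [0.8, 0.5, 0.6])
        per_locus = [fst(a, b) for a, b in [(0.2, 0.8), (0.4, 0.5), (0.1, 0.6)]]
        combined = multilocus_fst(t, ("a", 2021), ("b", 2021))
        assert min(per_locus) <= combined <= max(per_locus)

    def test_no_usable_loci_rejected(self):
        t = self._table([0.0], [0.0])
        with pytest.raises(ValueError):
            multilocus_fst(t, ("a", 2021), ("b", 2021))


class TestShiftFraction:
    def test_all_loci_at_source_frequency(self):
        p92 = np.array([0.2, 0.8, 0.5])
        pw = np.array([0.9, 0.1, 0.7])
        frac, n_exc = fraction_shifted_toward_wave(p92, pw, pw)
        assert frac == 1.0 and n_exc == 0

    def test_unchanged_loci_count_as_not_shifted(self):
        p92 = np.array([0.2, 0.8])
        frac, _ = fraction_shifted_toward_wave(p92, p92, np.array([0.9, 0.1]))
        assert frac == 0.0

    def test_loci_without_divergence_excluded(self):
        p92 = np.array([0.2, 0.5])
        pt = np.array([0.4, 0.6])
        pw = np.array([0.9, 0.5])
        frac, n_exc = fraction_shifted_toward_wave(p92, pt, pw)
        assert n_exc == 1 and frac == 1.0

    def test_gene_flow_pulls_toward_source(self):
        # neutral simulation with migration from the source population
        from skerryadapt.core_model import DemographicParams, generation_schedule, population_size_trajectory
        from skerryadapt.envelope import _simulate_counts

        p = DemographicParams(n0=60, r=0.3, k=300, m=4, f=2)
        sched = generation_schedule(2)
        sizes = population_size_trajectory(p, sched.total_generations)
        rng = np.random.default_rng(3)
        n_loci = 300
        p92 = rng.beta(2, 2, n_loci)
        pw = np.clip(p92 + rng.choice([-0.3, 0.3], n_loci), 0, 1)
        finals = np.array([
            _simulate_counts(p, np.array([round(f * 60)]), w, sizes,
                             sched.sampling_generations, rng)[0, -1]
            for f, w in zip(p92, pw)
        ])
        frac, _ = fraction_shifted_toward_wave(p92, finals / sizes[-1], pw)
        assert frac > 0.5


class TestSpaceTimeCorrelation:
    @staticmethod
    def _records(spatial, temporal):
        return [SignedFstRecord(f"L{i}", t, s)
                for i, (s, t) in enumerate(zip(spatial, temporal))]

    def test_perfect_agreement(self):
        s = [0.1, 0.2, 0.3, 0.4, 0.5]
        rho, p = space_time_correlation(self._records(s, s))
        assert rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        s = [0.1, 0.2, 0.3, 0.4, 0.5]
        rho, _ = space_time_correlation(self._records(s, [-x for x in s]))
        assert rho == pytest.approx(-1.0)

    def test_single_swap_matches_rank_formula(self):
        # temporal ranks (1,2,4,3,5,6): rho = 1 - 6*sum(d^2)/(n(n^2-1)) with
        # d^2 summing to 2 -> 1 - 12/210
        spatial = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        temporal = [0.01, 0.02, 0.04, 0.03, 0.05, 0.06]
        rho, _ = space_time_correlation(self._records(spatial, temporal))
        assert rho == pytest.approx(1 - 12 / 210)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            space_time_correlation(self._records([0.1] * 4, [0.1] * 4))

    def test_constant_vector_undefined(self):
        rho, p = space_time_correlation(
            self._records([0.3] * 6, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        )
        assert np.isnan(rho) and np.isnan(p)


class TestFisherTest:
    def test_identical_rows_give_p_one(self):
        assert allele_count_fisher_test([[10, 20], [10, 20]]) == pytest.approx(1.0)

    def test_fixed_difference_hypergeometric_tail(self):
        # both tails of the 10/0 vs 0/10 table: 2 / C(20,10)
        p = allele_count_fisher_test([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_doubling_counts_strengthens_evidence(self):
        p1 = allele_count_fisher_test([[12, 4], [5, 11]])
        p2 = allele_count_fisher_test([[24, 8], [10, 22]])
        assert p2 < p1

    def test_zero_margin_undefined(self):
        assert np.isnan(allele_count_fisher_test([[0, 10], [0, 20]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            allele_count_fisher_test([[-1, 2], [3, 4]])


class TestAlleleFrequencyTable:
    def test_frequencies_and_minimum_individual_rule(self):
        rows = []
        # six individuals with data in one group, four in the other
        for i in range(6):
            rows.append({"individual": f"a{i}", "population": "crab",
                         "year": 1992, "snp1": 1.0, "snp2": 2.0})
        for i in range(4):
            rows.append({"individual": f"b{i}", "population": "skerry",
                         "year": 2005, "snp1": 0.0, "snp2": 1.0})
        tab = allele_frequency_table(pd.DataFrame(rows))
        crab = tab[(tab["population"] == "crab") & (tab["locus"] == "snp1")]
        assert crab["frequency"].iloc[0] == pytest.approx(0.5)
        crab2 = tab[(tab["population"] == "crab") & (tab["locus"] == "snp2")]
        assert crab2["frequency"].iloc[0] == pytest.approx(1.0)
        skerry = tab[tab["population"] == "skerry"]
        assert skerry["frequency"].isna().all()  # only 4 individuals
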