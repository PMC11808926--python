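import numpy as np
import pandas as pd
import pytest

from skerryadapt.core_model import DemographicParams
from skerryadapt.filters import (
    apply_variant_filters,
    impute_modal_genotype,
    population_missingness_filter,
    reduce_ld_subsample,
    sample_series_from_genotypes,
)
from skerryadapt.simulate import ScenarioConfig, generate_genetic_dataset, write_vcf


@pytest.fixture(scope="module")
def vcf_fixture(tmp_path_factory):
    cfg = ScenarioConfig(
        params=DemographicParams(n0=40, r=0.3, k=150, m=3, f=2),
        n_control=30, n_outlier=10, inversions=(), missingness=0.02,
        n_diploid_per_sample=15,
    )
    ds = generate_genetic_dataset(cfg, seed=9)
    path = tmp_path_factory.mktemp("vcf") / "fixture.vcf"
    manifest = write_vcf(ds, str(path), seed=9)
    return str(path), manifest


class TestVariantFilters:
    def test_per_step_counts_match_planted_truth(self, vcf_fixture):
        path, manifest = vcf_fixture
        gm = apply_variant_filters(path)
        for step in ("after_qual", "after_indels", "after_biallelic", "after_mac"):
            assert gm.filter_log[step] == manifest[step], step
        assert set(gm.snp_columns) == set(manifest["surviving_sites"])

    def test_qual_threshold_is_inclusive(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"crab_1992_{i:03d}" for i in range(6)) + "\n"
        )
        gts = "\t".join(["0/1:50:30"] * 6)
        lines = [
            f"1\t100\tkeep40\tA\tT\t40.0\tPASS\t.\tGT:GQ:DP\t{gts}",
            f"1\t101\tdrop39\tA\tT\t39.9\tPASS\t.\tGT:GQ:DP\t{gts}",
        ]
        path = tmp_path / "edge.vcf"
        path.write_text(header + "\n".join(lines) + "\n")
        gm = apply_variant_filters(str(path))
        assert gm.snp_columns == ["keep40"]

    def test_missing_format_field_is_named(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcrab_1992_000\n"
        )
        path = tmp_path / "bad.vcf"
        path.write_text(header + "1\t100\tx\tA\tT\t50\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="GQ"):
            apply_variant_filters(str(path))


def _matrix_with_missingness():
    rng = np.random.default_rng(0)
    rows = []
    for pop, year in (("crab", 1992), ("skerry", 2005)):
        for i in range(20):
            rows.append({
                "individual": f"{pop}_{year}_{i:03d}",
                "population": pop, "year": year,
                **{f"s{j}": float(rng.integers(0, 3)) for j in range(50)},
            })
    df = pd.DataFrame(rows)
    # one individual with 6% missing, one with 10%
    df.loc[0, [f"s{j}" for j in range(3)]] = np.nan
    df.loc[1, [f"s{j}" for j in range(5)]] = np.nan
    return df


class TestMissingness:
    def test_context_thresholds(self):
        df = _matrix_with_missingness()
        pca = population_missingness_filter(df, "pca_collinear")
        assert set(pca.removed_individuals) == {"crab_1992_000", "crab_1992_001"}
        inversion = population_missingness_filter(df, "inversion")
        assert inversion.removed_individuals == []

    def test_frequency_context_removes_nothing(self):
        df = _matrix_with_missingness()
        res = population_missingness_filter(df, "frequency")
        pd.testing.assert_frame_equal(res.matrix, df)

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            population_missingness_filter(_matrix_with_missingness(), "plink")


class TestImputation:
    def test_mode_per_population_year_with_low_tie(self):
        df = pd.DataFrame({
            "individual": ["a", "b", "c", "d", "e", "f"],
            "population": ["crab"] * 3 + ["wave"] * 3,
            "year": [1992] * 3 + [2018] * 3,
            # crab mode 2; wave tie between 0 and 1 -> 0
            "s1": [2.0, 2.0, np.nan, 0.0, 1.0, np.nan],
        })
        out = impute_modal_genotype(df)
        assert out.loc[2, "s1"] == 2.0
        assert out.loc[5, "s1"] == 0.0

    def test_never_changes_observed_genotypes(self):
        df = _matrix_with_missingness()
        out = impute_modal_genotype(df)
        snps = [c for c in df.columns if c.startswith("s")]
        observed = ~df[snps].isna()
        assert (out[snps].to_numpy()[observed.to_numpy()]
                == df[snps].to_numpy()[observed.to_numpy()]).all()
        assert not out[snps].isna().any().any()


class TestLdSubsampling:
    def test_window_partition(self):
        m = pd.DataFrame({
            "snp_id": ["a", "b", "c"], "lg": [1, 1, 1],
            "cm": [10.1, 10.9, 11.2], "category": "spatial_outlier",
        })
        chosen = reduce_ld_subsample(m, seed=0)
        assert len(chosen) == 2 and "c" in chosen

    def test_sex_linkage_group_dropped(self):
        m = pd.DataFrame({
            "snp_id": ["a", "b"], "lg": [12, 12], "cm": [1.0, 2.0],
            "category": "spatial_outlier",
        })
        with pytest.warns(UserWarning):
            assert reduce_ld_subsample(m, seed=0) == []

    def test_lg2_cluster_and_configured_lg5_interval_removed(self):
        m = pd.DataFrame({
            "snp_id": ["in2", "out2", "in5", "out5"],
            "lg": [2, 2, 5, 5],
            "cm": [40.0, 70.0, 15.0, 50.0],
            "category": "spatial_outlier",
        })
        chosen = reduce_ld_subsample(m, seed=0, lg5_exclusion_cm=((10.0, 30.0),))
        assert sorted(chosen) == ["out2", "out5"]

    def test_one_snp_per_window_property(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(300)],
            "lg": rng.integers(1, 18, 300),
            "cm": rng.uniform(0, 80, 300),
            "category": "spatial_outlier",
        })
        chosen = reduce_ld_subsample(m, seed=5)
        sub = m[m["snp_id"].isin(chosen)]
        windows = list(zip(sub["lg"], np.floor(sub["cm"]).astype(int)))
        assert len(windows) == len(set(windows))
        assert not (sub["lg"] == 12).any()
        assert reduce_ld_subsample(m, seed=5) == chosen  # reproducible


class TestSampleSeries:
    def test_series_built_from_genotype_counts(self):
        cfg = ScenarioConfig(
            params=DemographicParams(n0=40, r=0.3, k=150, m=3, f=2),
            n_control=20, n_outlier=0, inversions=(), missingness=0.0,
            n_diploid_per_sample=12,
        )
        ds = generate_genetic_dataset(cfg, seed=4)
        loci = [c for c in ds.genotypes.columns if c.startswith("ctrl")]
        series = sample_series_from_genotypes(ds.genotypes, loci, seed=4)
        assert len(series) == 20
        # without missingness every sample keeps its full 24 allele copies
        assert all(s.sample_sizes == (24, 24, 24, 24) for s in series)
        truth = ds.truth["loci"].set_index("snp_id")
        # the 1992 sample comes from the founder pool, so counts should be
        # close to the founder frequency
        for s in series[:5]:
            f0 = truth.loc[s.locus, "founder_count"] / 40
            assert abs(s.observed_counts[0] / 24 - f0) < 0.35
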