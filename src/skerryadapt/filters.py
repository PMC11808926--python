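"""Genotype input/output, variant- and individual-level filters, imputation
and reduced-LD subsampling.

Genotypes travel as a wide table (one row per individual: id, population,
year, then one 0/1/2/NaN dosage column per SNP) plus a SNP map (snp_id,
linkage group, cM position, category).  VCF input (4.2, plain text) is read
with pysam; dosages count the ALT allele, and the "Wave allele" orientation
is assigned downstream from the source-population frequency, never from
REF/ALT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import SampleSeries

__all__ = [
    "GenotypeMatrix",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_snp_map",
    "apply_variant_filters",
    "population_missingness_filter",
    "impute_modal_genotype",
    "reduce_ld_subsample",
    "first_snp_per_group",
    "sample_series_from_genotypes",
]

META_COLUMNS = ("individual", "population", "year")

#: per-context missingness thresholds (fraction) for individuals and SNPs
_CONTEXT_THRESHOLDS = {"pca_collinear": 0.05, "inversion": 0.20}


@dataclass
class GenotypeMatrix:
    """Dosage matrix with individual labels and SNP map coordinates."""

    genotypes: pd.DataFrame
    snp_map: pd.DataFrame | None = None
    filter_log: dict = field(default_factory=dict)

    @property
    def snp_columns(self) -> list[str]:
        return [c for c in self.genotypes.columns if c not in META_COLUMNS]


def read_genotype_csv(path: str) -> pd.DataFrame:
    """Genotype CSV: individual, population, year, one dosage column per SNP."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype CSV lacks columns: {missing}")
    return df


def write_genotype_csv(genotypes: pd.DataFrame, path: str) -> None:
    genotypes.to_csv(path, index=False)


def read_snp_map(path: str) -> pd.DataFrame:
    """Map TSV with columns snp_id, lg, cm, category (tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp_id", "lg", "cm", "category") if c not in df.columns]
    if missing:
        raise ValueError(f"SNP map lacks columns: {missing}")
    return df


def _parse_sample_name(name: str) -> tuple[str, int]:
    parts = name.split("_")
    if len(parts) < 3:
        raise ValueError(
            f"sample name {name!r} not of the form <population>_<year>_<id>"
        )
    return parts[0], int(parts[1])


def apply_variant_filters(
    vcf_path: str,
    min_qual: float = 40.0,
    min_gq: int = 20,
    min_dp: int = 10,
    min_mac: int = 5,
) -> GenotypeMatrix:
    """Read a VCF and apply the variant-level filters, in order.

    Steps: site QUAL >= 40; drop indels; set genotypes with GQ < 20 or
    DP < 10 to missing; keep biallelic SNPs only; keep minor allele count
    >= 5 (counted after genotype masking).  The per-step survivor counts are
    recorded in the returned ``filter_log``.
    """
    import pysam

    vcf = pysam.VariantFile(vcf_path)
    for fmt in ("GQ", "DP"):
        if fmt not in vcf.header.formats:
            raise ValueError(f"VCF lacks required FORMAT field {fmt!r}")
    samples = list(vcf.header.samples)

    records = list(vcf)
    n_total = len(records)
    log: dict = {"n_sites": n_total, "n_genotypes_masked": 0}

    kept = [r for r in records if r.qual is not None and r.qual >= min_qual]
    log["after_qual"] = len(kept)

    def is_indel(rec) -> bool:
        alts = rec.alts or ()
        return len(rec.ref) != 1 or any(len(a) != 1 for a in alts)

    kept = [r for r in kept if not is_indel(r)]
    log["after_indels"] = len(kept)

    dosages = {}
    for rec in kept:
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            gq, dp = call.get("GQ"), call.get("DP")
            if gq is None or dp is None or gq < min_gq or dp < min_dp:
                if gq is not None or dp is not None:
                    log["n_genotypes_masked"] += 1
                continue
            col[i] = sum(gt)
        dosages[rec.id or f"{rec.chrom}:{rec.pos}"] = col
    log["after_genotype_mask"] = len(kept)

    kept_bi = [r for r in kept if r.alts is not None and len(r.alts) == 1]
    log["after_biallelic"] = len(kept_bi)
    bi_ids = {r.id or f"{r.chrom}:{r.pos}" for r in kept_bi}

    surviving = []
    for snp_id in dosages:
        if snp_id not in bi_ids:
            continue
        col = dosages[snp_id]
        n_called = np.sum(~np.isnan(col))
        if n_called == 0:
            continue
        alt_count = np.nansum(col)
        mac = min(alt_count, 2 * n_called - alt_count)
        if mac >= min_mac:
            surviving.append(snp_id)
    log["after_mac"] = len(surviving)

    meta = pd.DataFrame(
        [(s, *_parse_sample_name(s)) for s in samples],
        columns=["individual", "population", "year"],
    )
    geno = pd.concat(
        [meta] + [pd.Series(dosages[s], name=s) for s in surviving], axis=1
    )
    return GenotypeMatrix(genotypes=geno, filter_log=log)


def impute_modal_genotype(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosages with the population-year modal genotype.

    Ties break toward the lower dosage for determinism; imputation never
    changes non-missing genotypes.  A group that is entirely missing for a
    SNP is imputed with dosage 0.
    """
    snps = [c for c in genotypes.columns if c not in META_COLUMNS]
    out = genotypes.copy()
    for _, idx in genotypes.groupby(["population", "year"]).groups.items():
        block = out.loc[idx, snps].to_numpy(dtype=float)
        for j in range(block.shape[1]):
            col = block[:, j]
            nan = np.isnan(col)
            if not nan.any():
                continue
            present = col[~nan].astype(int)
            if len(present) == 0:
                mode = 0
            else:
                counts = np.bincount(present, minlength=3)
                mode = int(np.argmax(counts))  # argmax takes the lowest tie
            col[nan] = mode
        out.loc[idx, snps] = block
    return out


@dataclass
class MissingnessResult:
    matrix: pd.DataFrame
    imputed: pd.DataFrame | None
    removed_individuals: list[str]
    removed_snps: list[str]
    flagged_groups: list[tuple[str, int]]  # population-years left with < 2 individuals


def population_missingness_filter(
    gm: GenotypeMatrix | pd.DataFrame,
    context: str,
) -> MissingnessResult:
    """Context-dependent missing-data filtering.

    ``frequency``: nothing is removed (the >= 5 individuals-with-data rule is
    applied when frequencies are computed).  ``pca_collinear``: individuals
    with > 5% missing genotypes and SNPs with > 5% missing data within any
    population-year are removed, and an imputed copy is returned.
    ``inversion``: the same with a 20% threshold.
    """
    geno = gm.genotypes if isinstance(gm, GenotypeMatrix) else gm
    if context == "frequency":
        return MissingnessResult(geno, None, [], [], [])
    if context not in _CONTEXT_THRESHOLDS:
        raise ValueError(f"unknown context {context!r}")
    thr = _CONTEXT_THRESHOLDS[context]
    snps = [c for c in geno.columns if c not in META_COLUMNS]

    ind_missing = geno[snps].isna().mean(axis=1)
    keep_ind = ind_missing <= thr
    removed_ind = geno.loc[~keep_ind, "individual"].tolist()
    sub = geno.loc[keep_ind].reset_index(drop=True)

    snp_missing = sub.groupby(["population", "year"])[snps].apply(
        lambda g: g.isna().mean()
    )
    bad_snps = [s for s in snps if (snp_missing[s] > thr).any()]
    sub = sub.drop(columns=bad_snps)

    flagged = [
        (str(pop), int(year))
        for (pop, year), grp in sub.groupby(["population", "year"])
        if len(grp) < 2
    ]
    imputed = impute_modal_genotype(sub)
    return MissingnessResult(sub, imputed, removed_ind, bad_snps, flagged)


def reduce_ld_subsample(
    snp_map: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    exclude_lgs: tuple[int, ...] = (12,),
    lg2_exclusion_cm: tuple[float, float] = (36.0, 60.0),
    lg5_exclusion_cm: tuple[tuple[float, float], ...] = (),
) -> list[str]:
    """One random SNP per 1-cM window, after region exclusions.

    LG12 (sex-linked) is dropped entirely, the configured LG5 intervals
    (putative inversion; coordinates are configuration) and the dense LG2
    cluster between 36 and 60 cM are removed, remaining SNPs are binned into
    half-open windows [i, i+1) cM anchored at 0, and one uniformly random
    SNP per nonempty window is kept.  Reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    m = snp_map.copy()
    unmapped = m["lg"].isna() | m["cm"].isna()
    if unmapped.any():
        warnings.warn(
            f"excluding {int(unmapped.sum())} unmapped SNPs", stacklevel=2
        )
        m = m[~unmapped]
    m = m[~m["lg"].isin(exclude_lgs)]
    lo2, hi2 = lg2_exclusion_cm
    m = m[~((m["lg"] == 2) & (m["cm"] >= lo2) & (m["cm"] <= hi2))]
    for lo5, hi5 in lg5_exclusion_cm:
        m = m[~((m["lg"] == 5) & (m["cm"] >= lo5) & (m["cm"] <= hi5))]
    if m.empty:
        warnings.warn("no SNPs remain after region exclusions", stacklevel=2)
        return []
    m = m.assign(window=np.floor(m["cm"].to_numpy(dtype=float)).astype(int))
    chosen = []
    for _, grp in m.groupby(["lg", "window"], sort=True):
        ids = grp["snp_id"].tolist()
        chosen.append(ids[int(rng.integers(len(ids)))])
    return chosen


def first_snp_per_group(snp_map: pd.DataFrame, group_column: str) -> list[str]:
    """First SNP id per group label (e.g. one control SNP per contig)."""
    if group_column not in snp_map.columns:
        raise ValueError(f"SNP map lacks column {group_column!r}")
    return snp_map.groupby(group_column, sort=False)["snp_id"].first().tolist()


def sample_series_from_genotypes(
    genotypes: pd.DataFrame,
    loci: list[str],
    seed: int | np.random.Generator = 0,
    skerry_years: tuple[int, int, int] = (2005, 2018, 2021),
) -> list[SampleSeries]:
    """Build per-locus allele-count series for the demographic likelihood.

    The time series couples the Crab 1992 donor sample with the skerry
    samples; the per-locus source frequency comes from the merged Wave
    2018 + 2021 samples.  To avoid missing data, every sample is subsampled
    to the minimum number of individuals with data across loci (individuals
    drawn at random per locus, reproducibly under the seed).
    """
    rng = np.random.default_rng(seed)
    groups = [("crab", (1992,))] + [("skerry", (y,)) for y in skerry_years]
    wave_group = ("wave", (2018, 2021))

    def group_counts(pop: str, years: tuple[int, ...]) -> tuple[np.ndarray, int]:
        sub = genotypes[
            (genotypes["population"] == pop) & (genotypes["year"].isin(years))
        ]
        if sub.empty:
            raise ValueError(f"no individuals for {pop} {years}")
        dos = sub[loci].to_numpy(dtype=float)
        n_with = np.sum(~np.isnan(dos), axis=0)
        n_min = int(n_with.min())
        if n_min < 1:
            raise ValueError(
                f"a locus has no data in {pop} {years}; filter loci first"
            )
        counts = np.empty(len(loci), dtype=int)
        for j in range(len(loci)):
            have = np.flatnonzero(~np.isnan(dos[:, j]))
            pick = rng.choice(have, size=n_min, replace=False)
            counts[j] = int(dos[pick, j].sum())
        return counts, 2 * n_min

    counts_sizes = [group_counts(pop, years) for pop, years in groups]
    wave_counts, wave_size = group_counts(*wave_group)
    p_wave = wave_counts / wave_size

    out = []
    for j, locus in enumerate(loci):
        out.append(SampleSeries(
            locus=locus,
            sample_sizes=tuple(cs[1] for cs in counts_sizes),
            observed_counts=tuple(int(cs[0][j]) for cs in counts_sizes),
            p_wave=float(p_wave[j]),
        ))
    return out
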