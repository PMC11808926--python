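"""Synthetic study generator.

Generates complete synthetic datasets — genotypes, SNP maps, inversion
blocks, phenotypes, and truth manifests — with the statistical structure the
inference modules assume: a donor (Crab) population, a differentiated source
(Wave) population, a founder bottleneck of n0 haploid genomes, logistic
growth, migration from the source, optional per-locus directional selection,
inversions as single multi-arrangement loci expanded into diagnostic-SNP
blocks, and quantitative traits following the stabilizing-selection model
with a plastic offset.

The defaults are a scaled-down study profile (100 control-like loci, 30
outlier-like loci, 2 inversions, n0 = 60, K = 300) that keeps full-pipeline
runs fast while preserving every structural feature of the design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_model import (
    DemographicParams,
    generation_schedule,
    population_size_trajectory,
)
from .envelope import _simulate_counts, _step_success_probability

__all__ = [
    "InversionScenario",
    "TraitScenario",
    "ScenarioConfig",
    "SyntheticGeneticDataset",
    "generate_genetic_dataset",
    "generate_phenotype_dataset",
    "simulate_sample_series",
    "write_vcf",
    "DEFAULT_SCENARIO",
]

#: Genotyped sampling design: (population, year) cells and which generation
#: (relative to founding) a skerry sample corresponds to, given f.
GENOTYPE_SAMPLES = (
    ("crab", 1992), ("crab", 2018), ("crab", 2021),
    ("wave", 2018), ("wave", 2021),
    ("skerry", 2005), ("skerry", 2018), ("skerry", 2021),
)

PHENOTYPE_YEARS = (1996, 2002, 2005, 2018, 2021)


@dataclass(frozen=True)
class InversionScenario:
    """True arrangement frequencies and selection for one inversion."""

    name: str
    complexity: str  # "simple" (2 arrangements) or "complex" (3 arrangements)
    lg: int
    crab_freqs: tuple[float, ...]
    wave_freqs: tuple[float, ...]
    n_diagnostic_snps: int = 16
    s: float = 0.0  # genic selection favouring the Wave-major arrangement
    discordance: float = 0.0  # per-genotype diagnostic-SNP noise rate

    def __post_init__(self) -> None:
        n_arr = {"simple": 2, "complex": 3}.get(self.complexity)
        if n_arr is None:
            raise ValueError(f"complexity must be simple/complex, got {self.complexity}")
        for freqs in (self.crab_freqs, self.wave_freqs):
            if len(freqs) != n_arr or abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: need {n_arr} frequencies summing to 1")
        if self.n_diagnostic_snps < 4:
            raise ValueError("inversions need >= 4 diagnostic SNPs")

    @property
    def n_arrangements(self) -> int:
        return 2 if self.complexity == "simple" else 3


@dataclass(frozen=True)
class TraitScenario:
    """Generative parameters of one quantitative trait."""

    name: str
    crab_mean: float
    optimum: float
    v_g: float
    v_p: float
    plasticity: float


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic experiment."""

    params: DemographicParams = field(
        default_factory=lambda: DemographicParams(n0=60, r=0.3, k=300, m=3, f=2)
    )
    n_control: int = 100
    n_outlier: int = 30
    #: selection coefficient applied to selected outlier-like loci
    n_selected: int = 10
    s_selected: float = 0.1
    inversions: tuple[InversionScenario, ...] = (
        InversionScenario(
            name="INV1", complexity="simple", lg=1,
            crab_freqs=(0.85, 0.15), wave_freqs=(0.2, 0.8), s=0.1,
        ),
        InversionScenario(
            name="INV6", complexity="complex", lg=6,
            crab_freqs=(0.7, 0.2, 0.1), wave_freqs=(0.1, 0.3, 0.6), s=0.1,
        ),
    )
    n_diploid_per_sample: int = 30
    missingness: float = 0.02
    traits: tuple[TraitScenario, ...] = (
        TraitScenario("length", crab_mean=2.4, optimum=1.5, v_g=0.05,
                      v_p=0.1, plasticity=-0.2),
        TraitScenario("g_w", crab_mean=0.05, optimum=0.25, v_g=0.002,
                      v_p=0.004, plasticity=0.04),
    )
    control_crab_beta: tuple[float, float] = (2.0, 2.0)
    control_wave_sd: float = 0.05
    outlier_crab_beta: tuple[float, float] = (1.5, 6.0)
    outlier_wave_beta: tuple[float, float] = (6.0, 1.5)
    #: strength of stabilizing selection used to generate skerry phenotypes
    v_s_over_v_p: float = 10.0


DEFAULT_SCENARIO = ScenarioConfig()


@dataclass
class SyntheticGeneticDataset:
    """Genotypes, SNP map and ground truth for one synthetic study."""

    genotypes: pd.DataFrame  # columns: individual, population, year, <snp>...
    snp_map: pd.DataFrame    # columns: snp_id, lg, cm, category
    truth: dict


def _skerry_generations(f: float, years=(2005, 2018, 2021)) -> dict[int, int]:
    sched = generation_schedule(f)
    return dict(zip(years, sched.sampling_generations))


def _simulate_locus_trajectories(
    params: DemographicParams,
    start_counts: np.ndarray,
    p_wave: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-locus forward counts at the three post-founding sampling times."""
    sched = generation_schedule(params.f)
    sizes = population_size_trajectory(params, sched.total_generations)
    n = len(start_counts)
    out = np.empty((n, 3), dtype=np.int64)
    for j in range(n):  # per-locus loop keeps per-locus selection simple
        out[j] = _simulate_counts(
            params, np.array([start_counts[j]]), float(p_wave[j]), sizes,
            sched.sampling_generations, rng, s=float(s[j]),
        )[0]
    return out


def _hwe_dosages(
    rng: np.random.Generator, freq: np.ndarray, n_ind: int
) -> np.ndarray:
    """(n_ind x n_loci) dosage matrix at Hardy-Weinberg equilibrium."""
    return rng.binomial(2, freq[None, :], size=(n_ind, len(freq)))


def generate_genetic_dataset(
    config: ScenarioConfig, seed: int
) -> SyntheticGeneticDataset:
    """Simulate the full genotyping study.

    Control- and outlier-like loci draw donor and source frequencies from the
    configured divergence model; the skerry is founded with n0 haploid
    genomes binomially sampled from the donor frequencies and evolves forward
    under drift, migration and per-locus selection.  The 1992 "donor" sample
    is drawn from the founder pool itself (the sampled snails were collected
    together with the transplanted cohort), which couples the 1992 sample to
    the founder state exactly as the inference model assumes.  Inversions are
    simulated as single multi-arrangement loci and expanded into blocks of
    concordant diagnostic SNPs.
    """
    rng = np.random.default_rng(seed)
    params = config.params
    n_ind = config.n_diploid_per_sample
    sched = generation_schedule(params.f)
    sizes = population_size_trajectory(params, sched.total_generations)
    gen_of_year = _skerry_generations(params.f)

    # --- collinear loci -------------------------------------------------
    n_ctrl, n_out = config.n_control, config.n_outlier
    p_crab = np.concatenate([
        rng.beta(*config.control_crab_beta, size=n_ctrl),
        rng.beta(*config.outlier_crab_beta, size=n_out),
    ])
    p_wave = np.concatenate([
        np.clip(p_crab[:n_ctrl] + rng.normal(0, config.control_wave_sd, n_ctrl), 0, 1),
        rng.beta(*config.outlier_wave_beta, size=n_out),
    ])
    s = np.zeros(n_ctrl + n_out)
    sel_idx = n_ctrl + rng.choice(n_out, size=min(config.n_selected, n_out),
                                  replace=False)
    s[sel_idx] = config.s_selected

    founders = rng.binomial(params.n0, p_crab)
    traj = _simulate_locus_trajectories(params, founders, p_wave, s, rng)
    skerry_freq = {
        year: traj[:, i] / sizes[g]
        for i, (year, g) in enumerate(gen_of_year.items())
    }

    snp_ids = [f"ctrl_{j:04d}" for j in range(n_ctrl)] + [
        f"outl_{j:04d}" for j in range(n_out)
    ]
    lgs_avail = [lg for lg in range(1, 18) if lg != 12]
    lgs = rng.choice(lgs_avail, size=len(snp_ids))
    cms = rng.uniform(0.0, 80.0, size=len(snp_ids))
    categories = ["control"] * n_ctrl + ["spatial_outlier"] * n_out

    # --- per-sample genotypes ------------------------------------------
    blocks = []
    founder_freq = founders / params.n0
    for pop, year in GENOTYPE_SAMPLES:
        if pop == "crab":
            freq = founder_freq if year == 1992 else p_crab
        elif pop == "wave":
            freq = p_wave
        else:
            freq = skerry_freq[year]
        dos = _hwe_dosages(rng, freq, n_ind).astype(float)
        if config.missingness > 0:
            dos[rng.random(dos.shape) < config.missingness] = np.nan
        blk = pd.DataFrame(dos, columns=snp_ids)
        blk.insert(0, "year", year)
        blk.insert(0, "population", pop)
        blk.insert(0, "individual",
                   [f"{pop}_{year}_{i:03d}" for i in range(n_ind)])
        blocks.append(blk)
    geno = pd.concat(blocks, ignore_index=True)

    # --- inversions -----------------------------------------------------
    inv_truth = {}
    inv_map_rows = []
    for inv in config.inversions:
        n_arr = inv.n_arrangements
        crab = np.asarray(inv.crab_freqs)
        wave = np.asarray(inv.wave_freqs)
        wave_arr = int(np.argmax(wave - crab))

        counts = rng.multinomial(params.n0, crab).astype(float)
        arr_traj = {}
        for t in range(1, sched.total_generations + 1):
            n_prev, n_next = int(sizes[t - 1]), int(sizes[t])
            pool = counts * (n_prev - params.m) / n_prev + params.m * wave
            w = pool.copy()
            w[wave_arr] *= 1.0 + inv.s
            counts = rng.multinomial(n_next, w / w.sum()).astype(float)
            if t in set(gen_of_year.values()):
                year = [y for y, g in gen_of_year.items() if g == t][0]
                arr_traj[year] = counts / n_next

        # diagnostic-SNP allele profile per arrangement
        n_snp = inv.n_diagnostic_snps
        profile = np.zeros((n_arr, n_snp), dtype=int)
        profile[1] = 1
        if n_arr == 3:
            profile[2, : n_snp // 2] = 1

        karyotypes = {}
        inv_cols = [f"{inv.name}_snp{j:02d}" for j in range(n_snp)]
        dos_all = np.zeros((len(geno), n_snp), dtype=float)
        for pop, year in GENOTYPE_SAMPLES:
            if pop == "crab":
                freqs = crab
            elif pop == "wave":
                freqs = wave
            else:
                freqs = arr_traj[year]
            mask = (geno["population"] == pop) & (geno["year"] == year)
            idx = np.flatnonzero(mask.to_numpy())
            draws = rng.choice(n_arr, size=(len(idx), 2), p=freqs / freqs.sum())
            draws.sort(axis=1)
            for row, (a, b) in zip(idx, draws):
                karyotypes[geno.loc[row, "individual"]] = (int(a), int(b))
                dos_all[row] = profile[a] + profile[b]
        if inv.discordance > 0:
            noise = rng.random(dos_all.shape) < inv.discordance
            dos_all[noise] = rng.binomial(2, 0.5, size=int(noise.sum()))
        if config.missingness > 0:
            dos_all[rng.random(dos_all.shape) < config.missingness] = np.nan
        geno[inv_cols] = dos_all

        base_cm = rng.uniform(10.0, 40.0)
        for j, col in enumerate(inv_cols):
            inv_map_rows.append({
                "snp_id": col, "lg": inv.lg, "cm": base_cm + 0.1 * j,
                "category": "inversion_diagnostic", "inversion": inv.name,
                "complexity": inv.complexity,
            })
        inv_truth[inv.name] = {
            "complexity": inv.complexity,
            "wave_arrangement": wave_arr,
            "s": inv.s,
            "arrangement_trajectory": {y: v.tolist() for y, v in arr_traj.items()},
            "karyotypes": karyotypes,
        }

    snp_map = pd.DataFrame({
        "snp_id": snp_ids, "lg": lgs, "cm": cms, "category": categories,
        "inversion": "", "complexity": "",
    })
    snp_map = pd.concat([snp_map, pd.DataFrame(inv_map_rows)], ignore_index=True)

    truth = {
        "params": asdict(params),
        "seed": seed,
        "loci": pd.DataFrame({
            "snp_id": snp_ids,
            "category": categories,
            "p_crab": p_crab,
            "p_wave": p_wave,
            "s": s,
            "founder_count": founders,
            **{f"skerry_freq_{y}": skerry_freq[y] for y in gen_of_year},
        }),
        "inversions": inv_truth,
    }
    return SyntheticGeneticDataset(genotypes=geno, snp_map=snp_map, truth=truth)


def generate_phenotype_dataset(
    config: ScenarioConfig, seed: int, n_per_sample: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate trait tables under the stabilizing-selection model.

    Crab individuals are Gaussian around the donor mean, Wave individuals
    around the optimum, and skerry individuals around the deterministic mean
    trajectory started at (donor mean + plastic offset), all with shared
    phenotypic variance.
    """
    from .phenotypes import mean_phenotype_trajectory

    rng = np.random.default_rng(seed)
    n = n_per_sample if n_per_sample is not None else config.n_diploid_per_sample
    f = config.params.f
    rows = []
    truth: dict = {"traits": {}, "seed": seed}
    samples = (
        [("crab", y) for y in (1992, 2018, 2021)]
        + [("wave", y) for y in (2018, 2021)]
        + [("skerry", y) for y in PHENOTYPE_YEARS]
    )
    v_s_ratio = config.v_s_over_v_p
    truth["v_s_over_v_p"] = v_s_ratio
    for trait in config.traits:
        truth["traits"][trait.name] = asdict(trait)
        sd = math.sqrt(trait.v_p)
        v_s = v_s_ratio * trait.v_p
        max_gen = int(round((PHENOTYPE_YEARS[-1] - 1992) * f))
        traj = mean_phenotype_trajectory(
            x_start=trait.crab_mean + trait.plasticity,
            optimum=trait.optimum, v_g=trait.v_g, v_s=v_s, v_p=trait.v_p,
            n_generations=max_gen,
        )
        for pop, year in samples:
            if pop == "crab":
                mu = trait.crab_mean
            elif pop == "wave":
                mu = trait.optimum
            else:
                gen = int(round((year - 1992) * f))
                mu = traj[gen]
            vals = rng.normal(mu, sd, size=n)
            for i, v in enumerate(vals):
                rows.append({
                    "individual": f"{pop}_{year}_{i:03d}",
                    "population": pop, "year": year,
                    "trait": trait.name, "value": v,
                })
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["individual", "population", "year"],
        columns="trait", values="value",
    ).reset_index()
    wide.columns.name = None
    return wide, truth


def simulate_sample_series(
    params: DemographicParams,
    n_loci: int,
    sample_size: int = 60,
    seed: int = 0,
    p_wave: np.ndarray | None = None,
    p_wave_copies: int = 120,
):
    """Allele-count series drawn exactly from the inference model.

    Founder allele counts follow the model's uniform prior over {0..n0}, the
    1992 donor sample is a binomial draw from the founder pool, hidden counts
    evolve by migration + binomial drift, every sample is binomial with
    ``sample_size`` allele copies, and each locus's source frequency is known
    to the likelihood.  Such datasets are exchangeable with the likelihood,
    which makes them the right input for calibration experiments (parameter
    recovery, support-interval coverage).

    Source frequencies, when not supplied, are drawn uniformly on the grid of
    multiples of ``1/p_wave_copies`` — the granularity of a frequency
    estimated from a merged source sample of that many allele copies (this
    also lets the likelihood batch loci sharing a source frequency).

    Returns (list of SampleSeries, truth dict with founder counts and
    source frequencies).
    """
    from .likelihood import SampleSeries

    rng = np.random.default_rng(seed)
    sched = generation_schedule(params.f)
    sizes = population_size_trajectory(params, sched.total_generations)
    i0 = rng.integers(0, params.n0 + 1, size=n_loci)
    if p_wave is None:
        pw = rng.integers(0, p_wave_copies + 1, size=n_loci) / p_wave_copies
    else:
        pw = np.asarray(p_wave)
    k92 = rng.binomial(sample_size, i0 / params.n0)
    series = []
    for j in range(n_loci):
        hidden = _simulate_counts(
            params, np.array([i0[j]]), float(pw[j]), sizes,
            sched.sampling_generations, rng,
        )[0]
        counts = [int(k92[j])] + [
            int(rng.binomial(sample_size, hidden[t] / sizes[g]))
            for t, g in enumerate(sched.sampling_generations)
        ]
        series.append(SampleSeries(
            locus=f"L{j:04d}",
            sample_sizes=(sample_size,) * 4,
            observed_counts=tuple(counts),
            p_wave=float(pw[j]),
        ))
    truth = {"founder_counts": i0, "p_wave": pw}
    return series, truth


# ---------------------------------------------------------------------------
# VCF fixture with planted filter failures and a ground-truth manifest
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=skerryadapt-synthetic
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    dataset: SyntheticGeneticDataset,
    path: str,
    seed: int = 0,
    frac_low_qual: float = 0.1,
    frac_indel: float = 0.05,
    frac_low_gq: float = 0.05,
    frac_low_dp: float = 0.05,
) -> dict:
    """Write the dataset as a plain-text VCF with planted filter failures.

    A fraction of sites receive QUAL < 40, a fraction are written as indels,
    and per-genotype GQ/DP values below the filtering thresholds are planted
    at the given rates.  Returns a manifest with the expected survivor count
    after every filtering step, computed directly from the planted truth.
    """
    rng = np.random.default_rng(seed)
    geno = dataset.genotypes
    snps = [c for c in geno.columns if c not in ("individual", "population", "year")]
    n_site = len(snps)
    samples = geno["individual"].tolist()

    low_qual = rng.random(n_site) < frac_low_qual
    indel = rng.random(n_site) < frac_indel
    quals = np.where(low_qual, rng.uniform(10, 39.5, n_site), rng.uniform(40, 99, n_site))

    dos = geno[snps].to_numpy()  # individuals x sites, NaN = missing
    gq = np.where(rng.random(dos.shape) < frac_low_gq,
                  rng.integers(0, 20, dos.shape), rng.integers(20, 99, dos.shape))
    dp = np.where(rng.random(dos.shape) < frac_low_dp,
                  rng.integers(0, 10, dos.shape), rng.integers(10, 60, dos.shape))

    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [_VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    for j, snp in enumerate(snps):
        ref, alt = ("A", "AT") if indel[j] else ("A", "T")
        fields = [
            "1", str(1000 + j), snp, ref, alt, f"{quals[j]:.1f}", "PASS",
            f"NS={len(samples)}", "GT:GQ:DP",
        ]
        for i in range(len(samples)):
            if np.isnan(dos[i, j]):
                fields.append("./.:.:.")
            else:
                fields.append(f"{gt_strings[int(dos[i, j])]}:{gq[i, j]}:{dp[i, j]}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    # expected survivor counts, computed from the planted truth
    after_qual = ~low_qual
    after_indel = after_qual & ~indel
    masked = np.isnan(dos) | (gq < 20) | (dp < 10)
    kept_dos = np.where(masked, np.nan, dos)
    n_after_mask = int(after_indel.sum())  # masking drops genotypes, not sites
    survivors_mac = []
    for j in np.flatnonzero(after_indel):
        col = kept_dos[:, j]
        alt_ct = np.nansum(col)
        tot = 2 * np.sum(~np.isnan(col))
        mac = min(alt_ct, tot - alt_ct)
        if mac >= 5:
            survivors_mac.append(snps[j])
    manifest = {
        "n_sites": n_site,
        "after_qual": int(after_qual.sum()),
        "after_indels": int(after_indel.sum()),
        "after_genotype_mask": n_after_mask,
        "after_biallelic": n_after_mask,  # all synthetic sites are biallelic
        "after_mac": len(survivors_mac),
        "surviving_sites": survivors_mac,
    }
    return manifest
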