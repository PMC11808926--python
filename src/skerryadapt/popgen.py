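"""Allele-frequency statistics: FST, signed temporal FST, shift fractions,
space-time rank correlation, and allele-count contingency tests.

FST between two populations is computed from expected heterozygosities,
FST = (H_T - H_S) / H_T, where H_T uses the unweighted mean of the two
population frequencies and H_S the mean within-population heterozygosity.
Temporal FST (start vs end of the experiment) is given a sign: positive when
the allele more common in the spatial source (Wave) population increased
over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignedFstRecord",
    "allele_frequency_table",
    "fst",
    "signed_temporal_fst",
    "multilocus_fst",
    "fraction_shifted_toward_wave",
    "space_time_correlation",
    "allele_count_fisher_test",
]

#: Minimum individuals with data for a population-year frequency to be defined.
MIN_INDIVIDUALS = 5


@dataclass(frozen=True)
class SignedFstRecord:
    locus: str
    temporal_fst: float  # signed, in [-1, 1]
    spatial_fst: float   # in [0, 1]


def allele_frequency_table(
    genotypes: pd.DataFrame,
    snp_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per (locus, population, year) allele frequencies with missing-data rules.

    ``genotypes`` holds one row per individual with columns individual,
    population, year and one 0/1/2/NaN dosage column per SNP.  Frequencies
    are left undefined (NaN) when fewer than five individuals have data.
    """
    if snp_columns is None:
        snp_columns = [
            c for c in genotypes.columns
            if c not in ("individual", "population", "year")
        ]
    rows = []
    for (pop, year), grp in genotypes.groupby(["population", "year"]):
        dos = grp[snp_columns].to_numpy(dtype=float)
        n_with = np.sum(~np.isnan(dos), axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(dos, axis=0) / (2.0 * n_with)
        freq = np.where(n_with >= MIN_INDIVIDUALS, freq, np.nan)
        for snp, f, n in zip(snp_columns, freq, n_with):
            rows.append({
                "locus": snp, "population": pop, "year": year,
                "frequency": f, "n_individuals": int(n),
            })
    return pd.DataFrame(rows)


def _check_freq(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def fst(p1: float, p2: float) -> float:
    """Two-population FST from expected heterozygosities.

    H_T = 2 p_bar (1 - p_bar) with p_bar the unweighted mean frequency;
    H_S = mean of the two within-population heterozygosities.  Undefined
    (NaN) when H_T = 0, i.e. both populations fixed for the same allele.
    """
    _check_freq(p1, "p1")
    _check_freq(p2, "p2")
    pbar = 0.5 * (p1 + p2)
    h_t = 2.0 * pbar * (1.0 - pbar)
    if h_t == 0.0:
        return float("nan")
    h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return (h_t - h_s) / h_t


def signed_temporal_fst(
    p_start: float, p_end: float, p_crab: float, p_wave: float
) -> float:
    """Temporal FST signed by the direction of the Wave-major allele.

    Magnitude is fst(p_start, p_end); the sign is positive when the allele
    more common in the spatial Wave reference increased from start to end,
    negative when it decreased, and the value is 0 for no change.  Undefined
    (NaN) when the two spatial references do not differ.
    """
    for name, p in (("p_start", p_start), ("p_end", p_end),
                    ("p_crab", p_crab), ("p_wave", p_wave)):
        _check_freq(p, name)
    if p_crab == p_wave:
        return float("nan")
    if p_start == p_end:
        return 0.0
    magnitude = fst(p_start, p_end)
    wave_direction = math.copysign(1.0, p_wave - p_crab)
    change_direction = math.copysign(1.0, p_end - p_start)
    return magnitude * wave_direction * change_direction


def multilocus_fst(
    freq_table: pd.DataFrame,
    pop_a: tuple[str, int | None],
    pop_b: tuple[str, int | None],
    loci: list[str] | None = None,
) -> float:
    """Multi-locus FST as a ratio of sums, sum(H_T - H_S) / sum(H_T).

    ``pop_a`` / ``pop_b`` are (population, year) pairs; a year of None merges
    all years of that population (frequencies averaged weighted by
    individuals with data).  Loci with undefined frequencies or H_T = 0 are
    dropped.
    """
    def freqs(pop_year):
        pop, year = pop_year
        sub = freq_table[freq_table["population"] == pop]
        if year is not None:
            sub = sub[sub["year"] == year]
        sub = sub.dropna(subset=["frequency"])
        w = sub["n_individuals"]
        return (
            sub.assign(w=w)
            .groupby("locus")
            .apply(lambda g: np.average(g["frequency"], weights=g["w"]),
                   include_groups=False)
        )

    fa, fb = freqs(pop_a), freqs(pop_b)
    common = fa.index.intersection(fb.index)
    if loci is not None:
        common = common.intersection(loci)
    num = den = 0.0
    used = 0
    for loc in common:
        p1, p2 = float(fa[loc]), float(fb[loc])
        pbar = 0.5 * (p1 + p2)
        h_t = 2.0 * pbar * (1.0 - pbar)
        if h_t == 0.0:
            continue
        h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
        num += h_t - h_s
        den += h_t
        used += 1
    if used == 0:
        raise ValueError("no usable loci for multilocus FST")
    return num / den


def fraction_shifted_toward_wave(
    p_1992: np.ndarray,
    p_t: np.ndarray,
    p_wave: np.ndarray,
) -> tuple[float, int]:
    """Proportion of loci whose frequency moved toward the source population.

    A locus counts as shifted when sign(p_t - p_1992) equals
    sign(p_wave - p_1992); unchanged loci count as not shifted; loci with
    p_1992 = p_wave are excluded.  Returns (proportion, n_excluded).
    """
    p_1992 = np.asarray(p_1992, dtype=float)
    p_t = np.asarray(p_t, dtype=float)
    p_wave = np.asarray(p_wave, dtype=float)
    defined = ~(np.isnan(p_1992) | np.isnan(p_t) | np.isnan(p_wave))
    usable = defined & (p_wave != p_1992)
    n_excluded = int(defined.sum() - usable.sum())
    if not usable.any():
        raise ValueError("no usable loci (all have p_1992 == p_wave or missing data)")
    shifted = np.sign(p_t[usable] - p_1992[usable]) == np.sign(
        p_wave[usable] - p_1992[usable]
    )
    moved = (p_t[usable] != p_1992[usable])
    return float((shifted & moved).mean()), n_excluded


def space_time_correlation(
    records: list[SignedFstRecord],
) -> tuple[float, float]:
    """Spearman rank correlation of spatial vs signed temporal differentiation."""
    if len(records) < 5:
        raise ValueError("need at least 5 records")
    spatial = np.array([r.spatial_fst for r in records])
    temporal = np.array([r.temporal_fst for r in records])
    if np.all(spatial == spatial[0]) or np.all(temporal == temporal[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(spatial, temporal)
    return float(rho), float(p)


def allele_count_fisher_test(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-copy contingency table.

    Rows are populations, columns alleles, entries allele-copy counts
    (2 per diploid individual).  Undefined (NaN) when a margin is zero.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
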