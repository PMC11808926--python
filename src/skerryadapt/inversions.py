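"""Inversion karyotyping from diagnostic-SNP blocks and arrangement tracking.

Individuals are genotyped for each inversion by PCA of the inversion's
diagnostic-SNP dosage matrix followed by k-means clustering of the first two
principal components: 3 clusters for a simple inversion (two arrangements),
6 for a complex one (three arrangements).  Homokaryotype clusters sit at the
extremes of PC space, heterokaryotypes in between.  Arrangement frequencies
are obtained by allele counting within clusters, and the "Wave arrangement"
is the one most enriched in the Wave ecotype relative to the Crab ecotype
(merged 2018 + 2021 samples).  Each inversion can then be treated as a
single biallelic locus and passed through the neutral-envelope machinery.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .envelope import ExpectedRange, LocusClassification, classify_locus, expected_range_for_locus
from .likelihood import LikelihoodSurface, SampleSeries

__all__ = [
    "InversionDef",
    "KaryotypeAssignment",
    "karyotype_individuals",
    "arrangement_frequencies",
    "inversion_neutral_envelope",
    "arrangement_sample_series",
]

_ARRANGEMENT_NAMES = ("A", "B", "C")


@dataclass(frozen=True)
class InversionDef:
    """Diagnostic-SNP block defining one inversion."""

    name: str
    snp_ids: tuple[str, ...]
    complexity: str  # "simple" -> 2 arrangements / 3 karyotypes; "complex" -> 3 / 6

    def __post_init__(self) -> None:
        if len(self.snp_ids) < 4:
            raise ValueError(f"{self.name}: need >= 4 diagnostic SNPs")
        if self.complexity not in ("simple", "complex"):
            raise ValueError(f"complexity must be simple/complex, got {self.complexity}")

    @property
    def n_clusters(self) -> int:
        return 3 if self.complexity == "simple" else 6

    @property
    def n_arrangements(self) -> int:
        return 2 if self.complexity == "simple" else 3


@dataclass(frozen=True)
class KaryotypeAssignment:
    individual: str
    inversion: str
    karyotype: tuple[str, str]  # ordered arrangement pair, e.g. ("A", "B")
    cluster: int
    pc1: float
    pc2: float


def _map_clusters_simple(centroids: np.ndarray) -> dict[int, tuple[str, str]]:
    """3 clusters ranked along PC1: extremes homokaryotypes, middle het."""
    order = np.argsort(centroids[:, 0])
    return {
        int(order[0]): ("A", "A"),
        int(order[1]): ("A", "B"),
        int(order[2]): ("B", "B"),
    }


def _map_clusters_complex(centroids: np.ndarray) -> dict[int, tuple[str, str]]:
    """6 clusters: the maximally spread triple are homokaryotypes; each
    remaining cluster is the heterokaryotype of the homokaryotype pair whose
    centroid midpoint it sits closest to (a heterokaryotype is the genotypic
    average of its two homokaryotypes, so the midpoint criterion stays
    well-posed even when raw centroid distances tie)."""
    best_triple, best_spread = None, -np.inf
    for triple in itertools.combinations(range(len(centroids)), 3):
        pts = centroids[list(triple)]
        spread = sum(
            np.linalg.norm(pts[i] - pts[j])
            for i, j in itertools.combinations(range(3), 2)
        )
        if spread > best_spread:
            best_triple, best_spread = triple, spread
    homo = list(best_triple)
    # arrangement names by PC1 order of homokaryotype centroids
    homo_sorted = sorted(homo, key=lambda c: centroids[c, 0])
    arr_of = {c: _ARRANGEMENT_NAMES[i] for i, c in enumerate(homo_sorted)}
    mapping: dict[int, tuple[str, str]] = {
        c: (arr_of[c], arr_of[c]) for c in homo
    }
    pairs = list(itertools.combinations(homo, 2))
    for c in range(len(centroids)):
        if c in mapping:
            continue
        mid_dist = [
            np.linalg.norm(centroids[c] - 0.5 * (centroids[a] + centroids[b]))
            for a, b in pairs
        ]
        a, b = pairs[int(np.argmin(mid_dist))]
        mapping[c] = tuple(sorted((arr_of[a], arr_of[b])))
    return mapping


def karyotype_individuals(
    genotypes: pd.DataFrame,
    inversion: InversionDef,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Assign an inversion karyotype to every individual.

    ``genotypes`` holds one row per individual (column ``individual`` plus
    dosage columns); missing genotypes must have been imputed upstream.
    Returns a per-individual table (individual, karyotype, cluster, pc1, pc2)
    plus a diagnostics dict with the silhouette score and a heterozygosity
    consistency flag — heterokaryotype clusters are expected to carry higher
    mean per-SNP heterozygosity than homokaryotype clusters.
    """
    X = genotypes[list(inversion.snp_ids)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing genotypes must be imputed before karyotyping")
    if len(X) < inversion.n_clusters:
        raise ValueError(
            f"{len(X)} individuals < {inversion.n_clusters} clusters"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError(
            f"{inversion.name}: no genotype variance; all individuals appear "
            "to share one karyotype"
        )
    pcs = PCA(n_components=2, random_state=seed).fit_transform(X - X.mean(axis=0))
    km = KMeans(
        n_clusters=inversion.n_clusters, n_init=n_restarts, random_state=seed
    ).fit(pcs)
    mapping = (
        _map_clusters_simple(km.cluster_centers_)
        if inversion.complexity == "simple"
        else _map_clusters_complex(km.cluster_centers_)
    )

    sil = float(silhouette_score(pcs, km.labels_))
    if sil < 0.5:
        warnings.warn(
            f"{inversion.name}: silhouette score {sil:.2f} < 0.5; cluster "
            "separation is weak",
            stacklevel=2,
        )
    het = (X == 1).mean(axis=1)
    homo_clusters = [c for c, kt in mapping.items() if kt[0] == kt[1]]
    het_clusters = [c for c, kt in mapping.items() if kt[0] != kt[1]]
    mean_het_homo = float(np.mean([het[km.labels_ == c].mean() for c in homo_clusters]))
    mean_het_het = (
        float(np.mean([het[km.labels_ == c].mean() for c in het_clusters]))
        if het_clusters else float("nan")
    )
    het_ok = bool(np.isnan(mean_het_het) or mean_het_het > mean_het_homo)
    if not het_ok:
        warnings.warn(
            f"{inversion.name}: heterokaryotype clusters do not show elevated "
            "heterozygosity; karyotype mapping may be unreliable",
            stacklevel=2,
        )

    table = pd.DataFrame({
        "individual": genotypes["individual"].to_numpy(),
        "inversion": inversion.name,
        "karyotype": ["/".join(mapping[int(c)]) for c in km.labels_],
        "cluster": km.labels_,
        "pc1": pcs[:, 0],
        "pc2": pcs[:, 1],
    })
    diagnostics = {
        "silhouette": sil,
        "heterozygosity_consistent": het_ok,
        "mean_het_homokaryotype": mean_het_homo,
        "mean_het_heterokaryotype": mean_het_het,
    }
    return table, diagnostics


def arrangement_frequencies(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, str | None]:
    """Arrangement frequencies per population-year and the Wave arrangement.

    ``assignments`` is the karyotype table from :func:`karyotype_individuals`;
    ``metadata`` maps individual -> population, year.  Frequencies count
    arrangement alleles within karyotypes divided by 2n.  The Wave
    arrangement is the one with the largest frequency excess in the Wave
    ecotype over the Crab ecotype, using merged 2018 + 2021 samples; it is
    None when either reference sample is absent.
    """
    merged = assignments.merge(metadata, on="individual", how="left")
    rows = []
    for (pop, year), grp in merged.groupby(["population", "year"]):
        counts: dict[str, int] = {}
        for kt in grp["karyotype"]:
            for arr in kt.split("/"):
                counts[arr] = counts.get(arr, 0) + 1
        total = 2 * len(grp)
        for arr, ct in sorted(counts.items()):
            rows.append({
                "population": pop, "year": year, "arrangement": arr,
                "count": ct, "frequency": ct / total, "n_individuals": len(grp),
            })
    freq = pd.DataFrame(rows)

    def merged_freqs(pop: str) -> pd.Series | None:
        sub = freq[(freq["population"] == pop) & (freq["year"].isin([2018, 2021]))]
        if sub.empty:
            return None
        g = sub.groupby("arrangement")
        return g["count"].sum() / (2 * g["n_individuals"].sum())

    wave_f, crab_f = merged_freqs("wave"), merged_freqs("crab")
    wave_arr = None
    if wave_f is not None and crab_f is not None:
        diff = wave_f.sub(crab_f, fill_value=0.0)
        wave_arr = str(diff.idxmax())
    return freq, wave_arr


def arrangement_sample_series(
    freq: pd.DataFrame,
    wave_arrangement: str,
    inversion_name: str,
    p_wave_source: float,
) -> SampleSeries:
    """Collapse arrangement counts to a biallelic series for the envelope.

    The Wave-major arrangement is the focal allele; for complex inversions
    all other arrangements are pooled.  Sample sizes are 2 x karyotyped
    individuals in the skerry samples (1992 uses the Crab donor sample).
    """
    def cell(pop: str, year: int) -> tuple[int, int]:
        sub = freq[(freq["population"] == pop) & (freq["year"] == year)]
        if sub.empty:
            raise ValueError(f"no karyotyped sample for {pop} {year}")
        size = 2 * int(sub["n_individuals"].iloc[0])
        focal = sub.loc[sub["arrangement"] == wave_arrangement, "count"]
        return size, int(focal.iloc[0]) if len(focal) else 0

    cells = [cell("crab", 1992)] + [cell("skerry", y) for y in (2005, 2018, 2021)]
    return SampleSeries(
        locus=inversion_name,
        sample_sizes=tuple(c[0] for c in cells),
        observed_counts=tuple(c[1] for c in cells),
        p_wave=p_wave_source,
    )


def inversion_neutral_envelope(
    series: SampleSeries,
    surface: LikelihoodSurface,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpectedRange, LocusClassification]:
    """Neutral expected range for an inversion treated as a single locus."""
    erange = expected_range_for_locus(series, surface, n_reps=n_reps, seed=seed)
    p_1992 = series.observed_counts[0] / series.sample_sizes[0]
    return erange, classify_locus(erange, series.p_wave, p_1992)
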