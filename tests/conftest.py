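import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skerryadapt.core_model import (
    DemographicParams,
    generation_schedule,
    population_size_trajectory,
    transition_matrix,
)
from skerryadapt.likelihood import SampleSeries


@pytest.fixture
def small_params() -> DemographicParams:
    """A founder of 40 haploid genomes growing to K=150 with 3 migrants/gen."""
    return DemographicParams(n0=40, r=0.3, k=150, m=3, f=2)


def brute_force_log_likelihood(params: DemographicParams, series: SampleSeries) -> float:
    """Exhaustive enumeration over all hidden allele-count paths.

    Independent oracle for the forward algorithm; only feasible for tiny
    populations and short schedules.
    """
    sched = generation_schedule(params.f)
    sizes = population_size_trajectory(params, sched.total_generations)
    mats = [
        transition_matrix(int(sizes[t - 1]), int(sizes[t]), params.m, series.p_wave)
        for t in range(1, sched.total_generations + 1)
    ]
    sample_at = {g: c + 1 for c, g in enumerate(sched.sampling_generations)}
    total = 0.0
    ranges = [range(int(sizes[t]) + 1) for t in range(sched.total_generations + 1)]
    for path in itertools.product(*ranges):
        p = (1.0 / (params.n0 + 1)) * stats.binom.pmf(
            series.observed_counts[0], series.sample_sizes[0], path[0] / params.n0
        )
        for t in range(1, len(path)):
            p *= mats[t - 1][path[t - 1], path[t]]
            if t in sample_at:
                c = sample_at[t]
                p *= stats.binom.pmf(
                    series.observed_counts[c], series.sample_sizes[c],
                    path[t] / sizes[t],
                )
        total += p
    return float(np.log(total))


def hwe_inversion_block(
    freqs, n_individuals, n_snps=16, discordance=0.0, seed=0
):
    """Synthetic diagnostic-SNP block with known karyotype truth.

    Arrangements carry fixed allele profiles (one all-reference, one
    all-alternate, and for three-arrangement inversions one half/half);
    individuals draw two arrangements at Hardy-Weinberg proportions.
    Returns (genotype frame, true karyotypes as index pairs, snp columns).
    """
    rng = np.random.default_rng(seed)
    n_arr = len(freqs)
    profile = np.zeros((n_arr, n_snps), dtype=int)
    profile[1] = 1
    if n_arr == 3:
        profile[2, : n_snps // 2] = 1
    draws = rng.choice(n_arr, size=(n_individuals, 2), p=np.asarray(freqs))
    draws.sort(axis=1)
    dosages = (profile[draws[:, 0]] + profile[draws[:, 1]]).astype(float)
    if discordance > 0:
        noisy = rng.random(dosages.shape) < discordance
        dosages[noisy] = rng.binomial(2, 0.5, int(noisy.sum()))
    cols = [f"snp{j:02d}" for j in range(n_snps)]
    frame = pd.DataFrame(dosages, columns=cols)
    frame.insert(0, "individual", [f"ind{i:03d}" for i in range(n_individuals)])
    return frame, [tuple(d) for d in draws], cols


def karyotype_recovery(table: pd.DataFrame, truth: list, n_arrangements: int) -> float:
    """Best karyotype accuracy over arrangement-label permutations."""
    names = "ABC"[:n_arrangements]
    best = 0
    for perm in itertools.permutations(range(n_arrangements)):
        ok = sum(
            tuple(sorted(kt.split("/")))
            == tuple(sorted(names[perm[a]] for a in true_pair))
            for kt, true_pair in zip(table["karyotype"], truth)
        )
        best = max(best, ok)
    return best / len(truth)
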