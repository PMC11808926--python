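"""Elementary demographic quantities shared by inference and simulation.

The population model is a single founded population (the skerry) growing
logistically from ``n0`` haploid genomes toward a carrying capacity ``k``,
receiving ``m`` haploid migrant genomes per generation from a differentiated
source ("Wave") population, with non-overlapping generations and ``f``
generations per year.  All counts are haploid genome counts; reporting layers
convert to diploid individuals by halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DemographicParams",
    "GenerationSchedule",
    "SourceFrequency",
    "population_size",
    "population_size_trajectory",
    "expected_post_migration_count",
    "transition_matrix",
    "generation_schedule",
    "round_half_up",
    "SAMPLING_YEARS",
]

#: Calendar years at which the transplanted population was sampled.  The
#: first entry is the founding year (the donor population was sampled at the
#: moment of transplant).
SAMPLING_YEARS = (1992, 2005, 2018, 2021)

#: Year gaps between consecutive sampling occasions (13, 13 and 3 years).
_YEAR_GAPS = (13, 13, 3)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    Used for generation counts and population sizes; banker's rounding would
    silently shift sampling schedules for half-integer generation counts.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DemographicParams:
    """Demography of the founded population.

    Parameters
    ----------
    n0 : int
        Haploid founder genome count (>= 2).
    r : float
        Logistic growth rate per generation (>= 0).
    k : int
        Haploid carrying capacity (>= n0).
    m : float
        Haploid migrant genomes per generation from the source population.
    f : float
        Generations per year (> 0).
    """

    n0: int
    r: float
    k: int
    m: float
    f: float

    def __post_init__(self) -> None:
        for name in ("n0", "r", "k", "m", "f"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.n0 < 2 or int(self.n0) != self.n0:
            raise ValueError(f"n0 must be an integer >= 2, got {self.n0}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if self.k < self.n0 or int(self.k) != self.k:
            raise ValueError(f"k must be an integer >= n0, got {self.k}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.m >= self.n0:
            raise ValueError(
                f"m ({self.m}) must be smaller than the founder size n0 ({self.n0})"
            )
        if self.f <= 0:
            raise ValueError(f"f must be > 0, got {self.f}")

    @property
    def m_diploid(self) -> float:
        """Migrants per generation expressed as diploid individuals."""
        return self.m / 2.0


@dataclass(frozen=True)
class GenerationSchedule:
    """Integer generation indices of the post-founding sampling occasions."""

    f: float
    sampling_generations: tuple[int, int, int]
    total_generations: int

    def __post_init__(self) -> None:
        gens = self.sampling_generations
        if not all(b > a for a, b in zip(gens, gens[1:])):
            raise ValueError("sampling generations must be strictly increasing")
        if self.total_generations != gens[-1]:
            raise ValueError("total_generations must equal the last sampling generation")


@dataclass(frozen=True)
class SourceFrequency:
    """Focal-allele frequency in the migrant source (Wave) population."""

    p_wave: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_wave <= 1.0:
            raise ValueError(f"p_wave must lie in [0, 1], got {self.p_wave}")


def generation_schedule(f: float) -> GenerationSchedule:
    """Sampling generations for the 13 + 13 + 3 year sampling design.

    Each inter-sample interval spans ``round(gap * f)`` whole generations,
    rounded half away from zero, so the experiment lasts
    ``round(13f) + round(13f) + round(3f)`` generations in total.
    """
    if f <= 0:
        raise ValueError(f"f must be > 0, got {f}")
    steps = [round_half_up(gap * f) for gap in _YEAR_GAPS]
    gens = tuple(np.cumsum(steps).tolist())
    return GenerationSchedule(f=f, sampling_generations=gens, total_generations=gens[-1])


def population_size(params: DemographicParams, t: int) -> int:
    """Haploid population size at generation ``t`` under logistic growth.

    Evaluates N_t = K / (1 + ((K - N0)/N0) * exp(-r t)), rounded to the
    nearest integer and clamped to [1, K].  ``t = 0`` returns the founder
    size exactly.
    """
    if t < 0:
        raise ValueError(f"generation index must be >= 0, got {t}")
    if t == 0:
        return params.n0
    n0, k, r = params.n0, params.k, params.r
    nt = k / (1.0 + ((k - n0) / n0) * math.exp(-r * t))
    return max(1, min(params.k, round_half_up(nt)))


def population_size_trajectory(params: DemographicParams, total_generations: int) -> np.ndarray:
    """Vector of haploid population sizes for generations 0..total_generations."""
    return np.array(
        [population_size(params, t) for t in range(total_generations + 1)], dtype=int
    )


def expected_post_migration_count(
    i_prev: float, n_prev: int, m: float, p_wave: float
) -> float:
    """Expected focal-allele copy number after one round of migration.

    ``m`` of the ``n_prev`` resident genomes are replaced by migrant genomes
    carrying the focal allele at frequency ``p_wave``:

        i_exp = (i_prev / n_prev) * (n_prev - m) + p_wave * m
    """
    if not 0 <= i_prev <= n_prev:
        raise ValueError(f"i_prev must lie in [0, n_prev], got {i_prev} / {n_prev}")
    if m > n_prev:
        raise ValueError(f"m ({m}) cannot exceed the population size ({n_prev})")
    return (i_prev / n_prev) * (n_prev - m) + p_wave * m


def _selection_update(p: np.ndarray, s: float) -> np.ndarray:
    """Deterministic genic selection update p' = p(1+s) / (1 + p s)."""
    return p * (1.0 + s) / (1.0 + p * s)


def drift_success_probability(
    n_prev: int, m: float, p_wave: float, s: float = 0.0
) -> np.ndarray:
    """Binomial success probabilities for every parental count 0..n_prev.

    Migration acts first (shifting the expectation), then optional genic
    selection on the post-migration frequency, then the result is clamped to
    a valid probability.
    """
    i = np.arange(n_prev + 1, dtype=float)
    i_exp = (i / n_prev) * (n_prev - m) + p_wave * m
    p = np.clip(i_exp / n_prev, 0.0, 1.0)
    if s != 0.0:
        p = _selection_update(p, s)
    return p


def transition_matrix(
    n_prev: int, n_next: int, m: float = 0.0, p_wave: float = 0.0, s: float = 0.0
) -> np.ndarray:
    """Row-stochastic allele-count transition matrix for one generation.

    Entry ``[i, j]`` is the probability that ``i`` focal copies among
    ``n_prev`` parental genomes leave ``j`` copies among ``n_next`` offspring
    genomes: drift is binomial sampling of ``n_next`` genomes with success
    probability equal to the post-migration (optionally post-selection)
    frequency.
    """
    if n_prev < 1 or n_next < 1:
        raise ValueError("population sizes must be >= 1")
    p = drift_success_probability(n_prev, m, p_wave, s)
    j = np.arange(n_next + 1)
    return stats.binom.pmf(j[None, :], n_next, p[:, None])


def binomial_row_matrix(p: np.ndarray, n: int) -> np.ndarray:
    """Binomial pmf rows, one per success probability, computed in log space.

    Equivalent to ``stats.binom.pmf(arange(n+1), n, p[:, None])`` but built
    from two outer products and a single exp, which matters inside the
    likelihood's per-generation loop.
    """
    from scipy.special import gammaln

    p = np.asarray(p, dtype=float)
    j = np.arange(n + 1, dtype=float)
    logc = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    interior = np.clip(p, 1e-300, 1.0 - 1e-16)
    with np.errstate(divide="ignore"):
        logm = logc[None, :] + j[None, :] * np.log(interior[:, None])
        logm += (n - j)[None, :] * np.log1p(-interior[:, None])
    out = np.exp(logm)
    # exact absorbing rows for boundary probabilities
    zero = p <= 0.0
    one = p >= 1.0
    if zero.any():
        out[zero] = 0.0
        out[zero, 0] = 1.0
    if one.any():
        out[one] = 0.0
        out[one, n] = 1.0
    return out
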