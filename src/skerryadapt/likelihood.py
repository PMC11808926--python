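"""Maximum-likelihood demographic inference from allele-count time series.

The probability of an observed per-locus sample-count vector
``k = (k_1992, k_2005, k_2018, k_2021)`` is computed by summing over the
hidden true allele counts in the population at every generation:

    p(k) = sum  psi_92 * s_92 * M_92->05 * s_05 * M_05->18 * s_18
                * M_18->21 * s_21

where ``psi_92`` is a uniform prior over founder allele counts, ``s_T`` are
binomial sampling probabilities, and ``M`` chains one-generation
migration-drift transition matrices.  The sum is evaluated with a forward
algorithm (sequential matrix-vector products), never by naive enumeration,
but is numerically equal to it.

The 1992 sample is a binomial draw from the hidden founder allele count: the
donor sample was collected from the same pool of snails at the moment of
transplant, so the 1992 sample and the skerry founders are coupled through
the hidden 1992 state.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .core_model import (
    DemographicParams,
    binomial_row_matrix,
    drift_success_probability,
    generation_schedule,
    population_size_trajectory,
)

__all__ = [
    "SampleSeries",
    "LikelihoodSurface",
    "SupportInterval",
    "TransitionCache",
    "locus_log_likelihood",
    "dataset_neg_log_likelihood",
    "grid_search",
    "refine_and_support_limits",
    "sample_parameters_from_surface",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("n0", "r", "k", "m", "f")


@dataclass(frozen=True)
class SampleSeries:
    """Observed allele counts for one locus at the four sampling times.

    ``sample_sizes`` and ``observed_counts`` are in allele copies
    (2 x diploid individuals), ordered (1992, 2005, 2018, 2021).
    """

    locus: str
    sample_sizes: tuple[int, int, int, int]
    observed_counts: tuple[int, int, int, int]
    p_wave: float

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != 4 or len(self.observed_counts) != 4:
            raise ValueError("exactly four sampling times are required")
        for ss, k in zip(self.sample_sizes, self.observed_counts):
            if ss < 2:
                raise ValueError(f"sample sizes must be >= 2 allele copies, got {ss}")
            if not 0 <= k <= ss:
                raise ValueError(f"observed count {k} outside [0, {ss}]")
        if not 0.0 <= self.p_wave <= 1.0:
            raise ValueError(f"p_wave must lie in [0, 1], got {self.p_wave}")

    def relabeled(self) -> "SampleSeries":
        """The same data with allele labels swapped (counts and p_wave flipped)."""
        return SampleSeries(
            locus=self.locus,
            sample_sizes=self.sample_sizes,
            observed_counts=tuple(
                s - k for s, k in zip(self.sample_sizes, self.observed_counts)
            ),
            p_wave=1.0 - self.p_wave,
        )


@dataclass
class SupportInterval:
    """Profile-likelihood support interval (2-unit negative-log drop)."""

    parameter: str
    lower: float
    upper: float


@dataclass
class LikelihoodSurface:
    """Grid of parameter combinations with negative log-likelihoods."""

    table: pd.DataFrame  # columns n0, r, k, m, f, negloglik
    interpolated_best: dict = field(default_factory=dict)
    support_intervals: dict = field(default_factory=dict)

    @property
    def best_index(self) -> int:
        return int(self.table["negloglik"].idxmin())

    @property
    def best_params(self) -> DemographicParams:
        row = self.table.loc[self.best_index]
        return DemographicParams(
            n0=int(row["n0"]), r=float(row["r"]), k=int(row["k"]),
            m=float(row["m"]), f=float(row["f"]),
        )

    def params_at(self, index: int) -> DemographicParams:
        row = self.table.loc[index]
        return DemographicParams(
            n0=int(row["n0"]), r=float(row["r"]), k=int(row["k"]),
            m=float(row["m"]), f=float(row["f"]),
        )


class TransitionCache:
    """Bounded cache of one-generation transition matrices.

    Only square matrices (constant population size, i.e. the post-growth
    phase) are retained: these are reused for dozens of generations within a
    locus and across grid points sharing m and p_wave, while growth-phase
    matrices are used once each.
    """

    def __init__(self, max_entries: int = 512) -> None:
        self._store: OrderedDict = OrderedDict()
        self.max_entries = max_entries

    def get(
        self, n_prev: int, n_next: int, m: float, p_wave: float, s: float = 0.0
    ) -> np.ndarray:
        key = (n_prev, n_next, m, p_wave, s)
        mat = self._store.get(key)
        if mat is not None:
            self._store.move_to_end(key)
            return mat
        p = drift_success_probability(n_prev, m, p_wave, s)
        mat = binomial_row_matrix(p, n_next)
        if n_prev == n_next:
            self._store[key] = mat
            if len(self._store) > self.max_entries:
                self._store.popitem(last=False)
        return mat


def _sampling_weights(
    n_pop: int, sample_size: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Per-locus binomial sampling weights over hidden counts 0..n_pop.

    Row l, column i: probability of drawing ``observed[l]`` focal copies in a
    sample of ``sample_size[l]`` copies when the population of ``n_pop``
    genomes carries ``i`` focal copies.
    """
    freq = np.arange(n_pop + 1, dtype=float) / n_pop
    return stats.binom.pmf(
        observed[:, None], sample_size[:, None], freq[None, :]
    )


def _forward_group(
    params: DemographicParams,
    sizes: np.ndarray,
    sampling_gens: tuple[int, ...],
    p_wave: float,
    sample_sizes: np.ndarray,
    observed: np.ndarray,
    cache: TransitionCache,
    s: float = 0.0,
) -> np.ndarray:
    """Log-likelihoods for a batch of loci sharing one source frequency.

    ``sample_sizes`` and ``observed`` are (n_loci, 4) arrays ordered
    (1992, 2005, 2018, 2021).
    """
    n_loci = observed.shape[0]
    logp = np.zeros(n_loci)

    # founding generation: uniform prior coupled to the 1992 donor sample
    v = np.full((n_loci, params.n0 + 1), 1.0 / (params.n0 + 1))
    v = v * _sampling_weights(params.n0, sample_sizes[:, 0], observed[:, 0])

    sample_at = {g: idx + 1 for idx, g in enumerate(sampling_gens)}
    total = sampling_gens[-1]
    for t in range(1, total + 1):
        mat = cache.get(int(sizes[t - 1]), int(sizes[t]), params.m, p_wave, s)
        v = v @ mat
        if t in sample_at:
            col = sample_at[t]
            v = v * _sampling_weights(int(sizes[t]), sample_sizes[:, col], observed[:, col])
            norm = v.sum(axis=1)
            with np.errstate(divide="ignore"):
                logp += np.log(norm)
            # impossible observations leave a zero vector; keep it zero
            safe = np.where(norm > 0.0, norm, 1.0)
            v = v / safe[:, None]
    return logp


def _group_log_likelihoods(
    params: DemographicParams,
    loci: list[SampleSeries],
    cache: TransitionCache | None = None,
    s: float = 0.0,
) -> np.ndarray:
    """Per-locus log-likelihoods, batching loci that share p_wave."""
    if not loci:
        raise ValueError("at least one locus is required")
    cache = cache if cache is not None else TransitionCache()
    sched = generation_schedule(params.f)
    sizes = population_size_trajectory(params, sched.total_generations)

    out = np.empty(len(loci))
    order = np.argsort([lc.p_wave for lc in loci], kind="stable")
    i = 0
    while i < len(order):
        j = i
        pw = loci[order[i]].p_wave
        while j < len(order) and loci[order[j]].p_wave == pw:
            j += 1
        idx = order[i:j]
        ss = np.array([loci[g].sample_sizes for g in idx])
        ks = np.array([loci[g].observed_counts for g in idx])
        out[idx] = _forward_group(
            params, sizes, sched.sampling_generations, pw, ss, ks, cache, s=s
        )
        i = j
    return out


def locus_log_likelihood(
    params: DemographicParams,
    series: SampleSeries,
    cache: TransitionCache | None = None,
    s: float = 0.0,
) -> float:
    """Log-probability of one locus's sample-count vector under ``params``."""
    val = float(_group_log_likelihoods(params, [series], cache=cache, s=s)[0])
    if np.isnan(val):
        raise ValueError(f"non-finite log-likelihood for locus {series.locus}")
    return val


def dataset_neg_log_likelihood(
    params: DemographicParams,
    loci: list[SampleSeries],
    cache: TransitionCache | None = None,
) -> float:
    """Total negative log-likelihood over loci (independent-locus sum)."""
    logps = _group_log_likelihoods(params, loci, cache=cache)
    if np.isnan(logps).any():
        raise ValueError("non-finite log-likelihood encountered")
    return float(-logps.sum())


def grid_search(
    grid_spec: dict,
    loci: list[SampleSeries],
    fixed_f: float | None = None,
    cache: TransitionCache | None = None,
) -> LikelihoodSurface:
    """Evaluate the dataset likelihood on a Cartesian parameter grid.

    ``grid_spec`` maps parameter names (n0, r, k, m, f) to value lists.
    Combinations violating the demographic invariants are skipped with a log
    record.  Transition matrices are cached across grid points.
    """
    spec = dict(grid_spec)
    if fixed_f is not None:
        spec["f"] = [fixed_f]
    missing = [p for p in PARAM_NAMES if p not in spec]
    if missing:
        raise ValueError(f"grid_spec missing parameters: {missing}")
    if not loci:
        raise ValueError("at least one locus is required")

    cache = cache if cache is not None else TransitionCache()
    rows = []
    for combo in itertools.product(*(spec[p] for p in PARAM_NAMES)):
        kwargs = dict(zip(PARAM_NAMES, combo))
        try:
            params = DemographicParams(
                n0=int(kwargs["n0"]), r=float(kwargs["r"]), k=int(kwargs["k"]),
                m=float(kwargs["m"]), f=float(kwargs["f"]),
            )
        except ValueError as exc:
            logger.info("skipping invalid grid point %s: %s", kwargs, exc)
            continue
        try:
            nll = dataset_neg_log_likelihood(params, loci, cache=cache)
        except ValueError as exc:
            logger.info("skipping grid point %s: %s", kwargs, exc)
            continue
        rows.append({**kwargs, "negloglik": nll})
    if not rows:
        raise ValueError("no valid grid point could be evaluated")
    return LikelihoodSurface(table=pd.DataFrame(rows).reset_index(drop=True))


def profile(surface: LikelihoodSurface, parameter: str) -> pd.DataFrame:
    """Profile negative log-likelihood along one parameter (min over others)."""
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    prof = (
        surface.table.groupby(parameter)["negloglik"].min().reset_index()
        .sort_values(parameter)
    )
    return prof


def refine_and_support_limits(
    surface: LikelihoodSurface,
    parameter: str,
    drop: float = 2.0,
    n_dense: int = 2001,
) -> tuple[float, SupportInterval]:
    """Cubic interpolation of the profile likelihood plus support limits.

    The optimum is the minimum of a cubic-spline interpolation of the profile
    negative log-likelihood; support limits are the outermost points where
    the interpolated profile rises ``drop`` units above the interpolated
    minimum, bounded by the grid range.
    """
    prof = profile(surface, parameter)
    x = prof[parameter].to_numpy(dtype=float)
    y = prof["negloglik"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError(
            f"need >= 4 grid values along {parameter!r}, got {len(x)}"
        )
    spline = CubicSpline(x, y)
    xd = np.linspace(x[0], x[-1], n_dense)
    yd = spline(xd)
    i_min = int(np.argmin(yd))
    opt = float(xd[i_min])
    y_min = float(yd[i_min])

    below = yd <= y_min + drop
    lower = float(xd[np.argmax(below)])
    upper = float(xd[len(below) - 1 - np.argmax(below[::-1])])
    if below[0] or below[-1]:
        warnings.warn(
            f"profile for {parameter!r} does not rise {drop} units above the "
            "minimum on at least one side; support interval truncated at the "
            "grid range",
            stacklevel=2,
        )
    interval = SupportInterval(parameter=parameter, lower=lower, upper=upper)
    surface.interpolated_best[parameter] = opt
    surface.support_intervals[parameter] = interval
    return opt, interval


def sample_parameters_from_surface(
    surface: LikelihoodSurface,
    n_draws: int,
    seed: int | np.random.Generator,
) -> list[DemographicParams]:
    """Draw grid points with probability proportional to their likelihood."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    nll = surface.table["negloglik"].to_numpy(dtype=float)
    w = np.exp(-(nll - nll.min()))
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError("likelihood surface has no usable mass")
    idx = rng.choice(len(w), size=n_draws, p=w / total)
    return [surface.params_at(int(i)) for i in idx]
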