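"""Stabilizing-selection fits and phenotype screening.

The phenotype model assumes Gaussian stabilizing selection around an optimum
``O`` equal to the mean phenotype of the source (Wave) population:

    w(x) = exp(-(x - O)^2 / (2 V_s))

so the mean phenotype responds each generation by

    dx = (O - xbar) * V_g / (V_s + V_p)

starting from the donor mean plus a plastic offset, ``xbar_crab + p``.  The
fit estimates the ratio V_s/V_p (flat prior on [0, 50]), the plastic effect
``p`` and additive variance ``V_g`` (Gaussian priors from prior transect
studies), the optimum, the donor mean, and a shared phenotypic variance, by
MCMC over all individual trait values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import generation_schedule

__all__ = [
    "TraitConfig",
    "DEFAULT_TRAIT_CONFIGS",
    "StabilizingSelectionFit",
    "RateRecord",
    "FitnessSummary",
    "mean_phenotype_trajectory",
    "fit_stabilizing_selection",
    "fitness_and_reduction",
    "evolutionary_rates",
    "screen_informative_traits",
    "unimodality_test",
    "apply_trait_config",
]


@dataclass(frozen=True)
class TraitConfig:
    """Transformation rules for one shell trait."""

    name: str
    transform: str = "none"  # "log" or "none"
    relative_to_length: bool = False


#: Shell length and the five shape/growth traits with their conventional
#: transforms: height growth, aperture position and length are analyzed on a
#: log scale; width growth untransformed; aperture radius and position are
#: expressed relative to shell length.
DEFAULT_TRAIT_CONFIGS = (
    TraitConfig("length", transform="log"),
    TraitConfig("g_w", transform="none"),
    TraitConfig("g_h", transform="log"),
    TraitConfig("a0", transform="none", relative_to_length=True),
    TraitConfig("r0", transform="log", relative_to_length=True),
    TraitConfig("c", transform="none"),
    TraitConfig("thickness", transform="none"),
)


def apply_trait_config(
    df: pd.DataFrame, config: TraitConfig, length_column: str = "length"
) -> pd.Series:
    """Apply the trait's ratio-to-length and log transforms to a wide table."""
    vals = df[config.name].astype(float)
    if config.relative_to_length:
        vals = vals / df[length_column].astype(float)
    if config.transform == "log":
        vals = np.log(vals)
    return vals


def mean_phenotype_trajectory(
    x_start: float,
    optimum: float,
    v_g: float,
    v_s: float,
    v_p: float,
    n_generations: int,
) -> np.ndarray:
    """Deterministic mean-phenotype recursion toward the optimum.

    Iterates dx = (O - xbar) V_g / (V_s + V_p) for ``n_generations``
    generations; index 0 is the starting mean (donor mean plus plasticity).
    """
    if v_s + v_p <= 0:
        raise ValueError("V_s + V_p must be positive")
    if v_g < 0:
        raise ValueError("V_g must be >= 0")
    rate = v_g / (v_s + v_p)
    if rate > 1.0:
        warnings.warn(
            f"V_g/(V_s+V_p) = {rate:.3f} > 1: overshoot regime outside model validity",
            stacklevel=2,
        )
    out = np.empty(n_generations + 1)
    out[0] = x_start
    x = x_start
    for t in range(1, n_generations + 1):
        x = x + (optimum - x) * rate
        out[t] = x
    return out


@dataclass
class StabilizingSelectionFit:
    """Posterior summary of the stabilizing-selection fit for one trait."""

    trait: str
    draws: pd.DataFrame  # columns: ratio, p, v_g, optimum, x_crab, v_p
    point: dict
    interval: dict  # parameter -> (2.5%, 97.5%)
    rhat: dict
    f: float
    v_g_source: str = "crab"

    @property
    def ratio_median(self) -> float:
        return float(self.point["ratio"])


@dataclass
class FitnessSummary:
    w_no_plasticity: float
    w_with_plasticity: float
    reduction_no_plasticity: float
    reduction_with_plasticity: float


@dataclass
class RateRecord:
    trait: str
    haldanes: float
    darwin_numerator: float  # NaN when the initial mean is zero


def _gaussian_group_stats(values: np.ndarray) -> tuple[int, float, float]:
    n = len(values)
    mean = float(values.mean())
    ss = float(((values - mean) ** 2).sum())
    return n, mean, ss


def fit_stabilizing_selection(
    data: pd.DataFrame,
    trait: str,
    p_prior: tuple[float, float],
    v_g_prior: tuple[float, float],
    f: float = 2.0,
    ratio_bounds: tuple[float, float] = (0.0, 50.0),
    chains: int = 4,
    iters: int = 3000,
    burnin: int = 1000,
    walkers_per_chain: int = 12,
    seed: int = 0,
    rhat_threshold: float = 1.05,
    v_g_source: str = "crab",
    value_column: str = "value",
) -> StabilizingSelectionFit:
    """MCMC fit of the stabilizing-selection-with-plasticity model.

    ``data`` must have columns population (crab / wave / skerry), year, and
    the trait value column.  Crab samples (all years merged) inform the donor
    mean; Wave samples (merged) inform the optimum; skerry samples are fitted
    to the trajectory mean at their generation index under ``f`` generations
    per year.  All individuals share one phenotypic variance.  Sampling uses
    ``chains`` independent affine-invariant ensembles of 3000 iterations with
    1000 discarded as burn-in; split-R-hat must come in below 1.05.
    """
    import arviz
    import emcee

    crab = data.loc[data["population"] == "crab", value_column].dropna().to_numpy()
    wave = data.loc[data["population"] == "wave", value_column].dropna().to_numpy()
    skerry = data.loc[data["population"] == "skerry"]
    if len(crab) == 0 or len(wave) == 0 or len(skerry) == 0:
        raise ValueError("crab, wave and skerry samples are all required")

    crab_n, crab_mean, crab_ss = _gaussian_group_stats(crab)
    wave_n, wave_mean, wave_ss = _gaussian_group_stats(wave)
    sk_groups = []
    for year, grp in skerry.groupby("year"):
        vals = grp[value_column].dropna().to_numpy()
        if len(vals) == 0:
            continue
        gen = int(round((year - 1992) * f))
        sk_groups.append((gen, *_gaussian_group_stats(vals)))
    if not sk_groups:
        raise ValueError("no usable skerry samples")
    sk_gens = np.array([g[0] for g in sk_groups])
    sk_ns = np.array([g[1] for g in sk_groups], dtype=float)
    sk_means = np.array([g[2] for g in sk_groups])
    sk_sss = np.array([g[3] for g in sk_groups])
    n_total = crab_n + wave_n + sk_ns.sum()

    pooled_var = np.var(np.concatenate([crab, wave]), ddof=1)
    log_vp_lo, log_vp_hi = math.log(pooled_var) - 10.0, math.log(pooled_var) + 5.0
    p_mu, p_sd = p_prior
    vg_mu, vg_sd = v_g_prior
    lo_ratio, hi_ratio = ratio_bounds

    def log_prob(theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for a (nwalkers, 6) parameter block."""
        theta = np.atleast_2d(theta)
        ratio, p, v_g, opt, x_crab, log_vp = theta.T
        lp = np.zeros(len(theta))
        bad = (
            (ratio < lo_ratio) | (ratio > hi_ratio) | (v_g <= 0)
            | (log_vp < log_vp_lo) | (log_vp > log_vp_hi)
        )
        lp[bad] = -np.inf
        ok = ~bad
        if not ok.any():
            return lp if theta.shape[0] > 1 else lp[0]
        v_p = np.exp(log_vp[ok])
        v_s = ratio[ok] * v_p
        lam = 1.0 - v_g[ok] / (v_s + v_p)
        x0 = x_crab[ok] + p[ok]
        # Gaussian priors on the plastic effect and additive variance
        prior = (
            -0.5 * ((p[ok] - p_mu) / p_sd) ** 2
            - 0.5 * ((v_g[ok] - vg_mu) / vg_sd) ** 2
        )
        ll = -0.5 * n_total * (np.log(2 * np.pi) + log_vp[ok])
        ll -= 0.5 * (crab_ss + crab_n * (crab_mean - x_crab[ok]) ** 2) / v_p
        ll -= 0.5 * (wave_ss + wave_n * (wave_mean - opt[ok]) ** 2) / v_p
        # closed-form trajectory mean at each skerry sampling generation
        mu_sk = opt[ok, None] + (x0[:, None] - opt[ok, None]) * lam[:, None] ** sk_gens[None, :]
        ll -= 0.5 * np.sum(
            (sk_sss[None, :] + sk_ns[None, :] * (sk_means[None, :] - mu_sk) ** 2),
            axis=1,
        ) / v_p
        lp[ok] = prior + ll
        return lp if theta.shape[0] > 1 else lp[0]

    ndim = 6
    rng = np.random.default_rng(seed)
    chain_draws = []
    for _ in range(chains):
        p0 = np.column_stack([
            rng.uniform(lo_ratio + 0.5, min(hi_ratio, 30.0), walkers_per_chain),
            rng.normal(p_mu, max(p_sd, 1e-3), walkers_per_chain),
            np.abs(rng.normal(vg_mu, max(vg_sd, 1e-4), walkers_per_chain)) + 1e-8,
            rng.normal(wave_mean, math.sqrt(pooled_var / wave_n), walkers_per_chain),
            rng.normal(crab_mean, math.sqrt(pooled_var / crab_n), walkers_per_chain),
            rng.normal(math.log(pooled_var), 0.2, walkers_per_chain),
        ])
        sampler = emcee.EnsembleSampler(
            walkers_per_chain, ndim, log_prob, vectorize=True,
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31))
        ).get_state()
        sampler.run_mcmc(p0, iters, progress=False)
        chain_draws.append(sampler.get_chain(discard=burnin))  # (draw, walker, dim)

    # R-hat across the independent ensembles (walkers pooled within a chain)
    names = ["ratio", "p", "v_g", "optimum", "x_crab", "log_vp"]
    stacked = np.stack(
        [c.reshape(-1, ndim) for c in chain_draws]
    )  # (chain, draw, dim)
    rhat = {}
    for d, name in enumerate(names):
        rhat[name] = float(
            arviz.rhat(arviz.convert_to_dataset(stacked[:, :, d]))["x"].values
        )
    if max(rhat.values()) > rhat_threshold:
        raise RuntimeError(
            f"MCMC did not converge for trait {trait!r}: R-hat = {rhat}"
        )

    flat = stacked.reshape(-1, ndim)
    draws = pd.DataFrame(flat, columns=names)
    draws["v_p"] = np.exp(draws.pop("log_vp"))
    point = {c: float(draws[c].median()) for c in draws.columns}
    interval = {
        c: tuple(np.quantile(draws[c], [0.025, 0.975]).tolist())
        for c in draws.columns
    }
    return StabilizingSelectionFit(
        trait=trait, draws=draws, point=point, interval=interval,
        rhat=rhat, f=f, v_g_source=v_g_source,
    )


def fitness_and_reduction(
    x_crab: float, p: float, optimum: float, v_s: float
) -> FitnessSummary:
    """Gaussian fitness of the donor mean phenotype in the new environment.

    Computed with and without the plastic offset; the reduction is 1 - w.
    """
    if v_s <= 0:
        raise ValueError("V_s must be positive")
    w_no = math.exp(-((x_crab - optimum) ** 2) / (2.0 * v_s))
    w_pl = math.exp(-((x_crab + p - optimum) ** 2) / (2.0 * v_s))
    return FitnessSummary(
        w_no_plasticity=w_no,
        w_with_plasticity=w_pl,
        reduction_no_plasticity=1.0 - w_no,
        reduction_with_plasticity=1.0 - w_pl,
    )


def evolutionary_rates(
    x_start: float,
    x_end: float,
    pooled_sd: float,
    n_generations: int,
    trait: str = "",
) -> RateRecord:
    """Haldane rate (SD per generation) and proportional change in the mean.

    The second quantity is the absolute change divided by the initial mean
    (undefined, reported as NaN, when the initial mean is zero).
    """
    if pooled_sd <= 0:
        raise ValueError("pooled_sd must be positive")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    change = abs(x_end - x_start)
    haldanes = change / (pooled_sd * n_generations)
    darwin = change / abs(x_start) if x_start != 0 else float("nan")
    return RateRecord(trait=trait, haldanes=haldanes, darwin_numerator=darwin)


def unimodality_test(
    values: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Mixture-based unimodality check with parametric bootstrap calibration.

    The statistic is the log-likelihood ratio of a two-component versus a
    one-component Gaussian mixture; its null distribution is calibrated by
    refitting on samples simulated from the fitted single Gaussian.  Returns
    (statistic, p-value); small p rejects unimodality.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    values = values[np.isfinite(values[:, 0])].reshape(-1, 1)
    if len(values) < 8:
        raise ValueError("need at least 8 observations")

    def lrt(x: np.ndarray, rs: int) -> float:
        g1 = GaussianMixture(1, random_state=rs).fit(x)
        g2 = GaussianMixture(2, n_init=3, random_state=rs).fit(x)
        return 2.0 * len(x) * (g2.score(x) - g1.score(x))

    stat = lrt(values, 0)
    rng = np.random.default_rng(seed)
    mu, sd = values.mean(), values.std(ddof=1)
    null = np.array([
        lrt(rng.normal(mu, sd, size=len(values)).reshape(-1, 1), b)
        for b in range(n_boot)
    ])
    p = float((np.sum(null >= stat) + 1) / (n_boot + 1))
    return float(stat), p


def screen_informative_traits(
    df: pd.DataFrame,
    traits: list[str],
    corr_threshold: float = 0.5,
    population_column: str = "population",
) -> dict:
    """Screen trait pairs and traits for ecotype informativeness.

    A trait pair is informative when the two traits are strongly correlated
    across ecotypes (Crab + Wave pooled) but weakly correlated within each
    ecotype.  A single trait is informative when the interquartile range of
    each ecotype excludes every individual of the other ecotype.
    """
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    pops = set(df[population_column].unique())
    if not {"crab", "wave"} <= pops:
        raise ValueError("both crab and wave ecotypes must be present")
    crab = df[df[population_column] == "crab"]
    wave = df[df[population_column] == "wave"]
    pooled = pd.concat([crab, wave])

    pair_rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            between = pooled[a].corr(pooled[b])
            within = max(abs(crab[a].corr(crab[b])), abs(wave[a].corr(wave[b])))
            pair_rows.append({
                "trait_a": a, "trait_b": b,
                "between_corr": between, "within_corr": within,
                "informative": bool(
                    abs(between) >= corr_threshold and within < corr_threshold
                ),
            })

    trait_rows = []
    for t in traits:
        cq1, cq3 = crab[t].quantile([0.25, 0.75])
        wq1, wq3 = wave[t].quantile([0.25, 0.75])
        wave_in_crab = ((wave[t] >= cq1) & (wave[t] <= cq3)).any()
        crab_in_wave = ((crab[t] >= wq1) & (crab[t] <= wq3)).any()
        trait_rows.append({
            "trait": t,
            "informative": bool(not wave_in_crab and not crab_in_wave),
        })
    return {
        "pairs": pd.DataFrame(pair_rows),
        "traits": pd.DataFrame(trait_rows),
    }
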