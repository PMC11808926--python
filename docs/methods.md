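# Methods

`skerryadapt` implements the inference machinery for a natural transplant
experiment: a population of the Crab ecotype of *Littorina saxatilis* founded
on a small wave-exposed islet ("skerry") near a differentiated Wave-ecotype
population, sampled repeatedly over three decades (founding year 1992, then
2005, 2018 and 2021 for genotypes). The package asks, for SNPs, inversions
and quantitative traits, whether the observed change exceeds what drift,
gene flow and sampling alone can produce, and how strong selection must have
been where it does.

## Demographic model

The skerry holds `N_t` haploid genomes at generation `t`, growing
logistically from `n0` founders toward carrying capacity `K`:

    N_t = K / (1 + ((K - n0)/n0) exp(-r t))

rounded to the nearest integer (half away from zero), clamped to [1, K].
Each generation, `m` haploid genomes are replaced by migrants from the Wave
source population carrying the focal allele at frequency `p_wave`, so the
expected focal count moves from `i` to

    i_exp = (i / N_{t-1}) (N_{t-1} - m) + p_wave * m .

Drift is binomial: the next generation draws `N_t` genomes with success
probability `clamp(i_exp / N_{t-1}, 0, 1)`. Migration precedes drift within
a generation. Generations are non-overlapping with `f` per year; sampling
occasions fall `round(13f)`, `round(13f) + round(13f)` and
`round(13f) + round(13f) + round(3f)` generations after founding (58 in
total at f = 2). All internal counts are haploid; reported migrant numbers
in diploid individuals are `m / 2`.

Assumptions worth keeping in mind: one-way migration, no age structure, no
stochasticity in `K`, and free recombination between analyzed loci
(inversions are handled as single loci, see below).

## Likelihood of an allele-count time series

For one locus the data are sample counts `k = (k_1992, k_2005, k_2018,
k_2021)` with known sample sizes (allele copies). The likelihood sums over
the hidden true counts at every generation:

    p(k) = sum  psi_92 s_92 M_92->05 s_05 M_05->18 s_18 M_18->21 s_21

with a uniform prior `psi = 1/(n0+1)` over founder counts, binomial sampling
terms `s_T`, and chained per-generation transition matrices `M`. The 1992
donor sample is treated as a binomial draw from the hidden founder pool —
the sampled snails were collected together with the transplanted cohort, so
the sample and the founders share one hidden state. The sum is evaluated as
a forward pass (matrix–vector products with renormalization at sampling
times), which is numerically identical to exhaustive enumeration (checked to
1e-10 in the tests for tiny populations) but linear in the number of
generations. Transition matrices are cached; the constant-size (post-growth)
matrix is reused across generations and grid points sharing `m` and
`p_wave`. Loci are assumed independent, so dataset negative log-likelihoods
add across loci.

The parameter grid is searched exhaustively (invalid combinations skipped),
the profile negative log-likelihood along a parameter is interpolated with a
cubic spline, and support limits are taken where the interpolated profile
rises 2 units above its minimum — the conventional ~95% likelihood-ratio
region for one parameter. The profile-interpolated optima are reported as a
`{parameter: value}` mapping rather than a parameter object, because
interpolated founder sizes and capacities are legitimately non-integer.
Parameter combinations are resampled from the surface with probability
proportional to `exp(-(negloglik - min))` when downstream simulations must
propagate inference uncertainty.

## Neutral envelopes

For each locus, 1000 (configurable) neutral trajectories are simulated
forward: parameters drawn from the likelihood surface, founding count
`round(p̂_1992 × n0)`, migration + binomial drift to 2021, then binomial
sampling with the locus's observed final sample size. The 2.5–97.5%
quantiles of the simulated change (sampled 2021 frequency − observed 1992
frequency) form the locus's expected range without selection; it reflects
drift, sampling and parameter uncertainty jointly. A locus is flagged when
its observed change escapes the range, with a direction flag recording
whether the change points toward the source population's frequency. Under a
correctly specified neutral model ~5% of loci sit outside their own range
and ~50% above their median; the package ships this self-calibration as a
function and reruns it in `scripts/acceptance.py`.

Per-locus selection coefficients extend the same hidden-state likelihood
with a deterministic genic update `p' = p(1+s)/(1+ps)` applied after
migration and before drift, maximized on an `|s| < 1` grid. The genic,
post-migration convention is a package choice; the exact mirror of the
profile under allele relabeling is then `s -> -s/(1+s)` (relative fitnesses
swap), which the tests exploit.

The origin of focal-allele copies (standing variation in the donor versus
migrant introgression) is decomposed by forward simulation with three allele
labels updated by multinomial sampling. Replicates losing the focal allele
are excluded and counted. Two estimators are reported: the mean per-replicate
fraction and the copy-weighted (pooled) fraction; only the latter estimates
the ratio of expected copy numbers, which is what a deterministic iteration
of the labeled expectations computes — the tests compare on that scale.

## Population-genetic statistics

FST between two populations is `(H_T - H_S)/H_T` from expected
heterozygosities, with `H_T` built on the unweighted mean of the two
frequencies. Multi-locus FST combines as a ratio of sums (numerators and
denominators summed over loci) rather than a mean of ratios, the less biased
of the two conventions. Temporal FST (1992 vs 2021 on the skerry) is signed:
positive when the allele more common in the spatial Wave reference rose over
time. Spatial and signed temporal differentiation are compared by Spearman
rank correlation with mid-rank ties. Frequencies are undefined for
population-year cells with fewer than five genotyped individuals; per-SNP
population comparisons use two-sided Fisher exact tests on allele copies.

## Inversion karyotyping

Each inversion is scored from its diagnostic-SNP block: PCA on centered
(not variance-scaled) 0/1/2 dosages, then k-means on the first two
components with 20 restarts — 3 clusters for a simple inversion (two
arrangements), 6 for a complex one (three arrangements). For simple
inversions the clusters ranked along PC1 map to the two homokaryotypes and
the heterokaryotype. For complex inversions the maximally spread cluster
triple are the homokaryotypes; each remaining cluster maps to the
homokaryotype *pair whose centroid midpoint it sits closest to*. The
midpoint criterion matters: a heterokaryotype is the genotypic average of
its homokaryotypes, and with block-structured diagnostic SNPs every
heterokaryotype centroid is exactly equidistant from all three homokaryotype
centroids, so a raw nearest-two-centroids rule is degenerate and breaks ties
arbitrarily. Automated quality checks replace visual validation: a
silhouette score (warning below 0.5) and a heterozygosity consistency check
(heterokaryotype clusters must carry higher mean per-SNP heterozygosity than
homokaryotype clusters). Arrangement frequencies come from allele counting
within clusters; the "Wave arrangement" is the one most enriched in the Wave
ecotype relative to the Crab ecotype on merged 2018+2021 samples. Treating
the Wave-major arrangement as a biallelic locus (other arrangements pooled),
inversions pass through the same neutral-envelope machinery as SNPs.

## Phenotype model

Traits experience Gaussian stabilizing selection toward an optimum `O` set
by the Wave reference population: `w(x) = exp(-(x-O)^2 / (2 V_s))`. The mean
phenotype then responds per generation by `Δx̄ = (O - x̄) V_g/(V_s + V_p)`,
starting from the donor mean plus a plastic offset, `x̄_crab + p`. The
deviation from the optimum decays geometrically with ratio
`1 - V_g/(V_s+V_p)`.

The fit estimates `V_s/V_p` (flat prior on [0, 50], the range reported for
natural populations), `p` and `V_g` (Gaussian priors from prior transect
studies), `O`, `x̄_crab`, and a shared phenotypic variance `V_p` (flat on
log `V_p`), with every individual value Gaussian around its
population-appropriate mean: `x̄_crab` for donor samples, `O` for Wave
samples, the trajectory mean at the sample's generation for skerry samples.
Sampling uses four independent affine-invariant ensembles (emcee), 3000
iterations each with 1000 discarded as burn-in, and requires split-R̂ < 1.05
across ensembles; non-convergence raises with diagnostics. The optimum is
co-estimated from the Wave samples by default (a plug-in mean differs only
by the Wave sample's standard error). Inside the sampler the trajectory uses
its closed geometric form; the public recursion and the closed form agree
exactly and are cross-checked in tests.

Derived quantities: fitness of the donor mean in the new environment with
and without plasticity (`w = exp(-(x-O)^2/2V_s)`), rates of change in
haldanes (pooled start/end SD per generation — the SD pooling is a package
choice), and the proportional change in the mean (change divided by the
initial mean, reported as the "darwin numerator" rather than a per-megayear
rate). Trait screening flags pairs strongly correlated between ecotypes but
not within, and traits whose ecotype interquartile ranges exclude all
individuals of the other ecotype. The bimodality check is a two- versus
one-component Gaussian-mixture likelihood ratio calibrated by parametric
bootstrap from the fitted single Gaussian — an automated replacement for
visual scatter inspection; a dip-style statistic would serve the same role
but is easy to implement subtly wrong, and the mixture test directly targets
the two-ecotype alternative of interest.

## Synthetic data

The generator emulates the full study design. Control-like loci draw donor
frequencies from Beta(2,2) with the source frequency a clipped Gaussian
(sd 0.05) perturbation; outlier-like loci draw donor ~ Beta(1.5, 6) and
source ~ Beta(6, 1.5), mimicking strong spatial differentiation. The skerry
is founded by a binomial draw of `n0` genomes from donor frequencies; the
1992 donor sample is drawn from the founder pool, matching the likelihood's
coupling. A configurable subset of outlier-like loci evolves under genic
selection. Inversions are simulated as single multi-arrangement loci
(multinomial drift + migration, optional selection on the Wave-major
arrangement) and expanded into concordant diagnostic-SNP blocks with a
configurable discordance rate. Genotypes are Hardy–Weinberg draws with
configurable missingness. Phenotypes follow exactly the stabilizing-
selection generative model. The scaled-down default profile (100 control,
30 outlier loci, 2 inversions, n0 = 60, K = 300, m = 3, f = 2, 30 diploid
individuals per sample) keeps full-pipeline runs to seconds while preserving
every structural feature.

For calibration experiments (parameter recovery, support-interval coverage)
a second generator draws datasets *exchangeable with the likelihood itself*:
founder counts uniform on {0..n0} (the model's own prior), source
frequencies known, every sample binomial. This is the statistically correct
input for coverage checks; the realistic Beta-divergence generator
additionally carries prior misspecification and source-frequency estimation
noise, which belong to robustness questions rather than calibration.

What the synthetic data do **not** emulate: linkage and hitchhiking between
collinear loci, overlapping generations, spatial structure within
populations, genotyping batch effects, and trait measurement error beyond
the shared Gaussian variance. Passing tests therefore demonstrate that the
machinery is internally correct and calibrated under its own assumptions,
not that those assumptions hold for any particular field dataset.

## Numerical choices and problem sizes

- Binomial pmf matrices are built in log space from two outer products and
  one `exp`, with exact absorbing rows at p = 0, 1; rows sum to 1 within
  1e-12 up to the sizes used.
- Forward passes renormalize at sampling times only (transition matrices are
  row-stochastic, so no underflow accumulates between them).
- Rounding of generation counts and population sizes is half away from zero.
- Modal-genotype imputation breaks ties toward the lower dosage.
- 1-cM LD-reduction windows are half-open [i, i+1) anchored at 0 cM; region
  exclusions (sex-linked linkage group, the dense cluster on linkage group
  2 between 36 and 60 cM, configurable intervals on linkage group 5) apply
  first.
- Per-locus reproducibility: each locus derives its generator from
  (master seed, locus index), so subsets reproduce identically.
- Test-time study sizes: the envelope self-calibration runs 200 loci x 500
  replicates at n0 = 60, K = 300, m = 3, f = 2; parameter recovery runs 20
  datasets of 200 loci at n0 = 40, K = 150, r = 0.3, m = 3, f = 2 on an
  r x m grid with n0, K, f fixed at their true values; the phenotype
  recovery study runs 20 replicate fits at V_s/V_p = 10. These sizes were
  fixed once as the package's study conditions.

## Known limitations

- The likelihood treats the per-locus source frequency as known; estimation
  noise in small source samples propagates into migration estimates.
- Support limits rely on the asymptotic 2-unit profile-likelihood
  calibration; at grid boundaries intervals truncate (with a warning).
- Complex-inversion karyotyping assumes all six karyotype classes are
  separable in the first two principal components; very rare arrangements
  may leave clusters empty or merged, flagged by the silhouette check.
- The selection-coefficient fit assumes a constant `s` per generation;
  markers that decouple from a selected background over time violate this
  and show it as a poor profile rather than a diagnosed model failure.
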