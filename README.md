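# skerryadapt

Inference toolkit for detecting and quantifying rapid adaptation after a
population transplant, built around a 30-year field experiment with the
intertidal snail *Littorina saxatilis*: in 1992 snails of the crab-predation
("Crab") ecotype were moved onto a small wave-exposed islet (a skerry)
previously home to the wave-action ("Wave") ecotype, and the population was
re-sampled for genotypes and shell phenotypes over three decades. The
package is for population geneticists who want to separate selection from
drift, gene flow and sampling in this kind of time-series design — or to
simulate and analyze synthetic versions of it.

## What it computes

**Demographic inference.** The skerry holds N_t haploid genomes growing
logistically (founder N0, rate r, capacity K) and receives M haploid
migrants per generation from the Wave source. For each locus the probability
of the observed sample counts k = (k_1992, k_2005, k_2018, k_2021) sums over
the hidden true allele counts:

    p(k) = Σ ψ_92 s_92 M_92→05 s_05 M_05→18 s_18 M_18→21 s_21

with a uniform founder prior ψ, binomial sampling terms s_T, and
per-generation migration-drift transition matrices M whose rows are
Binomial(N_t, i_exp/N_{t-1}) with i_exp = (i/N)(N−M) + p_Wave·M. The total
negative log-likelihood over control loci is minimized on a parameter grid,
the profile likelihood is spline-interpolated, and support limits are read
off at a 2-unit rise.

**Neutral envelopes.** Per locus, 1000 neutral trajectories (parameters
resampled from the likelihood surface, binomial sampling at the final year)
give the 2.5–97.5% expected range of the 1992→2021 frequency change; loci
escaping their range toward the Wave frequency are selection candidates, and
a per-locus selection coefficient can be fitted by maximum likelihood.

**Statistics, inversions, phenotypes.** Heterozygosity-based FST and signed
temporal FST versus spatial differentiation (Spearman), shift-toward-source
fractions, Fisher exact tests on allele counts; inversion karyotyping by
PCA + k-means on diagnostic-SNP blocks with arrangement-frequency
trajectories run through the same neutral envelopes; and a Gaussian
stabilizing-selection model with plasticity fitted by MCMC, reporting
V_s/V_p, fitness reductions, and evolutionary rates in haldanes.

**Synthetic data.** `skerryadapt.simulate` generates complete studies —
genotypes, SNP maps, inversion blocks, phenotypes, truth manifests — with
exactly the structure the other modules assume, so the full pipeline is
testable without any downloads.

## Worked example

Simulate a scaled-down study and infer its demography:

```python
from skerryadapt import DemographicParams, grid_search, refine_and_support_limits
from skerryadapt.simulate import simulate_sample_series

true = DemographicParams(n0=40, r=0.3, k=150, m=3, f=2)
loci, truth = simulate_sample_series(true, n_loci=200, sample_size=60, seed=1)

surface = grid_search(
    {"n0": [40], "k": [150], "f": [2],
     "r": [0.1, 0.25, 0.4, 0.6], "m": [0, 1, 2, 3, 4, 5, 6]},
    loci,
)
best = surface.best_params
print("best grid point:", best, "| migrants (diploid):", best.m_diploid)
for parameter in ("r", "m"):
    opt, iv = refine_and_support_limits(surface, parameter)
    print(f"{parameter}: {opt:.2f}  support ({iv.lower:.2f}, {iv.upper:.2f})")
```

Output (seed 1):

```
best grid point: DemographicParams(n0=40, r=0.4, k=150, m=3.0, f=2.0) | migrants (diploid): 1.5
r: 0.39  support (0.24, 0.60)
m: 2.89  support (2.50, 3.26)
```

The migration grid point m = 3 haploid genomes per generation (1.5 diploid
individuals) is recovered exactly, the interpolated optimum 2.89 sits next
to the truth, and both 2-unit support intervals cover the generating values.
The growth-rate profile is flatter — once the population saturates, r only
affects early drift — so its interval is wide and truncates at the grid
edge (the run warns about this).

The same stages are available from the shell:

```bash
skerry-adapt simulate --seed 42 --out run/
skerry-adapt infer-demography --genotypes run/genotypes.csv --map run/map.tsv \
    --fix-f 2 --out run/
skerry-adapt envelope --genotypes run/genotypes.csv --map run/map.tsv \
    --reps 1000 --seed 17 --out run/
skerry-adapt karyotype --genotypes run/genotypes.csv --map run/map.tsv --out run/
skerry-adapt phenofit --phenotypes run/phenotypes.csv --f 2 --out run/
```

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.

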