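# tetragp

Genomic prediction with read-ratio genotypes for autotetraploid breeding
populations — and the resampling experiments that tell a breeding program
how many markers, probes, reads and training individuals it actually needs.

## The problem

Autotetraploid crops such as blueberry carry four homologous copies of each
chromosome, so a biallelic locus has five possible allele dosages (0–4).
Calling those dosages from sequencing reads is unreliable unless depth is
high (~60X is commonly recommended), which makes genotyping the main cost of
applying genomic selection.  Two ideas make the problem tractable:

1. **Ratio genotypes.**  Skip dosage calling entirely and use the continuous
   read ratio at each locus, `M_ij = #a / (#A + #a)`, as the marker
   covariate (the alternative-allele depth over total depth).
2. **Optimize the design factors.**  Measure how predictive ability degrades
   as marker density, capture-probe density, sequencing depth, and training
   population size/composition are reduced, and cut costs to just before the
   degradation starts.

`tetragp` implements both: the ratio-genotype G-BLUP model, and a factorial
grid of downsampling experiments driven either by real allele-count data
(AO/RO tables or a VCF with allele depths) or by a built-in synthetic
autotetraploid breeding-population generator, so the whole analysis runs at
desk scale with known ground truth.

## The model

Genetic covariance between individuals comes from the genomic relationship
matrix in the ratio parameterization

    G = Z Z' / h,      Z = M − column means,      h = Σᵢ s²ᵢ

where `s²ᵢ` is the sample variance of centered marker column `zᵢ`.  With
complete data this G has zero row sums and `trace(G) = n − 1` exactly — both
identities are asserted by the test suite.  Prediction uses the mixed model

    y = μ + g + ε,    g ~ MVN(0, G σ²ₐ),    ε ~ MVN(0, I σ²ₑ)

with one adjusted phenotype (LSMean over seasons) per genotype, fit by Gibbs
sampling with scaled-inverse-χ² priors on both variances (df 5, prior scales
from an R2 = 0.5 split of the phenotypic variance).  A closed-form BLUP at
fixed variance components serves as an independent oracle for the sampler.
Held-out predictions are scored by predictive ability (Pearson r against the
LSMeans) and MSE, and factor levels are compared by Tukey HSD compact letter
displays at α = 0.05.

The synthetic generator emulates the relevant structure of a real breeding
population: mapped biallelic markers grouped ~18 per capture probe on 12
chromosomes, biparental families from outcrossing tetraploid parents
(bivalent-pairing tetrasomic meiosis, so the single-locus gamete law is
hypergeometric), additive traits of configurable architecture and
heritability over two seasons, and read counts with truncated-Poisson depth
and a binomial allele split plus sequencing error.  Lower-depth scenarios
redraw each datapoint's total depth from `Poisson(target)` conditioned on a
2-read minimum, splitting alleles binomially at the observed ratio.

## A worked example

```python
import numpy as np
import tetragp as tg

data = tg.simulate_study(n_founders=24, n_families=20, family_size=12,
                         n_chrom=6, markers_per_chrom=100, seed=11)
y = data.phenotypes["polygenic"]

G = tg.build_g(tg.ratio_genotypes(data.rc))
(test,) = tg.make_test_sets(list(data.individual_ids), size=50, n_reps=1, seed=12)
train = np.setdiff1d(data.individual_ids, test)

fit = tg.fit_gibbs(y, G, train, n_iter=4000, burn_in=1000, thin=5, seed=13)
pred = tg.predict(fit, list(test))
r = tg.predictive_ability(pred.to_numpy(), y.reindex(list(test)).to_numpy())
```

Running this (it is `examples/05_gblup_fit.py`) prints:

```
G: 272 individuals from 600 markers, scale h = 30.35; trace = 271.00 (= n-1)
posterior means: sigma_a^2 = 356.949, sigma_e^2 = 212.003  (h2 ~ 0.63)
test set: predictive ability r = 0.612, accuracy vs truth = 0.797, MSE = 349.070
```

`r = 0.612` is the Pearson correlation between predicted and observed
adjusted phenotypes of the 50 held-out individuals; accuracy against the
simulator's noise-free true genetic values is higher (0.797) because the
phenotypes carry residual error.  The other scripts in `examples/` walk
through each capability one at a time: population simulation, filtering and
ratio genotypes, depth downsampling, the sampling designs, the full demo
grid (`tg.run_demo`), and the sequencing-budget arithmetic
(`tg.sequencing_budget(0.6, 12, 3000)` → 7.2 Gb per sample, 417 samples per
3000 Gb flow cell; at 60X, 36 Gb and 83 samples).

Real data enter through `tg.read_counts(ao_path, ro_path)` (TSV pair,
individuals × markers) or `tg.read_counts_vcf(path)` (per-sample AD fields),
followed by `tg.apply_filters` with the default thresholds (2X datapoint
minimum, 60X site mean, 20% missingness caps, 5% MAF).

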