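# Methods

This note documents the models, defaults and numerical choices behind
`tetragp`, and what the synthetic experiments do and do not establish.

## Ratio genotypes and the relationship matrix

Marker covariates are continuous read ratios `M_ij = AO_ij / (AO_ij +
RO_ij)` in [0, 1]; no dosage calling is attempted.  The relationship matrix
is `G = ZZ'/h` with `Z` the column-centered `M` and `h = Σᵢ s²ᵢ`.  The
variance divisor in `s²ᵢ` is `n − 1` (sample variance).  That choice is
deliberate and testable: it makes `trace(G) = n − 1` an exact identity on
complete data, alongside the zero row sums forced by centering.  Monomorphic
columns contribute zero to both `ZZ'` and `h` and are tolerated; an
all-monomorphic matrix (h = 0) is an error.

## The mixed model and its Gibbs sampler

The prediction model is `y = μ + g + ε`, `g ~ MVN(0, G σ²ₐ)`,
`ε ~ MVN(0, I σ²ₑ)`, with one adjusted phenotype per genotype (the incidence
matrix is an identity on the training rows; repeated records are out of
scope).  Both variances carry scaled-inverse-χ² priors with `df0 = 5` and
scales set from the training phenotypic variance split by `R2 = 0.5`
(`S_e = var(y)(1−R2)(df0+2)`; `S_a = var(y)·R2·(df0+2)/mean(diag G)`), the
default-hyper-parameter convention of Bayesian whole-genome regression
software.  Defaults follow the full-length chain convention (35,000
iterations, 5,000 burn-in, thinning 5); the grid runner uses shorter desk-
scale chains (below).

The sampler works in the eigenbasis of the training block `G_tt = VΛV'`:
with orthonormal `V`, the conditional posterior precision of the genetic
coefficients is diagonal (`1/σ²ₑ + 1/(λᵢσ²ₐ)`), so the whole coefficient
vector is drawn exactly in one vectorized step per iteration.  Eigenvalues
below `1e−10 × λ_max` are dropped (the centered G is always rank-deficient);
the genetic values of non-training individuals are drawn jointly each
iteration from their conditional MVN given the training vector, via the
precomputed conditional mean map `G_st V Λ⁻¹` and a Cholesky-type square
root of the Schur complement.  Posterior means over stored samples are
reported.  PSD handling: eigenvalues in `(−1e−8 · trace, 0)` are clipped to
zero; anything more negative raises.  Effective sample size
(initial-positive-sequence) and a split-chain R̂ of the variance chains are
logged but never trigger automatic re-runs.

`fit_closed_form` is the deterministic oracle: generalized least squares for
μ with `V = σ²ₐG_tt + σ²ₑI`, `g = σ²ₐ G_{·,t} V⁻¹(y − μ)`.  With variances
fixed, the Gibbs posterior mean equals this BLUP up to Monte-Carlo error
(asserted at correlation > 0.99); the two implementations share no linear
algebra path.

## Phenotype adjustment

LSMeans come from ordinary least squares on `value ~ genotype + year` (both
categorical, treatment coding); the adjusted mean of a genotype is its
fitted value averaged over the unweighted year grid.  On balanced data this
equals the genotype mean; a confounded design (a genotype observed in only
one year that no other genotype shares) is rank-deficient and raises.  A
single-season response is supported and degenerates to genotype means.

## Filters

Order of application (fixed; the criteria themselves do not imply one):
(1) chromosome whitelist; (2) datapoints below the 2-read minimum set
missing — depth-based missingness is counted before the missing-fraction
rules, matching the no-imputation intent; (3) markers with site-mean depth
(over non-missing datapoints) below 60X dropped; (4) markers then
individuals with more than 20% missing dropped; (5) markers with MAF below
0.05 dropped.  The allele frequency behind the MAF rule is the mean of
per-individual read ratios, which is robust to depth heterogeneity (a
read-pooled estimator would weight deep individuals more).  The 2X-minimum
plus 20%-missingness combination can leave a few missing cells; because the
model needs a complete M, those are mean-imputed per marker as a last
resort, with the count logged.  Mapping/call-quality filters (QUAL ≥ 10,
MQ ≥ 20) exist only in VCF input and are applied at parse time; AO/RO
tables are assumed pre-filtered upstream.

## Depth downsampling

A depth scenario redraws each datapoint's total `n' ~ Poisson(target)`
conditioned on `n' ≥ 2` — truncation by resampling, not clamping (a clamp
mode exists for sensitivity checks) — and splits `AO' ~ Binomial(n', p)`
with `p` the observed input ratio.  Totals are drawn fresh rather than
thinned because the scenario definition specifies the Poisson directly; the
binomial split is the resampling model consistent with the ratio
parameterization and leaves `E[AO'/n'] = p` exactly.  A hypergeometric
subsample-without-replacement mode is available for targets below the input
depth.  Five independent replicates per target are the default, with
deterministic per-replicate seeds.

## Sampling designs

*Markers*: cumulative (nested) series balanced across chromosomes.  For a
non-divisible quota (500 over 12 chromosomes → 41 or 42 each) the remainder
goes one marker at a time to the currently least-loaded chromosomes with
random tie-breaks, so per-size chromosome counts differ by at most one;
exhausted chromosomes spill their shortfall with a logged warning.
*Probes*: per-chromosome quotas proportional to probe counts
(largest-remainder rounding); within a chromosome probes are ordered by
position and taken every `floor(available/quota)` ranks from a random
offset.  Probe sets at different counts are **not** nested — the
fixed-spacing rule precludes it, and the cumulative approach applies only to
markers and training sets.  *Test sets*: fixed 200-individual (default)
simple random samples, one per replicate, reused across every factor of
that replicate.  *Training*: nested random series, or per-family quotas
with families under 10 members excluded and `min(k, available)` taken when
a family runs short.

## Evaluation

Predictive ability is the Pearson correlation between predictions and
LSMeans in the test set; MSE optionally standardized by the variance of the
observations (raw MSE is the default output).  Factor levels are compared
on replicate-level values by one-way ANOVA pooled variance and all-pairwise
studentized-range (Tukey HSD) tests at α = 0.05; the compact letter display
uses the insert-and-absorb algorithm with letters assigned in descending
order of level means.  PCA summaries report `100·λⱼ/Σ max(λᵢ, 0)` from the
eigendecomposition of G, clipping negative eigenvalues out of the
denominator.  The sequencing budget is `genome_Gb × depth` per sample and
`flowcell_Gb / (genome_Gb × depth)` samples per run, rounded to nearest
(the convention that reproduces both published multiplexing figures, 417
and 83; floor/ceil modes exist).

## The synthetic generator

What it emulates: ~12 chromosomes of mapped biallelic markers grouped ~18
per capture probe; tetraploid founders with per-marker allele frequencies
uniform in a configurable range and first-order Markov LD along
chromosomes (copy the previous allele with probability `ld_rho`, else a
fresh Bernoulli — correlation decays as `rho^k`; margins are exact at equal
frequencies and slightly smoothed otherwise); biparental families with
unequal sizes (coefficient of variation 0.4 by default, emulating real
cross plans where only a subset of families reaches 10 individuals);
bivalent-pairing tetrasomic meiosis with Poisson crossovers on the genetic
map, making the single-locus gamete law the closed-form hypergeometric draw
of 2 from 4; additive traits (QTL sampled among markers, normal or
signed-gamma effects, residual variance set to hit the target single-season
h² in the realized population, per-year fixed shifts); and read counts with
truncated-Poisson depth, binomial allele split, and a symmetric per-read
miscall rate folded into the success probability (default 0.001).

What it does not model: double reduction, multivalent or preferential
pairing, dominance and epistasis, genotype-by-environment interaction,
selection across generations, depth correlation within libraries, and
population structure beyond the family design.  Passing tests therefore
show that the pipeline's statistical machinery behaves as specified under a
clean additive tetrasomic model — not that real predictive abilities at any
particular budget will match the synthetic ones.

Trait presets span architectures: `oligogenic` (50 QTL, h² 0.6),
`polygenic` (500 QTL, h² 0.5), `highly_polygenic` (5000 QTL capped at the
marker count, h² 0.35).

## Problem sizes and chains

The package's own desk-scale conventions, chosen so every experiment runs
comfortably on one CPU: the bundled demo preset simulates ~300 individuals
(30 families), 1,200 markers on 12 chromosomes, and reduced factor grids
with 3 replicates and 2,000/500/5 chains; the parameter-recovery and
plateau analyses use 600 individuals (50 families), 3,000 markers, 5
replicates, and 1,500–3,000-iteration chains.  A study-scale preset
(`DemoScale.study()`: 1,804 individuals, ~10k markers, 5 replicates) and
the full-length 35,000/5,000/5 chains remain available where more precision
is wanted.  Short chains are adequate here because the eigenbasis sampler
mixes quickly (variance-chain effective sizes of several hundred from a few
hundred stored samples) and only posterior means are consumed.

## Known limitations

Family-balanced versus random training composition at *matched* size shows
no reliable advantage in this generator: with every test individual
guaranteed close relatives in a closed multi-family population, balanced
quotas mainly protect against under-represented families, an effect of a
few hundredths in r that drowns in replicate noise at desk scale.  The
demo reports the comparison rather than asserting a direction.  Residual
missingness handling (mean imputation) is a last resort, not an imputation
method; multiallelic VCF records are skipped, not decomposed; and the
G-matrix makes no correction for the extra sampling variance that very low
depth adds to read ratios.
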