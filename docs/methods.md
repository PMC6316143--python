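# Methods

## Model and units

All speciation times τ, population-mutation parameters θ = 4N_e µ, branch
lengths and genetic distances are in expected substitutions per site
(s/s). In these units the pairwise coalescent waiting time within a
population is exponential with mean θ/2, and the mutation rate µ never
appears until calibration, where dividing an s/s age by an absolute age in
years yields µ_y and multiplying by a generation time yields µ_g. This is
the same parameterization used by coalescent inference tools such as BPP,
and it is what makes the pipeline's estimand (the speciation time
d_1/2 = τ) directly convertible into rates.

The species tree is fixed: (((Homo, Pan), Gorilla), Pongo), one haploid
sequence per species. Gene genealogies follow the multispecies coalescent:
within each ancestral population holding k lineages the next coalescence
waits Exp(rate k(k−1)/θ); lineages that fail to coalesce before the older
speciation time carry into the parent population, which is how
incomplete lineage sorting (ILS) genealogies with Homo and Pan not sisters
arise. θ = 0 is treated as the zero-variance limit (coalescence
immediately on entering the population), which produces exactly
ultrametric, clock-true genealogies — the null configuration for the clock
test.

## Synthetic-data generator

The generator emulates a multilocus dataset of syntenic, effectively
unlinked autosomal segments: independent loci (no recombination within a
locus, free recombination between loci), gap-free 4-taxon alignments of
fixed length, clock-like substitution. Default truth values:

| parameter | default (s/s) | rationale |
|---|---|---|
| τ_HC | 0.00473 | Homo–Pan speciation time; the pipeline's estimand |
| θ_HC | 0.00304 | chosen so the mean Homo–Pan coalescent height τ + θ/2 = 0.00625 |
| τ_HCG, θ_HCG | 0.0074, 0.0012 | mean Homo–Gorilla height 0.008 |
| τ_root, θ_root | 0.0122, 0.0016 | mean Homo–Pongo height 0.013, matching the root-prior mean |

Default loci: 15,744 × 5000 bp at full scale (a 78,720,000-bp
supermatrix); tests and examples use far fewer. The default substitution
model is JC69, which keeps every likelihood in the pipeline closed-form
checkable; GTR with discrete-gamma rates (4 equal-probability categories,
bin-mean rates) and invariant sites is available to mirror the model
typically selected on real ape data. With the default parameters about
17% of loci show ILS (exp(−2(τ_HCG − τ_HC)/θ_HC) ≈ 0.17 of Homo–Pan
lineage pairs enter the HCG ancestor uncoalesced).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: alignment error and gaps, selection and
mutation-rate variation along the genome beyond the site-rate mixture,
linkage between nearby loci, post-speciation gene flow, and
sequencing/assembly artifacts.

Reproducibility: each locus draws from an RNG substream derived from
(dataset seed, locus index) via `numpy` seed sequences, so a single locus
can be regenerated without simulating its predecessors, and a fixed seed
gives byte-identical FASTA output.

## Clock filter

Per-locus log-likelihoods use Felsenstein pruning over compressed site
patterns (at most 256 for 4 taxa, so cost is bounded per likelihood
evaluation regardless of locus length). The free model has 5 branch
lengths on the unrooted tree ((Homo,Pan),Gorilla,Pongo); the clock model
has 3 node heights on the rooted ultrametric tree with Pongo as outgroup,
parameterized as non-negative height increments so the ordering constraint
is built in. df = 5 − 3 = 2 by standard nested-model counting.

Optimization is bounded L-BFGS-B (lnL tolerance ~1e-12) from a
distance-based start plus two random restarts; the free fit is
additionally started from the clock solution so lnL_free ≥ lnL_clock holds
numerically, and near-ties resolve toward the smaller total tree length.
The LRT statistic is clamped at 0 before the χ²(2) tail probability.
Under clock-true simulation the empirical rejection rate at α = 0.05 and
the full LR distribution match χ²(2) (checked by simulation at 1000 loci).

## Distances and the root prior

JC69 distances use the closed-form inversion d = −(3/4) ln(1 − 4p/3) of
the mismatch fraction p, with a delta-method standard error; p ≥ 3/4 is
reported as saturated (infinite) and such loci are dropped from per-locus
vectors with a warning. For any other model, the distance is a bounded
1-D likelihood optimization with the model's parameters supplied and held
fixed (estimated once, e.g. on the supermatrix — the package does not
re-select models per locus). Under JC69 the pooled mismatch count is
sufficient, so the supermatrix estimate equals the count-pooled estimate
exactly; this equivalence is asserted in tests.

The root-time prior is a maximum-likelihood gamma fit (shape α, rate β,
mean α/β) to the per-locus Homo–Pongo d_T/2 values, delegated to
`scipy.stats.gamma.fit` with the location fixed at zero — the same
profile-likelihood MLE that R's `MASS::fitdistr` computes. The gamma MLE
preserves the sample mean in the rate parameterization, so the prior mean
tracks half the observed Homo–Pongo divergence (≈ 0.013 s/s at the
defaults). Fewer than 10 values, non-positive values, or zero variance
are rejected; the pipeline then falls back to the G(16.7, 1264.0) default
rather than aborting.

## Bayesian inference of τ and θ

Inference deliberately targets the Homo–Pan pair alone (the two-lineage
MSC): per locus, divergence height h_i = τ + t_i with
t_i ~ Exp(mean θ/2), and x_i of L_i sites differing with JC69 probability
(3/4)(1 − exp(−8h_i/3)). Gorilla and Pongo inform the clock filter and
the root prior but not the likelihood. This reduction keeps the posterior
verifiable against deterministic quadrature while retaining the estimand
of interest; its cost is that ILS loci (whose excess heights are not
exponential with mean θ_HC/2) are mildly misspecified, which at small
locus counts biases τ slightly upward and θ downward. A full 4-taxon
gene-tree MCMC is out of scope.

Priors: θ ~ Gamma(2, 200) (rate parameterization; mean 0.01);
τ ~ Uniform(0, m), with m the root-prior mean (0.013 s/s by default) — a
simple proper bound standing in for a hierarchical internal-node prior
given the root age.

The sampler is Metropolis-within-Gibbs with four moves per iteration:
a random walk on τ holding the latent waiting times fixed; a log-scale
random walk on θ (with Jacobian); a vectorized reflected random walk over
all per-locus latent t_i (each locus accepts independently, so the sweep
is one array operation); and a translation move (τ, t) → (τ + δ, t − δ)
that leaves every h_i — and hence the likelihood — unchanged, decoupling
τ from the latent heights. Step sizes are tuned during burn-in (10% of
generations, minimum 200 iterations) toward 20–50% acceptance and then
frozen, preserving detailed balance for the retained draws.

Defaults: 2 independent chains × 2000 retained samples at thinning 50.
Diagnostics: per-chain ESS (via `arviz`), equal-tailed 95% intervals, and
a two-chain agreement check — τ means within 2 combined Monte-Carlo
standard errors, otherwise a convergence warning. With the likelihood
switched off the sampler reproduces its priors (KS-checked), and on
small datasets its means and spreads match `grid_posterior`, a
deterministic oracle that integrates each locus's latent height out by
Gauss-Legendre quadrature (after the exponential-CDF substitution
u = 1 − exp(−2t/θ), which makes the integrand smooth on (0,1)) and then
normalizes over a (τ, θ) grid.

## Calibration

µ_y = (d_1/2)/T_fossil and µ_g = µ_y·g, with bounds propagated from
d_1/2 ± 2 posterior s.d. for generational rates (reported to 2 decimals
on the 10⁻⁸ scale) and ± 1 s.d. for the yearly summary row (3 decimals);
both conventions are available through `n_sd`, and unrounded values are
always stored alongside. Rounding is half-away-from-zero via `decimal`.
Grids default to T_fossil ∈ 3.5–15 Ma and g ∈ 10–30 y (0.1 steps), with
each cell classified against the pedigree envelope
[0.89, 1.75] × 10⁻⁸ s/s/g — configuration constants taken from the
published whole-genome pedigree literature, not recomputed here. The
inversion g = µ_g·T_fossil/d_half answers "what ancestral generation time
would make the phylogenetic rate equal a given pedigree rate"; at
(1.75 × 10⁻⁸, 7.3 Ma, 0.00473) it gives 27.0 y, and at
(0.89 × 10⁻⁸, 5.7 Ma) it gives 10.7 y unrounded — the package reports
unrounded values and does not force agreement with any particular rounded
convention. Every pipeline run asserts the central inequality: the
coalescent-calibrated rate is at least the speciation-calibrated rate
whenever θ > 0.

## Problem sizes

Test and acceptance runs are sized for a single CPU: 20,000 genealogies
for the mean-height check (Monte-Carlo s.e. ≈ 1.1 × 10⁻⁵ s/s), 1000
clock-true loci of 1000 bp for LRT calibration (binomial s.e. ≈ 0.7% on
the rejection rate), 20 replicates of 500 loci × 1000 bp for posterior
coverage (desk-scale chains: 2 × 800 retained at thinning 10), and
≤ 5-locus datasets for the grid-integration cross-check. The full-scale
configuration (15,744 × 5000 bp, 20,000 samples at thinning 1000) is
available through the same interfaces.

## Known limitations

- The two-lineage reduction ignores ILS in the likelihood (see above);
  with genome-scale data and great-ape parameter values the induced bias
  is small relative to the posterior spread at desk scale, but it is a
  model approximation, not an implementation detail.
- JC69 underestimates distances when the true process is strongly
  heterogeneous; the GTR+Γ+I path mitigates this for distances but the
  MCMC likelihood is JC69-only.
- No gaps, missing data, or alignment uncertainty anywhere in the
  pipeline; real-data ingestion assumes clean equal-length ACGT
  alignments.
- The uniform τ prior truncates at the root-prior mean; posteriors for
  pairs whose true speciation time approaches the root age would be
  distorted.
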