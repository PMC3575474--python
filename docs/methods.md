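# Methods

## The generative model

Each individual in a two-way admixed population carries two haploid
genomes. Along the genetic map (distances in Morgans), the ancestry of a
haploid genome is modelled as a continuous-time two-state Markov chain
over {European, African} with switch intensity `T` per Morgan and
stationary distribution `(M, 1 − M)`, where `M` is the individual's
global European proportion. Over a distance `d` the chain copies its
state with probability `exp(−T d)` and otherwise redraws from the
stationary distribution, so

    P(same state over d) = exp(−T d) + (1 − exp(−T d)) · stationary(state),

and the mean European tract length is `1/(T (1 − M))` Morgans. This is
the standard Poisson-crossover approximation to `T` generations of
admixture; chromosomes are independent. `T` defaults to 6 generations,
the conventional depth for African-American admixture, and is exposed as
a parameter because admixture time is a property of the cohort, not of
the method.

Given ancestry, the allele at an AIM is Bernoulli with that ancestral
population's frequency — AIM panels are designed to be in linkage
equilibrium within each ancestral population, so markers are
conditionally independent given ancestry. The unphased genotype is the
sum over the two chains.

**Panel generation.** Ancestral frequency pairs are drawn as independent
Beta(a, a) variates and rejection-sampled to satisfy the minimum
differential `min_sigma` (default 0.30); the shape `a` is solved by
quadrature and root-finding so that the post-rejection mean of
σ = |p₁ − p₂| equals `sigma_target` (default 0.56). `sigma_target = 1`
with `min_sigma = 1` is special-cased to fixed-difference markers.
Positions are spread evenly along approximate human autosomal genetic
lengths, allocated proportionally to chromosome length. The defaults
(1440 markers, σ̄ = 0.56, min 0.30) reproduce the marker density and
informativeness of a genome-wide case-only AIM map.

**Ascertainment.** Disease follows a single-locus multiplicative model:
an individual with `a` European alleles at the causal marker is a case
with probability `baseline · ψ^a` (default baseline 0.05), and a control
with the complementary probability. Because acceptance depends only on
the causal-locus ancestry, the sampler draws `(M, causal chain states)`
first, assigns status, and fills the remaining tract conditionally on the
anchor states — the stationary chain is reversible, so outward
propagation with the forward kernel reproduces the unconditional law
restricted to the anchor. This is distributionally identical to rejecting
whole simulated genomes and roughly 20× cheaper at baseline 0.05. Global
proportions are drawn from a normal with mean 0.175 and SD 0.09 truncated
to [0, 1], matching the admixture distribution of African-American SLE
cohorts.

## Local-ancestry inference

The hidden state at a marker is the ordered pair of chain ancestries
(4 states); the transition kernel is the product of two independent
per-chain kernels, and the emission of an unphased dosage sums the two
orderings of allele assignment. Missing genotypes emit probability 1.
Forward messages are normalised per marker (the scaling constants give
the log-likelihood), which is stable for chromosomes of ≥10³ markers
without moving to log space. Posteriors are marginalised to European
dosage a ∈ {0, 1, 2}. Degenerate `M` of exactly 0 or 1 yields the
corresponding point-mass posterior directly. Inference is deterministic
and exact for the model — validated against brute-force enumeration of
all 4^m joint chain paths on small panels — in contrast to MCMC samplers
of the same HMM, whose output varies by run.

Global admixture is estimated per individual by maximising the
marker-independence likelihood in which each allele carries the mixture
frequency `M p₁ + (1 − M) p₂`; the scalar likelihood is unimodal in
practice and is maximised by vectorised golden-section search on [0, 1]
(tolerance 1e−6), with explicit boundary checks so fixed-ancestry
individuals return exactly 0 or 1. A panel with p₁ = p₂ everywhere has a
flat likelihood; the estimator warns and returns 0.5. Scans use estimated
M̂ by default; simulations can opt into truth `M`.

## Scan statistics

The case-only LOD at marker j under risk model ψ compares each case's
posterior dosage distribution with their personal Binomial(2, Mᵢ) prior,
both reweighted by ψ^a. At ψ = 1 the statistic is identically zero;
relabelling the ancestral populations and inverting ψ leaves it invariant.
The prior-risk grid is 27 models from 0.4 to 3.0 weighted by a gamma
density with mean 1.6 and SD 0.3 (shape (1.6/0.3)² ≈ 28.44, scale
0.3²/1.6 = 0.05625). "Averaging" LOD scores is implemented as
Bayes-factor averaging, `log₁₀ Σ w_m 10^LOD_m` (and `log₁₀ mean 10^score`
for the genome score), the convention of the admixture-mapping software
family this follows; a `literal` arithmetic-mean mode is provided for
comparison. LOD > 2 is treated as suggestive and LOD > 5 as genome-wide
significant. Risk estimation maximises the genome score over a fine ψ
grid (ties break to the smaller ψ). The case-control statistic compares
mean local deviation `D = (posterior dosage)/2 − M` between groups with a
pooled two-sample standard error; empirical peak significance fits a
normal to the per-replicate maxima of null (ψ = 1) scans and reports the
upper-tail (European-excess) probability.

Under the null the per-marker Bayes factor `10^LOD` has expectation
exactly 1 (a martingale in the cases); the raw expected LOD is slightly
negative, as for any log-likelihood ratio evaluated under the null. The
calibration tests therefore check `E[10^LOD] = 1` and uniformity of the
empirical peak p rather than a literal zero mean.

## Association layer

Allelic tests use the 1-df χ² without continuity correction and Wald
95% CIs (z = 1.96) on the log odds ratio, with Haldane–Anscombe 0.5 added
to all four cells only when one is zero; every result is labelled with
its counted allele, since a given allele can be risk in one population
and protective in another. Genetic models (additive/allelic, dominant,
recessive, 2-parameter genotypic) are compared by AIC = 2k − 2logL with
ties resolved toward fewer parameters; perfect separation is flagged and
refitted with a 0.5-count penalty. Covariate-adjusted and conditional
tests are ordinary logistic regressions (statsmodels) with Wald and
likelihood-ratio inference; aliased predictors are dropped with a
warning. Haplotype frequencies for ≤4 SNPs come from multinomial EM
assuming random haplotype pairing, iterated until the log-likelihood
gain is below 1e−8 (monotonicity asserted every iteration); pairwise LD
(r², D′ with the sign-dependent Dmax) derives from the 2-SNP EM fit.
Meta-analysis is fixed-effects inverse variance on log OR with the SE
recovered as (log upper − log lower)/3.92 — the simplest method
consistent with published combined ORs lying between the study ORs. QC
applies, in fixed order, individual missingness (>5%), SNP missingness
(>10%), MAF (<1%), and HWE in controls (χ² p < 0.001); individuals are
filtered before SNPs so one sloppy sample cannot knock out markers.

## Risk accounting

PAR uses the control frequency of the allele with OR > 1; the API forces
this orientation explicitly (warning and erroring on OR < 1 unless
negative PAR is requested) because published tables often report the
protective allele. With two-decimal published ORs the arithmetic is
sensitive to rounding: the three-SNP African-American joint PAR
reproduces exactly (18.1%), while the European-American joint PAR
recomputes to ≈15.0% against a printed 14.7%. The ancestry risk ratio λ
compares genotype-probability-weighted odds between carrying one vs zero
European alleles at a locus under within-ancestry HWE and a
multiplicative genotype model (OR(aa) = OR², OR(Aa) = OR); λ = 1 whenever
the ancestral frequencies coincide or OR = 1, and combined λ is the
product across loci under independence. Printed per-SNP λ values differ
between two sections of the source report ((1.12, 1.12, 1.16) vs
(1.12, 1.15, 1.12), products 1.455 and 1.443); both are covered in tests.
F_ST is the two-population Weir–Cockerham variance-components estimator
with observed heterozygosity (HWE proportions when only frequencies are
given); raw, possibly slightly negative values are returned with an
optional clamp. Informativeness for assignment is the entropy
decomposition `H(mean profile) − mean H(population profile)` in nats.

## What the simulations do and do not show

The generator reproduces the statistical structure the scan assumes:
Markov ancestry tracts, conditional linkage equilibrium of AIMs given
ancestry, Binomial dosage priors, single-locus multiplicative
ascertainment. It does not model background LD within ancestral
populations, X-chromosome dosage, genotyping error, three-way admixture,
or marker-informativeness ascertainment bias — so passing tests certify
the inference machinery, not robustness to those real-data features.
Localisation is resolution-limited: at ~0.025 M marker spacing adjacent
AIMs carry ≈87% of the causal locus's ancestry signal, and when the
causal AIM is weakly differentiated a stronger immediate neighbour often
attains the maximum. The recovery experiment therefore places the causal
locus at the panel's most ancestry-informative AIM, mirroring study
designs that centre on their most differentiated variant; misses in that
experiment are invariably immediate flanking markers.

## Problem sizes and numerical choices

Test experiments use: recovery at the full study scale (1440 AIMs, 1000
cases, 50 seeds); null calibration on a scaled-down cohort (240 markers
over 8 chromosomes, 300 cases, 60 null replicates, 50 observed seeds);
type-I calibration of the allelic χ² with 10⁴ null draws at 500/500.
These sizes were chosen so the distributional claims are tested at
meaningful resolution while the whole suite remains a routine local run.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns with the same configuration are
byte-identical, including written artifacts. Posterior normalisation
tolerances are 1e−9; EM convergence 1e−8; golden-section tolerance 1e−6;
ties in model selection and risk estimation break deterministically
(fewer parameters, smaller ψ).
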