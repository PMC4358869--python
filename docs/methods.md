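# Methods

`crossgs` simulates a two-way crossbreeding program in which purebred
lines are selected on genomic estimated breeding values (GEBV) for
either purebred or crossbred performance, with marker effects estimated
once from purebred data under an additive + dominance model.  This note
records the model, the defaults, the design choices that were genuinely
open, and what the reduced test profile does and does not demonstrate.

## Population simulation

**Genome.** One chromosome of 1 Morgan carries ~2500 candidate biallelic
loci (5000 in the high-LD regime, see below) at uniform random
positions.  Meiosis is Haldane: crossover counts are Poisson with mean 1
per gamete, crossover positions uniform, no interference.  Recurrent
mutation flips a transmitted allele with probability 2.5e-4 per locus
per gamete, in every simulated generation.  Keeping mutation active
after the breed split matters: post-split mutations are private to a
breed and are the main mechanism eroding the between-breed correlation
of LD phase at short distances (see "LD regimes").

**History.** 1000 discrete generations at census 2000, then 1000
generations with the census declining linearly to 100 (rounded to even
numbers so the sexes stay balanced).  The decline schedule is not
uniquely determined by its endpoints; linear is the simplest monotone
choice and reproduces the published allele-frequency spectrum (roughly
uniform between 0.01 and 0.99) and LD level.  Mating is random union of
gametes: each offspring draws one sire and one dam uniformly with
replacement; sex is assigned so that each generation is exactly half
male.  Only mutation and drift act.

**Breed formation.** Two disjoint random samples of 50 animals (25
males + 25 females) from the 100 final historical animals found breeds
A and B.  For 100 generations, 50 dams are drawn per generation, each
mated to a sire drawn uniformly from all males, with a fixed litter of
5 — census 250 per breed.  The founder counts follow the narrative
description (two samples of 50 animals); the parameter table's "50
founder males + 50 founder females per breed" cannot be satisfied by a
100-animal source generation.  The dam count is the unique choice that
keeps the census at the founding scale given the fixed litter size.
These choices were checked against the published LD statistics
(adjacent-SNP r², binned decay, phase persistence) and reproduce all of
them within their sampling tolerance.

**Expansion.** 8 generations with 100 sires and 100 dams sampled per
generation and 10 offspring per dam (census 1000).  Generation 8 is the
training population.

**Panels.** 1000 SNPs and 100 QTL are drawn without replacement
(disjoint) from candidate loci with MAF >= 0.05 in the last historical
generation.  If fewer than 1100 loci qualify the simulation raises and
asks for more candidate loci.

## LD regimes

The **low** regime is the literal published schedule above.  The
**high** regime increases LD in the common ancestral population by
appending a deeper bottleneck to the decline: census 16 for 20
generations, then 5 generations back at 100 so that the breed founders
can be sampled.  5000 candidate loci keep the MAF >= 0.05 panel
feasible despite the diversity lost in the bottleneck.

Calibration note: with the divergence structure fixed (founder split of
a 100-animal remnant, 100 generations at census 250, recurrent
mutation), the between-breed phase correlation saturates at ~0.50 for
the first 1-cM bin and ~0.67 below 50 kb as the ancestral bottleneck is
deepened; bottlenecks below census ~16 only destroy panel diversity
without raising phase persistence.  Independent post-split drift and
mutation, not ancestral LD, are binding.  The high regime therefore
roughly doubles phase persistence relative to the low regime (~0.5 vs
~0.25) rather than reaching the 0.7 sometimes quoted for strongly
related breeds; the high-regime checks in the acceptance suite document
this ceiling explicitly.

Distance conventions: positions are Morgans internally; 1 cM is taken
as 1 Mb when physical coordinates are needed (VCF export, the "<50 kb"
= <0.05 cM query).  Binned statistics use half-open 1-cM bins starting
at zero, and a printed "r² at 1 cM" corresponds to the first bin
(pairs 0-1 cM apart, upper-edge labelling): with Table-scale
parameters the left-edge reading produces values (~0.17) that are
irreconcilable with the published 0.29, while the first bin reproduces
it.

## Trait architecture

Unsigned additive effects |a| ~ Gamma(shape 0.4, scale 1.66); the sign
is a fair coin; dominance degrees h ~ N(0.5, 0.1) independent of a; and
d = h|a| — directional, almost surely positive dominance.

**Variance scaling.** `scale_effects` rescales d and a by two global
factors so that, at a supplied vector of reference allele frequencies
and under HWE,

    V_A = sum_j 2 p_j q_j alpha_j^2,  alpha_j = a_j + d_j (q_j - p_j)
    V_D = sum_j (2 p_j q_j d_j)^2

equal their targets (0.3 and 0.1) exactly.  V_D depends only on d, so d
is scaled first in closed form; V_A is then an exact quadratic in the
additive factor and its positive root is used (no iteration, no
tolerance).  Scaling is idempotent and the factors are recorded.

**Choice of reference frequencies.** Which frequencies anchor the
scaling is not determined by the published description, and the choice
is consequential.  Anchoring at the realised QTL frequencies of the
last historical generation makes the realised genetic variances exact
(V_A = 0.3, V_D = 0.1, phenotypic variance 1, h² = 0.3, H² = 0.4) but
drives the dominance-to-additive scale ratio so high that ~half of the
QTL become overdominant (|d| > |a|), far from the published 10-15%.
Anchoring at p = 1/2 (the frequency-free textbook expressions
V_A = Σa²/2, V_D = Σd²/4) reproduces the 10-15% overdominance share —
the sensitivity is sharp, because the overdominance threshold sits near
the mean dominance degree — but leaves the realised variances below
target (V_A ≈ 0.2, V_D ≈ 0.05 at uniform frequencies), lowering
heritability and with it selection accuracy and response.  The package
anchors at the realised base-population frequencies (exact variances;
all downstream statistics that depend on h² = 0.3 then match), accepts
the high overdominance share, and reports it honestly; the
frequency-free anchor remains available by passing a vector of 0.5s to
`scale_effects`.  The overdominance check in the acceptance suite
documents the resulting tension.

**Phenotypes.** y = G + e with e ~ N(0, 0.6); G sums -a/d/+a per QTL
genotype.

## Marker-effect estimation

Model: y_i = mu + Σ_j X_ij a_j + Σ_j Z_ij d_j + e_i with X the 0/1/2
allele count and Z the heterozygosity indicator.  Priors: Park-Casella
Bayesian LASSO on the additive effects (a_j ~ N(0, σ_e² τ_j²),
τ_j² ~ Exp(rate λ²/2), λ² ~ Gamma(0.52, rate 1e-4)); a common normal
variance with scaled-inverse-χ²(3, 0.0005) prior on the dominance
effects; scaled-inverse-χ²(3.5, 3) on σ_e².  The scaled-inverse-χ²
density is ∝ (σ²)^(−df/2−1) exp(−df·S/(2σ²)).  The Gibbs sampler
updates the intercept, each a_j (marker-specific shrinkage), each
1/τ_j² (inverse-Gaussian), λ², each d_j, σ_d², and σ_e²; because the
additive prior scales with σ_e², the residual-variance conditional has
df_e + n + m degrees of freedom and its scale sum includes Σ a_j²/τ_j².
Default chain: 10 000 iterations, 1 500 burn-in, no thinning; the
posterior summary is the plain mean of the retained draws.  Covariates
are left uncoded and unstandardised exactly as the model states, and no
breed fixed effect is fitted in the combined-reference mode (the
intercept absorbs the average).

The λ² hyperprior (shape 0.52, rate 1e-4) is weakly informative; the
posterior-mean effects that the acceptance runs consume are insensitive
to it within an order of magnitude in either parameter.

## Breeding values, selection, reporting

TBVP/GEBVP and TBVC/GEBVC follow the expected-progeny-value formula
(per locus: AA → p a + q d; Aa → 0.5(p−q)a + 0.5d; aa → −q a + p d)
with the mate line's allele frequencies: own line for purebred
performance, other line for crossbred performance.  True values use the
100 QTL and true effects; genomic values use the 1000 SNPs and the
posterior means.  Frequencies are recomputed each generation from all
current selection candidates of the relevant breed (for both GEBVP and
GEBVC — the purebred case mirrors the stated crossbred rule).
Additive/dominance components follow the same structure with only the
a-terms or only the d-terms retained, and sum to the total exactly.

The program founds each line with 100 sires and 200 dams sampled from
the training generation (litter 5 → 1000 candidates, 500 per sex);
generation 1 of selection is this founding cohort.  Each generation the
top 100 males and 200 females by the scenario's criterion are selected
within sex (ties broken by id), mated within line (each dam one sire,
drawn with replacement), while the selected A males × selected B
females produce 1000 terminal crossbreds.  Marker effects are never
re-estimated.  Summaries per generation: purebred means, breed average
BA, crossbred mean, expected heterosis H = Σ d_l (p_A,l − p_B,l)² over
QTL at candidate frequencies, QTL frequency divergence Σ(p_A−p_B)², and
the full/additive/dominance accuracies per breed for both criteria.
No mutation is applied in steps 4-5 (the selection phase is the
R-script part of the original design; mutation there would be
negligible over five generations anyway).

## Orchestration and reproducibility

`run_replicate` derives all randomness from
`SeedSequence(master_seed, spawn_key=(replicate,))` with named
substreams for simulation, trait, training noise, the three possible
sampler fits, founding, and each scenario.  All five scenarios of a
replicate share the steps-1-3 populations, the architecture, the
training fits and the founded lines, so scenario contrasts are paired.
Reruns are bit-identical.  `run_study` aggregates per-replicate tables
into means and standard errors (SD/√n).

## Reduced profile and what the tests show

The smoke profile (600 candidate loci, 200 SNPs, 30 QTL, 200
historical generations at census ≤ 200, 20 breed-formation
generations, 3 expansion generations) exercises every code path in
seconds but is not the study: its LD level, phase persistence and
accuracies are not comparable to the full-scale values.  Full-scale
checks (one 2000-generation replicate takes ~35 s; a full replicate
with three 10k-iteration fits ~75 s) live in the acceptance suite,
which uses a handful of replicates; consequently its stochastic checks
carry replicate-sampling noise of a few hundredths on correlations and
~0.1 on generation-5 means.

Known limitations: a single 1-Morgan chromosome; no epistasis, no
genotype-by-environment interaction, no inbreeding-depression
covariate in the estimation model; crossbreds are terminal and never
phenotyped for training; the high-LD regime's phase persistence is
bounded near 0.5 (first 1-cM bin) by post-split drift and mutation, as
discussed above.

The purebred-crossbred genetic correlation is reported as the average
of corr(TBVP, TBVC) over both breeds and the five candidate cohorts of
the reference scenario: it starts near 0.9 at founding and falls as the
lines drift apart, so a single summary number is an across-generation
average of the standard program, not a founding-generation property.

A further consequence of the exact-variance anchoring: with ~half of
the QTL overdominant, within-line selection approaches
heterozygote-advantage equilibria, which damps late-generation purebred
response and shrinks the purebred-response advantage of selecting on
own-line merit; architectures with mostly partial dominance (the
frequency-free anchor) separate those scenarios more cleanly.
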