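# Methods

`stocksim` reimplements, as a tested library, the computational pipeline of
a population-genomics study of hatchery stocking impacts on a wild
freshwater fish (a St. Lawrence River muskellunge system): forward
Wright–Fisher simulation of a three-deme stocking scenario ranked against an
empirical summary-statistic vector, maximum-likelihood admixture inference,
standard diversity and differentiation statistics, LD-based effective
population size, and coalescent ABC estimation of asymmetric migration and
divergence time.  This note records the models, the parameter choices that
matter, and the design decisions taken where the procedure was genuinely
open.

## Genotype container and filtering

Genotypes are biallelic diploid alt-allele counts (0/1/2, −1 missing) with
per-site metadata (chromosome, 1-based position, RAD-locus id) and a
sample→site pop map.  Site filters mirror a RADseq quality pipeline:
observed heterozygosity < 0.60 (paralog control), call rate ≥ 0.70 within
every sampling location and globally, and a MAF floor.  Missing genotypes
are excluded from the heterozygosity and MAF denominators; each removed
site is attributed to the first rule that rejects it.  The per-population
presence rule is read as a per-site call-rate threshold within each
location (the wording also admits a per-individual reading; per-site call
rate is what vcftools-style tooling applies).  One SNP per RAD locus is kept
by highest MAF with ties broken toward the smallest position.  The
plink-style LD prune slides 50-SNP windows in steps of 5 and removes, one at
a time, the SNP with the largest variance inflation factor (1/(1−R²) of a
mean-imputed regression on the rest of the window) until none exceeds 2.

## Diversity and differentiation

H_o is the mean fraction of heterozygotes over sites polymorphic within the
population (a "global" mode is exposed as well); H_s and π are unbiased gene
diversities 2p(1−p)·n/(n−1) on allele copies, with π averaged over all
assayed sites.  Pairwise F_ST is Weir & Cockerham's θ as a ratio of sums of
the per-site variance components a, b, c (negative components retained, the
standard convention).  D_xy is the mean between-population difference per
site and D_a = D_xy − (π₁+π₂)/2.  The Mantel test for isolation by distance
correlates upper triangles of F/(1−F) and distance matrices, with a
one-tailed permutation p-value (the IBD hypothesis is directional); identity
permutations are redrawn so that p = 1/(B+1) when the matrices are
identical.

## Admixture model

The binomial admixture likelihood
L = Σ_{il} g_il log(Σ_k q_ik f_kl) + (2−g_il) log(Σ_k q_ik (1−f_kl))
is maximised by EM at fixed K (missing cells skipped, F clamped to
[1e−6, 1−1e−6], best of `n_starts` random restarts, convergence when the
relative log-likelihood change drops below `tol`).  EM was chosen over
quasi-Newton block relaxation for robustness; the log-likelihood is
non-decreasing every iteration and this is asserted in tests.  Cluster
labels are arbitrary, so cluster→group matching maximises summed
within-group mean membership via the Hungarian algorithm, and all
classification logic runs on matched labels (label-switching invariant).
Ancestry classes use the study's thresholds: resident if local-cluster
q > 0.9, admixed-domestic if summed stocking-cluster q > 0.10, wild-ancestry
if a foreign non-stocking cluster exceeds 0.10, F0-immigrant if any foreign
cluster exceeds 0.9.  Because the thresholds overlap, a deterministic
precedence is required; F0-immigrant > resident > admixed > wild is applied.
Choice of K by masked-genotype cross-validation (10% of called cells held
out) is provided but is data-dependent and not part of the validated
pipeline.

## LD-based effective population size

For each retained locus pair, the squared Burrows composite correlation is
r² = Δ̂²/(p_a q_a p_b q_b) with Δ̂ half the (n−1)-denominator covariance of
the genotype vectors; pairs on the same chromosome are excluded when
physical-linkage control is on, and singletons are always dropped (default
MAF floor 0.05, exposed).  The random-mating, S ≥ 30 sampling correction
r²′ = r̄² − 1/S − 3.19/S² (S the harmonic-mean pairwise sample size) feeds
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′), with N̂e = ∞ when r²′ ≤ 0.
Confidence bounds are a delete-one-individual jackknife, normal theory on
the 1/N̂e scale (∞ maps to 0, so upper bounds can be reported as "inf").

## Forward stocking simulator

One neutral 10,000-kb chromosome, μ = r = 1e−8 per bp per generation.  An
ancestral population (2,400 diploids at baseline) at equilibrium splits into
three demes of 800 (variants ×2, ×0.75, ×0.5 with the ancestral size scaled
accordingly): the river mainstem (SLR), an adjacent lake (LDM) and the
stocking source (SRC).  SLR and LDM exchange migrants throughout divergence
(m_SLR→LDM = 5e−4, m_LDM→SLR = 2.5e−4); divergence lasts 2,685 generations
and the final 15 are the stocking era, when SRC sends migrants into SLR (m
on a grid from 1e−6 to 0.1) and into LDM at 1.5× that rate.  Migration is
backward (each offspring picks its parental deme, then two parents uniformly
from it) — the convention of the individual-based simulator the scenario was
designed for.  The mortality filter removes D ∈ {0, 50, 100, 200, 400}
uniformly chosen SRC individuals from the breeding pool in every stocking-era
generation (modelling few effective breeders; the alternative reading —
killing migrant-derived individuals in the recipients — is noted but not
default).  Sampling (224 SLR + 56 LDM + 100 SRC) happens immediately after
the last stocking generation.  Fixed and lost sites are purged every 50
generations; infinite-sites collisions are redrawn.

Desk-scale execution rescales by λ: sizes and durations ÷λ, rates ×λ
(capped), preserving θ = 4Nμ, ρ = 4Nr, Nm and t/N.  The 80,000-generation
burn-in is replaced by an msprime coalescent draw of equilibrium standing
variation (θ and ρ matched); the equivalence of the two burn-in paths is
tested on the folded site-frequency spectrum.  The default desk profile is
λ = 10.  At λ = 10 the rescaled demes hold 60 diploids, fewer than two of
the empirical sample sizes, so sampling is capped at the deme size; the
pooled MAF ≥ 1% SNP count is insensitive to this because the minor-allele
count threshold scales with the pooled sample size and the frequency
spectrum enters only logarithmically.

## Summary vector and model ranking

The 13-statistic vector holds nine mean admixture memberships (three groups
× three matched clusters at K = 3), three pairwise Weir–Cockerham F_ST
values, and the count of SNPs at pooled MAF ≥ 1%.  RMSE over the 13 entries
uses the raw SNP count: reverse-engineering the published ranking arithmetic
shows the raw count (not a standardised version) reproduces the printed RMSE
column, so the count dominates the metric.  A consequence, documented
prominently: scenarios that share θ (for example a migration grid at fixed
population size) have equal expected counts, so their relative RMSE is
decided by count noise — tens of SNPs per replicate — while the
admixture-membership differences move the RMSE at the 1e-3 level.  Running
the candidate scenarios under common random numbers (identical replicate
seeds, a paired-comparison variance-reduction design) cancels the burn-in
and divergence-era components of that noise but not the final-generation
jitter, which still dominates.  Ranking therefore discriminates population
size (through the count) strongly and migration rate only weakly; the test
suite exercises and records this property.  Replicate statistics are
averaged before the RMSE by default (the averaging order is not fixed by the
source; the per-replicate-RMSE mode is exposed).  The empirical 13-value
target ships as a versioned package fixture together with the published
20-scenario reference table.

## Coalescent ABC

A structured-coalescent simulator (authored here; msprime serves as an
independent oracle in tests) draws per-locus genealogies for two demes of
relative sizes N₁, N₂ with asymmetric scaled migration (per-lineage backward
jump rates M = 4 N_ref m), merging at T_split (units of 4 N_ref generations)
into an ancestral deme N_anc; mutations are Poisson with per-locus
θ_ref = 4 N_ref μl.  Loci are free of intralocus recombination and
independent of each other (RADseq convention).  Per locus it returns the
mscalc-style set π₁, π₂, S, F_ST (Hudson form 1 − mean-within/D_xy), D_xy,
D_a, plus the Wakeley–Hey site classes sx_A, sx_B (exclusive), s_s (shared)
and s_f (fixed).  The site classes were added to the nominal statistic list
because without them the direction of strongly asymmetric migration is close
to unidentifiable when deme sizes are equal — π/F_ST/D_xy are nearly
label-symmetric at high M — whereas the exclusive-polymorphism asymmetry
carries the directional signal; they are standard members of the mscalc
output the statistic set mirrors.

Rejection ABC standardises the across-locus means and SDs of these
statistics, keeps the closest `tolerance` fraction (default 0.5%) by
Euclidean distance, and optionally applies Epanechnikov-weighted
local-linear regression adjustment, on the log scale for strictly positive
parameters (rate-like parameters with log-uniform priors).  Priors (the
published appendix is not available, so these are declared defaults):
M ~ log-uniform [0.01, 100], N₁, N₂, N_anc ~ uniform [0.05, 5]·N_ref,
T_split ~ uniform [0, 5].  Desk-scale reference tables use 100,000
simulations of 200 loci (the study used 10⁶ simulations on thousands of RAD
loci); a power consideration fixed the locus count: the directional
signal at M ≈ 40 is a few percent of the per-locus noise, needing ≥ O(10²)
loci to resolve.  Divergence time converts to years as
τ·4·N_ref·generation-time; both factors are explicit inputs because the
source scaling (4·N_ref·g = 10⁶ years) mixes a 5- and a 6-year generation
time.

## Synthetic data generators

Balding–Nichols genotypes (ancestral p ~ U(0.05, 0.95), cluster frequencies
Beta with drift F_k, genotypes Binomial(2, qᵀf)) provide admixture truth
sets; the defaults match the validation conditions (K = 3, F_k = 0.2,
thousands of SNPs).  The LD-Ne test bed is an unlinked-loci Wright–Fisher
population initialised at the mutation–drift stationary law (segregating
classes ∝ 1/i + 1/(2N−i) plus fixed boundary states at per-site θ = 0.02)
and run 50 generations with matching recurrent mutation — long enough for
pedigree LD to equilibrate while the frequency spectrum stays stationary;
allele counts are placed exactly (binomial placement would smear the rare
classes, and initialising every locus as segregating without the
monomorphic reservoir visibly depletes singletons).  What these generators
do not emulate: RADseq coverage artifacts, allele dropout, genotyping error,
linked selection — so passing recovery tests demonstrates estimator
correctness under the stated models, not robustness to those artifacts.

## Numerical choices and degenerate inputs

Frequencies are clamped away from {0, 1} before logs; monomorphic pairs
yield F_ST = NaN; F = 1 linearises to +∞; admixture on effectively
panmictic groups is flagged degenerate rather than rejected; ABC drops
zero-variance statistics with a warning; jackknife subsets that fail are
skipped with a warning.  All stochastic components take explicit seeds and
are bit-reproducible given them.

## Problem sizes used in the test suite

Validation runs are desk-scaled: λ = 10 for the stocking scenario (10
replicates in the acceptance script, fewer in the quicker tests), a 2,000-kb
chromosome for the migration-grid recovery study, 100,000-draw ABC tables of
200 loci, and 20-replicate recovery sets for the LD-Ne estimator.  The
methods themselves accept full-scale parameters unchanged.

## Known limitations

Neutrality throughout (no selection against introgression, no deleterious
load); three demes only (no tributary network); single-chromosome genome;
equal descendant deme sizes; the ABC statistic set and priors are declared,
not recovered from the unavailable supplementary material; the raw-count
RMSE convention makes model ranking sensitive to the polymorphic-site
statistic by construction.
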