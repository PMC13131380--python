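# Methods

`ipsim` studies how genotyping errors in young selection candidates degrade
*indirect predictions* (IP) — breeding values computed as centered gene
content times SNP effects back-solved from a single-step GBLUP (ssGBLUP)
evaluation. Everything is simulation-based: the package generates a
breeding program, runs the evaluations, injects errors and measures the
damage. This note documents the models, the parameters that matter, the
numerical choices, and what the desk-scale experiment can and cannot show.

## Population simulation

**Historical phase.** A Wright–Fisher-style population (random union of
gametes, discrete generations, equal sex ratio, no selection) passes
through two bottlenecks to establish drift/LD structure and an effective
size of ~100 at full scale. Population size interpolates linearly within
each bottleneck phase. Recurrent mutation flips allele state at 1e-4 per
locus per gamete. Because drift fixes most loci, the simulator tracks a
locus *pool* (`pool_multiplier` × the panel size, default 8×) and, at the
end of the phase, draws the SNP panel and QTL positions from loci still
segregating at minor allele frequency ≥ `maf_min` (default 0.05) — exactly
as a genotyping panel is ascertained. Panel counts are apportioned to
chromosomes by map length, reallocating when drift leaves a chromosome
short (real panels also have uneven per-chromosome counts).

**Genome.** 29 chromosomes whose lengths descend from 146 to 40 cM and
total 23.33 M, mimicking the bovine autosomes; positions are uniform;
crossovers follow a homogeneous Poisson process on the genetic map
(Haldane mapping, no interference). Full scale carries 70,000 SNPs and
1,000 QTL; the desk profile 5,000 and 200.

**Trait.** Additive with heritability h² = 0.25 on phenotypic variance
σ²p = 1, of which a 0.05 fraction is a residual polygenic term simulated
as an infinitesimal effect (founders N(0, 0.05); offspring receive the
parent average plus Mendelian sampling with variance ½σ²pg(1 − F̄)).
QTL effects are drawn standard normal and rescaled so the *realized*
founder variance of the QTL sum equals (h² − rpg)·σ²p = 0.20. Rescaling
by the Hardy–Weinberg/linkage-equilibrium sum Σ2p(1−p)a² instead leaves
the realized variance ~10% short in bottlenecked founders (identity
disequilibrium), which measurably biases parent–offspring regressions;
the realized-variance scaling makes the simulated h² exact by
construction. Phenotypes (trait value + N(0, 0.75)) are recorded on both
sexes.

**Selection phase.** The current population starts from founders drawn
after an 8-generation random-mating expansion (dams growing exponentially
at the rate needed to supply the founder herd). Each of 15 generations:
dams are ranked on EBV, split into contiguous rank blocks assigned to
EBV-ranked sires (positive assortative mating); every dam leaves
`litter_size` = 5 offspring of random sex; EBV are refit; the lowest-EBV
60% of sires and 20% of dams are culled and replaced by the highest-EBV
new candidates, with the dam herd growing 30% per generation up to
`max_dams`. The cap exists because uncapped 30% compounding is
inconsistent with the near-stationary cohort sizes the design implies;
full scale caps at 2,500 dams (cohorts of 12,500), the desk profile at
160 (cohorts of 800, hence 3,200 training and 800 validation genotyped
animals).

**Within-simulation EBV.** Selection acts on EBV from a single-trait
pedigree BLUP (animal model, overall mean, true variance ratio λ = 3)
refit each generation on all phenotypes to date. Config switches allow
phenotypic selection and random (zero-intensity) selection; the latter is
used for drift and calibration checks.

**Seeding.** One master seed per replicate; the historical, founding and
selection stages draw from independently spawned substreams, and error
injection uses streams independent of the simulation, so all error
scenarios within a replicate evaluate the identical candidates.

## Evaluation model

Single-trait animal model y = 1μ + u + e with u ~ N(0, H σ²a),
σ²a = 0.25, σ²e = 0.75 fixed at the simulation values (the evaluation
treats all additive variance as genomic; the residual polygenic fraction
is deliberately ignored in the IP derivation). H⁻¹ = A⁻¹ plus the
genotyped-block correction G*⁻¹ − A22⁻¹, with:

- A⁻¹ by Henderson's rules, inbreeding from the Meuwissen–Luo algorithm;
- A22 extracted by sparse factorization of A⁻¹ (exact, scales to large
  pedigrees);
- G = ZZ′ / 2Σp(1−p) (VanRaden), Z centered by twice the allele
  frequency; monomorphic loci contribute zero columns and are excluded
  from the scaling constant;
- tuning/blending G* = (1−α)(11′c + dG) + αA22 with α = 0.05,
  c = mean(A22) − mean(G), d = 1 − c/2 (a two-equation
  diagonal/off-diagonal variant is available as `tuning="moments"`).

The additive shift is applied only upward by default (c = max(0, ·)): a
negative rank-one shift can make G* indefinite when the genomic mean
already exceeds the pedigree mean, which occurs under base-population
centering in strongly drifted populations.

The **benchmark** run includes training and candidate genotypes
(candidates carry no phenotypes); the **reduced** run drops candidate
genotypes. SNP effects come from the reduced run via
â = (1−α)·d·(1/k)·Z′t·G*tt⁻¹·ût, and IP = Zv·â with candidates centered
by the *same* frequencies used in training — errors never leak into the
centering constants. Each run computes its own tuning constants from its
own genotype set.

**Centering frequencies.** Default: observed training-set frequencies,
as production pipelines recompute frequencies from the data they ingest.
Consequence: IP are referenced to the training mean (mean Zt·â ≡ 0),
while benchmark GEBV under a complete pedigree are referenced to the
pedigree base and carry the full cumulative genetic trend. Location-free
statistics (correlations, regression slope, variance ratio) are
unaffected; location-dependent ones (standardized bias, RMSE, intercept)
include the trend offset — see Limitations. `centering="founder"` uses
generation-0 frequencies instead, putting IP on the pedigree base.

**Solvers.** The MME are kept as a sparse part (mean, incidence, λA⁻¹)
plus the dense genotyped-block correction. Pedigree-only systems use a
sparse LU factorization; genomic systems a dense symmetric solve when
small, otherwise Jacobi-preconditioned conjugate gradients (relative
residual 1e-10, the same family of solver as production
iteration-on-data programs). Both paths agree to 1e-6 on test problems
and the PCG path is deterministic. Symmetric matrices are re-symmetrized
after assembly; SPD inverses use Cholesky.

**APY.** The algorithm-for-proven-and-young inverse (core block inverted
directly, noncore animals regressed on the core with independent
residuals) is provided for fidelity, not scalability; with a full core it
equals the dense inverse, and back-solving through it reproduces the
direct-inverse IP to correlation > 0.99 at desk scale.

## Error model

A fraction `rate` of each candidate's loci — exactly `round(rate · n)`
per animal, matching a "5% of 70,000 = 3,500 markers" reading — is
selected uniformly (independent subsets per animal by default; one
shared subset optionally, as a platform artifact) and each selected code
is replaced by one of its two alternatives with probability ½. The side
experiment applies the same scheme to the *training* genotypes with
correct candidates; the erroneous training set then defines its own
frequencies and relationship matrices, as a pipeline ingesting bad data
would. This is the channel that inflates IP: corrupted frequencies are
pulled toward 0.5, which inflates the centered gene content of correct
candidates.

## Desk profile and evaluation statistics

The desk profile (the acceptance configuration) uses 30 sires /
120→160 dams, a shortened historical phase (300→60 over 150 generations,
then 60→30 over 150) targeting the same qualitative drift/LD regime,
5,000 SNPs, 200 QTL, 5 replicates; one replicate runs in ~1.5 minutes on
one CPU. Statistics per scenario and replicate: Pearson/Spearman
correlations between benchmark GEBV and IP, OLS intercept/slope of GEBV
on IP, RMSE, standardized bias (mean IP − mean GEBV)/σa with the *true*
σa = 0.25, and var(GEBV)/var(IP) (sample variances, n−1). Replicates are
summarized as mean ± SE; 95% CIs use Fisher z for correlations and OLS t
intervals for regression coefficients (the reference study does not name
its CI construction; any standard choice differs only in width).

## Calibration checks

- Parent–offspring regression under random mating and no selection
  recovers h²/2 = 0.125 within 3 SE over 20 seeds. The calibration uses
  a mild-drift configuration (N ≈ 200–250 historical, short); under the
  harsh desk bottleneck, negative linkage disequilibrium among panel
  survivors depresses the parent–offspring covariance below the
  idealized value — a real property of drifted populations, not an
  inheritance bug, so the calibration isolates the mechanics from it.
- Heterozygosity decays as H0(1 − 1/2N)^t under the neutral
  configuration; crossover counts per gamete average the map length in
  Morgans; zero-intensity selection shows no TBV trend over 20 seeds.
- Under EBV selection the desk profile gains ~0.27 phenotypic SD per
  generation and cohort mean TBV increases strictly every generation.

## What the desk scale reproduces, and what it cannot

Reproduced at the stated tolerances: the correct-scenario agreement
(Pearson/Spearman ≈ 0.98–1.00, slope ≈ 1.02), the E05/E10 degradation,
scenario monotonicity of every statistic in every run, and the direction
of the training-error side experiment.

Two structural gaps remain, measured and left visible in the acceptance
suite rather than patched:

1. **E20 tail.** With 5,000 markers each back-solved effect carries ~14×
   the per-marker weight of a 70,000-marker panel, so a 20% error rate
   injects relatively more noise per locus and dilutes less through LD:
   desk Pearson falls to ~0.88 (reference 0.93) and the slope reaches
   ~1.15 (reference 1.33). The attenuation structure is marker-density
   dependent; a desk panel cannot match both E05/E10 and E20
   simultaneously.
2. **Location statistics.** The reference study's GEBV and IP means are
   nearly equal (1.14 vs 1.17), implying a common, recent reference
   base; under this package's complete-pedigree evaluation the benchmark
   GEBV carry the full 15-generation trend while training-centered IP do
   not, so standardized bias and RMSE include a trend offset of several
   additive SD. The reference base used by the original analysis is not
   recoverable from its description; both centering conventions are
   implemented and the offset is absent from all location-free
   statistics.

Other limitations: no dominance/epistasis, no litter-size or mortality
modelling, no missing genotypes (code 5 is passed through, never
emitted), no variance-component estimation, and the desk historical
phase compresses ~2,000 generations into 300 with stronger per-generation
drift; LD beyond a few cM is therefore more intense than at full scale.
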