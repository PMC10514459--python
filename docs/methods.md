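# Methods

`erosim` models genome erosion in an island population founded from a large
mainland source: loss of heterozygosity, growth of inbreeding (F_ROH), and
the dynamics of deleterious variation (realized and masked load, purging)
under founder events, long-term isolation and recent bottlenecks.  This
note records the model, its assumptions, the calibrated constants, the
numerical choices, and what the desk-scale runs can and cannot show.

## The demographic model

The simulator is individual-based and non-Wright-Fisher: each cycle is one
calendar year, generations overlap, and population size N is emergent.
Within a year,

1. **Reproduction.** Females aged 1–13 each produce a litter whose size is
   drawn from `litter_probs`; the father is drawn uniformly from that
   year's breeding males (a random half of males aged 1–13, redrawn every
   year — a harem system).  Each calf receives one recombined gamete per
   parent plus Poisson-distributed new mutations.
2. **Viability selection.** Each individual survives with probability
   `min(1, W · (1 − m_age) · min(K/N, 1))`, where `W` is multiplicative
   genetic fitness (homozygous derived site: 1+s, heterozygous: 1+h·s,
   fixed deleterious included), `m_age` is the age-specific mortality
   (calves 0.2; ages 1–14: 0.05; 15: 0.74; 16: 1.0), and the density factor
   uses the post-reproduction census, calves included.  Survivors age one
   year; nothing survives past 16.
3. **Demographic events.** At scheduled years the island is founded by
   drawing K_founder individuals uniformly without replacement from the
   mainland (founders emigrate), or a population's carrying capacity
   changes instantaneously.

**Default litter distribution.** Reindeer bear single calves, so the
default is exactly one calf per eligible female per year.  The declining
1–8 distribution of annual reproductive output that motivates the harem
design then emerges for *males* (a breeding male sires approximately a
Poisson number of calves through female choice).  A per-female multi-calf
distribution remains configurable; with litter-heavy settings the
population turns over much faster and drifts correspondingly harder.

**Census vs capacity.** Because the density factor is computed from the
post-reproduction census, the post-survival census equilibrates near 0.8 K
rather than at K.  N "fluctuates around" K in this sense; no statistic in
the package depends on N = K exactly.

## Genome and fitness effects

The genome is `n_chromosomes × genes_per_chromosome` genes of 1,750 bp
(defaults: 6 × 500 = 5.25 Mb).  There is no recombination within a gene,
a crossover probability of 1e-3 per gene boundary, and free recombination
between chromosomes.  Mutations arise at 1.76e-9 per site per meiosis
(derived from 1.06e-8 per generation at a six-year generation time) and
are non-synonymous with probability 2.31/3.31.  Deleterious selection
coefficients are −Gamma(shape 0.186, mean 0.01314833), clamped at −1;
dominance follows the inverse s–h relationship (h = 0 for s < −0.1,
0.01 for −0.1 ≤ s < −0.01, 0.1 for −0.01 ≤ s < −0.001, 0.4 above), and the
same cut points define the weak/moderate/strong/very-strong reporting
bins.  An optional discrete recessive-lethal point mass exists and is off
by default (the gamma clamp already produces a lethal class).

## Population rescaling (ScalingPolicy)

Full-scale scenarios (mainland K = 50,000, 500,000-year burn-in, 30
replicates) are not desk-runnable.  `ScalingPolicy(lam)` applies the
standard forward-simulation rescaling: capacities ×λ, mutation and
inter-gene recombination rates ×1/λ, selection coefficients ×1/λ
(re-clamped at −1; dominance and category always from the unscaled draw),
and — by default — event times and burn-in ×λ as well.  This preserves
drift (t/2Ne), diversity (4Neμ) and selection (Ne·s) against the
full-scale model.  Keeping event times in calendar years while rescaling
capacities (available as `rescale_times=False`) makes per-year drift
1/λ-fold too fast relative to the demography: every island scenario then
collapses to its own small-population equilibrium and all founder sizes
produce near-identical ~90% heterozygosity losses, which is not a faithful
miniature of the full model.  Life history and age structure are never
rescaled.

Two hard limits of rescaling are built in or documented:

* **Capacity floor (4).** Rescaled capacities are floored at four
  individuals (two breeding pairs).  Measured at λ = 1/20, islands with
  K ∈ {2, 3} went extinct in 240/240 founder-phase attempts (density
  regulation plus inbreeding meltdown under 20-fold-amplified selection);
  a two-sex age-structured population of one pair is demographically
  meaningless.
* **Purging does not compress.** The per-generation rate of
  inbreeding-exposure purging is F × s_hom and saturates at lethality
  (s = −1), so a 20-fold shortening of the post-founding window cannot be
  compensated by scaling s.  Masked-load *reductions over fixed calendar
  windows* are therefore systematically smaller in rescaled runs than at
  full scale, while inbreeding F itself rescales correctly.

* **ROH thresholds are map-based.** The rescaled genetic map is 1/λ-fold
  denser per bp, so the simulated F_ROH threshold "0.1 Mb" becomes
  100 kb × λ of simulated sequence.  Polymorphism spacing does *not*
  rescale, which inflates the absolute F_ROH level of every population at
  strong rescaling (gaps between segregating sites exceed the shortened
  threshold); island–mainland contrasts in heterozygosity are unaffected.

## Equilibrium initialization

Instead of a 500,000-year burn-in, a replicate can start at analytic
mutation–drift equilibrium (`init="equilibrium"`, the default) followed by
a short relaxation (default 100 years in rescaled runs):

* the stationary age distribution and density factor are solved from the
  life table (bisection on the renewal condition);
* neutral sites are seeded from the standard spectrum E[#sites at derived
  count i] = θL/i with θ = 4 · r_θ · K · μ, where the diversity ratio
  r_θ = H_eq/(4μK) = **0.57** was measured for the default life history by
  running the engine itself to equilibrium (`estimate_ne_years_ratio`);
  because a lineage mutates once per generation, the implied effective
  size in year units is r_θ · T_gen · K ≈ 1.86 K (T_gen ≈ 3.3 years from
  the life table);
* deleterious sites are seeded from the same spectrum weighted by the
  diffusion sojourn-time ratio with α = 2 · Ne_years · s and the bin's
  dominance (computed in log space to avoid overflow at strongly selected
  α).

The initialization is neutral-exact and approximate for selected sites
(linkage disequilibrium and the longest-lived weak class equilibrate
during the relaxation; realized load relaxes from ~0.045 to ~0.035 over
the first ~300 years).  The calibration constant was measured once from
neutral runs and is recomputed only when the life history changes.

## Survivor conditioning at extreme rescaling

At λ = 1/20 the severe scenario's founder phase (K = 4 after flooring)
persists in only ~9% of attempts.  `founding_retries > 0` makes a
replicate rewind to a mainland snapshot at the founding year and redraw
founders whenever the island dies out — rejection sampling of island
trajectories conditional on persistence, which is the relevant ensemble
(the study population did persist).  The default is 0: extinction is then
flagged with its year and the run continues, as the scenario contract
specifies.

## Summary statistics

Per population, every recorded year (every 10 full-scale years), from a
uniform sample of ≤30 individuals: census N; heterozygous sites per kb;
F_ROH over tracts ≥ 0.1 Mb (map units, see above) where tracts are the
intervals of the physical map delimited by the individual's own
heterozygous sites and chromosome ends; realized load 1 − mean(W) with
fixed deleterious included; masked load 1 − mean(∏_het (1+s)/(1+h·s));
and mean derived-allele counts per DFE bin (hom ×2 + het, population-fixed
alleles included so island and mainland counts stay comparable after
independent fixation).

## Empirical-side toolkits

The ROH detector reproduces the PLINK sliding-window semantics (window
hit-fraction with reduced denominators at chromosome edges; runs split at
gaps; SNP-count, length, density and segment-heterozygote filters), with
named profiles for the reported parameterizations (windows of 100/1000
SNPs, 1/3 allowed heterozygotes).  Missing genotypes neither count as
heterozygous nor break runs.  The inbreeding clock g = 100/(2rL)
(r = 1.04 cM/Mb, six-year generations) reports g to two significant
figures (one decimal below 1) and years to the nearest year — the rounding
that reproduces the published timing table.  Note the published table's
"≥2 Mb → up to 2.4 generations" cell is inconsistent with the formula
(24.0; the years cell, 144, is consistent); the package follows the
formula.

Load accounting operates on ALT-polarized dosage tables with exhaustive
impact categories (HIGH/MODERATE/SYNONYMOUS/INTERGENIC).  R_xy uses
L_{x¬y}(S) = Σ f_x(1−f_y), standardized by an equally sized seeded random
draw of intergenic sites, with a delete-one jackknife over contiguous
equal-site blocks spanning the category and standardization sets jointly.
Both allele counts (2·hom + het) and variant counts (hom + het) are
reported, since published per-individual figures do not state which
convention they use.  The hard filters mirror the variant-calling
protocol: site quality ≥ 30, per-genotype depth within [⅓, 2]× the
sample mean, heterozygote reference-allele balance within [0.2, 0.8],
indels and SNPs within 5 bp of an indel removed.

## Synthetic data

The generator emulates exactly the statistical structure the toolkits
assume: category-labelled sites placed uniformly, per-site derived-allele
frequencies drawn once from per-category Beta distributions and shared
across populations (per-population overrides make them independent), an
optional multiplicative frequency deficit in one population (planting a
directional R_xy signal), Hardy–Weinberg genotypes, forced-homozygous
tracts, and a negative-binomial depth / Beta allelic-balance error model.
It does not emulate linkage disequilibrium (beyond planted tracts),
population structure within populations, or read-level errors — so passing
fixture tests demonstrates correctness of the statistics, not robustness
to LD or structure in real data.

## Problem sizes used in checks

Simulation checks run at λ = 1/20 with 2 chromosomes, 100-year
relaxation after analytic initialization, 10 replicates per scenario
(3 for the null), sampling 30 individuals: one replicate of the severe
scenario takes ~20 s and the whole simulation battery a few minutes on one
CPU.  Property checks use fixtures of ≤ a few thousand sites and
brute-force oracles at ≤ 200 individuals.

## Known limitations

* Desk-scale masked-load reductions over calendar windows undershoot the
  full-scale model (saturation argument above); the direction and ordering
  of purging across founder sizes is preserved, the magnitude is not.
* F_ROH absolute levels at strong rescaling are inflated by
  non-rescalable polymorphism spacing.
* The analytic initialization slightly over-seeds the masked load
  (relaxes within ~200 years) and starts with zero fixed load.
* No migration after founding, no environmental stochasticity, no sex
  chromosomes, no epistasis; mutations stack as separate records at
  colliding positions (effectively infinite-sites).
* The mutation rate is applied per meiosis; with the default life history
  a lineage experiences one meiosis per ~3.3 years, so per-calendar-year
  input is correspondingly lower than the nominal per-year figure.  All
  headline comparisons are island/mainland ratios and are insensitive to
  this convention.
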