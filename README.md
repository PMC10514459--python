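# erosim

Forward simulation and population-genomic statistics of **genome erosion in
founded island populations** — heterozygosity loss, runs of homozygosity
(ROH) and inbreeding, and the dynamics of deleterious genetic load
(realized, masked, purging) when a small number of colonizers founds an
isolated population that later recovers, persists at modest size, and
suffers a recent harvest bottleneck.  The motivating system is a
High-Arctic island reindeer population founded ~7,000 years ago from a
large mainland source, but every scenario parameter is configurable.

The package has two halves that meet in the middle:

* **A forward-in-time, age-structured, non-Wright-Fisher simulator.**
  One cycle = one calendar year.  Females aged 1–13 bear single calves
  (configurable litter distribution); a random half of age-eligible males
  breed each year (harem system); survival is
  `min(1, W · (1 − m_age) · min(K/N, 1))` with multiplicative genetic
  fitness `W`, age-specific mortality, and density regulation around a
  carrying capacity K.  The genome is gene-structured (6 chromosomes × 500
  genes × 1,750 bp by default) with within-gene linkage, a gamma
  distribution of deleterious fitness effects
  (s = −Gamma(0.186, mean 0.01314833), NS:SYN = 2.31:1) and inversely
  s-dependent dominance (h = 0, 0.01, 0.1, 0.4).  Scenarios are timed
  carrying-capacity events plus a founding event that samples colonizers
  out of the mainland.  Standard population rescaling (capacities ×λ,
  rates and s ×1/λ, durations ×λ) makes the full study design run on a
  laptop, with an analytic mutation–drift equilibrium initialization in
  place of a 500,000-year burn-in.

* **Empirical-side toolkits** that compute the matching statistics from
  annotated multi-sample VCFs (or simulator output): PLINK-parameterized
  sliding-window ROH detection and F_ROH by length class; heterozygosity
  per kb; the ROH-length inbreeding clock g = 100/(2rL); per-individual
  deleterious load counts and deleterious:synonymous ratios by impact
  category (HIGH / MODERATE / SYNONYMOUS); and the R_xy derived-allele
  frequency statistic with intergenic standardization and block-jackknife
  errors.  A synthetic-data generator produces VCF + annotation + popmap
  fixtures with known truth (controlled frequency differentials, planted
  ROH tracts, depth/allelic-balance error models) so the whole empirical
  side is testable without sequencing data.

## Worked example

Run ten replicates of the severe founder scenario (25 founders at
7,000 BP, recovery to 2,000 at 6,900 BP, 20,000 at 1,200 BP, bottleneck to
1,800 at 200 BP, 20,000 from 100 BP) rescaled by λ = 1/20 on a
two-chromosome genome, and compare the island to the mainland today:

```python
import numpy as np
from erosim import founder_scenario, ScalingPolicy, GenomeArchitecture
from erosim.simulate import ForwardSimulator

sim = ForwardSimulator(
    founder_scenario(k_founder=25, k_recovery=2_000),
    arch=GenomeArchitecture(n_chromosomes=2),
    policy=ScalingPolicy(lam=1 / 20),
    founding_retries=150,          # condition on island persistence
)
result = sim.run(n_replicates=10, base_seed=1)
ts = result.timeseries
today = ts[ts.year_bp == 0].groupby("population").het_per_kb.mean()
red = 100 * (today["mainland"] - today["island"]) / today["mainland"]
froh = ts[(ts.year_bp == 0) & (ts.population == "island")]["f_roh_0.1Mb"].mean()
print(f"heterozygosity reduction: {red:.1f}%   island F_ROH: {froh:.2f}")
```

```
heterozygosity reduction: 72.4%   island F_ROH: 0.99
```

The island has lost about three quarters of the mainland's heterozygosity
— the founder effect and five millennia at modest size dominate, not the
recent bottleneck — and essentially its whole genome sits in runs of
homozygosity longer than the (map-rescaled) 0.1 Mb threshold.  The same
`timeseries` frame carries realized/masked load and per-category
deleterious allele counts per decade for every replicate.

The same scenarios are available from the shell, as are the empirical
tools:

```bash
erosim simulate founder25_rec2000 --scale 0.05 --chromosomes 2 \
       --replicates 10 --seed 1 --out runs/severe
erosim synth --out fixture/
erosim roh  --vcf fixture/synthetic.vcf --annotation fixture/annotation.tsv \
       --popmap fixture/popmap.tsv --genome-bp 10000000 --out roh_out/
erosim load --vcf fixture/synthetic.vcf --annotation fixture/annotation.tsv \
       --popmap fixture/popmap.tsv --rxy pop0 pop1 --out load_out/
```

Every run writes a JSON manifest (config snapshot, seeds, output
checksums) sufficient to reproduce it.

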