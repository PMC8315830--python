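# Methods

`skyscan` reimplements, as a tested pipeline on coalescent-simulated data,
the population-genomic analysis of a two-population "sky island"
divergence: a pair of montane bird populations that split recently, each
collapsed to a fraction of its former size, and exchange almost no
migrants. The package provides the simulator that emulates that history,
the windowed divergence scan, the joint-SFS demographic inference, the
simulation-calibrated outlier procedure, a sweep scan, and the permutation
enrichment test, wired together by a pipeline driver.

## Demographic model

Four nested scenarios describe two demes ("west" and "east") splitting
from a common ancestor `T_split` generations ago:

| model | post-split sizes | gene flow | free parameters |
|-------|-----------------|-----------|-----------------|
| M1    | constant        | none      | 3 |
| M2    | constant        | continuous | 5 |
| M3    | step change     | none      | 5 |
| M4    | step change     | continuous | 7 |

Backward in time, each deme holds its *current* size (`N_w1`, `N_e1`)
from the present to `T_split/2`, its *founding* size (`N_w0`, `N_e0`)
from there to the split, and the demes then merge into an ancestral pool
of size `N_anc = N_w0 + N_e0`. Two conventions deserve comment:

* **The size step sits at the midpoint of the post-split period.** A
  "post-split decline" needs both a founding and a current size and a
  time at which one becomes the other; placing the step exactly at the
  split would give the founding sizes a zero-length epoch and make them
  unidentifiable. The midpoint is the simplest symmetric choice; nothing
  downstream depends delicately on it.
* **The ancestral pool equals the sum of the founding sizes.** The split
  is treated as a partition of the ancestral population. This removes one
  parameter per model and gives the parameter counts above; it also makes
  `N_anc` a derived quantity that the fits recover very precisely, since
  it controls the dominant (ancestral) part of coalescent depth.

Migration is parameterized as expected migrant **individuals per
generation** in the forward direction (`m_we` west→east), converted
internally to per-lineage backward rates `m/N_recipient`. Mutation rate
is fixed at `mu = 4.6e-9` per site per generation, generation time 5.35
years; these convert fitted split times to calendar years.

The default study scenario (`m4_paper()`) uses `N_anc = 60 000` split
equally, a ten-fold decline to `N_w1 = N_e1 = 3000`, `T_split = 2206`
generations (11.8 kya) and migration 0.005/0.012 migrants per generation.
The sizes were chosen once so that neutral expectations land near the
observed diversity of the study system (within-population diversity
~0.08–0.09%, between-population divergence ~0.0012/bp); everything else
is as reported for the system.

## Coalescent simulator

Genealogies are simulated by a standard exact (Gillespie-style)
structured coalescent over the piecewise-constant epochs: pairwise
coalescence at rate `1/(2N)` within a deme, backward migration per
lineage at `m/N`, both recomputed at epoch boundaries. Lineages carry
64-bit descendant bitmasks, capping samples at 64 haplotypes (the study
design uses 16: four diploids per population). Mutations follow the
infinite-sites model: Poisson with mean `TBL * mu * L`, placed on
branches proportionally to length at distinct integer positions
(collision re-draw).

**Windows are chunked.** A 50 kb scan window is composed of independent
fully linked chunks of 5 kb (free recombination between chunks, none
within). The scan uses 50 kb windows precisely because linkage
disequilibrium decays inside that distance, so modelling a window as one
genealogy would grossly overstate the variance of window statistics — a
single-genealogy window makes window Fst so noisy that planted divergent
regions cannot be separated from neutral ones at any reasonable effect
size. With 5 kb chunks the simulated Z(Fst) null is close to normal and
its 95th percentile sits near 1.75–1.80, which is also where the
empirical study's cutoff fell. The chunk size is a configurable
compromise: the per-chunk diversity (~15 SNPs at study parameters) sets
the effective linkage scale. `chunk_size >= L` recovers the
single-genealogy behaviour.

Reproducibility: one master seed; per-window seeds come from a
counter-based split (`SeedSequence.generate_state`), so any window can be
re-simulated alone and a fixed seed yields bit-identical VCF output.

Planted signals for power studies re-simulate a window with the focal
deme's current size multiplied by `shrink` (default 0.05): stronger local
drift depresses diversity there and inflates Fst, a stand-in for a local
sweep/divergence with a known location. Limitations: no sequencing error,
no missing genotypes, no forward selection, no recombination map — the
generator tests the statistical machinery, not robustness to data
artefacts, so green tests here say nothing about, e.g., polarization
error on real data.

## Window statistics

Hudson's Fst in ratio-of-averages form (numerator `(p1-p2)^2` minus the
`p(1-p)/(n-1)` sampling corrections, denominator the between-population
heterozygosity, summed over sites before the ratio): robust for small and
unequal samples, standard for window scans. Dxy uses the full window
length as denominator (all sites are callable in synthetic data; for
real data a per-window callable length can be passed to the statistic
functions directly). pi is the sample-size-corrected mean pairwise
difference. Windows with fewer than 3 SNPs get a missing Fst and never
enter the Z-transform or outlier calling — sparse windows otherwise
dominate the tails through sampling noise alone. The Z-transformation
uses the sample standard deviation (ddof=1) over all defined windows.

## Joint-SFS demographic inference

The data are reduced to the 2-D unfolded SFS **including the monomorphic
class** — keeping invariant sites anchors the absolute mutation input
`mu*L` and hence the size/time scale. Polarization is by the ancestral
(`AA`) allele; sites whose ancestral call matches neither allele are
dropped and counted.

The likelihood is multinomial composite: `sum obs(i,j) * log p(i,j)`.
Expected cell probabilities combine

* a Monte-Carlo **shape** — mean genealogy branch length subtending each
  joint class, from the same simulator (no mutations needed), and
* optionally an **exact scale** — the expected total branch length from
  the lineage-count Markov chain `(k_west, k_east)` integrated over the
  epochs by augmented matrix exponentials.

Zero cells are floored at `0.1/n_sims` before renormalization so a
finite simulation never produces `-inf`.

The search works on log10 parameters inside bounds (sizes 1e2–1e6, split
time 1e1–1e5 generations, migration 1e-4–10 migrants/gen):

1. **Moment candidates.** Exact pair-coalescence moments (a 3-state
   backward chain with migration, solved per epoch by matrix
   exponentials) give, for each candidate split time and migration level,
   the founding size that matches observed Dxy and the current size that
   best matches observed pi. This matters because histories differing
   mainly in split time mimic each other closely in the joint SFS of 16
   haplotypes — a short hard decline and a long mild one form distinct,
   nearly equally likely basins.
2. **Screening.** All candidates (plus random starts) are scored with a
   common-random-numbers Monte-Carlo likelihood; the best start per
   log-split-time bin survives.
3. **Polish.** Each surviving basin gets a bounded Nelder–Mead pass per
   estimation loop, again with a frozen per-loop Monte-Carlo stream.
4. **Final paired evaluation.** All polished points (and their raw
   starts) are re-scored with one large fresh stream; the best becomes
   the fit. Fitting competing models with the same seed correlates their
   final-evaluation error, sharpening AIC comparisons.

Model choice is minimum AIC (`2k - 2 lnL`), ties to fewer parameters.
Replicate fits give "top 5% most likely runs" confidence summaries
(median, min–max, 2.5–97.5 percentiles).

**Known limitation — composite-likelihood AIC.** With linked sites the
composite log-likelihood behaves like an inflated likelihood: the
overfitting gain of a richer nested model scales with the number of SNPs
per linked chunk (tens of units) while the AIC penalty is 2 per
parameter, and the Monte-Carlo error of any affordable final evaluation
(~±40 units) also exceeds the penalty margin. AIC selection is therefore
dependable when the generating model is the richest candidate (M4) and
close to a coin toss when it is the simplest (M1). This is a property of
composite-likelihood model selection itself, not of the optimizer.

A second practical point: at the study's own migration point estimates
(0.005–0.012 migrants/generation) M4 is observationally equivalent to M3
at any desk-scale data size. Validation experiments therefore use the
study-calibrated scenario for parameter recovery and a variant with 0.5
migrants/generation (`m4_identifiable()`) wherever the *migration
parameters themselves* must be distinguishable — chosen up front as a
precondition of the experiment, not tuned to outcomes.

## Simulation-calibrated outlier scan

The cutoff is the 95th percentile of Z(Fst) pooled over replicate genome
simulations under the fitted model, Z-transformed **within each
replicate** exactly as the empirical statistic is. "2000 genome-wide
nominal values" is read as 2000 replicate genome simulations; windows
above the cutoff (strict inequality) are flagged and adjacent flagged
windows merge into regions (gap tolerance configurable, default 0). Dxy
outliers use the same machinery on Z(Dxy) from the same replicates.

## Sweep scan

SweepFinder-style composite likelihood ratio. The background is the
genome-wide unfolded frequency-class distribution including the invariant
and fixed classes. At a grid point (10 kb spacing), a lineage at distance
`d` escapes the sweep with probability `p_esc = 1 - exp(-alpha d)`; the
`K ~ Binomial(n, p_esc)` escaped lineages plus the sweeping ancestor are
a pre-sweep sample of size `K+1` (hypergeometric downsampling of the
background) and the ancestor's allele fills the hitchhikers. `p_esc = 0`
concentrates all mass in the extreme classes; `p_esc = 1` returns the
background. The CLR maximizes the summed log ratio over a log-spaced
alpha grid (20 points, 1e-6–1e-1 per bp) and is floored at the neutral
limit 0. Invariant sites carry signal too (the invariant class becomes
*more* probable near a sweep) and enter through 16 quadrature distances
per window. Escape probabilities go through a 201-point lookup table.
Thresholds come from simulation under the fitted model (95th percentile
of neutral CLR); population comparisons use the two-sided Wilcoxon
rank-sum on grid-point CLRs and a chi-square goodness of fit on region
counts with the expectation vector exposed (default equal split).

## Enrichment

Genes overlap regions by ≥1 bp on half-open intervals. The Fisher test is
the one-sided hypergeometric upper tail `P(X >= k)` with the 2×2 odds
ratio excluding selected genes from the background margin. The
permutation null draws the same number of genes uniformly without
replacement B times (default 10 000) and the verdict requires the
observed category proportion to *strictly* exceed the null's 95th
percentile; an empirical `p = (1 + #{null >= obs}) / (B + 1)` is also
reported. An empty selection is an error (the proportion is undefined).
The synthetic annotation carries a flat "development" label on a
deterministic `round(n_genes * fraction)` of genes (default 3568/17 770 ≈
20.08%), with an optional bias that places development genes inside focal
windows — the planted-truth hook for power experiments.

## Validation experiments and problem sizes

`skyscan.experiments` packages the self-checks; the test suite and
`scripts/acceptance.py` run them at these sizes:

* simulator calibration: 10 000 single-deme windows against `E[pi]=4Nmu`
  and Watterson's `E[S]` (3 Monte-Carlo SE), Fst monotone over split
  times {500, 2206, 8000} at 2000 windows each;
* outlier scan: cutoff from 200 replicates × 500 windows, false-positive
  rate over 200 neutral genomes × 500 windows (band 5% ± 2%), sensitivity
  on 10 genomes × 10 planted windows at shrink 0.05;
* demographic recovery: 20 seeds per model, 2000 windows (100 Mb, larger
  than the study's 76 Mb fitting region), ~40 000 simulations per
  estimation loop with 300 000-simulation final evaluations; success =
  `N_anc` and `T_split` both within 25%;
* AIC selection: 3 seeds per generating model, all four candidates fit
  per dataset with a shared final-evaluation stream;
* enrichment: 200 random-region genomes for the false-verdict rate (≤7%
  at the strict 95th percentile), 10 planted genomes for power (≥90%),
  B = 2000 draws inside the bulk experiments, 10 000 in the pipeline
  default.

The acceptance script runs the same experiments at somewhat smaller
replication (6 recovery seeds, 3 AIC seeds, 50 calibration genomes) and
prints each number it computes.
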