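# Methods

`minecoast` asks a single scientific question: when a predominantly coastal
plant shows up in several isolated, heavy-metal–contaminated mine sites,
did it colonize the mine habitat once and spread, or many times
independently from the nearest coast?  The package implements the
population-genetic machinery needed to answer it from SNP data and from
forward simulations: a Wright–Fisher colonization simulator with an
isolation-by-distance (IBD) contrast that discriminates the two histories,
plus the supporting estimators (Weir–Cockerham F<sub>ST</sub>, nucleotide
diversity, windowed Tajima's D, LD pruning, f4 quartet tests with block
jackknife, F<sub>ST</sub>-outlier scans and exact multi-set overlap tests)
and a synthetic-data generator with known truth.

## The colonization simulator (`wfsim`)

Diploid, hermaphroditic Wright–Fisher demes with non-overlapping
generations.  A single chromosome of L = 50,000 bp evolves under infinite
sites (derived alleles at unique positions; collisions with currently
tracked positions are redrawn) with mutation rate μ = 7.5 × 10⁻⁹ /bp/gen
and recombination rate r = 4.0 × 10⁻⁹ /bp/gen.  Migration is backward:
each offspring first picks its parental deme (probability m per
neighbouring deme, remainder local), then two parents uniformly with
replacement from that deme — selfing is allowed, so a gamete's base
haplotype is simply a uniform draw over the parental deme's haplotypes.
Each gamete receives Poisson(r·(L−1)) crossovers at uniform breakpoints
and Poisson(μ·L) new mutations.

The demography, as data (an `EventSchedule` of found / resize /
set-migration / remove / sample events):

| stage | parameters |
|---|---|
| burn-in | one deme, N = 10,000, 100,000 generations (mutation–drift equilibrium; θL = 4Nμ L = 15) |
| coastal chain | p1, p2 founded from the ancestral deme with 500 individuals each at the end of burn-in (ancestral deme removed); p3 from p2 and p4 from p3 every 20 generations; every coastal deme grows to 1,000 ten generations after founding |
| coastal migration | stepping stone, adjacent demes only: p1↔p2 10⁻⁵, p2↔p3 and p3↔p4 10⁻⁴ /gen; each edge activates one generation after both demes exist |
| mines | 10,000 generations after the coastal chain completes, m1…m4 founded with 100 individuals each — `multiple_origin`: mk from pk; `single_origin`: all four from one coastal deme drawn uniformly per replicate.  mk↔pk migration 2 × 10⁻⁴ thereafter; mines stay at 100 individuals |
| sampling | 100 generations after mine founding: pairwise F<sub>ST</sub> among all 28 deme pairs, computed with the same Weir–Cockerham estimator used for empirical data, on the full census |

Integer rescaling by Q divides all sizes and durations by Q and
multiplies all per-generation rates by Q, preserving 4Nμ, 4Nr, Nm and
t/N exactly; Q must divide every size and duration.  Experiments and the
CLI default to the desk-scale Q = 10 (≈3 s per replicate on one CPU);
Q = 1 is supported but ~100× slower.  Replicates derive independent seeds
from the experiment seed via `numpy` `SeedSequence` spawning and are
bit-reproducible.

Implementation notes: haplotypes live in a dense uint8 matrix over the
currently segregating positions; transmission is a vectorized row gather
with rare recombinant gametes fixed up individually; columns lost or
fixed across all living haplotypes are dropped (their positions become
available to new mutations again — a negligible infinite-sites violation
at θL = 15) every 8 generations.  The engine is validated against neutral
theory: single-deme pairwise diversity matches 4Nμ and a clean two-deme
split matches E[F<sub>ST</sub>] = 1 − e^(−t/2N) within Monte-Carlo error
(see `tests/test_wfsim.py` and the acceptance suite).

## The IBD contrast (`ibd`)

Within each habitat class (mine–mine, coast–coast), pairwise
F<sub>ST</sub> is regressed on pairwise distance; the scenario contrast is
a paired two-sided t-test of the per-replicate difference in slope (and,
separately, intercept) between the classes.  Simulated distance is the
chain-step count |i − j| between deme positions on the p1–p4 line, mines
inheriting their geographically matched coastal deme's position (a
−log₁₀ effective-migration metric is available; any monotone remap of the
chain gives the same contrast direction).  Observed data use haversine km
on a sphere of radius 6,371.0088 km.

**Why the simulated slopes are computed on FST/(1−FST).**  A mine deme is
its source coastal deme plus a severe bottleneck (100 individuals for 100
generations, drift F_b = 1 − e^(−t/2N) ≈ 0.39).  Heterozygosity algebra
gives F_mine-pair = 1 − (1 − F_b)(1 − F_coast-pair): on the raw
F<sub>ST</sub> scale, mine differentiation is an affine *compression* of
the source pattern toward 1, so the raw mine slope is always ≈(1 − F_b)
times the coastal slope — shallower, regardless of how strong the
inherited geographic signal is.  The standard IBD linearization
F<sub>ST</sub>/(1 − F<sub>ST</sub>) (Rousset 1997) inverts exactly this
compression: on the linearized scale the mine slope is the coastal slope
*divided* by (1 − F_b) — steeper, with a higher intercept — whenever the
mines inherit their sources' differentiation (multiple origins), and the
mine line is flat at the bottleneck level (lower intercept) when all
mines share one source.  The contrast between the two scenarios, which is
what the test consumes, therefore flips sign between the scenarios only on
the linearized scale.

Two numerical guards follow from the small mutation supply (θL = 15, only
~50–150 segregating sites per replicate): F<sub>ST</sub> can saturate at
exactly 1 (zero within-habitat diversity at the informative sites), where
the odds are infinite, so values are capped at 0.99 before linearizing;
and the per-replicate slope uses the Theil–Sen median of pairwise slopes,
whose bounded influence keeps one or two saturated pairs from dominating
(in odds space OLS slope noise is strongly heavy-tailed).  Observed
datasets (tens of thousands of SNPs, moderate F<sub>ST</sub>) do not
saturate, and `observed_ibd` uses plain OLS on raw F<sub>ST</sub>, the
conventional presentation for field data.  Both the transform and the
estimator are arguments of `ibd_regression`/`scenario_contrast`.

The power of the slope contrast at desk scale is limited by the modest
mutation supply — the per-replicate slope is noisy, and the paired test's
strength fluctuates between experiments; the direction of the contrast
(mine steeper under multiple origins, reversed under a single origin) and
the intercept contrast are its stable features.

## Estimators (`popgen`)

* **Weir & Cockerham (1984) F<sub>ST</sub>** — the two-allele, two-
  population variance components a (among populations), b (among
  individuals within populations) and c (within individuals), requiring
  at least two genotyped individuals per population at a site; sites
  monomorphic across the pair are flagged undefined and excluded from
  both sums.  The multilocus estimate is the ratio of sums Σa/Σ(a+b+c);
  per-site values a/(a+b+c) are reported unclamped (small negatives are a
  property of the estimator and retain their rank information).  The
  implementation is verified against an independent ANOVA mean-squares
  formulation and a hand-evaluated table.
* **Nucleotide diversity** — per variant site: the unbiased pairwise
  difference (n/(n−1))·2p̂(1−p̂) with n allele copies, averaged over the
  SNP panel's sites (sites monomorphic within the focal population
  contribute zero; sites monomorphic across the whole panel are not part
  of a SNP panel and raise).  Reported per variant site, not per bp,
  matching the magnitudes RAD pipelines print.
* **Tajima's D** — non-overlapping 20 kb windows, half-open
  [start, start+20000) anchored at position 1 per scaffold, the standard
  a₁…e₂ constants, and n fixed at 2 × (population size) by skipping sites
  with missing genotypes in the focal population.  D is undefined (NaN)
  for S = 0, n < 4 or a non-positive variance; cross-population means use
  only windows defined in every population.
* **LD pruning** — MAF filter first (default 0.05), then a greedy scan in
  genome order dropping the later site of any pair with genotypic
  r² > 0.1 against the previous 50 retained sites on the same scaffold.
* **t-tests** — Welch (with the Welch–Satterthwaite df) and paired t,
  two-sided; both-degenerate-zero-variance inputs return p = 1 on equal
  means and p = 0 (flagged) otherwise.

## f4 quartet tests (`f4`)

f4((A,B),(C,D)) is the plain mean over usable sites of
(p_A − p_B)(p_C − p_D) (no small-sample correction is needed for f4,
unlike f2/f3).  Standard errors use a delete-one block jackknife over
contiguous SNP blocks (default 500 SNPs; SNP-count blocks because RAD
sites are sparse and unevenly spaced), with the weighted variance formula
that reduces to the classic equal-block expression; z = f4/SE.  For every
4-subset of populations all three arrangements are computed; the
arrangement consistent with the user-supplied Newick reference topology
(chosen by the four-point condition on path edge counts) is flagged as
the tested tree.  Quartets are typed by mine/coast composition
(1 = four coast, 2 = four mine, 3 = three coast + one mine, 4 = three
mine + one coast, 5 = two + two with same-habitat sisters, 6 = two + two
with mixed cherries — the 5/6 assignment is this package's convention).
The significance threshold is the two-sided Dunn–Bonferroni normal
quantile for the whole family of computed statistics — 3 × C(8,4) = 210
tests for eight populations, giving z = 3.67.

## Outlier scan and overlap tests (`outliers`)

Per mine–coast comparison, outlier SNPs are those with per-site
F<sub>ST</sub> at or above the 95th percentile (linear-interpolation
definition, ties included) of defined values; outlier scaffolds carry ≥1
outlier SNP.  Overlaps across comparisons are reported in exclusive
(upset-style, partitioning the union) counts, while significance uses
inclusive intersections: the exact distribution of the intersection size
of m independent, uniformly drawn fixed-size subsets of a common
universe, computed by iterated hypergeometric compounding in log space
(the log₁₀ p stays exact when the linear p underflows; for m = 2 the
distribution is exactly the Fisher/hypergeometric tail).  The background
universe is the set of SNPs (or scaffolds bearing ≥1 tested SNP) tested
in *every* compared set, and the outlier sets are intersected with it, so
the fixed-size sampling model holds exactly.

## Synthetic data (`synth`)

Hierarchical Balding–Nichols frequencies: ancestral p ~ Uniform(0.05,
0.95); a regional draw with drift intensity F_region = 0.01; a population
draw with F_habitat = 0.242; mines take one extra step with intensity
1 − mine_diversity_factor (default factor 0.733), which multiplies their
expected heterozygosity by exactly that factor.  Genotypes are
Binomial(2, p) within populations (Hardy–Weinberg), 27 individuals per
population by default, 20,000 SNPs placed on 2,000 scaffolds with
log-normal lengths.  The defaults target pair-class Weir–Cockerham
F<sub>ST</sub> of 0.25 (coast–coast, cross-region), 0.45 (mine–mine) and
0.34 (local mine–coast): under a hierarchical model the within-region
mine–coast value is bounded by the average of the other two, so the
headline trio 0.25/0.36/0.45 cannot be hit simultaneously; 0.34 is the
closest attainable value and the hierarchy ordering is preserved.

Planted outliers model divergent selection: at selected SNPs the mine
frequency moves toward the allele opposite the local coastal frequency
with weight 0.95 and the coastal frequency moves the other way (a
mine-only mode exists, but drift alone produces near-fixed differences —
the null 95th percentile sits near 0.77 — so one-sided shifts do not
separate reliably from the null tail).  Admixture edges replace the
recipient's frequencies with the (1−f)/f mixture after planting.
Population coordinates reproduce the study system's geography: four
regions across Great Britain and Ireland with local mine–coast pairs
16.1/14.8/25.6/26.8 km apart.

What the generator does *not* emulate: linkage disequilibrium within
scaffolds (sites are exchangeable given their frequencies), genotyping
error/allele dropout, and any site-frequency-spectrum shape beyond the
Balding–Nichols family — so passing tests demonstrate the estimators and
the overlap machinery, not robustness to RAD artefacts.

## Problem sizes and runtime

The test suite and the acceptance script run the scenario experiments at
Q = 10 with 100 replicates per scenario (≈5 min per scenario on one CPU),
the neutral-diversity check at N = 500 for 5,000 generations × 30
replicates, generator calibration at 8,000 SNPs × 5 seeds, and the
planted-overlap check at 4,000 SNPs × 5 seeds.

## Known limitations

* The simulator records no tree sequence and supports neither selection
  nor non-WF reproduction; it is purpose-built for the neutral
  colonization scenarios.
* Infinite sites is approximated on an integer lattice of L positions
  with redraw-on-collision; positions of lost/fixed mutations are reused.
* The multi-set test assumes outlier sets are uniform random subsets of
  the background under the null; clustered SNPs on a scaffold violate
  independence at the SNP level (the scaffold level is the primary unit,
  as in the study design this mirrors).
* `mine_coast_gap` and the other durations are interpreted in unscaled
  generations and must be divisible by Q.
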