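# Methods

`pbtkit` implements parentage-based tagging (PBT) analytics for hatchery
salmonid broodstock: every adult spawned at a hatchery is genotyped at a
small SNP panel, so any returning fish whose parents were broodstock can
be assigned to them genetically, which tags it with a birth cohort and a
program of origin without physical marks. Around that core the package
provides the supporting stages a PBT study needs — QC, genotype-identity
resolution, marker diagnostics, population-genetic summaries and
life-history tables — plus a forward simulator that generates full
multi-hatchery datasets with known truth.

## Data model

Genotypes are diploid calls at biallelic SNPs, coded 0/1/2 by the count
of the alternate allele, with 3 for a missing call. On disk a genotype
table has two allele columns per locus (`<locus>`, `<locus>_1`, missing =
`"0"` in both), the common two-column SNP-table layout. Sample metadata
carry program, spawn date, phenotypic sex, genetic sex (from a Y-linked
marker), fork length and adipose-fin status. Spawn *seasons* straddle the
calendar boundary (December–March); a date is labelled with the calendar
year of the season's January, with a configurable July 1 boundary.

Two special loci never enter the autosomal analysis panel: the Y-linked
sex marker, and a marker indexing the chromosome-5 inversion complex of
*O. mykiss* (ancestral A vs rearranged R arrangements; diploid states
AA/AR/RR), which is kept for karyotype summaries.

## QC

* Loci not genotyped in every study year are dropped from analysis.
* For re-genotyped samples the most complete row is kept (ties to the
  latest-loaded row, logged).
* Samples missing more than 10% of panel loci are removed; the rule is
  applied in whole loci, so with a 92-locus panel 82 calls are retained
  and 81 are not.
* Sex is resolved from the genetic marker when called, otherwise from the
  phenotypic record; samples with neither are removed. Conflicts resolve
  toward the genetic marker — it is the more objective datum — and are
  logged, since recorded-sex errors are exactly what the unconstrained
  parentage run is designed to absorb.

Every removal is itemized and the identity `input = retained + removed`
is asserted.

## Identity resolution

A fish spawned repeatedly (within a season, or iteroparously across
seasons) is sampled once per event under different sample ids. Sample
pairs are compared by unordered genotype agreement over loci called in
both; pairs with agreement ≥ 0.95 over ≥ 60 co-called loci become edges,
and connected components of the edge graph are individuals. The component
rule handles fish sampled up to many times transitively. The canonical
sample (fewest missing calls, ties lexicographic) names the fish and
supplies its working genotype. Clusters whose members disagree on
resolved sex, or contain two samples called as *opposite homozygotes* at
any locus (a mix-up signature that genotyping error cannot plausibly
produce), are removed.

A property worth stating plainly: with a per-gene-copy error rate ε, two
observations of the same fish disagree at a locus with probability ≈ 4ε
(each observation is wrong with probability ≈ 2ε). At ε = 0.005 and ~90
co-called loci the pair mismatch count is approximately Poisson(1.8), so
roughly 3–6% of same-fish pairs fall below the 0.95 threshold and a
two-sample fish then splits into two singletons. Threshold identity
matching therefore guarantees *no false merges* at panel sizes like this
(unrelated fish, and even full sibs, agree at far lower rates), but its
recall is bounded by that binomial tail; perfect recall would require
either a lower realized error rate (typical assays are well below 0.5%
per copy) or a relaxed threshold. The simulator's default ε is kept at
0.005 — the conservative value used for assignment — so recovery tests
measure recall under that conservative error model honestly.

## Parentage

### Trio likelihood

For offspring observation $o$ and candidate parents $m, f$ at locus $\ell$
with alternate-allele frequency $q_\ell$:

$$L_{\mathrm{par},\ell} = \sum_{g_m,g_f,g_o} P_{\mathrm{HWE}}(g_m)\,
P_{\mathrm{HWE}}(g_f)\, T(g_o \mid g_m, g_f)\, E(o_m \mid g_m)\,
E(o_f \mid g_f)\, E(o_o \mid g_o)$$

where $T$ is Mendelian transmission and $E$ the genotyping-error kernel:
each gene copy is read correctly with probability $1-\varepsilon$ and
flipped with $\varepsilon$, independently (rows sum to one; default
$\varepsilon = 0.005$ per copy, i.e. ≈1% per locus). The unrelated
likelihood replaces $T$ with an independent Hardy–Weinberg draw for
$g_o$. The trio LOD is $\sum_\ell \log_{10} L_{\mathrm{par},\ell} /
L_{\mathrm{unrel},\ell}$ over loci called in all three members
(per-locus complete case); loci where the observed trio admits no
error-free Mendelian phase are additionally flagged incompatible.
Allele frequencies come from pooled adult genotypes by allele counting;
monomorphic loci are excluded from LODs.

All per-locus quantities are precomputed as 4-state lookup tables
(0/1/2/missing), so LODs are table-gather sums.

### Candidate pools and search

Candidate parents for an offspring first spawning in season $y$ are
adults with a spawn event in seasons $y-a$, $a \in [2, 6]$ (the observed
spawning ages), across all programs; both members of a pair must share a
spawn season (they mated). The *constrained* run additionally requires an
identical recorded spawn date and opposite resolved sexes; the
*unconstrained* run ignores sex and date, which lets it recover
assignments broken by metadata recording errors. Iteroparous and repeat
spawners enter the pool of every season they spawned.

Exhaustive pair enumeration is quadratic in pool size, so the engine
first screens single-parent LODs (offspring × adults, computed as one
dense matrix product over one-hot genotype encodings), shortlists the
top K = 10 adults per parent season, and evaluates full trio LODs over
shortlisted pairs. A true parent essentially always carries one of the
highest single-parent LODs at ~90 informative loci, and truth-recovery
tests confirm the shortlist loses nothing at these panel sizes.

The best pair is categorised by the maximum a posteriori relationship
among parent-pair / mother-only / father-only / unrelated with equal
priors (single-parent likelihoods replace the other parent by an
unrelated draw); ties resolve toward the less specific relationship.

### FDR

Each offspring's test statistic is its best pair LOD. The null
distribution of a *single* unrelated pair's LOD is estimated once per fit
by simulating `null_sim_size` trios (default 100,000) at the estimated
allele frequencies with the empirical per-locus missingness. Because an
accepted trio's LOD sits far in the null's tail — beyond plain
Monte-Carlo resolution — the simulation draws half its trios from the
unrelated model and half from the parental model and reweights with
balance-heuristic importance weights $w = 1/(\tfrac12 + \tfrac12 \cdot
10^{\mathrm{LOD}})$, giving an unbiased tail estimate with no $1/n$
floor. The per-offspring p-value is then pool-size adjusted,
$p = 1 - (1-p_{\mathrm{single}})^{|\mathrm{pool}|}$ (independence
approximation, adequate at pool sizes ≥ 100), and Benjamini–Hochberg
across offspring yields q-values. A trio is accepted when its MAP
category is parent-pair and $q \le 0.01$.

### Two-pass marker exclusion and reconciliation

A preliminary constrained run feeds per-marker diagnostics: for each
locus, the fraction of accepted trios with an observed Mendelian
incompatibility, and the minimum per-copy error rate $\hat\varepsilon$
solving $Q(\hat\varepsilon) = $ observed rate, where $Q(\varepsilon)$ —
the probability a true trio at that locus shows an incompatibility when
all six gene copies err independently — is computed by exhaustive
enumeration and inverted by bracketed root finding ($Q$ is continuous and
increasing; rate 0 maps to $\hat\varepsilon=0$). Markers with
incompatibility rates above 2% are excluded, and the final constrained
and unconstrained runs use the reduced panel.

The two final runs are reconciled: identical accepted trios →
`both_runs`; accepted only unconstrained → `unconstrained_only`, tagged a
presumed metadata error; conflicting accepted pairs → the lower-q trio
(tie to constrained), `constrained_preferred`; accepted only constrained
→ `constrained_only`. The choice of the lower-q trio in conflicts is this
package's rule for a step that is otherwise under-determined. Residual
trios with both parents of one genetic sex, a parent-offspring season gap
below the minimum age, or a self-parent are removed with reasons. The
accounting identity (final = sum of provenance categories; removals
itemized) is asserted on every run.

## Population genetics

* **Heterozygosity**: observed fraction, and Nei's unbiased expectation
  $2\hat p\hat q \cdot 2N/(2N-1)$, averaged over loci.
* **Exact HWE**: the Levene–Haldane conditional distribution of the
  heterozygote count given allele counts; two-sided p sums $P(h)$ over
  all $h$ with $P(h) \le P(h_{\mathrm{obs}})$ (the "selome" convention,
  which reproduces published values for this system). The
  heterozygote-excess statistic is half the deviation from expectation,
  $D = (n_{AB} - 2\hat p\hat q N)/2$.
* **F_ST**: Weir–Cockerham (1984) variance components; multilocus
  $\hat\theta$ as a ratio of sums. A seeded utility subsamples equal
  numbers of broodstock per program (default 300) for replicated
  interannual / interprogram comparisons.
* **PCA**: 0/1/2 coding, mean imputation of missing calls, column
  centring, SVD scores; component signs fixed deterministically.

## Life history

From clusters and the pedigree: spawning-use classification (once /
repeat within a season / iteroparous across seasons; a fish with both
patterns carries the combined label and counts as iteroparous in the
use-exclusive table), age at spawning (offspring season minus parent
season — both parents share it by construction), spawn-date bins
(half-open 5- or 10-day bins anchored per program-season), straying
matrices (origin = parents' program; column percentages), observed
reproductive success by sex and use type (zero-offspring fish contribute
zeros), inversion-karyotype frequency tables with per-program exact HWE,
and a 1:2:1 segregation test for offspring of AR × AR matings
(chi-square, df 2; an exact multinomial substitute when any expected
cell is below 5). Kruskal–Wallis rank tests (tie-corrected, chi-square
reference) serve the ordinal group comparisons.

## Simulator

The forward simulator emulates the spawning ecology the analysis
assumes, not a full demographic model:

* **Genetics**: ancestral frequencies uniform on [0.2, 0.8] at 92
  autosomal loci; two lineages diverge by the Balding–Nichols model
  (Beta$(p(1-F)/F, (1-p)(1-F)/F)$) with $F$ = `lineage_fst` (default
  0.1, matching a clearly distinct coastal-vs-valley pair). The sex
  marker is transmitted as X/Y; the inversion marker is inherited like
  any locus but with lineage-specific R frequency (0.08 valley, 0.20
  coastal) and an optional odds multiplier on age-2 return per R copy
  (2.0 in the coastal lineage, reflecting the faster-development
  association of the rearranged haplotype).
* **Demography**: four programs (two large ones mating each female with
  a single male; two small ones dividing each female's eggs between two
  males), 200 spawners per program-year by default over 9 seasons
  (2011–2019). Spawning happens on 5-day operating days, so a female and
  her male(s) share a recorded date. Returning-offspring counts per pair
  are negative-binomial (mean 1.0, dispersion 0.5 — overdispersed family
  sizes stress the assignment ranking). Ages at return 2–6 with
  lineage- and sex-specific distributions (valley fish mostly age 2,
  coastal mostly age 3); strays re-route per a row-stochastic matrix
  (default 97% home); iteroparous fish (female-biased in the valley
  lineage) re-enter the next season; repeat spawners (male-biased)
  spawn twice within a season. Founder fish top up each program-year to
  its target, representing broodstock whose parents predate the study.
* **Observation**: one sample row per spawn event; each gene copy flips
  with ε = 0.005; calls go missing at 2% (3% in the acceptance
  conditions); phenotypic sex and spawn date carry rare recording errors
  (0.2% each); lengths are age-dependent normals for metadata
  completeness only. The genetic-sex column always reflects the true sex
  up to genotyping error.

What the simulator does *not* model: environmental forcing, growth,
selection at the inversion beyond the age-at-return weighting,
program-size trends, or linkage between loci. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated error model, not robustness to ecological misspecification.

All randomness flows from a single integer seed through one generator;
emitted tables record the seed in a header comment, and every pipeline
stage is deterministic given config and seed.

## Problem sizes and defaults

Tests and acceptance checks run the full pipeline at 4 programs × 200
spawners × 6 seasons (≈5,400 samples, ≈2,200 assignable offspring) over
20 simulation seeds, with `null_sim_size` 20,000 for the null tail
(resolution far beyond the q = 0.01 decision point once importance
weighting is applied); the library default of 100,000 is comfortable for
one-off analyses. Smaller two-program configurations back the unit
tests.

## Known limitations

* The FDR pool-size adjustment treats pool pairs as independent; at very
  small pools (tens of pairs) it is conservative.
* The top-K single-parent screen is a heuristic accelerator; K = 10 is
  validated by simulation at ~90 informative loci and should be raised
  for much smaller panels.
* Identity recall at the 0.95 genotype-identity threshold is bounded by
  the same-fish mismatch tail described above; the module reports splits
  it cannot see, so downstream iteroparity counts are slight
  undercounts when the realized error rate approaches 0.005/copy.
* Single-parent (mother-only / father-only) assignments are categorised
  but not emitted as pedigree links.
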