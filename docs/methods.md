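# Methods

`rarecnv` implements the statistical pipeline used to prioritize rare copy
number variants (CNVs) in a case-control/trio cohort of a severe,
heritable phenotype — concretely, idiopathic short stature: ~200 affected
children (height SDS below −2) plus their parents, screened against ~800
population controls, with roughly 30 array-derived CNV calls per genome.
This note records the models, the parameters that matter, and the choices
made where the design was genuinely open.

## Filtering cascade

Raw calls pass five ordered stages; each removed call records its first
failing stage so the funnel counts are monotone.

1. **Calling prefilter.** Size ≥ 10 kb, marker support ≥ 5, Y chromosome
   excluded (array calling there is unreliable).
2. **Candidate floor.** Size ≥ 50 kb, the resolution at which independent
   validation (MLPA) is dependable. The floor is inclusive: a 50.0 kb call
   is kept. Configurable.
3. **Polymorphism exclusion.** A patient call matched by same-type control
   calls covering *more than* 95% of the patient call in *more than* 15
   distinct control samples (~2% of 820) is a common polymorphism. The
   overlap fraction is computed relative to the query call — removing
   patient calls common in controls is a statement about the patient call —
   with a reciprocal mode behind `FilterConfig.reciprocal`. Matching is
   always same-type: gains and losses are separate mutational events.
4. **Gene-coverage exclusion.** A call below the 95% criterion whose
   overlapped genes are *each* fully contained (gene span ⊆ control call)
   in calls of *at least* 15 distinct control samples is removed: its gene
   dosage content is common even if its exact breakpoints are not. A
   gene-free call returns false here — it is handled by the next stage,
   and letting the vacuous case trigger removal would double-count
   exclusion reasons.
5. **Exonic filter.** Calls touching no exon (intronic/intergenic only)
   are removed from the gene-centric analysis.

Carrier counting is backed by per-(chromosome, type) interval trees and is
tested for equality against a quadratic double-loop oracle.

## Size burden

The unit of counting is the CNV call (a per-sample mode is available). For
each threshold t of a log-spaced grid (default 50–1000 kb, 200 points) the
2×2 table of calls > t vs ≤ t by group gives a sample odds ratio
a·d/(b·c) and a two-sided Fisher exact p. The selected threshold minimizes
p (ties → smaller t); it is flagged significant only against 0.05
Bonferroni-corrected for the grid size, and the full curve is exported so
other selection criteria can be applied. Quintile borders are the
20/40/60/80/100th percentiles of the pooled size distribution under linear
interpolation between order statistics (configurable in principle; the
original study's borders cannot be recomputed without its raw calls), with
right-closed bins and per-bin in/out Fisher tests.

## Segregation and de novo enrichment

A child call matches a parent when a same-type parental call covers ≥ 50%
of the child interval. This match fraction is deliberately looser than the
0.95 population-frequency criterion: breakpoint estimates jitter between
arrays and MLPA, and parental confirmation is often a single probe. No
match in either parent → de novo; a match in an affected parent →
inherited from the affected parent (an affected match wins when both
parents match); a match only in an unaffected parent flags the call for
exclusion. Missing parental data yields `unresolved`, not an error.

De novo excess is tested against a population rate of 6×10⁻³ de novo CNVs
per haploid genome per generation (2 haploid genomes per patient; 200
patients ⇒ expectation 2.4). The default test is the Poisson upper tail
(P(X ≥ 7 | μ = 2.4) = 0.0116); a binomial tail and a Fisher test of
observed-vs-expected counts are exposed as alternatives, since the exact
2×2 construction behind published versions of this comparison is usually
unstated.

MLPA relative quantities classify as deletion < 0.75 and duplication
> 1.25, boundaries reading as normal (the thresholds are strict); the
noiseless expectation is copy state / 2.

## Pseudomarker association

Markers sit at the distinct endpoints of all segments (cases + controls
pooled); a sample carries a marker iff a same-type call's half-open
interval contains the position (start in, end out). The statistic is the
Pearson χ² on the carrier×group 2×2 without continuity correction; the
permutation p uses the +1 correction, p = (1 + #{χ²_perm ≥ χ²_obs}) /
(1 + n_perm), and therefore never returns 0. One permutation set is shared
across markers by default (faster, preserves the between-marker
correlation of a single cohort relabeling); per-marker independent
permutations and exhaustive enumeration (exact, for ≤ ~16 samples) are
selectable. Default n_perm 10,000, seed required. Gains and losses are
separate families; Bonferroni applies over the union of tested markers.

## GWAS-locus overlap

n_tests counts SNPs inside the union of candidate intervals (joint
counting — with 36,316 SNPs this reproduces the printed 1.377×10⁻⁶ bound
at α = 0.05); per-CNV significance compares the minimum contained SNP p
against α/n_tests, and a conventional genome-wide CNV bound of
0.05/2000 = 2.5×10⁻⁵ is also reported. Enrichment of
significant-locus-containing CNVs is a Monte-Carlo null of our own design
(the quantity is rarely given a method in publications): each draw
re-places the size-matched intervals uniformly on the genome (chromosome
chosen proportional to the space that fits the interval) and re-counts;
+1-corrected p.

## Expression concordance

Per gene inside a candidate CNV, carriers vs non-carriers are compared by
one-way ANOVA (for two groups, F = t² exactly; checked numerically). Fold
changes use the signed-reciprocal convention on anti-logged group means:
+1.25 minimum for up-regulation in gains, −1.33 for down-regulation in
losses, per-gene α = 0.05 uncorrected. The cohort-level excess of
concordant genes is tested as P(X ≥ k) under Binomial(n, 0.025): the null
concordance probability is α × ½ because only one direction counts per
gene; it is a parameter (`null_concordance_p`) and is echoed in the
output. Genes with fewer than two carriers or two comparison samples are
reported untestable (NaN) rather than erroring — single-carrier genes are
the norm for rare CNVs.

## Candidate rule and report

A CNV is a candidate iff its segregation supports pathogenicity (de novo,
or inherited from the likewise affected parent) AND at least one line of
gene evidence holds: a known human growth gene, a murine growth-phenotype
knockout, a functional candidate gene, or a patient-database imbalance
annotated with the phenotype. Syndrome-region overlap and the
haploinsufficiency count (genes with HI percentile < 10) are reported but
do not gate the rule, which is monotone in the evidence flags. Evidence
flags are consumed from the gene annotation file; the pipeline does not
query OMIM/MGI/Decipher-style databases itself. Cohort summaries (group
n, sex, mean height SDS, mean size, phenotype splits) are computed at
full precision and rounded only for display. The carrier-vs-rest height
comparison is a two-sided rank-sum test, exact by enumeration for
combined n ≤ 20 without ties, normal approximation with tie correction
otherwise.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with explicit
seeds everywhere and byte-identical reruns:

- **Background calls.** Per-sample counts Poisson (mean 32); sizes
  log-normal in kb, truncated below at the 10 kb calling floor. Default
  log-mean 4.8 and log-sd 0.85 put the quintile borders of the pooled
  distribution near 68/99/150/298 kb — the regime reported for real
  array calls of this design. The true size law of array calls is
  unknown; log-normal is a modelling choice with the right heavy tail.
- **Polymorphic pool.** A fixed set of loci (sizes ≥ 50 kb so they reach
  the frequency filter) carried independently by cases and controls at
  rate 0.05 — ~41 of 820 controls, safely above the >15 exclusion bound.
- **Pathogenic spikes.** 10% of cases receive one spiked CNV centred on a
  random gene (log-normal sizes, median ~1 Mb, floor 100 kb — the
  ~0.1–14 Mb range of real candidates), absent from all controls; 35%
  are de novo (absent from both parents), the rest copied into one
  parent who is then flagged affected (height drawn short). Genes
  contained in a spike are dosage sensitive.
- **Burden signal.** `case_size_shift` multiplies case call sizes
  (default 1 = null); `case_excess_rate` gives each case call above
  100 kb that probability of spawning an extra tail call, injecting an
  excess of large calls whose threshold-scan recovery point is the
  100 kb boundary itself.
- **Expression.** Gene baselines N(8, 1) log2 units, noise SD 0.3;
  carriers of dosage-sensitive genes shift by +log2(1.5) (gain, one
  extra copy on two) or −1 (loss, one copy lost of two).
- **SNP tracks.** Uniform background p-values; each signal locus gets one
  SNP at its midpoint below the requested level.
- **MLPA.** Ratio = copy state / 2 + N(0, 0.05).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-level intensity noise and wave artefacts,
breakpoint estimation error, segmental-duplication hotspots and
recurrence, LD among SNPs, batch effects in expression, and population
stratification. Results on synthetic cohorts validate the statistical
machinery, not array QC.

## Numerical choices and problem sizes

Fisher p-values are the two-sided sum of hypergeometric probabilities at
most the observed table's (tested against full enumeration for all
tables with margins ≤ 12); binomial/Poisson tails use stable survival
functions (tested against log-space summation). Degenerate association
markers (all or no carriers) report p = 1 and are flagged. The null
calibration of the threshold scan tolerates the discreteness of Fisher
p-values (no midpoint correction is applied).

The shipped test suite exercises the cascade and burden properties at the
study's own scale (200 cases / 820 controls, 20 cascade replicates, 100
null + 50 signal scan replicates) and completes in about five minutes on
one CPU; smaller toy cohorts back the unit tests.

## Known limitations

Single-trio segregation only (no extended pedigrees); no paternity checks;
no higher copy states than 3; no sex chromosomes; no VCF symbolic-allele
I/O; the enrichment null ignores assembly gaps unless chromosome lengths
are adjusted by the caller.
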