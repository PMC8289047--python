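# Methods

`altiscan` re-implements, as a tested library, the population-genomic
inference chain used to study a recent highland colonization by a small
passerine: a structured-coalescent simulator, demographic model choice from
the folded joint site-frequency spectrum (SFS), a simulation-calibrated
FST / diversity-ratio divergence scan, an adaptive-allele dosage statistic,
and a phenotype-PC x expression correlation stage.  This note records the
models, the numerical choices, and the places where the design was genuinely
open.

## Coalescent simulator

The simulator draws genealogies from the continuous-time structured
coalescent on a piecewise-constant demography.  Within a deme of diploid
size `N`, each pair of lineages coalesces at rate `1/(2N)` per generation;
migration moves single lineages between demes; at the split time all
lineages merge into the ancestral deme.  Size changes are instantaneous
steps.  There is no recombination within a locus and no selection: the
"spiked" divergent sites used as scan positive controls are frequency-based
constructs, not sweep simulations.

Migration is parameterized as the expected number of migrant lineages per
generation entering the recipient deme (`Nm` units); the backward
per-lineage trace rate is `Nm / N_recipient`.  A per-generation *fraction*
of 0.08 would homogenize two demes within tens of generations and is
incompatible with the weak differentiation (mean FST about 0.026) the
demography is meant to reproduce, so the migrant-number reading is used.

Mutations follow the infinite-sites model: Poisson counts with mean
`mu * L * total branch length`, placed uniformly on branches.  Two
granularities are offered:

* **unlinked sites** — one genealogy per segregating site.  Because longer
  genealogies carry more mutations, a segregating site's genealogy is
  length-biased; sites are therefore drawn in two passes (a pool of
  genealogies scored by total length, then resampling proportional to
  length).  Ignoring this bias shifts the SFS by several percent, enough to
  corrupt demographic fits.
* **linked loci** — one genealogy per 50-kb locus with Poisson mutations,
  used for windowed statistics and the scan null, where intra-window
  linkage matters.

Default demography: highland size 85 058, split 2 598 generations ago,
0.08 migrants per generation from lowland into highland, mutation rate
3.3e-9 per site per generation, one-year generations.  The lowland and
ancestral sizes are not identified by published point estimates; the
default 350 000 puts neutral diversity `4*N*mu` on the 1e-3 per-site scale
typical of abundant passerines, and both are ordinary config parameters.

The expected SFS is computed by branch-length weighting: each replicate
genealogy contributes every branch to the SFS cell of its descendant
configuration, weighted by branch length — a Rao-Blackwellised average over
mutation placement, so 10 000 genealogy replicates resolve the spectrum far
better than 10 000 single-site draws.  Replicate `r` re-seeds the kernel at
`seed + r`, giving common random numbers (CRN): the same genealogy stream is
reused across parameter values, so likelihood *differences* between nearby
parameter points are far less noisy than the likelihoods themselves.

All kernels are numba-compiled; an independent coalescent implementation
(msprime) is used in the test suite as a cross-validation oracle for the
folded SFS, never as the engine.

## Demographic inference

Eight models are supported: constant single population (M1), single
population with a size step (M2), a split with lowland-to-highland (M3),
highland-to-lowland (M4) or bidirectional (M5) gene flow, and the same three
with founder-size changes in both daughter demes (M6-M8).

The fit maximizes a multinomial composite log-likelihood conditional on
segregating sites, `sum(obs_cell * log(expected_proportion))`, with expected
proportions floored at 1e-8.  Optimization is
expectation-conditional-maximization (ECM): bounded 1-D Brent maximizations
cycling over parameters, stopping after a configurable minimum number of
cycles (default 20, maximum 80) once a full cycle gains less than 0.01
log-units.

Four numerical devices make noisy-likelihood ECM reliable; all were adopted
after observing concrete failure modes without them:

1. **Ridge-aligned coordinates.**  The conditional SFS likelihood is nearly
   invariant under a joint rescaling of all sizes and times, so the natural
   parameters form a diagonal ridge that one-parameter-at-a-time moves
   cannot follow.  When the split time is free, daughter-deme sizes are
   optimized as drift amounts `T/(2N)`; a move in `T` then travels along the
   ridge with the strongly identified drift (and migrant-dose) combinations
   held fixed.
2. **Staged restarts.**  The near-isolation optimum has a narrow basin;
   from a high-migration start, plain ECM settles in a broad
   migration-drift-equilibrium basin.  The first restart therefore fits the
   no-migration model before releasing migration; remaining restarts draw
   uniform starts (log-uniform within bounds).
3. **Per-restart polish and out-of-sample evaluation.**  Each restart's
   endpoint is refined with extra ECM cycles at 8x the Monte-Carlo draw
   count, and restarts are compared — and final likelihoods reported — on an
   evaluation stream the optimizer never maximized.  In-sample evaluation
   lets higher-dimensional models climb Monte-Carlo noise and defeat the AIC
   penalty.
4. **Warm-nested starts and projection** (`fit_models`).  A submodel's
   optimum seeds its supermodels, and a supermodel's optimum projected back
   into the submodel space is offered to the submodel.  Without the second
   step a supermodel can outrank its submodel purely through extra
   optimization effort, which AIC would misread as evidence.

Model comparison uses `AIC = 2k - 2 logL` with `k` the number of *free*
parameters; fixed (profiled-out) parameters do not count.  Confidence
intervals come from a parametric bootstrap: fresh SFS replicates simulated
at the point estimates, each refit from a warm start, summarized by
empirical 2.5/97.5 percentiles (flagged low-confidence below 20 successful
replicates).

### Identifiability limits

Two limits of folded-SFS inference shape the interface and are worth
stating plainly:

* **Overall scale.**  Conditional on segregating sites, the SFS shape is
  unchanged when all sizes and times are multiplied by a constant; absolute
  times are identified only once at least one size is pinned (e.g. the
  lowland/ancestral sizes).  An absolute mutation-rate anchor through the
  monomorphic fraction would add almost nothing here: the competing
  parameter combinations differ in expected total branch length by a few
  tenths of a percent.
* **Isolation versus migration.**  A recent clean split and an older split
  with strong gene flow produce folded joint spectra whose composite
  likelihoods differ by only a few log-units at 1e5 SNPs — within fit noise.
  Divergence-time recovery studies in this package therefore hold the
  migration rate at its known simulation value; with migration free, the
  point estimate of `T` can wander along this ridge by several fold while
  the fit remains statistically equivalent.

The recovery checks in the acceptance suite use 100 000 unlinked SNPs for
11 + 12 diploids, 10 000 genealogy replicates per likelihood evaluation,
and three data seeds (a single restart suffices once migration is profiled
out, since the remaining two-parameter surface is unimodal) — sizes chosen
to keep a full recovery run in minutes on one CPU while leaving the
assertions comfortably inside their tolerances.

## Summary statistics

* **FST**: per-site Weir & Cockerham (1984) variance-components estimator
  (`a/(a+b+c)` for two populations), unclamped, with the Hudson
  ratio-of-estimates form as an independent cross-check.  Sites need at
  least two non-missing genotypes per population.
* **Diversity**: per-site unbiased heterozygosity `n/(n-1) * 2p(1-p)`
  summed over fixed non-overlapping windows and divided by window length
  (the published scan used 50-kb "sliding windows" without a stated step;
  non-overlapping windows make the "first 1000 windows" rule well defined
  and are the default).
* **DXY**: `p1(1-p2) + p2(1-p1)` summed per window over window length.
* **Tajima's D**: the 1989 constants; sites with missing genotypes in the
  focal population are excluded so the sample size is constant within a
  window.  Note the neutral expectation of D is slightly negative (about
  -0.05 to -0.1 at these sample sizes), not exactly zero.
* **HWE**: Wigginton-style exact test by enumeration of heterozygote counts
  conditional on allele counts.
* **LD**: squared Pearson correlation of dosage vectors; greedy
  left-to-right pruning drops later sites within 20 kb at r^2 >= 0.5.
* **PCA**: Patterson normalization (center by `2p`, scale by
  `sqrt(p(1-p))`), missing entries zero after centering, deterministic sign
  (largest-magnitude score positive).
* **Folded joint SFS**: keyed by pooled-minor-allele counts per population;
  when the pooled count is exactly half, the lexicographically smaller of
  the two conjugate cells is used.  Sites with any missing genotype are
  excluded (no projection); the filters applied before structure analyses
  (MAF, missingness, HWE, LD pruning) are exposed as a configurable cascade
  and are not applied before the scan by default, matching the reading that
  the published filters belong to the structure analyses.

## The divergence scan

The null calibration simulates neutral data under a fitted (or supplied)
demography: by default 2000 linked 50-kb loci, each a single genealogy
carrying 410 sites — matching the roughly-410-SNPs-per-window scale of the
original genealogy-conditioned null.  The FST cutoff is the 99% empirical
quantile of per-site FST; the diversity-ratio cutoff the 95% quantile of
per-locus `pi_low/pi_high`.  Under the default demography and 11+12
diploids these land near 0.22 and 1.4; the published cutoffs (0.24, 1.06)
depend on unprinted nuisance sizes and can be pinned with
`NullCalibration.override` rather than re-derived.

HD-SNPs ("highly divergent") are sites with FST strictly above the cutoff.
Outlier windows are ranked by HD count (ties broken by genomic order), kept
while the count is at least 13 and at most 1000 windows are taken — both
constants configurable.  The diversity-ratio flag requires
`pi_low/pi_high` strictly above its cutoff; a window with zero highland but
positive lowland diversity is flagged (the most conservative reading of a
highland diversity drop), zero in both is not.  Candidate regions are
windows passing *both* criteria, merged when adjacent; genes overlap by at
least 1 bp under half-open interval arithmetic.  Over-representation of a
gene category among candidates is tested with a df-1 Pearson chi-square
(no continuity correction) plus a two-sided Fisher exact cross-check.

Spiked positive controls mimic a completed highland sweep from standing
variation: the alt allele fixed in highland, still at `1 - delta` in
lowland, so spiked windows both gain FST and lose highland diversity.  A
spike with `delta = 1` (fixed difference) removes diversity in both
populations equally and is deliberately invisible to the ratio criterion.

## Dosage and phenotype-expression stages

At each HD-SNP the highland major allele (frequency > 0.5, missing
genotypes ignored, exact ties dropped) is the high-elevation adaptive
allele; per-individual dosage sums adaptive-allele copies, with missing
genotypes contributing zero and counted separately.  Groups are compared
with a two-sided Welch t-test (pooled-variance optional).  Because HD-SNPs
are ascertained for highland-lowland divergence, highland dosages exceed
lowland dosages by construction; the statistic summarizes separation and is
not, by itself, evidence of selection.

Phenotypes are standardized (units differ by orders of magnitude) before
PCA; constant traits are dropped with a warning.  Expression is correlated
gene-by-gene as Pearson r between `log(TPM + 1)` and the PC1 scores
(Spearman available), with two-sided p from the t transform on n-2 degrees
of freedom, ranking by |r| and selection at raw p < 0.05; a
Benjamini-Hochberg option exists but is off by default to match the
original raw-p selection rule.  Differential-expression calling is upstream
and out of scope — DEG lists arrive as inputs.

## Synthetic data: what it does and does not emulate

The generator reproduces the study's sampling design (11 highland + 12
lowland diploids), its weak differentiation regime, linked 50-kb windows,
small correlated phenotype panels with a dominant axis, and expression
matrices with genes coupled to the phenotype PC at a chosen correlation.
It does **not** model recombination within loci, sequencing error, depth
variation, genotype-calling artifacts, forward selection, or ascertainment
from a real SNP-calling pipeline.  Green tests therefore certify the
statistical machinery under the stated model, not robustness to the
technical noise of real resequencing data.

## Pipeline and reproducibility

`run_pipeline` executes the configured stages in dependency order, writes
every artifact under one directory, and emits a manifest with the config
hash and SHA-256 of each artifact; two runs from the same config and seed
are byte-identical.  Stage seeds derive from the global seed hashed with the
stage name, so any stage can be reproduced in isolation.  Every published
analysis constant is a named config key with that published value as its
default (window 50 000; HD minimum 13; 1000 windows; quantiles 0.99/0.95;
MAF 0.1; missingness 0.10; HWE p 0.01; LD r^2 0.5 within 20 kb; cohort
depth 6 reads x individuals; mu 3.3e-9; one-year generations; 100 bootstrap
replicates; ECM cycles 20-80; alpha 0.05).

## Known limitations

* The conditional-on-S likelihood cannot separate isolation from migration
  at realistic SNP counts (above); treat free-migration time estimates as
  ridge coordinates, not point estimates.
* Monte-Carlo likelihoods make AIC comparisons noisy at small draw counts;
  `fit_models` mitigates but does not eliminate this.
* The HWE filter and exact test assume autosomal diploid sites.
* The scan assumes two populations; no haplotype statistics (iHS/XP-EHH)
  or composite-likelihood sweep scans are provided.
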