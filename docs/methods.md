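# Methods

## Setting

`spaceomics` analyses longitudinal whole-blood RNA profiles from a short
spaceflight mission: four crew members sampled at seven draws — three
pre-flight (days −92, −44, −3 relative to launch), the day after return
(R+1), and three recovery draws (R+45, R+82, R+194). The timepoint
vocabulary is fixed to these seven labels, with an escape hatch (any
`label → signed days` map) because everything downstream only needs signed
days. The package covers four analysis families: pathway co-regulation and
return-day disruption of expression, site-level m6A differential
methylation with recovery reversal, dual-quantifier consensus differential
expression, and cross-crew transcript-catalog uniqueness.

## Expression model

Counts from two quantifiers are averaged per gene on their shared gene
universe, normalized to counts per million (CPM), log-transformed as
log2(CPM+1), and z-scored per gene across all 28 samples. The log transform
stabilizes the strong mean–variance coupling of counts before
standardization; the SD uses the sample (n−1) denominator. Genes with zero
variance are set aside rather than z-scored — they carry no longitudinal
signal and would otherwise produce 0/0 rows.

**Co-regulation score.** For a pathway P with member rows in the z-matrix,

    score(P) = Σ_s m_s²,   m_s = mean_{g∈P} z[g, s].

Because rows are centered, score is near zero when members fluctuate
independently and grows when they move together. Significance comes from a
permutation null of uniform random gene sets of the same size drawn from
the detected-gene universe (restricting the universe to detected genes
avoids a size bias), with p = (1 + #{null ≥ observed}) / (n_perm + 1) and
Benjamini–Hochberg (BH) adjustment across tested pathways. Null sets are
drawn independently per pathway; sharing one batch of permutations across
pathways would correlate their p-values and inflate the variance of the
family-wise rejection rate. Pathways with fewer than `min_size` (default 5)
or more than `max_size` (default 500) detected members are skipped and
reported.

**Trajectories and dz.** A pathway's trajectory is the median z over all
(member gene × subject) values at each timepoint — the pooled reading; a
flag (`average_subjects_first`) instead averages each gene across subjects
before the median. For each pathway, an ordinary least-squares line through
the three pre-flight medians (closed-form normal equations; three points
warrant no weighting) is extrapolated to the return day, and

    dz = z_observed(R+1) − z_predicted(R+1).

Pathways are ranked by signed dz, highest first (most disrupted upward),
ties broken by name; `absolute=True` ranks by |dz|. dz is affine-
equivariant — dz(a·z+b) = a·dz(z) — so the ranking does not depend on the
z-scale's origin. Any post-launch day present in the trajectory can be
scored against the same pre-flight fit (`return_day=45`, say), which is how
"returning to baseline in recovery" claims are examined. dz is computed for
all size-eligible pathways by default, with a flag to restrict to pathways
significant by co-regulation.

**Consensus differential expression.** The two quantifiers differ in how
they assign multi-mapped reads, so their gene-level significance calls
differ even when their abundance estimates agree. A gene counts as
differentially expressed only when both pipelines call it so at FDR < 0.05.
The bundled `simple_de` is a deliberately plain location test on
log2(CPM+1): a paired t-test on subject-blocked differences when every
subject appears in both groups, else Welch's test, with BH adjustment. It
exists so synthetic studies are self-contained; it is not a substitute for
a count-model DE engine on real data. For contrasts pooling several
timepoints per side, each sequencing run is treated as an independent
replicate (unblocked Welch) — with four subjects, the blocked test's three
degrees of freedom leave essentially no power under a BH burden of
hundreds of genes.

## Methylation model

Input is a site table: per candidate site, a 5-mer context, transcript and
gene annotation, and per-sample (coverage, modified-read) counts. Sites are
filtered to ≥ 20× coverage in every sample of the contrast ("minimum 20×"
read as ≥, applied per sample: one under-covered sample makes a pooled
group fraction unreliable). m6A occurs in the DRACH consensus (D=A/G/U,
R=A/G, A, C, H=A/C/U; T≡U — exactly 18 distinct 5-mers), implemented as an
explicit position check.

Two engines test each site for a group difference in methylation fraction:

* `pooled` — sum (modified, unmodified) within each group; two-sided Fisher
  exact test on the 2×2 table (scipy's implementation; an independent
  hypergeometric enumeration backs it in the tests).
* `logistic` — binomial likelihood-ratio test keeping per-sample totals
  separate, equivalent to logistic regression of per-read modification on a
  group indicator. With a single binary covariate the MLEs are the pooled
  per-group fractions, so the LRT is evaluated in closed form (no IRLS),
  with p from χ²₁.

Default: logistic when both groups have ≥ 2 samples, else pooled. q-values
are BH across tested sites (the cited site-calling tool defaults to SLIM;
BH is standard, conservative, and matches the FDR convention used
elsewhere in the package — a documented divergence). A site is significant
at q < 0.01; significant sites partition into hyper (diff > 0) and hypo
(diff < 0) by the sign of `meth_diff = pct_test − pct_ref` in percentage
points, so in the flight profile (R+1 vs all pre-flight) "hyper" means
higher at return.

**Reversal.** A hyper site at return is *reversed* at a recovery day if the
recovery-vs-return contrast is significant with negative diff
(symmetrically for hypo sites); genes carrying reversed sites are reported
deduplicated. Profile membership (FP1 = R+1 vs pre-flight; RP1/RP2 = each
recovery day vs R+1) follows the narrative defaults and is configurable.

**Density and overlaps.** Pathway methylation density is significant sites
per detected gene: density(P) = #sig sites on genes of P / |P ∩ detected
genes|; pathways with no detected genes are skipped. Density is correlated
(Pearson and Spearman) against co-regulation scores over shared pathways,
and the significant-methylation gene set is intersected with the consensus
DEG set. Sites are keyed by (gene, transcript, position); collapsing across
transcripts of one gene is exposed as a flag since the collapse rule is a
genuine free choice.

## Transcript catalogs

Per-sample de novo assemblies are compared against a reference annotation
elsewhere; this package consumes the resulting tracking table (presence per
sample plus a one-letter class code: `=` exact match, `c` contained,
`j` novel junction, `u` fully novel, etc. — the 15-letter alphabet is
enforced). Samples with average read length below 400 bp are excluded
before any catalog analysis (degraded runs depress assembly sensitivity);
the QC field is mandatory there. A transcript is *consensus-present* at a
timepoint if present in every retained subject's sample; it is *unique* to
a timepoint within a window if consensus-present there and absent from
every retained sample at every other window timepoint. Presence is strict
across subjects while absence is strict across samples — the asymmetry
maximizes specificity. Consequences, both property-tested: uniqueness sets
within a window are pairwise disjoint, and enlarging a window can only
shrink them, so the same timepoint may legitimately have different unique
sets in overlapping windows. A `min_subjects` option relaxes the focal
consensus.

## Synthetic studies

The generator emits study-shaped inputs with recorded ground truth
(`SimTruth`), at the mission design (4 × 7) by default.

* **Counts**: NB per gene/sample; log2 mean = gene baseline
  (Normal(6, 1.5) log2 units ≈ median 64 counts, ~100-fold spread) +
  subject effect (Normal(0, 0.2 log2 units) — non-trivial inter-subject
  variance, as the use of subject covariates in the study design implies) +
  pathway effect. Dispersion default 10 (biological CV ≈ 32%). Pathway
  effects are additive on the log2 scale, matching fold-change semantics: a
  *disrupted* pathway adds its shift (default 0.8, chosen for testability —
  the study reports no effect sizes) only at R+1; a *trending* pathway adds
  slope·t through the return day (so it continues its pre-flight trend and
  has dz ≈ 0), then decays linearly to baseline by R+194. The linear decay
  is the simplest testable reading of "returning to baseline in recovery".
* **Dual quantifiers**: outside declared homolog groups both views equal
  the input up to small independent multiplicative noise; inside a group,
  view A concentrates ~90% of each sample's group total on the dominant
  member (primary-mapping behavior) and view B keeps the fractional split
  (multi-mapping-aware behavior). Minority shares are floored to whole
  reads so group totals are conserved exactly in floating point.
* **Methylation**: coverage ~ NB(mean 50, dispersion 20); modified reads ~
  Binomial(coverage, π) with site baselines π ~ Beta(2, 8) (mean 20%).
  Effect sites shift π by Δ/100 at R+1; non-reversal sites keep the shift
  through recovery (so recovery-vs-return is null for them), reversal sites
  return to baseline from R+45 on. Baselines of effect sites are re-centered
  so the shifted fraction stays inside (0, 1); an overflowing Δ warns and
  clips. True sites carry DRACH 5-mers; 30% of null sites carry non-DRACH
  decoys.
* **Catalogs**: shared transcripts present everywhere up to independent
  dropout; planted unique transcripts present in all subjects at their
  focal timepoint and absent everywhere else, hence exactly recoverable at
  zero dropout.

Every generator is a pure function of (parameters, seed). Not emulated:
read sequences, alignment and coverage biases along transcripts, library
composition effects, correlation between expression and methylation, or
any real effect-size distribution. Passing recovery tests therefore
demonstrate the *estimators* are correct and calibrated under the stated
model — not that the model captures everything in real missions.

## Numerical choices

* BH adjustment is applied within each stage's test family, never pooled
  across stages; NaN p-values propagate without consuming rank.
* Permutation p-values are lower-bounded at 1/(n_perm+1) by construction;
  `n_perm ≥ 100` is enforced.
* dz tie-breaks are lexicographic by pathway name; ranks are 1..n.
* Correlations on degenerate (zero-variance) vectors are reported as NA
  with a warning rather than raising.
* Self-correlation of bitwise-identical count columns is reported as
  exactly 1.0, bypassing floating-point round-off in the covariance path.
* Readers reject malformed input naming the offending line or cell; count
  TSVs round-trip at full precision (`float_precision="round_trip"`).
* Gene identifiers are opaque; version suffixes are stripped only via the
  explicit `strip_gene_versions` call.

## Problem sizes

The orchestrated default study runs 2000 genes × 28 samples, 60 pathways
(500 permutations each), 400 methylation sites, and an 82-transcript
catalog — chosen so a full run completes in seconds while every stage
retains enough signal for its recovery checks (disruption ranking,
methylation power ≥ 80% at Δ=30pp/50×, reversal profiling, planted unique
transcripts). The test suite's calibration checks use 500 null pathways at
500 permutations and 1500 null methylation sites.

## Known limitations

* `simple_de` ignores count dispersion; it is a location test on
  transformed values and will be anticonservative for very low counts.
* The pooled methylation engine ignores between-sample overdispersion in
  methylation fraction; the logistic engine keeps totals separate but
  likewise models a common within-group fraction.
* Trajectory medians pool genes × subjects; with four subjects the median
  is dominated by gene variation.
* No uncertainty interval accompanies dz (none is defined for it), so
  ranking stability under resampling is not quantified.
* The generator's effect sizes are conventions for testability, not
  estimates from mission data.
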