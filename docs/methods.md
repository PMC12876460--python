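# Methods

This note documents the statistical procedures implemented in
`vertescreen`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Significance classification

Inputs are statistical-results rows, one per gene × parameter × zygosity,
as produced by a mixed-model phenotyping framework.  The framework's models
are *not* re-fit here; p-values are consumed as given.

Rules, applied per gene over all of its rows:

- **Per-sex significance**: significant in males (females) iff any row has
  the male (female) knockout-effect p-value < α.  Comparisons are strict
  (`<`); a p-value exactly at α is not significant.  α defaults to 10⁻⁴.
- **Sex category**: male-only / female-only / both sexes from the two
  per-sex calls; "not considered" when no row carries any sex-stratified
  p-value (the analysis was run without sex strata); "considered but not
  significant" otherwise.  These five categories partition all genes with
  ≥ 1 row.  Missing p-values are ignored (never significant), not imputed.
- **Sexual dimorphism**: any sex × genotype interaction p < α.
- **Main-effect-only screen**: any genotype main-effect p < α *and* no
  interaction p < α in any row (the interaction vetoes across rows).
- **Life stage**: by procedure code — embryo gross morphology procedures
  (GEL/GEM/GEO/GEP, i.e. E9.5/E12.5/E14.5–15.5/E18.5) map to "embryo";
  X-ray, combined SHIRPA/dysmorphology and body composition (XRY/CSD/DXA)
  map to "adult".  Unknown codes are an error naming the code.
- **Zygosity tallies** are over gene × zygosity pairs among a gene's
  significant rows, so totals can exceed the number of genes (a gene hit in
  both homozygous and heterozygous rows counts in both tallies).

Parameter selection is config-driven: an include list (empty = default
open), exclude lists with recorded reasons (ribcage, skull/teeth,
appendicular skeleton, body length), and automatic removal of parameters
with zero significant genes.  The shipped catalogue
(`data/vertebral_parameters.yaml`) lists the 25 retained vertebral
parameters with their six categories and is editable for other screens.
Gene identity is by symbol, case-sensitive.

## Penetrance

Penetrance is x/n where x counts mutant animals scored "abnormal" and n
counts mutant animals with a definitive call.  Before counting:
experimental-group records only; category strings are case-normalized and
whitespace-trimmed and must equal "abnormal" or "normal" — everything else
("imageOnly", free-text notes) is a non-call and is excluded.  Strata are
gene × parameter × life stage × zygosity, with or without a sex split;
pooled counts are by construction the sums of the per-sex counts.

The exact 95% interval is Clopper–Pearson: the Beta quantiles
`Beta(x, n−x+1)` at (1−conf)/2 and `Beta(x+1, n−x)` at 1−(1−conf)/2, with
low = 0 at x = 0 and high = 1 at x = n.  The implementation uses scipy's
Beta quantile function; the test suite verifies it against an independent
oracle that inverts the binomial tail sums by bisection, and checks the
interval's conservative coverage (≥ nominal) by exact enumeration and
simulation.  The minimum-N rule (default n ≥ 3, applied to the
post-exclusion denominator) drops under-observed strata into a separate
"excluded" table rather than silently.

Summaries report the median and IQR (Q3 − Q1) of stratum penetrance,
counts at or above the high-penetrance thresholds (0.5 and 0.8, inclusive,
configurable), and per-parameter medians.  No covariates (centre, batch)
are modelled — counts only.

## Genomic clustering test

For a target gene set T and window w, the statistic is

S(w) = #{ g ∈ T : ∃ h ∈ T, h ≠ g, same chromosome, |start_g − start_h| ≤ w }.

Annotation cleaning: standard chromosomes only (1–19, X, Y; a "chr" prefix
is stripped), rows with missing coordinates dropped, duplicate symbols
resolved by keeping the smallest start.  Distance is between those
de-duplicated start coordinates, boundary inclusive; because the dedup rule
is start-based, starts are the natural coordinate, and the choice is
isolated in one function so midpoint or gap alternatives could be swapped
in.  The fast implementation sorts targets per chromosome and inspects
adjacent gaps (the nearest same-chromosome target is always adjacent in
start order); an O(n²) all-pairs oracle in the tests confirms equality.

The null samples k = |T| gene symbols uniformly without replacement from
the full annotation, n_perm times (default 5,000), recomputing S(w) each
time.  Reported per window: permutation mean µ and sample SD σ (n−1
denominator — conventional for permutation summaries and pinned so tests
are exact), z = (S − µ)/σ (undefined and flagged, not raised, when σ = 0),
and the right-tail Monte-Carlo p-value with +1 smoothing,
p = (#{S* ≥ S} + 1)/(n_perm + 1), so p ∈ [1/(n_perm+1), 1].  Each window
gets its own seed sub-stream, so adding windows never changes existing
results.  Testing several windows (defaults 1, 2, 5, 10 Mb) is handled by
reporting a Bonferroni-adjusted α = α/#windows alongside.  The null is
uniform over genes — not matched for GC, length or gene density.

z-scores are rounded to two decimals (half-even) in the report layer only;
full precision is retained internally.

### Calibration check design

Under the null (targets drawn from the same universe as the permutations),
the Monte-Carlo p-value is approximately uniform, but discreteness of the
count statistic makes the +1-smoothed p slightly conservative in proportion
to the tie mass.  The calibration suite therefore evaluates uniformity at a
5 Mb window — near half-saturation for 204 targets on the ~2.7 Gb synthetic
genome, where the count distribution is widest and ties are rarest — over
600 repetitions at n_perm = 200, requiring the Kolmogorov–Smirnov sup-norm
deviation to stay below 0.1.  The repetition count is chosen so that the
check's own sampling noise (≈ 1.36/√reps) sits well inside the bound rather
than straddling it.  The positive control plants 10 clusters of 5 target
genes within 100 kb each among 204 targets and requires p ≤ 0.01 at 1 Mb
with 1,000 permutations (the p-value floor 1/1001 leaves ample room).

## Vertebral categories, intersections, pleiotropy

Parameters map to exactly one of six categories: somitogenesis, spine
shape, tail morphology, vertebral form, vertebral number, vertebral
processes.  Gene sets per category use set semantics (a gene on two
parameters of one category counts once).  Intersection cells are
*exclusive*: each gene of the union is assigned to the cell of exactly the
categories containing it, so cells partition the union and their counts sum
to its size — the numbers an UpSet plot displays.  Only the cell table is
produced; rendering is out of scope (any UpSet plotting tool can consume
the TSV).

Pleiotropy relates each gene's vertebral parameter count to its supplied
total phenotype count (totals are inputs, not recomputed — what counts as
one "phenotype" is the upstream resource's definition).  Flags:
vertebral-only (fraction = 1), majority-vertebral (fraction ≥ 0.5, boundary
inclusive), and lethality-only-other for genes whose every non-vertebral
phenotype label contains "preweaning lethality" (case-insensitive
substring, configurable).

## Somite expression

The expression matrix is normalized log-scale values for somite samples
labelled by developmental stage ∈ {8, 18, 21, 25, 27, 35} somites and
somite maturation level ∈ {SI, SII, SIII} (the three most recently formed
somites).  A gene is "expressed" when its mean over all samples exceeds a
threshold (default 0 on the log scale — the minimal assumption, exposed as
`--expr-threshold`); genes absent from the matrix are "not expressed" with
an absent flag.  The genome-wide reference for "above median" is the median
of per-gene mean expression over *all* matrix genes.

DE testing is not re-implemented: maturation-DE (between somite levels) and
stage-DE (between stages) gene lists are inputs.  Cross-reference counts
obey inclusion–exclusion exactly, and DE flags are only honoured for
expressed genes.

Clustering of dynamics: per-gene stage profiles (means over levels and
replicates within each stage; level profiles for the maturation axis),
z-standardized per gene — making the result invariant to per-gene affine
rescaling — then hierarchical clustering with correlation distance and
average linkage, cut at k (defaults: 8 stage clusters, 3 maturation
patterns).  No literature-standard algorithm exists for this grouping, so
the method is a documented, deterministic choice (no random
initialization), and both metric and linkage are arguments.  Cluster
labels are method-dependent identifiers, not biologically canonical; they
should be compared up to label permutation (the tests use the adjusted
Rand index).

## Synthetic-data generator

The generator's defaults are the study conditions: 204 target genes,
α = 10⁻⁴, a ~2.7 Gb genome with 19 autosomes + X + Y at realistic lengths,
the six somite stages with SI/SII/SIII trios, 5% non-call records, and
sex-category / life-stage / zygosity mixes matching the screen's observed
proportions (53/34/41/71/5 by sex category; 63/139/2 by life stage; mostly
homozygous hits with occasional heterozygous and X-linked hemizygous).
Planted penetrance defaults span 0.2–1.0.  One seed drives everything, with
fixed per-operation sub-streams.

Design choices worth knowing:

- Gene starts are uniform per chromosome (chromosome chosen proportional to
  length) with a fixed 10 kb gene length; only start coordinates matter to
  the clustering statistic.  Real annotation is clumped (gene deserts, gene
  dense regions), so synthetic null distributions are narrower than real
  ones — calibration conclusions transfer, absolute means do not.
- Significant p-values are drawn log-uniform on [10⁻¹⁰, 10⁻⁴) — strictly
  below threshold, avoiding boundary ambiguity.  Non-significant p-values
  are drawn uniform on [α, 1) rather than (0, 1), so planted truth is
  recoverable by construction and recovery tests can demand 100% agreement;
  the cost is a slightly non-uniform null that downstream code never
  exploits (it only compares against α).
- Spatial clusters are planted by relocating cluster members within
  `cluster_span_bp` of an anchor gene; the operation returns an updated
  locus list rather than mutating its input.
- Expression clusters use eight canonical stage shapes (monotone up/down,
  mid peak/valley, early/late transient, step up/down) and three maturation
  patterns (decreasing, increasing, SII-transient), additive on a
  N(5, 1) baseline with amplitude 2 and N(0, noise_sd) noise; a configurable
  fraction of genes is planted "not expressed" far below threshold.  At
  noise_sd = 0 within-cluster profiles are identical, so hierarchical
  clustering must recover the partition exactly — the recovery tests use
  that.
- What the generator does **not** emulate: centre/batch structure, body
  weight covariates, realistic parameter-specific sample sizes, linkage
  between a gene's phenotype and its genomic neighbourhood, count-based
  RNA-seq noise (expression noise is Gaussian on the log scale), or the
  full breadth of the phenotyping framework's export schema.  Passing tests
  demonstrate algorithmic correctness and statistical calibration, not
  fidelity to any particular real export.

## Problem sizes in the test and acceptance suites

The suites run on reduced problem sizes chosen to leave sampling error well
inside each stated tolerance: 2,000-gene universes for permutation tests
(1,000 permutations for power checks, 200 for calibration repetitions),
500-gene tables for classification recovery, pooled strata of n = 1,000 for
the ±0.05 penetrance recovery bound, 2,000 simulated strata for interval
coverage, and 80 stage-DE genes for zero-noise cluster recovery.

## Known limitations

- The clustering null is uniform over genes; enrichment against a
  density-matched null would be a different (stricter) question.
- Penetrance is a raw binomial proportion; no shrinkage or covariate
  adjustment, so small-n strata are noisy (hence the minimum-N rule).
- The "expressed" threshold is a single global cut on mean log expression;
  no per-sample library normalization is attempted (inputs are assumed
  already normalized and batch-corrected).
- Expression cluster identities depend on the chosen metric/linkage/k;
  only partitions, not labels, are meaningful.
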