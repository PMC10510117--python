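# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical conventions and the known limitations of `cnvpop`.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. The
CNVnator-style call dialect (9 columns: type, chr:start-end, size,
normalized RD, four e-values, q0) uses 1-based inclusive coordinates and is
converted at the I/O boundary; GFF3 likewise, BED is passed through.
Chromosome names are normalized (case-insensitive `chr` prefix stripped)
only for cross-source matching; original names are preserved in outputs.

## Call filtering

Calls pass when `pval < 0.01`, `q0 < 0.5` and `size > 1000` bp, all strict.
The strictness matters at the boundaries: a call of exactly 1,000 bp or with
p exactly 0.01 is excluded, and the test suite pins this.

## CNVR construction

Within one chromosome and one svtype stratum (deletions and duplications are
merged separately by default), every maximal set of transitively overlapping
call intervals (any overlap of at least 1 bp; touching intervals do not
overlap in half-open coordinates) becomes one region spanning their union.
No reciprocal-overlap fraction is required. Cross-type merging is available
and labels mixed regions `MIXED`. Regions are then required to be carried by
at least three samples in at least one population, and partitioned into
shared (carried in both populations) and population-specific sets. The
implementation is a sort-and-sweep; tests verify it against an independent
per-base coverage oracle.

## Read-depth genotyping

A region's copy number is `CN = 2 × (regional mean read depth / genome-wide
mean read depth)`. When genotyping from caller output, the per-sample
regional estimate is the mean normalized RD of that sample's overlapping
same-stratum calls (normalized RD already has a genome-wide mean of 1).
Samples without an overlapping call are diploid by default (`CN = 2`).

## V_ST

For a region with copy numbers across two (or more) populations,

- `V_T` — unbiased (n−1) variance of all pooled values,
- `V_S` — unweighted mean of the within-population unbiased variances,
- `V_ST = (V_T − V_S) / V_T`.

Conventions: groups with fewer than two samples are an error; a region with
zero total variance is reported as undefined (NaN) rather than an error;
negative values (when `V_S > V_T`) are kept as computed. The
unbiased-variance convention is pinned by the two worked examples, which are
exact rationals: 8/27 ≈ 0.296296 for the duplication configuration and
25/63 ≈ 0.396825 for the deletion configuration.

Candidate regions are those at or above the nearest-rank percentile
threshold (default q = 0.98: sort ascending, take the element at rank
⌈q·n⌉; "above" means `value ≥ threshold`). When gene annotations are
supplied, each gene receives the maximum V_ST over the regions overlapping
it, and the threshold may be taken over gene-level values instead.

Candidates are confirmed with one-way fixed-effects ANOVA
(`F = MSB / MSE`, df `(k−1, N−k)`) and Tukey HSD pairwise p-values from the
studentized-range distribution with the Tukey–Kramer standard error for
unequal group sizes. For `k = 2` the Tukey p-value equals the ANOVA
p-value, which the tests verify to 1e−6. If `MSE = 0` with a nonzero
between-group difference, `F = ∞` and `p = 0`; if all values are identical
the result is NaN.

## Clustering and multiscale bootstrap

Samples are clustered on the 0/1 CNVR-carriage matrix. The default distance
is the Jaccard distance between carriage profiles (two samples carrying
nothing are at distance 0); Euclidean and 1−Pearson variants are available.
UPGMA (size-weighted average linkage) builds an ultrametric tree; because
exact distance ties are common on binary data, ties are broken by the
lexicographically smallest pair of minimum member identifiers, which makes
the tree deterministic.

Cluster support follows the multiscale bootstrap. Rows (regions) are
resampled with replacement at scale factors `r ∈ {0.5, …, 1.4}` of the
original row count (`nboot = 1000` per scale). For each observed cluster
(identified by its member set) the per-scale bootstrap probability `BP_r`
is counted, transformed as `z_r = Φ⁻¹(1 − BP_r)` and fitted by weighted
least squares to `z_r = v·√r + c/√r`, with inverse-variance weights from
the delta method, `w = nboot·φ(z)² / (BP(1−BP))`. The approximately
unbiased support is `AU = 1 − Φ(v − c)` and the bias-corrected bootstrap
probability `BP = 1 − Φ(v + c)`. Counted probabilities are clamped to
`[1/(2·nboot), 1 − 1/(2·nboot)]`.

Degenerate fits: a scale whose counted BP is exactly 0 or 1 carries no
curvature information. If fewer than two scales are informative, the
two-parameter fit is ill-posed; the edge then reports the clamped counted
BP at the scale nearest `r = 1` as both AU and BP and is flagged
`degenerate_fit`. This makes a cluster present in every resample at every
scale report support ≈ 1 (up to the clamp) rather than the ≈ 0.5 a forced
fit of a constant curve would produce.

## Annotation and enrichment

Region–feature intersection is a sorted sweep per chromosome. Gene overlaps
count at any positive overlap; QTL overlaps require strictly more than
1 kb. Over-representation of a hit-gene set against term gene-sets uses the
one-sided hypergeometric tail `p = P[X ≥ k]` with `X ~ Hypergeom(N, K, n)`
over the supplied gene universe; raw p < 0.05 is the default reporting
convention, with optional Benjamini–Hochberg correction.

## Synthetic-data generator

The generator emulates the *statistical shape* of a two-breed resequencing
CNV landscape, not sequencing itself. Defaults (the study conditions):

- 2 populations × 10 samples; 26 autosomes with lengths laddering from
  275 Mb down to 45 Mb (CNVR counts then correlate with chromosome length).
- 5,000 ground-truth regions; 69 % deletions / 31 % duplications.
- Sizes from a truncated log10-normal (mean 3.845, sd 0.40, range
  1.2–400 kb), giving a sub-10 kb median with a long tail. A log-uniform
  law on the same range would put the median near 20 kb, contradicting the
  sub-10 kb requirement, so the log-normal was chosen.
- Regions placed uniformly without overlap within each (chromosome, svtype)
  stratum.
- Carrier frequencies: 92.5 % of regions are shared, drawn around a common
  base U(0.3, 0.9) with ±0.05 population jitter; population-specific
  regions carry at U(0.3, 0.5) in their own population and 0 in the other;
  50 differentiated regions get a near-swept high side
  (U(max(0.9, gap + 0.06), 1.0)) against a low side
  U(0.05, min(0.2, f_high − gap)), enforcing a frequency gap ≥ 0.7.
- Per-sample carriage is Bernoulli at the population frequency; carriers
  emit one call with Gaussian boundary jitter (sd 300 bp) snapped to the
  300 bp bin grid, plus read-depth noise (sd 0.25) on copy numbers.
- Nuisance realism: 5 % of emitted calls violate the p-value filter, 5 %
  the q0 filter, and 5 % extra sub-1 kb decoy calls are added, so the
  strict filter has real work to do.

All randomness derives from `numpy.random.SeedSequence([seed, k])` with a
fixed stream index per stage, so every artefact is byte-reproducible from
the seed.

What the generator does **not** emulate: read alignment and caller error
structure (false negatives correlated with mappability), linkage between
regions, multi-allelic copy states beyond one carrier state per region, sex
chromosomes, and inter-individual global coverage differences.

## Numerical choices

- Unbiased (n−1) variances everywhere in V_ST; this is what makes the
  worked-example values exact rationals.
- Nearest-rank percentile (no interpolation), so the threshold is always an
  observed value.
- Tukey p-values via `scipy.stats.studentized_range.sf`; ANOVA p-values via
  `scipy.stats.f.sf`.
- Probit transforms and tail probabilities via `scipy.stats.norm`; the WLS
  fit solves the 2×2 normal equations directly.
- Jaccard distances are computed with one `X.T @ X` product and symmetrized
  to remove floating-point asymmetry.

## Limitations

- The acceptance evidence is desk-scale: exact worked examples, oracle
  equivalence on random inputs, and recovery on synthetic data. Headline
  counts from the original study (tens of thousands of calls from ~200 GB
  of reads) are out of scope.
- AU values are asymptotic approximations; with `nboot = 1000` they carry
  Monte-Carlo error, and the degenerate-fit fallback reports a clamped
  counted BP rather than an extrapolated value.
- Read-depth genotyping from caller output sees only samples with calls;
  non-carriers are assumed diploid rather than re-measured from coverage.
- The enrichment test treats genes as exchangeable (no gene-length or
  region-size bias correction).
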