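# Methods

This note describes the statistical procedures, the synthetic-data model
and the numerical choices behind `hordeomics`. It documents what each
stage computes and why, in the order the pipeline runs.

## Study design and data model

The unit of analysis is a proteins × samples matrix of label-free peak
areas over a fixed design: seven genotypes — wild type (WT), three
hordein single mutants (B, C, D) and their double mutants (BC, CD, BD) —
with three biological replicates each (21 samples). Values are
non-negative; missing measurements are stored as NaN and never silently
as zero. Genomic coordinates are 1-based and inclusive at both ends
everywhere in the package (the EnsemblPlants convention); conversion to
Python slices happens only at the point of slicing, and one property test
plants a marker at a known locus and retrieves the identical substring
through the extraction path.

## Phenotype statistics

Percent change vs wild type is `(m − m_WT)/m_WT × 100`, computed from
unrounded means and rounded to one decimal only in output tables.

Tukey's HSD is offered in a summary-statistic mode because published
trait tables usually print only (mean, sd, n): the pooled mean squared
error is reconstructed as `MSE = Σᵢ(nᵢ−1)sᵢ² / Σᵢ(nᵢ−1)` and the
studentized range statistic
`q = |mᵢ − mⱼ| / √(MSE/2 · (1/nᵢ + 1/nⱼ))` is referred to the
studentized range distribution with k groups and `Σ(nᵢ−1)` error degrees
of freedom (`scipy.stats.studentized_range`). For balanced raw-data
input this coincides with the classical procedure; tests cross-check it
against `statsmodels.pairwise_tukeyhsd` to 1e-6. When every group has
zero variance and means differ, p is reported as 0 with a warning.

Compact letter displays use the insert–absorb algorithm: groups are
added one at a time to letter columns of mutually non-significant
members, conflicting columns are split, absorbed (contained) columns
removed, and a final pass guarantees the defining invariant — two groups
share a letter iff they are not significantly different at α = 0.05.
Intransitive significance patterns simply yield groups with several
letters. The invariant is verified exhaustively for up to five groups on
randomized p-matrices.

## Differential abundance

Pre-treatment is log10 transformation followed by mean-centring of each
protein row across all samples. Zeros and missing values are imputed at
half the protein's smallest positive value before the log (logged);
proteins with no positive value in a contrast's groups are excluded from
that contrast with a logged count.

Per-protein contrasts use a two-sample t-test on log2 replicate values;
the effect estimate is `mean(log2 mutant) − mean(log2 reference)`. The
default is the **pooled-variance (Student) test**: at triplicate group
sizes the Welch/Satterthwaite correction is markedly conservative — its
empirical size in null simulations at n = 3 per group is ≈ 0.033 at a
nominal 0.05 — while the pooled test attains ≈ 0.048. The
unequal-variance form remains available (`Config.ttest = "welch"`) for
designs where variance heterogeneity dominates. Welch p-values are
symmetric in the contrast direction, and so is the pooled test, so
volcano classification is exactly antisymmetric under swapping mutant
and reference.

Benjamini–Hochberg adjustment (statsmodels step-up, validated against an
independent implementation to 1e-12) is applied within each contrast.
Volcano status is up when FC > 2 and down when FC < 0.5 with a raw
p ≤ 0.05 gate, matching the volcano-plot convention; the stricter BH
q ≤ 0.05 gate is used when the differential set feeds the co-abundance
network (both gates configurable). Whether published volcano calls were
multiplicity-adjusted is ambiguous in the source material, so both modes
are exposed rather than hard-coding one.

PCA operates on the normalized matrix with samples as observations, via
SVD, with a deterministic sign convention (the largest-magnitude loading
of each component is made positive). Variance fractions are relative to
the total sample variance, hence in [0, 1], non-increasing, and summing
to ≤ 1.

PLS-DA replaces the proprietary OPLS-DA implementation used in
commercial software: for a two-class response the discriminant subspace
and the VIP ranking are equivalent in practice. The response is coded
±1, a NIPALS PLS regression (scikit-learn) with 2 components (default,
configurable — the original component count is unstated) is fitted
without re-scaling (the data are already centred), and
`VIP_j = √(P · Σₐ w²ₐⱼ SSYₐ / Σₐ SSYₐ)` computed from the unit-norm
x-weights and the response sum of squares explained per component. This
normalization forces mean(VIP²) = 1, which the tests assert to 1e-9.
Selection keeps VIP > 1.2 truncated to the 100 highest scores.

## Amino-acid composition shift

Per-protein composition is percent of each of the 20 standard residues;
unknown residues (X) are accepted in input sequences but excluded from
the denominator, so profiles always sum to 100. The shift statistic is
the per-residue ratio of the **unweighted** arithmetic mean composition
of the up set over the down set — deliberately not abundance-weighted,
so it measures which way the proteome's composition moves, not its mass
balance. A residue absent from the down set yields an undefined ratio
(never infinity), and swapping the sets inverts every defined ratio
exactly.

No test is named in the source material for calling per-residue shifts
significant; the package uses a two-sided Mann–Whitney U on the
per-protein residue percentages between the two sets, BH-adjusted across
the 20 residues, because compositions are bounded and non-normal at
typical set sizes.

Residue-rich classification divides a protein's residue percent by the
mean percent of a background proteome and calls it rich at a factor of
at least 1.5 — the boundary is inclusive ("at least"). The background is
always a user-supplied (or synthetic) protein set rather than a shipped
frequency table, avoiding an invented constant; the same 1.5× rule
applies to lysine, methionine and tryptophan.

## Ternary abundance bias

For a chosen triple of genotypes, each protein's replicate means are
normalized to fractions summing to 1 and assigned to the nearest of
seven ideal points in the simplex: the corners (1,0,0), (0,1,0),
(0,0,1), the edge midpoints (½,½,0), (½,0,½), (0,½,½) and the centre
(⅓,⅓,⅓) — the standard corner/edge/centre scheme for expression-bias
categorization; the cited categorization method does not restate its
ideal points, so the set is explicit and swappable. Distances are plain
Euclidean; ties break in the fixed label order. Raw means are used by
default (a log10 mode exists; the original normalization scale is
unstated). Assignment is verified against a brute-force nearest-point
computation on random simplex points and is invariant to uniform
scaling of the input triplet.

## Co-abundance network and modules

Nodes are the union of proteins significant in any WT–DM or DM–DM
contrast (BH-gated by default). Edges are Pearson correlations of
log10-transformed profiles across all 21 samples, kept at r ≥ 0.95
(positive) or r ≤ −0.95 (negative); the exact preprocessing of the
original network plugin is undocumented, so the transform is logged and
configurable (raw/log10/z-score). Zero-variance profiles have undefined
correlation and are excluded with a log entry. Raising the cutoff can
only remove edges (tested), and correlations are invariant to positive
per-protein scaling.

Modules come from average-linkage agglomerative clustering (scipy) of
z-scored profiles under distance 1 − r, cut to exactly k clusters;
k = 12 is the observed module count in the motivating study and is a
parameter, not an inferred quantity — no cut criterion is given there.
Average linkage is the robust default for correlation distances; single
and complete linkage are available. Module ids are ordered by decreasing
size with ties broken by the lexicographically first member, making
labels deterministic. On three well-separated planted archetypes (noise
sd ≤ 0.1 on log10 scale) recovery is exact (adjusted Rand index 1).

Network measures (degree, clustering coefficient, components, density)
ignore edge sign and come from networkx, cross-checked in tests against
a direct adjacency-matrix computation.

## Chromosome mapping and promoter analysis

Mapping is an exact id join against the locus table; proteins without an
entry fall back to a naive shared-5-mer best hit against reference
translations (a desk-scale stand-in for a full alignment search),
requiring at least 50% of the query's 5-mers shared, ties broken toward
the lowest (chromosome, start). Unmapped proteins are reported, never
dropped silently, and a hook accepts an externally produced mapping
table for real data.

Upstream extraction takes the 1,000 bp 5' of the gene: for + strand
genes the genome bases [start−1000, start−1]; for − strand genes the
reverse complement of [end+1, end+1000]; windows truncate at chromosome
boundaries with a log entry. The returned sequence reads 5'→3' on the
coding strand with offset 1 the most-upstream base.

Motif scanning is exact string matching (100% identity) of the Prolamin
box (TGTAAAG and TGTAAAGT), Pyrimidine box (CTTTT), GA-MYB (AACA) and GA
(TAACAAA) elements, overlapping occurrences included, N never matching.
Scanning is coding-strand only by default because these are directional
promoter elements defined relative to the gene's 5' end; a double-strand
mode exists behind a flag. Every TGTAAAGT hit implies a TGTAAAG hit at
the same offset (family collapsing, property-tested). AACA is expected
roughly 3.9 times per kb by chance at uniform base composition, so
combination classes are defined by family presence/absence (≥ 1 hit),
not hit counts: each gene gets a label over {Pyr, Pbox, GAMyb, GA}
(e.g. "Pyr-Pbox-GAMyb"), with UpSet-style intersection counts.

Circos export writes three plain-text track files — chromosome bands,
a heatmap of per-genotype log2 mean abundance (value order WT, B, C, D,
BC, CD, BD, innermost first) and correlation links — for external
rendering; no figures are drawn.

## Synthetic-data generator

The generator is first-class, tested code that emulates the study
conditions; its defaults are the conditions all ground-truth-recovery
tests run under.

* **Classes and counts** (200 proteins): 12 B-hordeins, 10 C-hordeins,
  3 D-hordeins, 5 γ-hordeins, 15 lysine-rich (LEA-like), 15 fatty-acid
  metabolism, 15 starch metabolism, 125 housekeeping — hordeins a few
  percent of the proteome, consistent with a storage-protein family
  resolved into multiple proteoforms.
* **Sequences** are built with exact residue counts apportioned from a
  class profile by the largest-remainder rule and shuffled, so
  composition constraints hold by construction, not in expectation:
  hordein-like sequences have Q+P = 48% (constraint ≥ 40%), lysine-rich
  sequences K = 12% against a ≈ 5.3% background mean (constraint
  ≥ 1.5×). Infeasible profile settings raise at generation time.
* **Effects** (log2, vs WT baseline): each hordein class is suppressed
  by −6 (essentially complete loss on a peak-area scale) in the
  genotypes carrying its mutation; the lys3 trans-effect is modelled as
  full C-hordein suppression plus attenuated (−2) B-hordein suppression
  in C-carrying genotypes; γ-hordeins are mildly elevated (+1) when
  B-hordeins are lost; lysine-rich and fatty-acid classes are
  compensated (+1.5) and starch metabolism reduced (−1) in BC and CD.
  The compensation magnitudes are configurable and not claimed to match
  any measured values — the source material does not quantify them.
* **Noise** is multiplicative log-normal, `2^N(0, 0.25)` per cell —
  the standard error structure for peak areas; nothing is stated about
  the real error model, so this is the package's choice. At sd 0.25 and
  n = 3, mean log2 ratios recover the planted effects with RMSE < 0.25
  (Monte-Carlo tested).
* **Loci**: hordein genes alternate between two disjoint windows on the
  1H short arm; all other classes scatter over 2H–7H. Chromosome
  lengths are scaled down to hundreds of kb (genes every 5 kb with
  ≥ 1 kb flanks) so a full genome is generated in memory in well under a
  second; coordinate semantics are unchanged.
* **Promoters**: each gene's 1,000 bp coding-strand upstream window is
  uniform-random ACGT with its class's motif combination planted at
  recorded non-overlapping offsets (storage proteins carry
  Pyr+Pbox+GAMyb, lysine-rich genes Pyr+Pbox, metabolic classes
  Pyr+GAMyb(+GA), housekeeping cycles through sparse combinations).
  Accidental motif occurrences in the random background are left in
  place: scanner recall is evaluated at planted positions from the
  manifest, while precision is evaluated against a brute-force scan.
* **Phenotypes**: trait means per genotype are the configured wild-type
  level times (1 + effect%), with sd a fixed CV — exact by default so
  percent changes recompute to the planted effects, or sampled from the
  true normal distribution (`phenotype_sampling`) for null-uniformity
  and power simulations.

Everything derives from one integer seed (independent substreams per
stage via seed sequences); two runs with the same parameters are
byte-identical.

**What passing tests do and do not show.** The generator plants clean
class structure: effects are identical within a class, noise is
homoscedastic and log-normal, promoter background is uniform, and loci
are regularly spaced. Real grain proteomes have correlated proteoforms,
heteroscedastic and occasionally missing peak areas, repeat-rich
promoter background and uneven gene density — so ground-truth recovery
here validates the arithmetic and the thresholds of the pipeline, not
its performance on real instrument data. Published protein counts from
the real dataset (which require the deposited raw data) are consequently
not reproduced; the count→percent arithmetic and every procedure that
produced them are.

## Numerical conventions and degenerate inputs

* Reported percentages are rounded to one decimal; all internal
  computation is on unrounded values.
* Residue-rich threshold, fold-change, p/q gates, correlation cutoff,
  VIP threshold, upstream length and module count all live in `Config`,
  validated on construction (e.g. correlation cutoff must lie in (0,1]).
* Degenerate cases are defined, not accidental: identical groups give
  Tukey p = 1; all-zero ternary triplets are excluded with a log entry;
  constant PLS predictors get weight 0 and finite VIP; zero-variance
  network profiles are excluded from pairing; an empty significant set
  yields an empty network with a warning.
* Ties: ternary categories break in the fixed ideal-point order; module
  ids by size then first member; fallback mapping by lowest
  (chromosome, start).

## Problem sizes

Default test and pipeline sizes — 200 proteins × 21 samples, 1,000
random kilobase sequences for scanner validation, 10,000 simplex points,
1,000 null proteins — were chosen so the complete synthetic pipeline
runs in a few seconds and the whole suite in well under a minute on one
CPU, while keeping Monte-Carlo standard errors far inside the asserted
tolerances.

## Known limitations

* The k-mer mapping fallback is not an aligner; distant homologs map
  poorly. Real analyses should supply an externally computed mapping.
* PLS-DA with two components approximates, but is not identical to,
  orthogonalized (OPLS) implementations for more than two classes.
* The summary-statistic Tukey mode assumes the printed sds estimate a
  common within-group variance; strongly heteroscedastic traits violate
  this, as they would in the classical procedure.
* Module count k is a parameter, not estimated; choosing k from the
  data (e.g. by silhouette) is out of scope.
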