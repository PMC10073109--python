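# Methods

This note documents the statistical procedures `methrev` implements, the
parameters that matter, the synthetic data model used for validation, and
the design decisions taken where the problem was genuinely open.

## The analysis model

The pipeline treats a 450K-style methylation array as a probes × samples
matrix of β values, β = M / (M + U + offset), where M and U are the
methylated and unmethylated fluorescence intensities of one CpG in one
sample and the offset (default 100, configurable) regularizes
low-intensity probes. β lies in [0, 1) for any finite signals when the
offset is positive. Cells whose detection p-value is ≥ α (default 0.01)
cannot be distinguished from background and are set to missing; the
boundary is inclusive on removal. Probes on chrX/chrY (sex-specific
methylation) and probes whose interrogating oligonucleotide carries an
annotated SNP in its last 10 bases (genotype, not methylation, drives the
signal) are removed before testing. No between-array normalization is
performed here: inputs are assumed normalized upstream (e.g. control-probe
normalization when starting from IDATs), which is out of scope.

### Differential methylation

For each CpG and a two-group comparison, the test is a one-way
fixed-effects ANOVA on β values with missing values dropped pairwise with
their labels. With two groups this is exactly the pooled-variance t test
(F = t²), which the suite verifies to 1e-10 relative tolerance. When the
within-group variance is exactly zero and the means differ, the test is
reported as F = ∞, p = 0 rather than failing. Probes with fewer than
`min_samples_per_group` (default 2) non-missing values in either group get
missing statistics and are never silently dropped — probe accounting is
preserved end to end. Tests run on β directly, with no M-value transform,
because the effect-size gate is itself on the β scale.

Raw p-values are adjusted across all tested probes with the
Benjamini–Hochberg step-up procedure, q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1,
with missing entries passed through and m counting only tested probes.
A CpG is **informative** when |Δβ| ≥ δ_min and q ≤ q_max, both inclusive:
δ_min = 0.66 for the developmental (NCC vs melanocyte) comparison,
0.20 for the progression (primary vs metastatic) comparison, q_max = 0.01
for both. Direction is stated relative to group1, the designated state of
interest (NCC, metastatic): "hypo" means group1's mean is lower.

### Reversal catalog

Two comparisons with aligned group1 semantics are intersected per
direction: a reversal CpG is informative with the same direction in both.
The operation is symmetric and the catalog's hyper/hypo sets are disjoint
by construction. For ranking, each CpG's key is min(|Δβ_a|, |Δβ_b|) —
a reversal is only as strong as its weaker comparison — with ties broken
by probe id and a default floor of 0.30 (the ">30% change" notion used to
pick top CpGs). Which aggregate (min, mean, or a single comparison) the
original top-five ranking used is not specified anywhere; min is this
package's documented choice.

### Promoter window and association

CpGs map to a transcript when their strand-aware signed offset from its
TSS, d = pos − TSS (+ strand) or TSS − pos (− strand), satisfies
−300 ≤ d ≤ +63 with both endpoints inclusive (offset 0 is the TSS base).
The genome build is whatever the supplied annotation uses; the annotation
file is authoritative. Region methylation per sample is the complete-case
arithmetic mean over member probes (missing members ignored; a sample with
no observed member is missing). A sample is **hypomethylated** when its
region mean is strictly below 0.33; the value 0.33 itself is *not*
hypomethylated.

Associations use self-contained test implementations so boundary and tie
behavior is fully specified:

- **Fisher exact (two-sided)** — probability-ordering definition: with
  margins fixed, sum hypergeometric probabilities of every table no more
  likely than the observed one, with a 1 + 1e-7 relative tolerance for
  floating-point ties. Verified exhaustively against an exact rational
  enumeration oracle for every 2×2 table with total ≤ 40. The sidedness of
  the original test is not stated; two-sided is the conventional default
  and is the weaker (more conservative) claim.
- **Mann–Whitney U (two-tailed, unpaired)** — U counts pairs with
  x > y plus half the ties. Exact p by enumerating all C(n₁+n₂, n₁) rank
  assignments when n₁+n₂ ≤ 12 and the data are tie-free (enumeration stays
  sub-second there; ties make the exact null nonstandard); otherwise the
  normal approximation with tie correction and 0.5 continuity correction.
- **Spearman** — Pearson correlation of mid-ranks, with identical or
  exactly reversed rankings snapped to ±1; two-sided p from the t
  approximation with n − 2 df. Fewer than 3 complete pairs yields a
  missing result. An exact permutation p is a non-goal at the cohort sizes
  targeted.

### Knockdown signature

The signature is the set of genes down-regulated in *every* knockdown
context: log2FC < 0 and p < 0.05 (strict, per context), genes absent from
any context excluded. If more than 500 qualify, the 500 with the most
negative mean log2FC are kept, ties broken by gene id — whether the
original 500 was "all qualifying genes" or a capped ranking is unstated,
and both behaviors are reachable through `max_genes`. The per-sample
score is the scaled average expression: each signature gene z-scored
across samples (n−1 denominator; zero-variance genes dropped with a
warning), then averaged per sample. The alternative order (average, then
scale) differs only by a per-cohort affine map and is exposed as a flag;
z-then-mean is the default because it preserves cross-gene comparability.
Expression input is assumed log-scale/normalized; a log2(x+1) flag exists
for raw counts. DE calling itself is out of scope — DE tables are inputs.

### Bisulfite clones

Per CpG, percent methylation = 100 × methylated / informative calls over
clones. CpGs with fewer than 8 informative clones are flagged low-coverage
but still reported: the 8-clone rule governs clone selection, not
reporting, and flags keep the output total.

## Synthetic data model

The generator produces everything the pipeline consumes, with ground
truth. β values are Beta-distributed, parameterized by (mean,
concentration): background probes draw one shared state per probe
(mean 0.1, 0.5 or 0.9 with weights 0.45/0.10/0.45 — the bimodal marginal
typical of 450K arrays) used identically in all groups and both studies;
concentration 20 gives sd ≈ 0.065 at mean 0.1. Planted reversal probes
(default 40: 20 hyper, 20 hypo) instead use group means 0.5 ± Δ/2 with
Δ = 0.8 in the developmental and 0.35 in the progression study,
consistently oriented in both. Five planted hypo probes are placed inside
a + strand transcript's −300..+63 window (emulating the isoform promoter
DMR); a − strand decoy transcript on another chromosome collects only
background probes. Detection p-values are ~Uniform(0, 0.005) except for a
2% fraction pushed above 0.01; 3% of probes are on sex chromosomes and 5%
carry the SNP flag, never overlapping planted probes.

Group sizes default to 4 NCC vs 8 melanocyte and 30 primary vs 60
metastatic — the progression cohort is scaled down from the real 109 vs
364 to keep simulations snappy while preserving the size ratio and ample
power at Δβ = 0.35 (`full_scale=True` restores the original sizes).
Expression for the progression samples follows
isoform = 6 − 4 × (region mean β) + N(0, 0.5²); 200 planted signature
genes (of 1,000) track the centred isoform expression with unit slope and
N(0, 0.5²) noise; knockdown DE tables in two contexts give planted genes
log2FC ∈ −U(0.5, 3) with p ∈ U(10⁻⁶, 0.04) and background genes null
uniform p with N(0, 0.8²) log2FC. A single seed fans out to per-component
PCG64 streams, so regenerating one component never perturbs another.

**What the generator does not emulate:** Infinium I/II probe-chemistry
differences, batch effects, copy-number distortion of β, spatial
correlation between neighboring CpGs, and realistic LD between SNP flags
and methylation. Passing tests therefore demonstrate that the pipeline's
logic and thresholds behave as specified under the assumed distributional
model — not that the thresholds are optimal for any particular real
cohort.

## Operating characteristics the suite verifies

- End-to-end reversal recovery on the default configuration over 20
  seeds: sensitivity ≥ 0.95 and precision ≥ 0.95 (observed ≈ 1.0/1.0).
- Signature derivation recovers ≥ 95% of planted genes with ≤ 5% false
  members (observed 100%/0%).
- Null simulations (no planted effects): raw p ≤ 0.05 fraction within
  0.05 ± 0.02 in the large comparison, and an empty reversal catalog at
  default thresholds in ≥ 95% of seeds.
- Exact-test kernels match brute-force enumeration oracles (Fisher: all
  tables with total ≤ 40; Mann–Whitney: all tie-free splits with
  n₁+n₂ ≤ 7); BH matches a naive O(m²) oracle; two-group F = t².

## Numerical and degenerate-input choices

Threshold ties are inclusive exactly as printed (detection p = α masked;
|Δβ| = δ_min informative; region mean = 0.33 not hypomethylated). Probes
missing from the manifest are an error by default (a flag downgrades to
warn-and-drop) because silent probe loss corrupts downstream counts.
Zero-variance ANOVA inputs return (F=0, p=1) when means agree and
(∞, 0) otherwise. Fisher odds ratios use an infinite sentinel when
bc = 0. Empty reversal catalogs, empty signatures, and zero-informative
runs are valid clean outcomes, not errors. TSV round-trips are
bit-identical (shortest-representation floats, empty cells for missing);
report JSON carries no timestamps, so a config + seed reruns
byte-identically.

## Known limitations

Covariate adjustment, surrogate-variable analysis, region *de novo*
segmentation, confidence intervals for the odds ratio, and exact Spearman
permutation tests are out of scope. The ANOVA assumes approximate
normality of β within groups; at the small developmental group sizes
(4 vs 8) raw p-values are only approximately calibrated for extreme-mean
probes, which is why the Δβ effect-size gate, not the p-value alone,
carries the specificity burden there.
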