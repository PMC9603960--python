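# Methods

## Data model and conventions

Expression is held feature × sample with an explicit sample → group map
(H/L). Genomic coordinates are 1-based inclusive throughout (GTF
convention); any future BED export would convert to 0-based half-open.
Missing values are not permitted in expression tables: a zero is a
measurement, an empty cell is an error, because downstream correlations
need complete vectors. Biotypes are caller-supplied annotation, never
inferred from id prefixes.

## Differential expression

The DE engine is a self-contained gene-wise negative-binomial test:

- **Library sizes** by median-of-ratios: per sample, the median across
  all-positive features of the ratio to the feature's geometric mean;
  when no feature is positive in every sample the estimator degenerates
  and total-count scaling is used.
- **Dispersion** per feature by method of moments on the pooled
  within-group variance, `phi = (var − mean) / mean²`, floored at 1e-8.
- **Test statistic**: Wald contrast of log normalized group means with
  the delta-method variance `(1/mu + phi)/n` per group. The statistic is
  referenced against a t distribution with `n_H + n_L − 2` degrees of
  freedom rather than the normal: with three samples per group the
  dispersion is estimated from the same handful of observations as the
  means, and the normal reference is visibly anticonservative (null
  rejection near the top of the acceptable range), while the t reference
  gives a null rejection rate of ~0.04 at p < 0.05.
- **Fold change** `log2((mean_H + c)/(mean_L + c))` on normalized counts
  with pseudocount c = 0.5 (bounded, symmetric shrinkage at zero means).
  The direction convention is fixed as H over L.
- **Calls**: up if log2FC ≥ +1 and p < 0.05, down if log2FC ≤ −1 and
  p < 0.05, else ns — magnitude inclusive, p strict. Thresholds are
  configurable; BH adjustment is computed on request but calls use raw p.

Degenerate cases: an all-zero feature reports (log2FC 0, p 1, ns); a
feature with identical counts in every sample has log2FC exactly 0 only
when the library size factors coincide, since normalization rescales a
constant row otherwise — its call is ns regardless.

This engine intentionally does not reproduce any external DE package
numerically; its contract is calibration and effect-size recovery on
synthetic data (see below), not replication of a specific fitter.

miRNA tag counts are depth-normalized per million without a length term;
FPKM (with its per-sample identity Σ_g FPKM_gs · length_g(kb) = 10⁶) is
applied only to transcript-level biotypes, where fragment counts scale
with transcript length.

## Target inference

Canonical seed sites are exact reverse complements of miRNA positions
2–7 (6mer) or 2–8 (7mer-m8) in the target sequence, with an adenine in
the target opposite miRNA position 1 upgrading to 7mer-A1 / 8mer. U and
T are equivalent; non-IUPAC characters are rejected. The default minimal
class is 7mer-m8, since canonical prediction tools require ≥ 7-nt sites;
6mer sites are admitted only on request. Overlapping sites are all
reported (an 8mer necessarily nests a 7mer-A1 one position downstream
when weak classes are scanned). Imported prediction tables can be
intersected — keeping pairs present in both sources — which mirrors the
common practice of requiring agreement between two predictors.

lncRNA target genes are assigned in three modes: **cis** (same
chromosome, span distance ≤ 100 kb by default; the window is a common
convention, exposed as a parameter), **antisense** (same chromosome,
opposite strand, span overlap ≥ 1 bp; positional overlap is used rather
than hybridization energy, which is out of scope), and **trans**
(|Pearson| ≥ 0.9 across all samples, aligned with the co-expression
cutoff used in network assembly; constant-expression features are
excluded with a logged warning). Novel lncRNA candidates pass a
structural filter (length > 200 bp, ≥ 2 exons) and must have both
supplied coding-potential scores < 0 (intersection of two independent
non-coding calls).

## ceRNA network assembly

Correlations are computed across all samples pooled — with n = 3 + 3,
pooling both groups is the only way the sample size supports the
thresholds — on log2(FPKM + 1) for transcript biotypes and log2(CPM + 1)
for miRNAs; raw-scale layers are available by flag. Spearman is the
Pearson correlation of average ranks (tie-aware); both statistics are
computed with a single square root of the variance product, which keeps
results exact on integer-valued input so that boundary cases (SCC exactly
−0.7, PCC exactly 0.9) are decided deterministically. Zero-variance
vectors yield an undefined correlation; such pairs are dropped with a
logged count, never silently passed.

Gates follow the printed inequalities strictly: miRNA–target pairs with
SCC < −0.7 (both members differentially expressed; the DE gate can be
disabled for method studies) and (ceRNA, mRNA) pairs with PCC > 0.9.
No correlation p-value gate is applied — only magnitude cutoffs. Triplet
assembly is exhaustive: every (ceRNA, miRNA, mRNA) combination with both
negative edges, both predicted-target links and the positive edge,
sorted lexicographically. The resulting network deduplicates nodes and
edges across triplets; edge types are `mirna_ceRNA`, `mirna_mRNA` and
`coexpression`. The node count is defined as the number of unique ids.
Hubs are nodes of degree ≥ 3 in the deduplicated simple graph.

## Synthetic data

The generator emulates the motivating study design at roughly 20× reduced
feature counts (defaults 1,000 mRNA, 500 lncRNA, 650 circRNA, 100 miRNA;
3 samples per group), which is sufficient for correctness and recovery
testing at desk scale. Counts are sampled from NB(mean, dispersion)
directly — not rounded Gaussians — matching the DE model. Base means are
lognormal(4, 1); per-sample depth factors lognormal(0, 0.1); decoy
dispersion 0.1. A configurable fraction (default 10%) of features is
differentially expressed with |log2FC| uniform on [1, 4] and random sign
(the study reports no effect-size distribution; this range is stated as
configuration, not as an estimate).

Planted ceRNA motifs use a single latent factor per triplet,
`z_s = s·delta·g_s + u_s` with `g_s = ±1/2` by group,
`u_s ~ N(0, 0.5²)`, and triplet-alternating sign `s`; the miRNA loads
with −beta, ceRNA and mRNA with +beta (beta = 1), plus N(0, sigma²)
motif noise (sigma = 0.1 default) on the log2 scale. This is the
simplest mechanism that guarantees the required sign structure and is
analytic at sigma = 0, where the monotone latent mapping forces
Spearman = −1. Consequences of the defaults:

- each planted member carries a true group |log2FC| of beta·delta = 4 —
  at the upper end of the configured DE range and well within the
  magnitudes such studies report — so the members survive the DE gate
  with high probability at n = 3;
- the latent jitter sd 0.5 puts the planted pairwise |SCC| near 0.95;
- the alternating sign keeps planted features from skewing library
  composition in one direction, which would otherwise let depth
  normalization (CPM/FPKM totals) absorb the planted signal itself;
- planted members use base mean 400 and dispersion 0.01: high-expression,
  low-noise features, without dominating library totals.

Planted targeting is realized twice: in the miRNA-target pair table and
as a perfect 8mer site written into each partner sequence, so both the
table-driven and the sequence-driven target paths can recover it. Decoy
target pairs (default 300) are random (miRNA, target) pairs with no
expression coupling, emulating prediction false positives.

All stages draw from child streams of one master seed with fixed stage
labels, so any stage is reproducible in isolation.

**What the generator does not emulate**: read-level sampling (FASTQ),
splice structure beyond two-exon transcripts, isoform ambiguity,
sequence composition biases, shared miRNAs between motifs, and correlated
decoys (hub co-expression). Passing recovery tests therefore demonstrates
the pipeline's correctness under the stated generative model, not its
error rates on real tissue data, where correlation confounding is
stronger.

## Enrichment

One-sided over-representation only: p = P[X ≥ k] from the hypergeometric
distribution with the term intersected with the universe; k = 0 reports
p = 1. The universe is explicit and caller-supplied (recommended: all
features of the tested biotype present after all-zero removal — the
background is stated rather than implicit). BH-adjusted values are
reported alongside raw p. No ontology-graph propagation or
pathway-topology weighting is performed, and the statistic is not
intended to reproduce numbers from modified-Fisher tools.

## Numerical and degenerate-input choices

- Strict inequalities exactly as configured; boundary correlations are
  excluded by construction and covered by float-exact tests.
- Ties in Spearman use average ranks.
- The qPCR transform is 2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(reference).
- Readers reject malformed input (duplicate ids, non-numeric or missing
  cells, exons outside their transcript span, unlabeled samples) rather
  than coercing.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen as
the package's own defaults: 200 random instances of ≤ 50 nodes for the
assembly oracle, 2,000 features for DE calibration and effect-size
recovery, and the 2,060-feature recovery benchmark (20 planted lncRNA
triplets, 2,000 decoy features). These run in seconds on one CPU.

## Known limitations

- With n = 6 samples, Spearman takes only coarse values; the −0.7 gate
  is effectively a rank-pattern filter, and correlation estimates are
  unstable by nature at this design size.
- The NB test's method-of-moments dispersion has only 4 degrees of
  freedom at the default design; no information is shared across genes,
  so power is below that of shrinkage-based fitters.
- circRNA expression is treated like any other layer once loaded;
  junction-read-per-million quantification upstream of the package is
  the caller's responsibility.
- Antisense lncRNA targeting uses positional overlap, not base-pairing
  thermodynamics.
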