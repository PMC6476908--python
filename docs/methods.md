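# Methods

## Scope and data model

`spermkit` analyses bulk RNA-seq of mature sperm downstream of alignment:
its inputs are per-sample read intervals (BED-like), a gene/transcript/exon
annotation (GFF3/GTF), a RepeatMasker-style repeat table, optional gene-set
collections (GMT), and count matrices for small RNAs. Read trimming,
alignment and duplicate removal are upstream concerns; the declared
`total_mapped_count` of a sample is the depth denominator and may exceed
the number of records supplied (the records can be a filtered subset).

All coordinates are internally 0-based half-open; GFF/GTF conversion
happens only in the I/O layer. Overlap computations are unstranded by
default: the library preparation's strandedness is not something the
pipeline can infer, so strand is carried on records but only consulted
when explicitly requested.

## SRE calling

An SRE is a maximal genomic interval of pooled read coverage. Reads from
all samples are pooled, per-base coverage is segmented into covered runs,
runs separated by uncovered gaps of at most `max_gap` bp (default 0) are
merged, and a merged interval is emitted iff its peak pooled coverage is at
least `min_support` (default 3) reads. Both knobs are exposed; the
defaults are the simplest rule consistent with "reads clustering at a
locus" and are validated against a brute-force per-base oracle rather than
against any reference caller. Calling on pooled reads gives the cohort a
single SRE coordinate system; quantification is then per sample:

    RPKM(s, SRE) = overlapping_reads(s) * 1e9 / (length_bp * total_mapped_count(s))

with ≥ 1 bp overlap counting a read once per SRE (SREs are disjoint, so a
read counts at most once per SRE but may touch two adjacent SREs).

Decile ranks (1 = most abundant) order SREs by mean RPKM descending with
deterministic (chrom, start) tie-breaks; the decile of the r-th ranked of
n is `ceil(10 r / n)`. Classification precedence is
EXON > NOVEL_INTRONIC > UPDOWN10K > ORPHAN with a 10 kb window, and every
gene satisfying the winning rule is linked (one mitochondrial-style SRE
can legitimately link several overlapping genes). Orphans additionally
carry their distance to the nearest gene span; `orphan_proximity` reports
the fraction within 30 kb, the signal that orphan elements are often
unannotated exons of nearby genes.

## Transcript integrity

TIN is the entropy-effective fraction of a transcript's exonic span that
is covered: with per-base depths `c_i` over `L` exonic bases and
`p_i = c_i / Σc` over covered bases, `TIN = 100 · exp(−Σ p_i ln p_i) / L`.
It is scale invariant, 0 iff nothing is covered, maximal for uniform
coverage, and equals `100 · f` exactly for uniform coverage of a fraction
`f`. Unlike the commonly used implementation, every exonic base enters the
computation (no position subsampling): at desk scale the exact computation
is cheap, deterministic, and testable against closed forms. When coverage
is exactly uniform over its support, the entropy is evaluated analytically
as `ln n` so the closed-form cases carry no floating-point round-off.
Fragmentation classes: fragmented (TIN ≤ 25), intact (TIN > 75),
intermediate between. Transcripts with zero coverage keep TIN = 0; any
abundance filter ("FPKM > 0 and TIN > 0") is applied by the caller, not
inside the operation. Transcript length for covariate correlations uses
CDS length where annotated, exonic length otherwise.

## Abundance statistics

- CV = sample (n−1) SD / mean, computed on normalized abundances
  (config-switchable to raw counts); classes stable (< 0.25), moderate
  (0.25–0.75 inclusive at both boundaries, reading "between" inclusively),
  unstable (> 0.75). Zero-mean features are flagged `undefined` and
  excluded from tallies.
- Gene stability requires unanimity: a gene is assigned a class only if
  every one of its SREs carries that class.
- Enrichment partition: a feature is X-enriched iff its FPKM in tissue X
  exceeds 40 and stays below 10 in both other tissues; at most one label
  can hold, everything else is `unassigned`. The 40/10 thresholds are the
  published partition rule for human testes/sperm/seminal-fluid reference
  profiles, which the user supplies.
- Across-fraction variability: one-way ANOVA plus all-pairs Tukey HSD
  (studentized range, via statsmodels); groups under 2 members are
  excluded with a warning.
- Over-representation: upper-tail hypergeometric p per gene set
  (sets intersected with the user-supplied universe first), Bonferroni
  over the number of sets tested. This replaces GO-tool dependencies with
  the same statistical skeleton over arbitrary GMT collections.
- De novo contig filter: identity > 85 % and FPKM > 50 strictly,
  detection in ≥ 5 samples inclusively.

## Small RNAs

piRNA clusters are called per sample from reads whose interval length is
26–33 nt inclusive: reads separated by ≤ `max_gap` (default 1,000 bp) are
merged, and merged intervals are kept iff the span is ≥ 5 kb and at least
`min_reads` (default 10) reads support it. The density model of the
reference caller is deliberately replaced by this declared
merge-and-threshold rule. A consensus step groups per-sample clusters
transitively by ≥ 1 bp overlap and keeps groups supported by ≥ 3 distinct
samples, emitting the union span; the output is invariant to sample
ordering. Multi-mapper weighting of small-RNA counts is not implemented;
raw counts are used (extension point). CPM = count × 1e6 / depth; the
miRNA detection filter demands a nonzero raw count in every sample.

## Seasonal differential abundance

`SeasonalCountModel.fit()` runs:

1. **Size factors** — median-of-ratios against the geometric-mean
   pseudo-reference over zero-free features, rescaled to geometric mean 1;
   total-count fallback (with a warning) if no zero-free feature exists.
2. **Dispersion** — method of moments, `alpha = (s² − mu)/mu²`, floored at
   `alpha_min = 1e-4`, then shrunk 50 % toward the median raw estimate of
   the feature's abundance decile. When the design is available the
   moments are computed within each season group and pooled by degrees of
   freedom: an all-sample variance would count a genuine seasonal shift as
   biological dispersion, which in measurements on planted data cut
   sensitivity for |log2FC| = 2 effects from ~0.9 to ~0.34. The
   design-free form remains available (`design=None`).
3. **NB Wald test** — per feature, `log mu = log(size factor) + intercept
   + batch + season` fitted by IRLS at fixed dispersion (working weights
   `mu/(1 + alpha·mu)`), batched across features in numpy since the design
   matrix is shared; iteration cap 50, coefficient tolerance 1e-6,
   non-converged features flagged with p = 1. The season coefficient is
   converted to log2FC and tested against the standard normal. The fit
   agrees with statsmodels' per-feature NB GLM to ~1e-4 relative
   (verified in the tests); it is not a numerical clone of any published
   DE package, whose empirical-Bayes shrinkage is intentionally out of
   scope.
4. **BH-FDR** — Benjamini–Hochberg step-up (statsmodels), validated
   against the literal step-up definition by brute force.
5. **Significance** — `q < 0.05` strictly, and `2^|log2FC| > 1.5`: the
   fold-change bound applies to the absolute fold change since
   down-regulated features with negative log2FC must qualify too.

Designs require ≥ 2 samples per season and batches not perfectly
confounded with season (checked via design-matrix rank).

## Synthetic cohorts

The generator emulates the structures this kind of study reports, and its
defaults are the package's study conditions:

| parameter | default | why |
|---|---|---|
| design | 5 summer + 5 winter, 2 batches | the cohort layout of a seasonal sperm study |
| abundance | log-normal, sdlog 1.65 | analytically puts ~65 % of read mass in the top decile of features (Φ(1.65 − 1.2816) ≈ 0.64), the published skew of the sperm transcriptome |
| covered fraction f | Beta(1, 3) | P(f ≤ 0.25) ≈ 0.58 and P(f > 0.75) ≈ 0.016 — most transcripts heavily fragmented, intact ones rare |
| read length | 75 nt | paired-end sperm libraries' read length |
| NB dispersion | 0.2 | moderate overdispersion typical of bulk RNA-seq counts |
| batch effect | 0.5 log2 | a realistic sequencing-run multiplier |
| planted log2FC | 20 features, 2–6 in magnitude, half per direction | a small seasonal signal against a null bulk |
| piRNA clusters | 2 planted (7–8 kb), density 0.05 reads/bp | above-background islands of 26–33 nt reads |
| miRNA loci | 2, 22 nt stacks | the miRNA length mode |
| genome | 2 × 1 Mb, 100 genes × 3 exons | small enough for second-scale runs, large enough for intergenic structure |

Fragmentation is a single contiguous covered window per transcript with
uniform expected coverage inside it (read starts may hang off either edge
and are clipped), which yields the closed form TIN = 100·f used by the
recovery tests; decaying or multi-window coverage profiles are config
extensions, not modelled. Reads are emitted as aligned blocks (a read
crossing an exon boundary contributes one interval per exon). Orphan read
clusters are auto-placed in the widest intergenic gaps with > 15 kb
clearance. One global seed drives everything through deterministic
per-generator substreams, so outputs are byte-identical across runs;
per-seed top-decile shares still fluctuate strongly (sd ≈ 13 points at
100 genes) because a single heavy-tail draw can dominate a small cohort —
calibration checks therefore average over seeds.

What the generator does **not** emulate: sequencing error, quality scores,
mappability structure, spliced multi-isoform transcripts, strand
asymmetry, multi-mapping small RNAs, or correlated sample effects beyond
one multiplicative batch. Passing tests show the algorithms implement
their definitions and recover planted structure under these idealized
conditions; they do not certify performance on real libraries.

## Numerical and design choices

- Problem sizes in the tests (2 × 1 Mb genomes, 100–500 genes, 2,000
  count features, 20 seeds for the statistical suites) are chosen so the
  whole suite runs in well under a minute while leaving the statistical
  assertions adequately powered.
- Boundary conventions are all explicit and tested: CV 0.25/0.75 →
  moderate; TIN 25 → fragmented, 75 → intermediate; enrichment strictly
  > 40 / strictly < 10; contig identity/FPKM strict, sample count
  inclusive; q = 0.05 not significant; FC bound strict; piRNA lengths
  26 and 33 inclusive; cluster span ≥ 5 kb inclusive; gene gap of exactly
  10 kb still UPDOWN10K (orphans are strictly beyond 10 kb).
- Decile ties break by (chrom, start) after mean abundance, making labels
  a deterministic, permutation-invariant function of the data.
- The repeat-class vocabulary {SINE, LINE1, LINE_other, LTR, DNA,
  simple_repeat, low_complexity, satellite, other} is assigned by
  class-string prefix; multi-class reads count once per class and once in
  the any-repeat total.
- An exact positional dedup utility exists but is off by default
  (duplicate removal is assumed upstream).

## Known limitations

- The SRE caller is not splice-aware; a spliced read contributes one
  interval per aligned block.
- Wald tests at n = 5 + 5 are approximate; the empirical null is verified
  (KS D < 0.05, false-positive proportion ≪ 0.05 at q < 0.05) but small-n
  anti-conservativeness of Wald inference is not corrected beyond that.
- Hypergeometric over-representation ignores gene-set hierarchies and
  inter-set dependence (Bonferroni is the only multiplicity handling).
- Tissue-enrichment reference FPKM profiles must be supplied by the user;
  none ship with the package.
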