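# spermkit

Toolkit for profiling the RNA cargo of mature sperm from bulk RNA-seq
alignments, built around the *sperm RNA element* (SRE) abstraction and a
seasonal (summer vs winter) differential-abundance stage.

Mature spermatozoa carry a sparse, heavily fragmented transcriptome:
whole-transcript quantification is unreliable, because most transcripts
survive only as pieces. `spermkit` therefore works at the level of SREs —
short genomic intervals defined directly by clustered read coverage — and
layers the downstream analyses a sperm RNA-seq study needs on top of them:

- **SRE calling & classification** — pooled per-base coverage is segmented
  into maximal covered intervals (inter-read gap ≤ `max_gap`, peak pooled
  coverage ≥ `min_support`); each SRE is quantified per sample in RPKM,
  ranked into abundance deciles, and classified with the precedence
  `EXON > NOVEL_INTRONIC > UPDOWN10K > ORPHAN` against a GFF/GTF
  annotation (orphans are > 10 kb from any gene).
- **Transcript integrity (TIN)** — for a transcript with per-base exonic
  depths `c_i` over `L` bases, with `p_i = c_i / Σc` over covered bases,

  ```
  H = −Σ p_i ln p_i        TIN = 100 · exp(H) / L
  ```

  so full uniform coverage scores exactly 100 and uniform coverage of a
  fraction `f` of the span scores exactly `100·f`. Classes: fragmented
  (TIN ≤ 25), intermediate, intact (TIN > 75).
- **Abundance statistics** — coefficient-of-variation stability classes
  (stable < 0.25, moderate 0.25–0.75, unstable > 0.75), all-SREs-agree
  gene-level stability, the testes/sperm/seminal-fluid enrichment
  partition (> 40 FPKM in one tissue, < 10 FPKM in the other two),
  one-way ANOVA + Tukey HSD across fractions, hypergeometric
  over-representation with Bonferroni correction, and the de novo contig
  filter (> 85 % identity, > 50 FPKM, ≥ 5 samples).
- **Repeats & lncRNAs** — per-class repeat read fractions with
  length-and-depth normalization, lncRNA detection, and candidate cis
  targets (coding genes < 20 kb from a lncRNA).
- **Small RNAs** — CPM normalization, the detected-in-all-samples miRNA
  filter, de novo piRNA cluster calling (26–33 nt reads, ≥ 5 kb span),
  a ≥ 3-samples reproducibility consensus, and repeat overlap.
- **Seasonal differential abundance** — a statsmodels-style
  `SeasonalCountModel` whose `fit()` returns `SeasonalDEResults`:
  median-of-ratios size factors, design-aware method-of-moments NB
  dispersion with decile-trend shrinkage, per-feature NB Wald tests of
  the season effect with batch adjustment, BH-FDR, and the significance
  rule `q < 0.05` and `|FC| > 1.5`.
- **Synthetic cohorts** — `SimulationConfig` + generators that plant known
  ground truth for every stage: heavy-tailed abundances (top decile ≈ 65 %
  of read mass), Beta-distributed covered fractions (TIN = 100·f closed
  form), planted log2 fold changes with batch structure, planted piRNA
  clusters and miRNA loci, and intergenic orphan read clusters.

## Worked example

```python
from spermkit import SimulationConfig, run_pipeline

res = run_pipeline(SimulationConfig(seed=1))
print(f"SREs called: {len(res.sres)}")
print(f"top-decile mass share: {res.decile_share[1]:.1f}%")
print(f"consensus piRNA clusters: {len(res.pirna_consensus)}")
print(res.de.summary(top=5))
```

prints

```
SREs called: 296
top-decile mass share: 70.4%
consensus piRNA clusters: 2
Seasonal differential abundance (NB Wald, summer vs winter)
============================================================
features tested:      2000
samples:              10 (5 summer / 5 winter)
significant (q < 0.05, |FC| > 1.5): 22 (10 up, 12 down in summer)

          log2fc             p             q       direction
F00009  5.845193  5.391120e-63  1.078224e-59    up_in_summer
F00007  5.822681  1.418814e-53  1.418814e-50    up_in_summer
F00008 -5.186784  6.294608e-37  4.196406e-34  down_in_summer
F00017  5.675111  6.285376e-35  3.142688e-32    up_in_summer
F00006 -4.128866  3.841234e-32  1.536494e-29  down_in_summer
```

296 SREs are called from the ten simulated samples; the most abundant
tenth of them carries 70 % of the abundance mass (the generator is
calibrated so this hovers around two thirds); both planted piRNA clusters
survive the ≥ 3-sample consensus; and the seasonal model recovers the
planted fold changes (features F00001–F00020 carry effects of |log2FC|
2–6; the q-values above are Benjamini–Hochberg adjusted).

The same stages are exposed on the command line for file-based input
(BED reads, GFF3/GTF annotation, TSV matrices):

```sh
spermkit simulate --seed 1 --out cohort/
spermkit sre cohort/reads_*.bed --annotation cohort/annotation.gff3 --out sres.tsv
spermkit de --counts cohort/counts.tsv --samples samples.tsv --out de.tsv
```

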